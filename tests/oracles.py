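"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation paths they check: alignment
scores come from exhaustive enumeration of all monotone alignments, motif
matching from a position-by-position token walk, and tree comparison from
bipartition sets.
"""
from __future__ import annotations

from Bio.Align import substitution_matrices

B62 = substitution_matrices.load("BLOSUM62")


def enumerate_global_score(a: str, b: str, gap_open: float = 10.0,
                           gap_extend: float = 0.5) -> float:
    """Optimal affine-gap global score by exhaustive alignment enumeration.

    Gap run of length L costs gap_open + (L-1)*gap_extend, matching the
    aligner convention.  Exponential — tiny sequences only.
    """
    best = [float("-inf")]

    def rec(i, j, score, last):
        if i == len(a) and j == len(b):
            if score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + B62[a[i], b[j]], "m")
        if i < len(a):
            cost = gap_extend if last == "a" else gap_open
            rec(i + 1, j, score - cost, "a")
        if j < len(b):
            cost = gap_extend if last == "b" else gap_open
            rec(i, j + 1, score - cost, "b")

    rec(0, 0, 0.0, "m")
    return best[0]


def brute_force_motif_scan(sequence: str, patterns) -> list[tuple[str, int]]:
    """Position-by-position degenerate-token matcher (no regex)."""
    hits = []
    for pat in patterns:
        w = len(pat.tokens)
        for start in range(len(sequence) - w + 1):
            ok = True
            for k, tok in enumerate(pat.tokens):
                if tok is not None and sequence[start + k] not in tok:
                    ok = False
                    break
            if ok:
                hits.append((pat.name, start))
    return sorted(hits)


def naive_fasta_parse(text: str) -> list[tuple[str, str]]:
    """Character-by-character FASTA join oracle."""
    records, name, chunks = [], None, []
    for line in text.splitlines():
        if line.startswith(">"):
            if name is not None:
                records.append((name, "".join(chunks)))
            name = line[1:].split()[0]
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    if name is not None:
        records.append((name, "".join(chunks)))
    return records


def random_additive_tree(n_leaves: int, rng):
    """A random binary tree with positive branch lengths and its leaf
    distance matrix (skbio TreeNode + numpy matrix)."""
    import numpy as np
    from skbio import TreeNode

    nodes = [TreeNode(name=f"t{i}") for i in range(n_leaves)]
    for t in nodes:
        t.length = float(rng.uniform(0.1, 1.0))
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(children=[nodes[i], nodes[j]])
        parent.length = float(rng.uniform(0.1, 1.0))
        nodes = [t for k, t in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode(children=nodes)
    names = sorted(t.name for t in root.tips())
    dm = root.tip_tip_distances(endpoints=names)
    return root, names, np.asarray(dm.data)
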