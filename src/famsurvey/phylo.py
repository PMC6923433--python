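"""Distance-based phylogeny: Poisson-corrected distances, neighbor joining,
column-bootstrap supports, and anchor-based subfamily assignment.

The procedure mirrors the classical survey workflow: align the family
proteins, drop every column containing a gap (complete deletion), convert
the observed difference fraction p to a Poisson-corrected distance
d = -ln(1 - p), build a neighbor-joining tree, and attach bootstrap
percentages obtained by resampling the retained columns with replacement.

Determinism is contractual: NJ ties on the Saitou-Nei Q criterion are broken
by the lexicographically smallest pair of cluster keys (a cluster's key is
the sorted tuple of its leaf names), and bootstrap resampling is driven by
an explicit seed, so taxon input order never changes the result.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix, TreeNode

from Bio.Align import substitution_matrices

D_MAX = 10.0  # cap for saturated (p -> 1) Poisson distances
_B62 = substitution_matrices.load("BLOSUM62")

_ALPHA = "ACDEFGHIKLMNPQRSTVWYX-"
_AIDX = {c: i for i, c in enumerate(_ALPHA)}
_GAP_SCORE = -8.0


@dataclass
class MultipleAlignment:
    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def complete_deletion_columns(self) -> list[int]:
        """Indices of columns containing no gap in any row."""
        return [
            j for j in range(self.n_columns)
            if all(r[j] != "-" for r in self.rows)
        ]


# ---------------------------------------------------------------------------
# progressive alignment

def _symbol_scores() -> np.ndarray:
    s = np.zeros((len(_ALPHA), len(_ALPHA)))
    for a in _ALPHA[:-1]:
        for b in _ALPHA[:-1]:
            s[_AIDX[a], _AIDX[b]] = _B62[a, b]
        s[_AIDX[a], _AIDX["-"]] = _GAP_SCORE
        s[_AIDX["-"], _AIDX[a]] = _GAP_SCORE
    return s


_SYM = _symbol_scores()


def _profile_counts(rows: list[str]) -> np.ndarray:
    arr = np.zeros((len(rows[0]), len(_ALPHA)))
    for r in rows:
        for j, c in enumerate(r):
            arr[j, _AIDX[c]] += 1
    return arr


def _align_profiles(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Needleman-Wunsch on two profiles with mean-of-pairs column scores.

    Linear gap penalty; traceback tie order diagonal > up > left.
    """
    ca, cb = _profile_counts(rows_a), _profile_counts(rows_b)
    na, nb = len(rows_a), len(rows_b)
    score = (ca @ _SYM @ cb.T) / (na * nb)
    gap_a = (ca @ _SYM[:, _AIDX["-"]]) / na  # align col of A to new gap col
    gap_b = (cb @ _SYM[:, _AIDX["-"]]) / nb
    la, lb = score.shape
    M = np.zeros((la + 1, lb + 1))
    M[1:, 0] = np.cumsum(gap_a)
    M[0, 1:] = np.cumsum(gap_b)
    ptr = np.zeros((la + 1, lb + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    ptr[1:, 0] = 1
    ptr[0, 1:] = 2
    for i in range(1, la + 1):
        diag = M[i - 1, :-1] + score[i - 1]
        up = M[i - 1, 1:] + gap_a[i - 1]
        row = M[i]
        for j in range(1, lb + 1):
            best, p = diag[j - 1], 0
            if up[j - 1] > best:
                best, p = up[j - 1], 1
            left = row[j - 1] + gap_b[j - 1]
            if left > best:
                best, p = left, 2
            row[j] = best
            ptr[i, j] = p
    out_a, out_b = [], []
    i, j = la, lb
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 0:
            out_a.append(i - 1); out_b.append(j - 1); i -= 1; j -= 1
        elif p == 1:
            out_a.append(i - 1); out_b.append(-1); i -= 1
        else:
            out_a.append(-1); out_b.append(j - 1); j -= 1
    out_a.reverse(); out_b.reverse()
    new_a = ["".join(r[k] if k >= 0 else "-" for k in out_a) for r in rows_a]
    new_b = ["".join(r[k] if k >= 0 else "-" for k in out_b) for r in rows_b]
    return new_a, new_b


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    def counts(s):
        d: dict[str, int] = {}
        for i in range(len(s) - k + 1):
            w = s[i:i + k]
            d[w] = d.get(w, 0) + 1
        return d
    ca, cb = counts(a), counts(b)
    shared = sum(min(n, cb.get(w, 0)) for w, n in ca.items())
    denom = max(min(len(a), len(b)) - k + 1, 1)
    return 1.0 - shared / denom


def progressive_align(records) -> MultipleAlignment:
    """Deterministic guide-tree progressive alignment of protein sequences.

    The guide tree is NJ on 3-mer count distances; profiles are merged in
    guide-tree postorder.  An externally aligned FASTA can be used instead
    of this aligner anywhere a MultipleAlignment is accepted.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("progressive alignment needs at least 2 sequences")
    ids = [r[0] for r in records]
    seqs = dict(records)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    if len(records) == 2:
        a, b = records
        ra, rb = _align_profiles([a[1]], [b[1]])
        return MultipleAlignment(ids=[a[0], b[0]], rows=[ra[0], rb[0]])
    n = len(records)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = _kmer_distance(records[i][1], records[j][1])
    guide = nj_tree(DistanceMatrix(dm, ids))
    # postorder merge of aligned blocks
    blocks: dict[int, tuple[list[str], list[str]]] = {}
    for node in guide.postorder(include_self=True):
        if node.is_tip():
            blocks[id(node)] = ([node.name], [seqs[node.name]])
        else:
            child_blocks = [blocks.pop(id(c)) for c in node.children]
            cur_ids, cur_rows = child_blocks[0]
            for nxt_ids, nxt_rows in child_blocks[1:]:
                cur_rows, nxt_aligned = _align_profiles(cur_rows, nxt_rows)
                cur_ids = cur_ids + nxt_ids
                cur_rows = cur_rows + nxt_aligned
            blocks[id(node)] = (cur_ids, cur_rows)
    out_ids, out_rows = blocks[id(guide)]
    order = {name: i for i, name in enumerate(ids)}
    pairs = sorted(zip(out_ids, out_rows), key=lambda t: order[t[0]])
    return MultipleAlignment(ids=[p[0] for p in pairs], rows=[p[1] for p in pairs])


def sum_of_pairs_score(aln: MultipleAlignment) -> float:
    total = 0.0
    for j in range(aln.n_columns):
        col = [r[j] for r in aln.rows]
        for x in range(len(col)):
            for y in range(x + 1, len(col)):
                a, b = col[x], col[y]
                if a == "-" and b == "-":
                    continue
                total += _GAP_SCORE if "-" in (a, b) else _B62[a, b]
    return total


# ---------------------------------------------------------------------------
# distances

def poisson_distance(aln: MultipleAlignment, columns=None) -> DistanceMatrix:
    """Poisson-corrected distance matrix over complete-deletion columns.

    p(i, j) is the fraction of differing residues over the retained columns;
    d = -ln(1 - p), capped at D_MAX when p is saturated.
    """
    cols = aln.complete_deletion_columns() if columns is None else list(columns)
    if len(aln.ids) < 2:
        raise ValueError("need at least 2 taxa")
    if not cols:
        raise ValueError("no complete-deletion columns available")
    n = len(aln.ids)
    mat = np.zeros((n, n))
    cap = 1.0 - math.exp(-D_MAX)
    for i in range(n):
        ri = aln.rows[i]
        for j in range(i + 1, n):
            rj = aln.rows[j]
            diff = sum(1 for c in cols if ri[c] != rj[c])
            p = diff / len(cols)
            d = D_MAX if p >= cap else -math.log(1.0 - p)
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, aln.ids)


def pairwise_poisson_matrix(records, gap_open: float = 15.0,
                            gap_extend: float = 2.0) -> DistanceMatrix:
    """Poisson-corrected distances from pairwise global alignments.

    For divergent families whose full multiple alignment retains almost no
    gap-free column, per-pair p-distances (differing fraction over columns
    where both sequences hold a residue) are the robust alternative to
    complete deletion on the joint alignment.  Gap costs are stiffer than
    the scoring defaults: cheap gap extension lets the optimal alignment of
    two unrelated proteins fragment into coincidentally matching islands,
    which deflates p exactly where it should saturate.
    """
    from . import align as _align  # local import to avoid a cycle

    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least 2 sequences")
    ids = [r[0] for r in records]
    n = len(ids)
    mat = np.zeros((n, n))
    cap = 1.0 - math.exp(-D_MAX)
    for i in range(n):
        for j in range(i + 1, n):
            pw = _align.global_align(records[i][1], records[j][1],
                                     gap_open=gap_open, gap_extend=gap_extend)
            cols = [(a, b) for a, b in zip(pw.a_aligned, pw.b_aligned)
                    if a != "-" and b != "-"]
            p = sum(1 for a, b in cols if a != b) / max(len(cols), 1)
            d = D_MAX if p >= cap else -math.log(1.0 - p)
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids)


# ---------------------------------------------------------------------------
# neighbor joining

def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Returns an unrooted tree rendered with a trifurcating root (2n-3
    branches).  Negative branch lengths are clamped to 0 for display; the
    raw value is kept on the node as ``raw_length``.
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    data = np.asarray(dm.data, dtype=float)
    if not np.allclose(data, data.T):
        raise ValueError("distance matrix is not symmetric")

    def make_tip(name):
        t = TreeNode(name=name)
        t.raw_length = None
        return t

    if n == 2:
        a, b = make_tip(ids[0]), make_tip(ids[1])
        half = data[0, 1] / 2.0
        for t in (a, b):
            t.length = max(half, 0.0)
            t.raw_length = half
        root = TreeNode(children=[a, b])
        return root

    keys = [(name,) for name in ids]                 # canonical cluster keys
    nodes = {(name,): make_tip(name) for name in ids}
    D = {keys[i]: {keys[j]: data[i, j] for j in range(n) if j != i} for i in range(n)}

    def attach(child: TreeNode, length: float) -> TreeNode:
        child.length = max(length, 0.0)
        child.raw_length = length
        return child

    while len(D) > 3:
        m = len(D)
        r = {k: sum(D[k].values()) for k in D}
        best = None
        for ki in D:
            for kj in D[ki]:
                if kj <= ki:
                    continue
                q = (m - 2) * D[ki][kj] - r[ki] - r[kj]
                cand = (q, ki, kj)
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and (ki, kj) < (best[1], best[2])
                ):
                    best = cand
        _, ki, kj = best
        dij = D[ki][kj]
        bi = dij / 2.0 + (r[ki] - r[kj]) / (2.0 * (m - 2))
        bj = dij - bi
        new_key = tuple(sorted(ki + kj))
        new_node = TreeNode(children=[attach(nodes.pop(ki), bi),
                                      attach(nodes.pop(kj), bj)])
        nodes[new_key] = new_node
        newD = {}
        for k in D:
            if k in (ki, kj):
                continue
            newD[k] = {k2: v for k2, v in D[k].items() if k2 not in (ki, kj)}
            duk = (D[ki][k] + D[kj][k] - dij) / 2.0
            newD[k][new_key] = duk
        newD[new_key] = {k: newD[k][new_key] for k in newD if k != new_key}
        D = newD

    (ka, kb, kc) = sorted(D)
    dab, dac, dbc = D[ka][kb], D[ka][kc], D[kb][kc]
    ba = (dab + dac - dbc) / 2.0
    bb = (dab + dbc - dac) / 2.0
    bc = (dac + dbc - dab) / 2.0
    root = TreeNode(children=[attach(nodes.pop(ka), ba),
                              attach(nodes.pop(kb), bb),
                              attach(nodes.pop(kc), bc)])
    return root


def tree_bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions, each normalized to the side excluding a
    fixed reference taxon (the lexicographically smallest leaf name)."""
    leaves = sorted(t.name for t in tree.tips())
    ref = leaves[0]
    allset = frozenset(leaves)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = allset - side
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out


def bootstrap_support(aln: MultipleAlignment, b_replicates: int, seed: int) -> TreeNode:
    """NJ tree with bootstrap percentages on internal edges.

    Complete deletion is applied first; replicates resample the retained
    columns with replacement.  Internal node names carry the integer
    support percentage.
    """
    if b_replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    cols = aln.complete_deletion_columns()
    base = nj_tree(poisson_distance(aln, columns=cols))
    counts: dict[frozenset, int] = {bp: 0 for bp in tree_bipartitions(base)}
    rng = np.random.default_rng(seed)
    cols_arr = np.asarray(sorted(cols))
    for _ in range(b_replicates):
        sample = rng.choice(cols_arr, size=len(cols_arr), replace=True)
        rep_tree = nj_tree(poisson_distance(aln, columns=sample.tolist()))
        rep_bps = tree_bipartitions(rep_tree)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    leaves = sorted(t.name for t in base.tips())
    ref, allset = leaves[0], frozenset(leaves)
    for node in base.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = allset - side
        if side in counts:
            node.name = str(round(100.0 * counts[side] / b_replicates))
    return base


def path_distance(tree: TreeNode, a: str, b: str) -> float:
    """Sum of branch lengths on the path between two leaves."""
    ta = tree.find(a)
    return ta.distance(tree.find(b))


# ---------------------------------------------------------------------------
# subfamily assignment

def assign_subfamilies(dm: DistanceMatrix, anchors: dict[str, str],
                       tol: float = 1e-9) -> dict[str, str]:
    """Assign each non-anchor taxon the subfamily of its nearest anchor group.

    ``anchors`` maps anchor taxon ids (e.g. Arabidopsis gene ids present in
    the distance matrix) to subfamily labels.  Distance to a group is the
    mean distance to its anchors; a tie within ``tol`` leaves the gene
    unassigned.
    """
    groups: dict[str, list[str]] = {}
    for aid, sub in anchors.items():
        if aid not in dm.ids:
            raise KeyError(f"anchor {aid!r} absent from distance matrix")
        groups.setdefault(sub, []).append(aid)
    out: dict[str, str] = {}
    for taxon in dm.ids:
        if taxon in anchors:
            continue
        dists = sorted(
            (float(np.mean([dm[taxon, a] for a in members])), sub)
            for sub, members in groups.items()
        )
        if len(dists) > 1 and dists[1][0] - dists[0][0] <= tol:
            out[taxon] = "unassigned"
        else:
            out[taxon] = dists[0][1]
    return out
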