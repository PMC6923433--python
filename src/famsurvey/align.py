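"""Pairwise protein alignment statistics for homology screening and
duplication calling.

Global alignments use affine gaps with EMBOSS-needle-style defaults
(BLOSUM62, open 10, extend 0.5; a gap of length L costs open + (L-1)*extend).
Local alignments are Smith-Waterman scored with BLAST-style gap costs
(open 11, extend 1) so the default Karlin-Altschul parameters
(lambda = 0.267, K = 0.041, the gapped BLOSUM62 constants) apply to the raw
score: E = K * m * n * exp(-lambda * S).

Statistics reported per pair:

* identity   — identical columns / alignment length
* similarity — positive-substitution columns / aligned residue-pair columns
  (the "aligned region": columns where both sequences hold a residue)
* coverage   — aligned residue-pair columns / length of the longer sequence

so identity <= similarity always holds (positives are a superset of
identities and there are never more pair columns than alignment columns),
and the statistics are insensitive to where co-optimal alignments place
their gaps.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .models import AA20

DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass
class PairwiseAlignment:
    a_aligned: str
    b_aligned: str
    score: float
    identity: float
    similarity: float
    coverage: float
    evalue: float | None = None


def _validate(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    bad = set(seq) - AA20 - {"X"}
    if bad:
        raise ValueError(f"{label}: invalid residues {sorted(bad)}")


def _aligner(mode: str, matrix, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.substitution_matrix = matrix if matrix is not None else _BLOSUM62
    al.open_gap_score = -float(gap_open)
    al.extend_gap_score = -float(gap_extend)
    return al


def _stats(a_row: str, b_row: str, matrix, len_a: int, len_b: int):
    ncol = len(a_row)
    ident = pos = npairs = 0
    for x, y in zip(a_row, b_row):
        if x == "-" or y == "-":
            continue
        npairs += 1
        if x == y:
            ident += 1
        if matrix[x, y] > 0:
            pos += 1
    if npairs == 0:
        return 0.0, 0.0, 0.0
    return ident / ncol, pos / npairs, npairs / max(len_a, len_b)


def global_align(a: str, b: str, matrix=None, gap_open: float = 10.0,
                 gap_extend: float = 0.5) -> PairwiseAlignment:
    """Optimal affine-gap global alignment of two protein sequences.

    The (a, b) order is canonicalized internally so that align(a, b) and
    align(b, a) return identical statistics even when co-optimal alignments
    exist.
    """
    _validate(a, "a"); _validate(b, "b")
    matrix = matrix if matrix is not None else _BLOSUM62
    swapped = b < a
    x, y = (b, a) if swapped else (a, b)
    aln = _aligner("global", matrix, gap_open, gap_extend).align(x, y)[0]
    r0, r1 = str(aln[0]), str(aln[1])
    if swapped:
        r0, r1 = r1, r0
    ident, sim, cov = _stats(r0, r1, matrix, len(a), len(b))
    return PairwiseAlignment(r0, r1, float(aln.score), ident, sim, cov)


def local_align_evalue(a: str, b: str, matrix=None, gap_open: float = 11.0,
                       gap_extend: float = 1.0, lam: float = DEFAULT_LAMBDA,
                       k: float = DEFAULT_K) -> PairwiseAlignment:
    """Smith-Waterman local alignment with a Karlin-Altschul E-value.

    E = K * m * n * exp(-lambda * S) with m, n the full sequence lengths and
    S the optimal raw local score (>= 0 by construction).
    """
    if lam <= 0 or k <= 0:
        raise ValueError("lambda and K must be positive")
    _validate(a, "a"); _validate(b, "b")
    matrix = matrix if matrix is not None else _BLOSUM62
    swapped = b < a
    x, y = (b, a) if swapped else (a, b)
    al = _aligner("local", matrix, gap_open, gap_extend)
    score = float(al.score(x, y))
    if score > 0:
        aln = al.align(x, y)[0]
        r0, r1 = str(aln[0]), str(aln[1])
        if swapped:
            r0, r1 = r1, r0
        ident, sim, cov = _stats(r0, r1, matrix, len(a), len(b))
    else:
        r0 = r1 = ""
        ident = sim = cov = 0.0
    ev = karlin_altschul_evalue(score, len(a), len(b), lam, k)
    return PairwiseAlignment(r0, r1, score, ident, sim, cov, evalue=ev)


def local_score(a: str, b: str, matrix=None, gap_open: float = 11.0,
                gap_extend: float = 1.0) -> float:
    """Optimal Smith-Waterman score only (no traceback; fast screening path)."""
    _validate(a, "a"); _validate(b, "b")
    return float(_aligner("local", matrix, gap_open, gap_extend).score(a, b))


def karlin_altschul_evalue(score: float, m: int, n: int,
                           lam: float = DEFAULT_LAMBDA, k: float = DEFAULT_K) -> float:
    return k * m * n * math.exp(-lam * score)
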