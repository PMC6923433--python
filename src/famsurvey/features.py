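"""Protein characterization and histidine-box motif scanning.

Desaturases carry short conserved histidine-rich boxes (part of the diiron
catalytic centre); membrane-bound subfamilies have three, the soluble
FAB2-type two.  The packaged patterns use a small degenerate grammar:

* an uppercase letter matches that residue;
* ``X`` matches any residue (wildcard);
* ``(Y)`` immediately after letter ``Z`` widens the previous token to the
  two-way alternative ``{Z, Y}`` (e.g. ``DAA(S)DEKRHE`` token 3 = {A, S}).

Molecular weights are average isotopic masses (residue masses + one water);
isoelectric points are solved by bisection on the net-charge curve using the
EMBOSS pKa table (N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5,
K 10.8, R 12.5, Y 10.1).
"""
from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .io import load_hbox_table
from .models import AA20

EMBOSS_PKA_POSITIVE = {"Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
EMBOSS_PKA_NEGATIVE = {"Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}

WATER_MW = 18.0153


class GrammarError(ValueError):
    pass


class StatsError(ValueError):
    pass


@dataclass
class ProteinStats:
    length: int
    molecular_weight: float
    isoelectric_point: float


@dataclass(frozen=True)
class MotifPattern:
    name: str
    subfamily: str
    tokens: tuple  # each token: frozenset of residues, or None for wildcard

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class MotifHit:
    pattern: str
    start: int  # 0-based residue offset
    match: str


# ---------------------------------------------------------------------------
# protein statistics

def molecular_weight(sequence: str) -> float:
    _check_alphabet(sequence)
    return float(ProteinAnalysis(sequence).molecular_weight())


def net_charge(sequence: str, ph: float) -> float:
    """Net protein charge at a given pH under the Henderson-Hasselbalch model."""
    counts = {aa: sequence.count(aa) for aa in "CDEHKRY"}
    charge = 1.0 / (1.0 + 10 ** (ph - EMBOSS_PKA_POSITIVE["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (EMBOSS_PKA_NEGATIVE["Cterm"] - ph))
    for aa in "KRH":
        charge += counts[aa] / (1.0 + 10 ** (ph - EMBOSS_PKA_POSITIVE[aa]))
    for aa in "DECY":
        charge -= counts[aa] / (1.0 + 10 ** (EMBOSS_PKA_NEGATIVE[aa] - ph))
    return charge


def isoelectric_point(sequence: str, tol: float = 1e-4) -> float:
    _check_alphabet(sequence)
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(sequence, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def _check_alphabet(sequence: str) -> None:
    if not sequence:
        raise StatsError("empty sequence")
    bad = [i for i, aa in enumerate(sequence) if aa not in AA20]
    if bad:
        raise StatsError(f"non-standard residues at 0-based positions {bad[:10]}")


def protein_stats(sequence: str) -> ProteinStats:
    return ProteinStats(
        length=len(sequence),
        molecular_weight=molecular_weight(sequence),
        isoelectric_point=isoelectric_point(sequence),
    )


# ---------------------------------------------------------------------------
# H-box grammar

def compile_hbox_pattern(pattern: str, name: str = "", subfamily: str = "") -> MotifPattern:
    """Compile a degenerate H-box string into a token list.

    Raises GrammarError with the 1-based column of the offending character.
    """
    tokens: list = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "(":
            if not tokens or tokens[-1] is None:
                raise GrammarError(f"col {i + 1}: '(' without preceding residue")
            if i + 2 >= len(pattern) or pattern[i + 2] != ")":
                raise GrammarError(f"col {i + 1}: dangling '('")
            alt = pattern[i + 1]
            if alt not in AA20:
                raise GrammarError(f"col {i + 2}: invalid alternative {alt!r}")
            tokens[-1] = tokens[-1] | frozenset({alt})
            i += 3
        elif ch == "X":
            tokens.append(None)
            i += 1
        elif ch in AA20:
            tokens.append(frozenset({ch}))
            i += 1
        else:
            raise GrammarError(f"col {i + 1}: invalid character {ch!r}")
    if not tokens:
        raise GrammarError("empty pattern")
    return MotifPattern(name=name or pattern, subfamily=subfamily, tokens=tuple(tokens))


def _pattern_regex(pattern: MotifPattern) -> re.Pattern:
    parts = []
    for tok in pattern.tokens:
        if tok is None:
            parts.append("[A-Z]")
        elif len(tok) == 1:
            parts.append(next(iter(tok)))
        else:
            parts.append("[" + "".join(sorted(tok)) + "]")
    return re.compile("(?=(" + "".join(parts) + "))")


def scan_hboxes(sequence: str, patterns) -> tuple[list[MotifHit], bool]:
    """All (possibly overlapping) occurrences of each pattern, by start.

    Returns (hits, complete) where ``complete`` is True iff every pattern of
    the set matches at least once — a False flag on a family member marks a
    truncated gene product missing one of its boxes.
    """
    hits: list[MotifHit] = []
    seen: set[str] = set()
    for pat in patterns:
        rx = _pattern_regex(pat)
        for m in rx.finditer(sequence):
            hits.append(MotifHit(pattern=pat.name, start=m.start(), match=m.group(1)))
            seen.add(pat.name)
    hits.sort(key=lambda h: (h.start, h.pattern))
    complete = all(p.name in seen for p in patterns)
    return hits, complete


def subfamily_patterns(subfamily: str | None = None) -> list[MotifPattern]:
    """Compiled packaged H-box patterns, optionally restricted to one subfamily."""
    df = load_hbox_table()
    if subfamily is not None:
        df = df[df["subfamily"] == subfamily]
        if df.empty:
            raise KeyError(f"no packaged H-box patterns for subfamily {subfamily!r}")
    return [
        compile_hbox_pattern(
            row.pattern, name=f"{row.subfamily}-box{row.box_index}", subfamily=row.subfamily
        )
        for row in df.itertuples()
    ]
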