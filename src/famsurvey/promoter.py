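"""Promoter extraction and strand-aware cis-regulatory element scanning.

Promoters are the 2000 bp immediately 5' of the ATG translational start
(first CDS base), reverse-complemented for minus-strand genes so the
returned string always reads toward the ATG.  Positions are reported
relative to the ATG: -1 is the base immediately 5' of the A, so a promoter
of length L spans -L..-1.  Hits on the complementary strand are reported at
the template-strand coordinate of their 5'-most template base.

The packaged element table uses PlantCARE-vocabulary consensi and is
explicitly user-replaceable; overlapping matches of one element are all
reported.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from .io import load_cis_elements
from .models import GeneModel

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class CisElement:
    name: str
    consensus: str
    category: str = ""

    def __post_init__(self):
        bad = set(self.consensus.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: invalid IUPAC codes {sorted(bad)}")


@dataclass(frozen=True)
class ElementHit:
    gene: str
    element: str
    position: int          # relative to ATG; 5'-most template base of the hit
    strand: str            # "template" | "complementary"
    match: str              # template-strand bases at the hit location


@dataclass
class Promoter:
    gene: str
    sequence: str
    truncated: bool = False


def default_elements() -> list[CisElement]:
    df = load_cis_elements()
    return [CisElement(r.name, r.consensus, r.category) for r in df.itertuples()]


def extract_promoter(genome: dict, model: GeneModel, length: int = 2000) -> Promoter:
    """Upstream promoter sequence of one gene model, strand-aware."""
    chrom = model.locus.chromosome
    if chrom not in genome:
        raise KeyError(f"{model.locus.locus_id}: chromosome {chrom} absent from genome")
    seq = genome[chrom]
    if not model.cds:
        raise ValueError(f"{model.mrna_id}: no CDS; cannot locate ATG")
    if model.locus.strand == "+":
        atg = min(s for s, _ in model.cds)      # 1-based first CDS base
        lo = max(atg - 1 - length, 0)
        prom = seq[lo:atg - 1]
    else:
        cds_end = max(e for _, e in model.cds)  # 1-based last genomic CDS base
        prom = str(Seq(seq[cds_end:cds_end + length]).reverse_complement())
    truncated = len(prom) < length
    if truncated:
        warnings.warn(
            f"{model.locus.locus_id}: promoter truncated to {len(prom)} bp at contig edge",
            stacklevel=2,
        )
    return Promoter(gene=model.locus.locus_id, sequence=prom.upper(), truncated=truncated)


def _iupac_regex(consensus: str) -> re.Pattern:
    parts = []
    for ch in consensus.upper():
        opts = IUPAC[ch]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("(?=(" + "".join(parts) + "))")


def scan_elements(promoter: Promoter | str, elements=None, gene: str | None = None) -> list[ElementHit]:
    """All element occurrences on both strands, ordered by (position, name).

    A complementary-strand hit is an occurrence of the reverse complement of
    the consensus on the template string; it is reported at template
    coordinates.
    """
    if isinstance(promoter, str):
        promoter = Promoter(gene=gene or "", sequence=promoter.upper())
    elements = default_elements() if elements is None else list(elements)
    seq = promoter.sequence
    L = len(seq)
    hits: list[ElementHit] = []
    for el in elements:
        for strand, consensus in (
            ("template", el.consensus),
            ("complementary", str(Seq(el.consensus).reverse_complement())),
        ):
            for m in _iupac_regex(consensus).finditer(seq):
                hits.append(ElementHit(
                    gene=promoter.gene, element=el.name,
                    position=m.start() - L, strand=strand, match=m.group(1),
                ))
    hits.sort(key=lambda h: (h.position, h.element, h.strand))
    return hits


def summarize_elements(hits, genes=None, elements=None) -> pd.DataFrame:
    """Gene x element count matrix with a per-cell ``multiple`` (>=2) notion.

    Returns a long-format frame (gene, element, count, multiple) covering
    every requested gene/element combination, including zero rows.
    """
    elements = default_elements() if elements is None else list(elements)
    names = [e.name for e in elements]
    if genes is None:
        genes = sorted({h.gene for h in hits})
    counts = {(g, n): 0 for g in genes for n in names}
    for h in hits:
        if (h.gene, h.element) in counts:
            counts[(h.gene, h.element)] += 1
    rows = [
        {"gene": g, "element": n, "count": counts[(g, n)],
         "multiple": counts[(g, n)] >= 2}
        for g in genes for n in names
    ]
    return pd.DataFrame(rows)
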