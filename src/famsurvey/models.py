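"""Shared domain types for the gene-family survey pipeline.

Coordinates are 1-based and inclusive throughout the public API (GFF3
convention); any half-open arithmetic is internal to individual functions.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

SUBFAMILIES = ("FAB2", "FAD2", "FAD3/7/8", "FAD6", "DES1", "SLD1", "unassigned")

AA20 = set("ACDEFGHIKLMNPQRSTVWY")

_MSU_LOCUS_RE = re.compile(r"^LOC_Os(\d{2})g\d+")


def chromosome_from_locus_id(locus_id: str) -> int | None:
    """Parse the chromosome number from an MSU-style ``LOC_OsNNgXXXXX`` id.

    Returns None when the id does not follow the convention; callers must
    then supply the chromosome explicitly (e.g. from the GFF3 seqid).
    """
    m = _MSU_LOCUS_RE.match(locus_id)
    return int(m.group(1)) if m else None


@dataclass(frozen=True)
class GeneLocus:
    """Genomic identity of one gene: id, chromosome, span, strand, rank.

    ``ordinal`` is the 1-based rank of this gene among *all* annotated genes
    on its chromosome sorted by start coordinate; the tandem-duplication
    rule counts intervening genes with it.
    """

    locus_id: str
    chromosome: int
    start: int
    end: int
    strand: str
    ordinal: int | None = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.locus_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_id}: strand must be '+' or '-'")
        parsed = chromosome_from_locus_id(self.locus_id)
        if parsed is not None and parsed != self.chromosome:
            raise ValueError(
                f"{self.locus_id}: id encodes chromosome {parsed}, got {self.chromosome}"
            )


@dataclass
class GeneModel:
    """One transcript: exon/CDS/UTR intervals of a gene, in transcription order.

    Intervals are (start, end) 1-based inclusive genomic coordinates.  A CDS
    whose total length is not divisible by 3 is flagged (``cds_frame_ok``)
    rather than rejected: truncated gene models occur in real annotations.
    """

    locus: GeneLocus
    mrna_id: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        for name, ivs in (("exon", self.exons), ("CDS", self.cds)):
            for s, e in ivs:
                if s > e:
                    raise ValueError(f"{self.mrna_id}: bad {name} interval ({s},{e})")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.mrna_id}: overlapping exons")
        # store exons/CDS in transcription order (5'->3')
        rev = self.locus.strand == "-"
        self.exons = sorted(self.exons, reverse=rev)
        self.cds = sorted(self.cds, reverse=rev)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def cds_frame_ok(self) -> bool:
        return self.cds_length % 3 == 0


@dataclass
class ProteinRecord:
    id: str
    sequence: str
    annotation: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.id}: empty protein sequence")
        bad = set(self.sequence) - AA20 - {"X"}
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def has_ambiguous(self) -> bool:
        return "X" in self.sequence


@dataclass
class FamilyGene:
    """One named member of the surveyed gene family."""

    name: str
    locus: GeneLocus
    protein: ProteinRecord
    subfamily: str = "unassigned"
    ortholog_anchor: str = ""
    flags: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.subfamily not in SUBFAMILIES:
            raise ValueError(f"{self.name}: unknown subfamily {self.subfamily!r}")
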