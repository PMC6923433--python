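"""Gene-structure statistics (introns, phases, UTRs) and chromosome counts.

Intron counting is CDS-based: introns are the gaps between consecutive CDS
intervals of a transcript, matching the convention of reporting "introns in
the coding sequence".  Introns lying wholly within UTRs are counted
separately and excluded from the headline number.  The phase of an intron
is the number of bases of the interrupted codon already emitted 5' of it
(cumulative CDS length mod 3).
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .models import GeneLocus, GeneModel


@dataclass
class StructureStats:
    gene: str
    n_exons: int
    n_introns: int
    intron_phases: list[int]
    has_utr5: bool
    has_utr3: bool
    transcript_length: int
    n_utr_introns: int = 0
    cds_frame_ok: bool = True


def intron_stats(model: GeneModel) -> StructureStats:
    """Intron count, phases, and UTR presence for one gene model."""
    if not model.cds:
        raise ValueError(f"{model.mrna_id}: gene model has no CDS")
    cds = model.cds  # transcription order
    phases = []
    cum = 0
    for s, e in cds[:-1]:
        cum += e - s + 1
        phases.append(cum % 3)
    n_cds_introns = len(cds) - 1
    total_introns = len(model.exons) - 1
    return StructureStats(
        gene=model.locus.locus_id,
        n_exons=len(model.exons),
        n_introns=n_cds_introns,
        intron_phases=phases,
        has_utr5=bool(model.utr5),
        has_utr3=bool(model.utr3),
        transcript_length=sum(e - s + 1 for s, e in model.exons),
        n_utr_introns=max(total_introns - n_cds_introns, 0),
        cds_frame_ok=model.cds_frame_ok,
    )


@dataclass
class ChromosomeDistribution:
    counts: dict[int, int]
    occupied: set[int] = field(default_factory=set)

    @property
    def n_occupied(self) -> int:
        return len(self.occupied)

    def missing(self, n_chromosomes: int) -> set[int]:
        return set(range(1, n_chromosomes + 1)) - self.occupied


def chromosome_distribution(loci) -> ChromosomeDistribution:
    """Per-chromosome gene counts and the set of occupied chromosomes."""
    counts = Counter(
        loc.chromosome if isinstance(loc, GeneLocus) else int(loc) for loc in loci
    )
    return ChromosomeDistribution(counts=dict(counts), occupied=set(counts))


def structure_table(stats_list) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": s.gene,
            "n_exons": s.n_exons,
            "n_introns": s.n_introns,
            "phases": ",".join(map(str, s.intron_phases)),
            "utr5": s.has_utr5,
            "utr3": s.has_utr3,
            "transcript_length": s.transcript_length,
        }
        for s in stats_list
    )
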