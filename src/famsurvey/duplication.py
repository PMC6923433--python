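"""Tandem and segmental duplication classification within a gene family.

Two explicit pairwise rules drive the calls:

* tandem  — same chromosome, fewer than 5 annotated genes between the two
  loci (genome-wide gene ordinals, any strand), and >50% protein identity
  under global alignment; qualifying pairs are closed into clusters by
  single linkage.
* segmental — alignable region covering >75% of the longer protein and
  >75% similarity (positive substitutions) within that region; both
  inequalities strict.  Pairs inside one tandem cluster are excluded so
  each mechanism is reported per distinct partner; a gene may still carry
  both labels via different partners.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from . import align
from .models import FamilyGene


@dataclass
class PairEvidence:
    gene_a: str
    gene_b: str
    intervening: int | None
    identity: float
    similarity: float
    coverage: float


@dataclass
class DuplicationCall:
    type: str  # "tandem" | "segmental"
    members: list[str]
    chromosomes: list[int]
    evidence: list[PairEvidence] = field(default_factory=list)


def _pair_stats(a: FamilyGene, b: FamilyGene) -> align.PairwiseAlignment:
    return align.global_align(a.protein.sequence, b.protein.sequence)


def call_tandem(family: list[FamilyGene], gene_order: dict[int, list[str]],
                max_intervening: int = 4, min_identity: float = 0.5) -> list[DuplicationCall]:
    """Tandem clusters: single-linkage closure of qualifying pairs.

    ``gene_order`` maps chromosome -> all annotated locus ids sorted by
    start (from the genome annotation, not just the family).
    """
    ordinal: dict[str, int] = {}
    for chrom, ids in gene_order.items():
        for rank, lid in enumerate(ids, 1):
            ordinal[lid] = rank
    for g in family:
        if g.locus.locus_id not in ordinal:
            raise KeyError(f"locus {g.locus.locus_id} has no genome-wide ordinal")

    qualifying: list[PairEvidence] = []
    adj: dict[str, set[str]] = {g.name: set() for g in family}
    genes = sorted(family, key=lambda g: (g.locus.chromosome, g.locus.start, g.name))
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            if a.locus.chromosome != b.locus.chromosome:
                continue
            between = abs(ordinal[a.locus.locus_id] - ordinal[b.locus.locus_id]) - 1
            if between > max_intervening:
                continue
            pw = _pair_stats(a, b)
            if pw.identity > min_identity:
                qualifying.append(PairEvidence(a.name, b.name, between,
                                               pw.identity, pw.similarity, pw.coverage))
                adj[a.name].add(b.name)
                adj[b.name].add(a.name)

    calls: list[DuplicationCall] = []
    seen: set[str] = set()
    by_name = {g.name: g for g in family}
    for g in genes:
        if g.name in seen or not adj[g.name]:
            continue
        stack, cluster = [g.name], set()
        while stack:
            cur = stack.pop()
            if cur in cluster:
                continue
            cluster.add(cur)
            stack.extend(adj[cur] - cluster)
        seen |= cluster
        members = sorted(cluster, key=lambda n: by_name[n].locus.start)
        calls.append(DuplicationCall(
            type="tandem", members=members,
            chromosomes=sorted({by_name[n].locus.chromosome for n in members}),
            evidence=[e for e in qualifying if e.gene_a in cluster and e.gene_b in cluster],
        ))
    calls.sort(key=lambda c: (c.chromosomes, c.members))
    return calls


def call_segmental(family: list[FamilyGene], tandem_calls=None,
                   min_coverage: float = 0.75,
                   min_similarity: float = 0.75) -> list[DuplicationCall]:
    """Segmental pairs: coverage > min_coverage and similarity > min_similarity."""
    tandem_sets = [set(c.members) for c in (tandem_calls or [])]
    calls: list[DuplicationCall] = []
    genes = sorted(family, key=lambda g: g.name)
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            if any({a.name, b.name} <= ts for ts in tandem_sets):
                continue
            pw = _pair_stats(a, b)
            if pw.coverage > min_coverage and pw.similarity > min_similarity:
                calls.append(DuplicationCall(
                    type="segmental", members=sorted([a.name, b.name]),
                    chromosomes=sorted({a.locus.chromosome, b.locus.chromosome}),
                    evidence=[PairEvidence(a.name, b.name, None, pw.identity,
                                           pw.similarity, pw.coverage)],
                ))
    calls.sort(key=lambda c: c.members)
    return calls


@dataclass
class DuplicationSummary:
    n_tandem_genes: int
    n_segmental_genes: int
    n_duplicated_genes: int
    family_size: int
    percent_duplicated: float
    overlap: list[str]  # genes carrying both labels

    @property
    def fraction_duplicated(self) -> float:
        return self.percent_duplicated / 100.0


def duplication_summary(tandem_calls, segmental_calls, family_size: int) -> DuplicationSummary:
    tandem_genes = {m for c in tandem_calls for m in c.members}
    seg_genes = {m for c in segmental_calls for m in c.members}
    union = tandem_genes | seg_genes
    pct = 100.0 * len(union) / family_size if family_size else 0.0
    return DuplicationSummary(
        n_tandem_genes=len(tandem_genes),
        n_segmental_genes=len(seg_genes),
        n_duplicated_genes=len(union),
        family_size=family_size,
        percent_duplicated=round(pct, 1),
        overlap=sorted(tandem_genes & seg_genes),
    )
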