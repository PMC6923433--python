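"""Three-route candidate identification, redundancy removal and naming.

Candidates come from (1) domain evidence — an external profile-search hit
table, or the internal fallback of requiring at least two histidine-box
matches; (2) a local-alignment homology screen against query proteins at a
configurable E-value ceiling (default 1e-10); (3) a case-insensitive
keyword screen over the functional annotation table.  Evidence is merged
by locus, one representative transcript is kept per locus (longest CDS,
ties broken by the lowest ``.N`` splice-variant suffix), and members are
named ``Os<SUBFAMILY>-<k>`` within each subfamily by chromosomal position
(singleton subfamilies are unnumbered).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from . import align as _align
from .features import scan_hboxes, subfamily_patterns
from .models import FamilyGene, GeneLocus, ProteinRecord

DEFAULT_EVALUE_MAX = 1e-10

# the classical Arabidopsis desaturase query anchors used for the screen
DEFAULT_QUERY_IDS = {
    "AT3G12120": "FAD2", "AT2G43710": "FAB2", "AT4G04930": "DES1",
    "AT2G46210": "SLD1", "AT1G06080": "ADS1",
}


@dataclass
class CandidateEvidence:
    locus_id: str
    sources: set[str] = field(default_factory=set)
    best_evalue: float | None = None
    matched_query: str | None = None

    def __post_init__(self):
        if not self.sources:
            raise ValueError(f"{self.locus_id}: evidence with no source")
        if ("homology" in self.sources) != (self.best_evalue is not None):
            raise ValueError(f"{self.locus_id}: best_evalue present iff homology source")


_SUFFIX_RE = re.compile(r"\.(\d+)$")


def locus_of(protein_id: str) -> str:
    """Strip a splice-variant ``.N`` suffix from a transcript/protein id."""
    return _SUFFIX_RE.sub("", protein_id)


def variant_number(protein_id: str) -> int:
    m = _SUFFIX_RE.search(protein_id)
    return int(m.group(1)) if m else 1


# ---------------------------------------------------------------------------
# screens

def domain_screen(proteome, domain_hits: pd.DataFrame | None = None,
                  hbox_fallback: bool = True, min_boxes: int = 2):
    """Loci with protein-domain evidence.

    ``domain_hits`` is a precomputed hit table with columns
    (protein_id, domain_id, evalue) from an external profile search.  When
    it is absent and ``hbox_fallback`` is enabled, a protein qualifies if it
    carries at least ``min_boxes`` packaged histidine-box matches.  Returns
    (locus set, mode string recorded in provenance).
    """
    if domain_hits is not None:
        required = {"protein_id", "domain_id", "evalue"}
        if not required <= set(domain_hits.columns):
            raise ValueError(f"domain hit table needs columns {sorted(required)}")
        return {locus_of(p) for p in domain_hits["protein_id"]}, "hit_table"
    if not hbox_fallback:
        raise ValueError("no domain evidence: provide a hit table or enable the "
                         "H-box fallback")
    patterns = subfamily_patterns()
    loci = set()
    for pid, seq in proteome:
        hits, _ = scan_hboxes(seq, patterns)
        if len(hits) >= min_boxes:
            loci.add(locus_of(pid))
    return loci, "hbox_fallback"


def homology_screen(queries, proteome, evalue_max: float = DEFAULT_EVALUE_MAX,
                    score_cutoff: bool = True) -> list[CandidateEvidence]:
    """Best local-alignment E-value of every proteome entry across queries.

    Entries are kept iff E <= evalue_max.  The Smith-Waterman score is
    computed first (fast path); the E-value uses the Karlin-Altschul
    formula with the module defaults.
    """
    queries = list(queries)
    if not queries:
        raise ValueError("empty query set")
    evidence: dict[str, CandidateEvidence] = {}
    for pid, seq in proteome:
        best_e, best_q = None, None
        for qid, qseq in queries:
            s = _align.local_score(qseq, seq)
            e = _align.karlin_altschul_evalue(s, len(qseq), len(seq))
            if best_e is None or e < best_e:
                best_e, best_q = e, qid
        if best_e is not None and best_e <= evalue_max:
            lid = locus_of(pid)
            prev = evidence.get(lid)
            if prev is None or best_e < prev.best_evalue:
                evidence[lid] = CandidateEvidence(
                    locus_id=lid, sources={"homology"},
                    best_evalue=best_e, matched_query=best_q)
    return sorted(evidence.values(), key=lambda e: e.locus_id)


def keyword_screen(annotations: pd.DataFrame,
                   phrase: str = "fatty acid desaturase") -> set[str]:
    """Case-insensitive substring match of ``phrase`` in the description."""
    needle = phrase.lower()
    return {
        row.locus_id for row in annotations.itertuples()
        if needle in str(row.description).lower()
    }


# ---------------------------------------------------------------------------
# merge + naming

def merge_and_deduplicate(evidence_sets, proteome, annotation,
                          manual_include=(), manual_ids=None):
    """Union evidence by locus; keep one representative transcript per locus.

    ``evidence_sets`` is an iterable of either locus-id sets or
    CandidateEvidence lists.  ``annotation`` is a GenomeAnnotation (for loci
    and CDS lengths).  ``manual_include`` loci are added with a
    ``manual_include`` flag (the precedent of retaining a known truncated
    member that the domain screen misses).

    Returns a list of FamilyGene with subfamily unassigned.
    """
    merged: dict[str, CandidateEvidence] = {}

    def add(lid, sources, evalue=None, query=None):
        cur = merged.get(lid)
        if cur is None:
            merged[lid] = CandidateEvidence(
                locus_id=lid, sources=set(sources),
                best_evalue=evalue, matched_query=query)
        else:
            new_sources = cur.sources | set(sources)
            best_e, best_q = cur.best_evalue, cur.matched_query
            if evalue is not None and (best_e is None or evalue < best_e):
                best_e, best_q = evalue, query
            if "homology" not in new_sources:
                best_e = best_q = None
            merged[lid] = CandidateEvidence(
                locus_id=lid, sources=new_sources,
                best_evalue=best_e, matched_query=best_q)

    for ev_set in evidence_sets:
        for item in ev_set:
            if isinstance(item, CandidateEvidence):
                add(item.locus_id, item.sources, item.best_evalue, item.matched_query)
            else:
                add(str(item), {"screen"})
    for lid in manual_include:
        if lid not in annotation.loci:
            raise KeyError(f"manual include {lid!r} absent from annotation")
        add(lid, {"manual"})
        merged[lid].sources.add("manual")

    proteins = {pid: seq for pid, seq in proteome}
    cds_len = {m.mrna_id: m.cds_length for m in annotation.models}

    out: list[FamilyGene] = []
    for lid in sorted(merged):
        if lid not in annotation.loci:
            continue  # evidence for loci outside the annotation is dropped
        variants = [pid for pid in proteins if locus_of(pid) == lid]
        if not variants:
            continue
        variants.sort(key=lambda p: (-cds_len.get(p, 3 * len(proteins[p])),
                                     variant_number(p)))
        rep = variants[0]
        flags = set()
        if "manual" in merged[lid].sources:
            flags.add("manual_include")
        out.append(FamilyGene(
            name=lid, locus=annotation.loci[lid],
            protein=ProteinRecord(rep, proteins[rep]),
            flags=flags,
        ))
    return out


def assign_family_names(candidates: list[FamilyGene], subfamilies: dict[str, str],
                        overrides: dict[str, str] | None = None,
                        prefix: str = "Os") -> list[FamilyGene]:
    """Name members ``Os<SUBFAMILY>-<k>`` positionally within subfamilies.

    ``subfamilies`` maps locus id -> subfamily label; numbering follows
    (chromosome, start) ascending; subfamilies with a single member are
    unnumbered.  ``overrides`` (locus id -> final name) is applied last and
    must not introduce duplicate names.
    """
    overrides = overrides or {}
    if len(set(overrides.values())) != len(overrides):
        raise ValueError("duplicate names in override map")
    for g in candidates:
        g.subfamily = subfamilies.get(g.locus.locus_id, "unassigned")
    by_sub: dict[str, list[FamilyGene]] = {}
    for g in candidates:
        by_sub.setdefault(g.subfamily, []).append(g)
    for sub, genes in by_sub.items():
        genes.sort(key=lambda g: (g.locus.chromosome, g.locus.start))
        label = sub.split("/")[0] if "/" in sub else sub
        for k, g in enumerate(genes, 1):
            if sub == "unassigned":
                continue
            g.name = f"{prefix}{label}" if len(genes) == 1 else f"{prefix}{label}-{k}"
    for g in candidates:
        if g.locus.locus_id in overrides:
            g.name = overrides[g.locus.locus_id]
    names = [g.name for g in candidates]
    if len(set(names)) != len(names):
        raise ValueError("naming produced duplicates")
    return sorted(candidates, key=lambda g: (g.locus.chromosome, g.locus.start))
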