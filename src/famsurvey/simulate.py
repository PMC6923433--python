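"""Synthetic annotated genomes, proteomes, promoters, expression matrices
and Ct tables with machine-readable planted truth.

The generator emulates the statistical structure a gene-family survey
assumes: a multi-chromosome genome whose annotated gene set contains a
planted desaturase-like family organised into subfamilies, with tandem
arrays (few intervening genes, controlled protein identity), diverged
segmental duplicate pairs (controlled coverage/similarity), histidine-box
motifs planted at recorded positions, 2-kb promoters carrying planted
cis-elements on both strands, tissue x gene expression with four group
archetypes, and qPCR Ct tables with known fold changes.

Everything is driven by one mandatory seed; identical seeds give
byte-identical outputs.  Background sequences are rejection-corrected so
that they contain no accidental H-box or cis-element matches, making
false-positive tests exact.  Planted identity/coverage/similarity targets
are verified with the package's own alignment module before emission and
resampled (bounded retries) until within +/-0.03.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from . import align as _align
from .expression import ExpressionMatrix, QpcrTable
from .features import MotifPattern, scan_hboxes, subfamily_patterns
from .promoter import CisElement, Promoter, default_elements, scan_elements

_B62 = substitution_matrices.load("BLOSUM62")
_AA = "ACDEFGHIKLMNPQRSTVWY"
_CODONS = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()

# residues scoring <= 0 against each residue: substitutions drawn from these
# sets keep planted similarity targets exact (no accidental positives)
_NONPOS = {a: [b for b in _AA if b != a and _B62[a, b] <= 0] for a in _AA}
# mildly negative partners (score in [-1, 0] where available): dense runs of
# such substitutions cost less than a gap, so the optimal alignment keeps
# them aligned and planted similarity targets survive re-alignment
_MILDNEG = {
    a: ([b for b in _AA if b != a and -1 <= _B62[a, b] <= 0] or _NONPOS[a])
    for a in _AA
}

MAX_RETRIES = 25


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration and truth

@dataclass
class TandemSpec:
    size: int = 3
    intervening: int = 2          # background genes between adjacent members
    identity: float = 0.6


@dataclass
class SegmentalSpec:
    coverage: float = 0.85
    similarity: float = 0.85


@dataclass
class FamilySimConfig:
    seed: int
    n_chromosomes: int = 6
    n_background_genes: int = 14       # per chromosome
    protein_length: int = 200
    subfamily_sizes: dict = field(default_factory=lambda: {
        "FAD2": 4, "FAB2": 9, "FAD3/7/8": 4, "FAD6": 1, "DES1": 1, "SLD1": 1,
    })
    tandem_specs: list = field(default_factory=lambda: [
        TandemSpec(size=3, intervening=2, identity=0.6),
        TandemSpec(size=2, intervening=1, identity=0.6),
    ])
    segmental_specs: list = field(default_factory=lambda: [
        SegmentalSpec(0.85, 0.85), SegmentalSpec(0.85, 0.85),
    ])
    subthreshold_segmental: SegmentalSpec | None = field(
        default_factory=lambda: SegmentalSpec(0.5, 0.5))
    member_divergence: float = 0.4     # mutated fraction for ordinary members
    anchor_divergence: float = 0.3
    include_truncated: bool = True     # one member missing its final H-box
    include_splice_variant: bool = True
    n_promoter_genes: int = 9
    promoter_spec: dict = field(default_factory=lambda: {
        "ABRE": [(-150, "template"), (-420, "template")],
        "MBS": [(-800, "complementary")],
        "LTR": [(-1200, "template")],
        "ARE": [(-600, "template")],
    })
    intergenic: int = 2300
    promoter_length: int = 2000

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        for s in self.segmental_specs:
            if not (0 < s.coverage <= 1 and 0 < s.similarity <= 1):
                raise ConfigError("coverage/similarity targets must be in (0, 1]")
        for t in self.tandem_specs:
            if not 0 < t.identity <= 1:
                raise ConfigError("identity targets must be in (0, 1]")


_ANCHOR_IDS = {
    "FAD2": "AT3G12120", "FAB2": "AT2G43710", "FAD3/7/8": "AT2G29980",
    "FAD6": "AT4G30950", "DES1": "AT4G04930", "SLD1": "AT2G46210",
}


@dataclass
class TruthRecord:
    family_loci: list = field(default_factory=list)       # locus ids
    subfamily: dict = field(default_factory=dict)         # locus -> subfamily
    tandem_clusters: list = field(default_factory=list)   # lists of locus ids
    segmental_pairs: list = field(default_factory=list)   # [locus_a, locus_b]
    subthreshold_pairs: list = field(default_factory=list)
    hbox_hits: dict = field(default_factory=dict)         # locus -> [[pattern, start]]
    truncated: list = field(default_factory=list)
    splice_variants: dict = field(default_factory=dict)   # locus -> [mrna ids]
    promoter_elements: dict = field(default_factory=dict) # locus -> [[el, pos, strand]]
    intron_counts: dict = field(default_factory=dict)     # mrna -> n introns

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# protein construction

def _random_protein(rng, length: int) -> list[str]:
    return list(rng.choice(list(_AA), size=length))


def _clean_against_patterns(seq: list[str], patterns, rng, keep=()) -> list[str]:
    """Mutate residues until no pattern matches outside the kept spans."""
    kept = [(s, s + n) for s, n in keep]
    for _ in range(200):
        hits, _c = scan_hboxes("".join(seq), patterns)
        bad = [h for h in hits
               if not any(s <= h.start and h.start + len(h.match) <= e for s, e in kept)]
        if not bad:
            return seq
        for h in bad:
            span = [i for i in range(h.start, h.start + len(h.match))
                    if not any(s <= i < e for s, e in kept)]
            if not span:
                continue
            pos = int(rng.choice(span))
            seq[pos] = str(rng.choice([a for a in _AA if a != seq[pos]]))
    raise ConfigError("could not scrub accidental motif matches from background")


def _realize_pattern(pat: MotifPattern, rng) -> str:
    out = []
    for tok in pat.tokens:
        if tok is None:
            out.append(str(rng.choice(list(_AA))))
        else:
            out.append(str(rng.choice(sorted(tok))))
    return "".join(out)


def _box_positions(length: int, patterns) -> list[int]:
    anchors = [0.10, 0.35, 0.70]
    pos = []
    for k, pat in enumerate(patterns):
        p = int(anchors[k % 3] * length)
        pos.append(p)
    for (a, pa), (b, pb) in zip(zip(pos, patterns), zip(pos[1:], patterns[1:])):
        if a + len(pa) >= b:
            raise ConfigError("protein too short for the requested H-box set")
    if pos[-1] + len(patterns[-1]) > length:
        raise ConfigError("protein too short for the requested H-box set")
    return pos


def _plant_boxes(seq: list[str], patterns, positions, rng) -> list[tuple[str, int]]:
    truth = []
    for pat, pos in zip(patterns, positions):
        real = _realize_pattern(pat, rng)
        seq[pos:pos + len(real)] = list(real)
        truth.append((pat.name, pos))
    return truth


def _build_subfamily_ancestor(subfamily, length, rng, all_patterns):
    pats = subfamily_patterns(subfamily)
    positions = _box_positions(length, pats)
    seq = _random_protein(rng, length)
    keep = [(p, len(pat)) for p, pat in zip(positions, pats)]
    truth = _plant_boxes(seq, pats, positions, rng)
    seq = _clean_against_patterns(seq, all_patterns, rng, keep=keep)
    # planting realizations then cleaning may not disturb boxes; verify
    hits, _ = scan_hboxes("".join(seq), pats)
    assert {(h.pattern, h.start) for h in hits} >= set(truth)
    return seq, pats, positions, truth


def _mutate(seq: list[str], fraction: float, rng, protected: set[int],
            n_mut: int | None = None) -> list[str]:
    """Substitute residues at non-protected positions with BLOSUM-nonpositive
    replacements; the mutated fraction fixes the planted identity."""
    free = [i for i in range(len(seq)) if i not in protected]
    m = int(round(fraction * len(seq))) if n_mut is None else n_mut
    if m > len(free):
        raise ConfigError(
            f"cannot plant identity: need {m} mutations but only "
            f"{len(free)} unprotected positions")
    out = list(seq)
    for i in rng.choice(free, size=m, replace=False):
        choices = _NONPOS[out[i]]
        out[int(i)] = str(rng.choice(choices))
    return out


def _derive_member(base: list[str], identity: float, rng, protected: set[int],
                   all_patterns, keep) -> list[str]:
    """A mutant of ``base`` hitting a whole-protein identity target."""
    L = len(base)
    n_protected = len(protected)
    m = int(round((1.0 - identity) * L))
    for _ in range(MAX_RETRIES):
        cand = _mutate(base, 0.0, rng, protected, n_mut=m)
        cand = _clean_against_patterns(cand, all_patterns, rng, keep=keep)
        pw = _align.global_align("".join(base), "".join(cand))
        if abs(pw.identity - identity) <= 0.03:
            return cand
    raise ConfigError(f"could not hit identity target {identity}")


def _derive_segmental_partner(base: list[str], spec: SegmentalSpec, rng,
                              protected: set[int], all_patterns, keep):
    """Truncated-and-mutated partner hitting coverage/similarity targets.

    The optimal alignment may gap out dense mutation runs, shifting the
    measured statistics away from their planted values, so the truncation
    span and mutation count are adjusted by feedback from the alignment
    module until both targets verify within +/-0.03.
    """
    L = len(base)
    span = int(round(spec.coverage * L))
    m = int(round((1.0 - spec.similarity) * span))
    for _ in range(3 * MAX_RETRIES):
        span = max(min(span, L), 10)
        prot = {p for p in protected if p < span}
        kp = [(s, n) for s, n in keep if s + n <= span]
        free_pos = [i for i in range(span) if i not in prot]
        m = max(min(m, len(free_pos)), 0)
        cand = list(base[:span])
        # mutate all free positions except evenly spaced survivors: bounded
        # run lengths plus mild substitution scores make gapping unprofitable
        n_keep = len(free_pos) - m
        if n_keep > 0:
            offset = float(rng.random())
            kept = {free_pos[int((k + offset) * len(free_pos) / (n_keep + 1))]
                    for k in range(1, n_keep + 1)}
        else:
            kept = set()
        mutated = 0
        for i in free_pos:
            if i in kept or mutated >= m:
                continue
            cand[i] = str(rng.choice(_MILDNEG[cand[i]]))
            mutated += 1
        cand = _clean_against_patterns(cand, all_patterns, rng, keep=kp)
        pw = _align.global_align("".join(base), "".join(cand))
        cov_err = pw.coverage - spec.coverage
        sim_err = pw.similarity - spec.similarity
        if abs(cov_err) <= 0.03 and abs(sim_err) <= 0.03:
            return cand
        span -= int(round(cov_err * L * 0.8)) or (1 if cov_err > 0 else -1)
        m += int(round(sim_err * span * 0.8)) or (1 if sim_err > 0 else -1)
    raise ConfigError(
        f"could not hit segmental targets cov={spec.coverage} sim={spec.similarity}")


def simulate_proteins_with_boxes(subfamily: str, n: int, length: int, seed: int):
    """n proteins of one subfamily, each carrying every subfamily H-box
    exactly once at a recorded position; returns (records, truth) where
    truth maps protein id -> [(pattern_name, start), ...]."""
    rng = np.random.default_rng(seed)
    all_pats = subfamily_patterns()
    records, truth = [], {}
    for i in range(n):
        seq, pats, positions, t = _build_subfamily_ancestor(
            subfamily, length, rng, all_pats)
        pid = f"{subfamily.replace('/', '')}_sim{i + 1}"
        records.append((pid, "".join(seq)))
        truth[pid] = t
    return records, truth


def simulate_background_proteins(n: int, length: int, seed: int):
    """Proteins guaranteed to contain no packaged H-box match (exact negatives)."""
    rng = np.random.default_rng(seed)
    pats = subfamily_patterns()
    out = []
    for i in range(n):
        seq = _clean_against_patterns(_random_protein(rng, length), pats, rng)
        out.append((f"bg{i + 1}", "".join(seq)))
    return out


# ---------------------------------------------------------------------------
# gene / genome assembly

@dataclass
class _Gene:
    locus_id: str
    chromosome: int
    strand: str
    protein: str | None            # None for non-coding filler (unused)
    is_family: bool
    subfamily: str = ""
    seq: str = ""                  # template (coding-strand) gene sequence
    exons: list = field(default_factory=list)   # local 1-based intervals
    cds: list = field(default_factory=list)
    utr5: list = field(default_factory=list)
    utr3: list = field(default_factory=list)
    n_introns: int = 0
    variant_cds: list | None = None             # local CDS of a .2 variant
    variant_protein: str | None = None
    start: int = 0
    end: int = 0
    description: str = ""


def _back_translate(protein: str, rng) -> str:
    return "".join(str(rng.choice(_CODONS[aa])) for aa in protein) + "TAA"


def _random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _build_gene_body(g: _Gene, rng, force_intronless: bool = False) -> None:
    cds_seq = _back_translate(g.protein, rng)
    utr5_len = 50 if rng.random() < 0.7 else 0
    utr3_len = 80 if rng.random() < 0.7 else 0
    n_introns = 0 if force_intronless else int(rng.integers(0, 4))
    cuts = sorted(rng.choice(np.arange(30, len(cds_seq) - 30), size=n_introns,
                             replace=False)) if n_introns else []
    pieces, last = [], 0
    for c in cuts:
        pieces.append(cds_seq[last:int(c)])
        last = int(c)
    pieces.append(cds_seq[last:])
    introns = ["GT" + _random_dna(rng, int(rng.integers(60, 120))) + "AG"
               for _ in range(n_introns)]
    seq_parts, cds_local, exon_local = [], [], []
    cursor = 0
    if utr5_len:
        seq_parts.append(_random_dna(rng, utr5_len))
        cursor += utr5_len
    for k, piece in enumerate(pieces):
        s = cursor + 1
        seq_parts.append(piece)
        cursor += len(piece)
        cds_local.append((s, cursor))
        if k < len(introns):
            seq_parts.append(introns[k])
            cursor += len(introns[k])
    if utr3_len:
        seq_parts.append(_random_dna(rng, utr3_len))
        cursor += utr3_len
    g.seq = "".join(seq_parts)
    g.cds = cds_local
    g.n_introns = n_introns
    g.utr5 = [(1, utr5_len)] if utr5_len else []
    g.utr3 = [(cursor - utr3_len + 1, cursor)] if utr3_len else []
    exon_local = list(cds_local)
    if utr5_len:
        s, e = exon_local[0]
        exon_local[0] = (1, e)
    if utr3_len:
        s, e = exon_local[-1]
        exon_local[-1] = (s, cursor)
    g.exons = exon_local
    if g.variant_protein is not None:
        # shorter splice form: same exons, CDS trimmed at the 3' end
        # (+3 drops the stop codon of the full-length form)
        trim = 3 * (len(g.protein) - len(g.variant_protein)) + 3
        vcds = list(cds_local)
        s, e = vcds[-1]
        vcds[-1] = (s, e - trim)
        g.variant_cds = vcds


def _local_to_genomic(local, gstart, glen, strand):
    if strand == "+":
        return [(gstart + s - 1, gstart + e - 1) for s, e in local]
    return sorted((gstart + glen - e, gstart + glen - s) for s, e in local)


@dataclass
class SimulatedFamily:
    config: FamilySimConfig
    genome: dict            # chromosome int -> sequence
    gff3: str
    proteome: list          # [(mrna_id, protein sequence)]
    annotations: pd.DataFrame
    anchors: list           # [(anchor id, protein)]
    anchor_map: dict        # anchor id -> subfamily
    truth: TruthRecord

    def write(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        from .io import write_fasta, write_tsv
        genome_recs = [(f"Chr{c:02d}", s) for c, s in sorted(self.genome.items())]
        write_fasta(genome_recs, outdir / "genome.fa")
        (outdir / "genes.gff3").write_text(self.gff3)
        write_fasta(self.proteome, outdir / "proteome.fa")
        write_tsv(self.annotations, outdir / "annotations.tsv")
        write_fasta(self.anchors, outdir / "anchors.fa")
        write_tsv(pd.DataFrame(
            [{"anchor": a, "subfamily": s} for a, s in self.anchor_map.items()]),
            outdir / "anchors.tsv")
        self.truth.to_json(outdir / "truth.json")
        for name in ("genome.fa", "genes.gff3", "proteome.fa", "annotations.tsv",
                     "anchors.fa", "anchors.tsv", "truth.json"):
            paths[name] = outdir / name
        return paths


def simulate_family_genome(config: FamilySimConfig) -> SimulatedFamily:
    """Annotated genome + proteome + planted-truth record (see module doc)."""
    rng = np.random.default_rng(config.seed)
    all_pats = subfamily_patterns()
    truth = TruthRecord()
    L = config.protein_length

    # --- subfamily ancestors, boxes, anchors -------------------------------
    ancestors, box_keep, box_truth, box_protected = {}, {}, {}, {}
    anchors, anchor_map = [], {}
    for sub in config.subfamily_sizes:
        seq, pats, positions, t = _build_subfamily_ancestor(sub, L, rng, all_pats)
        ancestors[sub] = seq
        box_keep[sub] = [(p, len(pat)) for p, pat in zip(positions, pats)]
        box_truth[sub] = t
        box_protected[sub] = {
            i for p, pat in zip(positions, pats) for i in range(p, p + len(pat))}
        anchor_seq = _derive_member(seq, 1.0 - config.anchor_divergence, rng,
                                    box_protected[sub], all_pats, box_keep[sub])
        aid = _ANCHOR_IDS.get(sub, f"AT0G{abs(hash(sub)) % 90000 + 10000:05d}")
        anchors.append((aid, "".join(anchor_seq)))
        anchor_map[aid] = sub

    # --- family member proteins -------------------------------------------
    # layout plan: per chromosome, ordered slot list of ("bg", None) and
    # ("fam", member); tandem members are separated by spec.intervening
    # background genes, everything else by larger background runs.
    members: list[dict] = []   # name, subfamily, protein(list), role

    def new_member(sub, protein, role):
        members.append({"sub": sub, "protein": protein, "role": role})
        return len(members) - 1

    sizes = dict(config.subfamily_sizes)

    def take(sub, n):
        if sizes.get(sub, 0) < n:
            raise ConfigError(f"subfamily {sub} too small for requested plan")
        sizes[sub] -= n

    plan: dict[int, list] = {c: [] for c in range(1, config.n_chromosomes + 1)}

    # tandem clusters: first on the largest membrane subfamily present
    tandem_subs = ["FAD2", "FAB2", "FAD3/7/8"]
    for ti, tspec in enumerate(config.tandem_specs):
        sub = tandem_subs[ti % len(tandem_subs)]
        take(sub, tspec.size)
        base = _derive_member(ancestors[sub], 1.0 - config.member_divergence,
                              rng, box_protected[sub], all_pats, box_keep[sub])
        cluster = [new_member(sub, base, "tandem")]
        prev = base
        for _ in range(tspec.size - 1):
            nxt = _derive_member(prev, tspec.identity, rng,
                                 box_protected[sub], all_pats, box_keep[sub])
            cluster.append(new_member(sub, nxt, "tandem"))
            prev = nxt
        chrom = (ti % config.n_chromosomes) + 1
        plan[chrom].append(("tandem", cluster, tspec))
        truth.tandem_clusters.append(cluster)

    # segmental pairs on distinct chromosomes
    seg_sub = "FAB2"
    seg_pairs = []
    for si, sspec in enumerate(config.segmental_specs):
        take(seg_sub, 2)
        base = _derive_member(ancestors[seg_sub], 1.0 - config.member_divergence,
                              rng, box_protected[seg_sub], all_pats, box_keep[seg_sub])
        partner = _derive_segmental_partner(base, sspec, rng,
                                            box_protected[seg_sub], all_pats,
                                            box_keep[seg_sub])
        ia = new_member(seg_sub, base, "segmental")
        ib = new_member(seg_sub, partner, "segmental")
        seg_pairs.append((ia, ib))
        truth.segmental_pairs.append([ia, ib])
        c1 = (2 * si + 2) % config.n_chromosomes + 1
        c2 = (2 * si + 3) % config.n_chromosomes + 1
        plan[c1].append(("single", ia))
        plan[c2].append(("single", ib))

    # sub-threshold pair (planted as NOT duplicated)
    if config.subthreshold_segmental is not None and sizes.get("FAD3/7/8", 0) >= 2:
        take("FAD3/7/8", 2)
        base = _derive_member(ancestors["FAD3/7/8"], 1.0 - config.member_divergence,
                              rng, box_protected["FAD3/7/8"], all_pats,
                              box_keep["FAD3/7/8"])
        partner = _derive_segmental_partner(
            base, config.subthreshold_segmental, rng,
            box_protected["FAD3/7/8"], all_pats, box_keep["FAD3/7/8"])
        ia = new_member("FAD3/7/8", base, "subthreshold")
        ib = new_member("FAD3/7/8", partner, "subthreshold")
        truth.subthreshold_pairs.append([ia, ib])
        plan[3 % config.n_chromosomes + 1].append(("single", ia))
        plan[4 % config.n_chromosomes + 1].append(("single", ib))

    # remaining ordinary members (one may be C-terminally truncated)
    truncated_done = not config.include_truncated
    splice_done = not config.include_splice_variant
    chrom_cycle = 0
    ordinary = []
    for sub, left in sizes.items():
        for _ in range(left):
            prot = _derive_member(ancestors[sub], 1.0 - config.member_divergence,
                                  rng, box_protected[sub], all_pats, box_keep[sub])
            role = "ordinary"
            if not truncated_done and len(box_keep[sub]) == 3:
                # cut just before the final H-box: completeness flag must drop
                cut = box_keep[sub][-1][0] - 3
                prot = prot[:cut]
                role = "truncated"
                truncated_done = True
            elif not splice_done:
                role = "splice"
                splice_done = True
            idx = new_member(sub, prot, role)
            ordinary.append(idx)
            plan[chrom_cycle % config.n_chromosomes + 1].append(("single", idx))
            chrom_cycle += 1

    # --- assemble chromosomes ----------------------------------------------
    genes: list[_Gene] = []
    by_chrom: dict[int, list[_Gene]] = {}
    member_gene: dict[int, _Gene] = {}
    for chrom in range(1, config.n_chromosomes + 1):
        slots: list = []
        items = plan.get(chrom, [])
        n_items = len(items)
        bg_left = config.n_background_genes
        lead = max(bg_left // (n_items + 1), 1)
        for item in items:
            for _ in range(min(lead, bg_left)):
                slots.append(("bg", None))
                bg_left -= 1
            if item[0] == "single":
                slots.append(("fam", item[1]))
            else:
                _, cluster, tspec = item
                for k, midx in enumerate(cluster):
                    if k:
                        for _ in range(min(tspec.intervening, bg_left)):
                            slots.append(("bg", None))
                            bg_left -= 1
                    slots.append(("fam", midx))
        for _ in range(bg_left):
            slots.append(("bg", None))
        chrom_genes = []
        for slot_i, (kind, midx) in enumerate(slots):
            lid = f"LOC_Os{chrom:02d}g{(slot_i + 1) * 100:05d}"
            strand = "-" if (slot_i % 5 == 4) else "+"
            if kind == "bg":
                bg_prot = _clean_against_patterns(
                    _random_protein(rng, int(rng.integers(120, 260))), all_pats, rng)
                g = _Gene(locus_id=lid, chromosome=chrom, strand=strand,
                          protein="".join(bg_prot), is_family=False,
                          description="expressed protein")
            else:
                m = members[midx]
                desc = "putative fatty acid desaturase"
                if midx % 3 == 1:
                    desc = "Fatty Acid Desaturase family protein"
                g = _Gene(locus_id=lid, chromosome=chrom, strand=strand,
                          protein="".join(m["protein"]), is_family=True,
                          subfamily=m["sub"], description=desc)
                if m["role"] == "splice":
                    g.variant_protein = g.protein[:-20]
                member_gene[midx] = g
                m["locus"] = lid
            _build_gene_body(g, rng, force_intronless=(kind == "fam" and
                                                       members[midx]["role"] == "splice"))
            chrom_genes.append(g)
        by_chrom[chrom] = chrom_genes
        genes.extend(chrom_genes)

    # genomic placement
    genome: dict[int, str] = {}
    for chrom, chrom_genes in by_chrom.items():
        parts, cursor = [], 0
        for g in chrom_genes:
            gap = _random_dna(rng, config.intergenic)
            parts.append(gap)
            cursor += len(gap)
            gseq = g.seq if g.strand == "+" else str(Seq(g.seq).reverse_complement())
            g.start = cursor + 1
            g.end = cursor + len(gseq)
            parts.append(gseq)
            cursor += len(gseq)
        parts.append(_random_dna(rng, config.intergenic))
        genome[chrom] = "".join(parts)

    # --- promoter planting --------------------------------------------------
    elements = {e.name: e for e in default_elements()}
    fam_genes = [g for g in genes if g.is_family]
    promoter_targets = fam_genes[:config.n_promoter_genes]
    for g in promoter_targets:
        genome[g.chromosome], planted = _plant_promoter(
            genome[g.chromosome], g, config, elements, rng)
        truth.promoter_elements[g.locus_id] = planted

    # --- truth bookkeeping, annotation emission ----------------------------
    for midx, g in member_gene.items():
        m = members[midx]
        truth.family_loci.append(g.locus_id)
        truth.subfamily[g.locus_id] = m["sub"]
        sub_pats = subfamily_patterns(m["sub"])
        hits, complete = scan_hboxes(g.protein, sub_pats)
        truth.hbox_hits[g.locus_id] = sorted([h.pattern, h.start] for h in hits)
        if not complete:
            truth.truncated.append(g.locus_id)
        if g.variant_protein is not None:
            truth.splice_variants[g.locus_id] = [f"{g.locus_id}.1", f"{g.locus_id}.2"]
    truth.family_loci.sort()
    truth.tandem_clusters = [
        sorted(member_gene[m].locus_id for m in cl) for cl in truth.tandem_clusters]
    truth.segmental_pairs = [
        sorted(member_gene[m].locus_id for m in pr) for pr in truth.segmental_pairs]
    truth.subthreshold_pairs = [
        sorted(member_gene[m].locus_id for m in pr) for pr in truth.subthreshold_pairs]

    gff3 = _emit_gff3(by_chrom, truth)
    proteome = []
    for g in genes:
        proteome.append((f"{g.locus_id}.1", g.protein))
        if g.variant_protein is not None:
            proteome.append((f"{g.locus_id}.2", g.variant_protein))
    annotations = pd.DataFrame(
        [{"locus_id": g.locus_id, "description": g.description} for g in genes])

    return SimulatedFamily(config=config, genome=genome, gff3=gff3,
                           proteome=proteome, annotations=annotations,
                           anchors=anchors, anchor_map=anchor_map, truth=truth)


def _plant_promoter(chrom_seq: str, g: _Gene, config, elements, rng):
    """Clean the 2-kb window upstream of the ATG and plant the configured
    elements; verify the scan reproduces exactly the planted hits."""
    Lp = config.promoter_length
    cds_genomic = _local_to_genomic(g.cds, g.start, len(g.seq), g.strand)
    if g.strand == "+":
        atg = min(s for s, _ in cds_genomic)
        lo, hi = atg - 1 - Lp, atg - 1          # 0-based window on template
        window = list(chrom_seq[lo:hi])
    else:
        cds_end = max(e for _, e in cds_genomic)
        lo, hi = cds_end, cds_end + Lp
        window = list(str(Seq(chrom_seq[lo:hi]).reverse_complement()))

    wanted = []
    for name, plants in config.promoter_spec.items():
        el = elements[name]
        for pos, strand in plants:
            wanted.append((name, pos, strand, el.consensus))
    expected = {(n, p, s) for n, p, s, _ in wanted}
    el_list = list(elements.values())

    def plant_all():
        for name, pos, strand, consensus in wanted:
            i = pos + Lp
            word = consensus if strand == "template" else str(
                Seq(consensus).reverse_complement())
            window[i:i + len(word)] = list(word)

    planted_spans = []
    for name, pos, strand, consensus in wanted:
        i = pos + Lp
        planted_spans.append((i, i + len(consensus)))

    ok = False
    for _ in range(300):
        plant_all()
        hits = scan_elements(Promoter(gene=g.locus_id, sequence="".join(window)),
                             el_list)
        got = {(h.element, h.position, h.strand) for h in hits}
        if got == expected:
            ok = True
            break
        extra = got - expected
        for el_name, pos, strand in extra:
            i = pos + Lp
            width = len(elements[el_name].consensus)
            span = [j for j in range(i, i + width)
                    if not any(a <= j < b for a, b in planted_spans)]
            if span:
                j = int(rng.choice(span))
                window[j] = str(rng.choice([b for b in "ACGT" if b != window[j]]))
            else:  # overlap entirely inside plants: nudge a flanking base
                for j in (i - 1, i + width):
                    if 0 <= j < Lp and not any(a <= j < b for a, b in planted_spans):
                        window[j] = str(rng.choice([b for b in "ACGT" if b != window[j]]))
                        break
    if not ok:
        raise ConfigError(f"{g.locus_id}: could not plant promoter elements cleanly")

    if g.strand == "+":
        new = chrom_seq[:lo] + "".join(window) + chrom_seq[hi:]
    else:
        new = chrom_seq[:lo] + str(Seq("".join(window)).reverse_complement()) + chrom_seq[hi:]
    planted = sorted([n, p, s] for n, p, s in expected)
    return new, planted


def _emit_gff3(by_chrom, truth: TruthRecord) -> str:
    lines = ["##gff-version 3"]
    for chrom in sorted(by_chrom):
        for g in by_chrom[chrom]:
            seqid = f"Chr{chrom:02d}"
            glen = len(g.seq)
            lines.append("\t".join([
                seqid, "famsurvey_sim", "gene", str(g.start), str(g.end), ".",
                g.strand, ".", f"ID={g.locus_id}"]))
            transcripts = [(f"{g.locus_id}.1", g.cds)]
            if g.variant_cds is not None:
                transcripts.append((f"{g.locus_id}.2", g.variant_cds))
            for mrna_id, cds_local in transcripts:
                lines.append("\t".join([
                    seqid, "famsurvey_sim", "mRNA", str(g.start), str(g.end), ".",
                    g.strand, ".", f"ID={mrna_id};Parent={g.locus_id}"]))
                truth.intron_counts[mrna_id] = len(cds_local) - 1
                for label, ivs in (("exon", g.exons), ("CDS", cds_local),
                                   ("five_prime_UTR", g.utr5),
                                   ("three_prime_UTR", g.utr3)):
                    for k, (s, e) in enumerate(
                            _local_to_genomic(ivs, g.start, glen, g.strand), 1):
                        lines.append("\t".join([
                            seqid, "famsurvey_sim", label, str(s), str(e), ".",
                            g.strand, ".",
                            f"ID={mrna_id}.{label}{k};Parent={mrna_id}"]))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# expression / qPCR simulation

TISSUES = {
    "VR": "vegetative", "VL": "vegetative", "VS": "vegetative",
    "RR": "reproductive", "RL": "reproductive", "RS": "reproductive",
    "I1": "reproductive", "I2": "reproductive", "I3": "reproductive",
    "An": "reproductive", "Pi": "reproductive", "Le": "reproductive",
    "Pa": "reproductive", "Ov": "reproductive", "Em": "reproductive",
    "En": "reproductive",
}

# archetype levels in log2 units (level mean, jitter sd across tissues)
LEVELS = {"high": (10.0, 0.4), "mid": (6.5, 0.3), "off": (4.0, 0.25),
          "floor": (2.0, 0.25)}


def default_expression_spec(n_genes: int = 40) -> list[str]:
    """Planted group labels: composition keeps the high-level share of the
    pooled means below the 70th percentile so percentile thresholds fall in
    the gaps between archetype levels."""
    counts = {"I": round(0.15 * n_genes), "IV": round(0.25 * n_genes)}
    counts["II"] = round(0.30 * n_genes)
    counts["III"] = n_genes - sum(counts.values())
    labels = (["I"] * counts["I"] + ["II"] * counts["II"]
              + ["III"] * counts["III"] + ["IV"] * counts["IV"])
    return labels


def simulate_expression(spec=None, seed: int = 0, noise_sd: float = 0.3,
                        n_replicates: int = 3):
    """Tissue x gene log2 expression with planted group archetypes.

    ``spec`` is a list of group labels (I-IV) or None for the default
    40-gene composition.  Returns (ExpressionMatrix, truth) with truth a
    dict gene -> group label.
    """
    labels = default_expression_spec() if spec is None else list(spec)
    rng = np.random.default_rng(seed)
    tissues = list(TISSUES)
    veg = [t for t in tissues if TISSUES[t] == "vegetative"]
    rep = [t for t in tissues if TISSUES[t] == "reproductive"]
    genes = [f"G{i + 1:03d}" for i in range(len(labels))]
    truth = dict(zip(genes, labels))

    def lvl(name):
        mu, sd = LEVELS[name]
        return rng.normal(mu, sd)

    mean_rows = {}
    third_veg = True
    for gene, lab in zip(genes, labels):
        row = {}
        if lab == "I":
            row = {t: lvl("high") for t in tissues}
        elif lab == "IV":
            row = {t: lvl("floor") for t in tissues}
        elif lab == "II":
            hv = str(rng.choice(veg))
            hr = str(rng.choice(rep))
            for t in tissues:
                row[t] = lvl("high") if t in (hv, hr) else lvl("mid")
        else:  # III: category-specific, alternating vegetative/reproductive
            if third_veg:
                high = set(veg)
            else:
                high = set(rng.choice(rep, size=5, replace=False))
            third_veg = not third_veg
            for t in tissues:
                row[t] = lvl("high") if t in high else lvl("off")
        mean_rows[gene] = row

    cols, data, meta = [], [], []
    for t in tissues:
        for r in range(1, n_replicates + 1):
            cols.append(f"{t}_r{r}")
            meta.append({"sample": f"{t}_r{r}", "tissue": t,
                         "category": TISSUES[t], "replicate": r})
    values = pd.DataFrame(index=genes, columns=cols, dtype=float)
    for gene in genes:
        for t in tissues:
            base = mean_rows[gene][t]
            for r in range(1, n_replicates + 1):
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                values.loc[gene, f"{t}_r{r}"] = base + noise
    samples = pd.DataFrame(meta).set_index("sample")
    return ExpressionMatrix(values=values, samples=samples), truth


def simulate_stress_arms(lfc_by_gene: dict, sd: float, n_replicates: int,
                         seed: int, baseline: float = 8.0):
    """Control/treated replicate frames with planted log2 fold changes."""
    rng = np.random.default_rng(seed)
    genes = list(lfc_by_gene)
    control = pd.DataFrame(
        rng.normal(baseline, sd, size=(len(genes), n_replicates)), index=genes)
    treated = pd.DataFrame(
        rng.normal(baseline, sd, size=(len(genes), n_replicates)), index=genes)
    treated = treated.add(pd.Series(lfc_by_gene), axis=0)
    return control, treated


def simulate_qpcr(spec=None, seed: int = 0, noise_sd: float = 0.0,
                  n_replicates: int = 3, reference_gene: str = "Os03g0234200",
                  calibrator: str = "control"):
    """Ct table with planted fold changes: expected 2^-ddCt equals the
    planted value exactly at zero Ct noise.

    ``spec``: dict gene -> {sample: fold change vs calibrator}; default
    plants folds {1, 8, 2, 0.25} at a 3 h treatment sample.
    """
    if spec is None:
        spec = {
            "GeneA": {"ABA_3h": 1.0}, "GeneB": {"ABA_3h": 8.0},
            "GeneC": {"ABA_3h": 2.0}, "GeneD": {"ABA_3h": 0.25},
        }
    rng = np.random.default_rng(seed)
    ref_ct, target_base = 20.0, 25.0
    samples = sorted({s for folds in spec.values() for s in folds} | {calibrator})
    rows = []
    for sample in samples:
        for rep in range(1, n_replicates + 1):
            rows.append({"gene": reference_gene, "sample": sample,
                         "replicate": rep,
                         "ct": ref_ct + (rng.normal(0, noise_sd) if noise_sd else 0.0)})
    truth = {}
    for gene, folds in spec.items():
        for sample in samples:
            fold = folds.get(sample, 1.0) if sample != calibrator else 1.0
            truth[(gene, sample)] = fold
            ct = target_base - np.log2(fold)
            for rep in range(1, n_replicates + 1):
                rows.append({"gene": gene, "sample": sample, "replicate": rep,
                             "ct": float(ct) + (rng.normal(0, noise_sd)
                                                if noise_sd else 0.0)})
    table = QpcrTable(data=pd.DataFrame(rows), reference_gene=reference_gene,
                      calibrator_sample=calibrator)
    return table, truth
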