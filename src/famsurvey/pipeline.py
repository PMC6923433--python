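"""End-to-end orchestration: identify -> characterize -> phylogeny ->
duplication -> promoters, with a machine-readable survey report.

Reruns with identical inputs and configuration are byte-identical: the
report embeds no timestamps, every stochastic stage takes an explicit seed,
and provenance records parameters plus SHA-256 checksums of the inputs.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import duplication as dup
from . import expression as expr
from . import features, identify, io, phylo, promoter, structure


@dataclass
class PipelineConfig:
    genome: str
    gff3: str
    proteome: str
    annotations: str
    anchors_fasta: str
    anchors_map: str              # TSV: anchor, subfamily
    out_dir: str
    evalue_max: float = identify.DEFAULT_EVALUE_MAX
    keyword: str = "fatty acid desaturase"
    manual_include: list = field(default_factory=list)
    tandem_max_intervening: int = 4
    tandem_min_identity: float = 0.5
    segmental_min_coverage: float = 0.75
    segmental_min_similarity: float = 0.75
    promoter_length: int = 2000
    bootstrap: int = 0
    seed: int = 1
    stages: dict = field(default_factory=lambda: {
        "identify": True, "features": True, "structure": True,
        "phylogeny": True, "duplication": True, "promoter": True,
    })

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages in dependency order; returns the report dict
    (also written to ``<out_dir>/report.json`` with per-stage TSVs)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "tool": "famsurvey", "version": __version__, "seed": config.seed,
            "parameters": {
                "evalue_max": config.evalue_max,
                "tandem_max_intervening": config.tandem_max_intervening,
                "tandem_min_identity": config.tandem_min_identity,
                "segmental_min_coverage": config.segmental_min_coverage,
                "segmental_min_similarity": config.segmental_min_similarity,
                "promoter_length": config.promoter_length,
                "bootstrap": config.bootstrap,
            },
            "inputs": {
                name: _sha256(getattr(config, name))
                for name in ("genome", "gff3", "proteome", "annotations",
                             "anchors_fasta", "anchors_map")
            },
            "stages": dict(config.stages),
        }
    }
    if not any(config.stages.values()):
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        return report

    annotation = io.read_gff3(config.gff3)
    proteome = io.read_fasta(config.proteome)
    annotations_df = io.read_tsv(config.annotations)
    anchors = io.read_fasta(config.anchors_fasta)
    anchor_map = {
        r.anchor: r.subfamily for r in io.read_tsv(config.anchors_map).itertuples()
    }

    family = []
    if config.stages.get("identify", True):
        dom, dom_mode = identify.domain_screen(proteome)
        hom = identify.homology_screen(anchors, proteome, config.evalue_max)
        key = identify.keyword_screen(annotations_df, config.keyword)
        family = identify.merge_and_deduplicate(
            [dom, hom, key], proteome, annotation,
            manual_include=config.manual_include)
        # subfamily assignment by distance to anchors, then positional naming
        recs = [(g.locus.locus_id, g.protein.sequence) for g in family] + anchors
        dm = phylo.pairwise_poisson_matrix(recs)
        sub_by_locus = phylo.assign_subfamilies(dm, anchor_map)
        family = identify.assign_family_names(family, sub_by_locus)
        report["identification"] = {
            "domain_mode": dom_mode,
            "n_members": len(family),
            "subfamily_sizes": {
                k: int(v) for k, v in pd.Series(
                    [g.subfamily for g in family]).value_counts().sort_index().items()
            },
        }

    roster_rows = []
    for g in family:
        row = {
            "name": g.name, "locus": g.locus.locus_id,
            "chromosome": g.locus.chromosome, "start": g.locus.start,
            "end": g.locus.end, "strand": g.locus.strand,
            "subfamily": g.subfamily, "length_aa": g.protein.length,
        }
        if config.stages.get("features", True):
            stats = features.protein_stats(g.protein.sequence)
            hits, complete = features.scan_hboxes(
                g.protein.sequence, features.subfamily_patterns(g.subfamily)
                if g.subfamily != "unassigned" else features.subfamily_patterns())
            if not complete:
                g.flags.add("truncated")
            row.update({
                "mw_da": round(stats.molecular_weight, 1),
                "pi": round(stats.isoelectric_point, 2),
                "n_hbox_hits": len(hits),
                "hboxes_complete": complete,
            })
        roster_rows.append(row)
    roster = pd.DataFrame(roster_rows)
    if not roster.empty:
        io.write_tsv(roster, out / "family_roster.tsv")
    report["family_roster"] = roster.to_dict(orient="records")

    if config.stages.get("structure", True) and family:
        fam_loci = {g.locus.locus_id for g in family}
        reps = {g.protein.id for g in family}
        stats_list = [structure.intron_stats(m) for m in annotation.models
                      if m.locus.locus_id in fam_loci and m.mrna_id in reps]
        io.write_tsv(structure.structure_table(stats_list), out / "structure.tsv")
        dist = structure.chromosome_distribution([g.locus for g in family])
        report["structure"] = {
            "intronless_genes": sorted(s.gene for s in stats_list if s.n_introns == 0),
            "chromosome_counts": {str(k): v for k, v in sorted(dist.counts.items())},
            "occupied_chromosomes": sorted(dist.occupied),
        }

    if config.stages.get("phylogeny", True) and len(family) >= 3:
        recs = [(g.name, g.protein.sequence) for g in family]
        dm = phylo.pairwise_poisson_matrix(recs)
        tree = phylo.nj_tree(dm)
        io.write_newick(tree, out / "family_tree.nwk")
        report["phylogeny"] = {
            "tree_file": "family_tree.nwk",
            "n_taxa": len(recs),
            "method": "NJ on Poisson-corrected pairwise distances",
        }

    if config.stages.get("duplication", True) and family:
        tandem = dup.call_tandem(
            family, annotation.gene_order,
            max_intervening=config.tandem_max_intervening,
            min_identity=config.tandem_min_identity)
        segmental = dup.call_segmental(
            family, tandem_calls=tandem,
            min_coverage=config.segmental_min_coverage,
            min_similarity=config.segmental_min_similarity)
        summary = dup.duplication_summary(tandem, segmental, len(family))
        report["duplication"] = {
            "tandem_clusters": [c.members for c in tandem],
            "segmental_pairs": [c.members for c in segmental],
            "n_tandem_genes": summary.n_tandem_genes,
            "n_segmental_genes": summary.n_segmental_genes,
            "percent_duplicated": summary.percent_duplicated,
            "both_mechanisms": summary.overlap,
        }

    if config.stages.get("promoter", True) and family:
        genome_raw = dict(io.read_fasta(config.genome))
        genome = {io._seqid_to_chromosome(k): v for k, v in genome_raw.items()}
        reps = {g.protein.id: g for g in family}
        hits = []
        for m in annotation.models:
            if m.mrna_id not in reps:
                continue
            prom = promoter.extract_promoter(genome, m, config.promoter_length)
            hits.extend(promoter.scan_elements(prom))
        summary_df = promoter.summarize_elements(
            hits, genes=sorted({g.locus.locus_id for g in family}))
        io.write_tsv(summary_df, out / "promoter_elements.tsv")
        report["promoter"] = {
            "n_hits": len(hits),
            "genes_with_multiple_ABRE": sorted(
                summary_df[(summary_df["element"] == "ABRE")
                           & summary_df["multiple"]]["gene"]),
        }

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
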