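import numpy as np
import pytest

from famsurvey import align, io
from famsurvey.simulate import (
    ConfigError, FamilySimConfig, SegmentalSpec, TandemSpec, TruthRecord,
    simulate_family_genome, simulate_proteins_with_boxes,
)


def _small_config(seed, **kw):
    base = dict(
        seed=seed, n_chromosomes=4, n_background_genes=8,
        subfamily_sizes={"FAB2": 4, "FAD2": 3},
        tandem_specs=[TandemSpec(size=2, intervening=2, identity=0.6)],
        segmental_specs=[SegmentalSpec(0.85, 0.85)],
        subthreshold_segmental=None, include_truncated=False,
        include_splice_variant=False, n_promoter_genes=2,
    )
    base.update(kw)
    return FamilySimConfig(**base)


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        a = simulate_family_genome(_small_config(7))
        b = simulate_family_genome(_small_config(7))
        assert a.genome == b.genome
        assert a.gff3 == b.gff3
        assert a.proteome == b.proteome
        assert a.truth.to_json() == b.truth.to_json()

    def test_different_seeds_differ(self):
        a = simulate_family_genome(_small_config(7))
        b = simulate_family_genome(_small_config(8))
        assert a.genome != b.genome


class TestPlantedStructure:
    def test_tandem_cluster_by_construction(self, sim, annotation):
        # default config plants one cluster of 3 (2 intervening) + one of 2
        assert sorted(len(c) for c in sim.truth.tandem_clusters) == [2, 3]
        for cluster in sim.truth.tandem_clusters:
            chroms = {annotation.loci[l].chromosome for l in cluster}
            assert len(chroms) == 1
            ords = sorted(annotation.loci[l].ordinal for l in cluster)
            gaps = [b - a - 1 for a, b in zip(ords, ords[1:])]
            assert all(g <= 2 for g in gaps)

    def test_planted_identity_verified_by_aligner(self, sim):
        prot = dict(sim.proteome)
        for cluster in sim.truth.tandem_clusters:
            for a, b in zip(cluster, cluster[1:]):
                pw = align.global_align(prot[a + ".1"], prot[b + ".1"])
                assert pw.identity > 0.5
        for a, b in sim.truth.segmental_pairs:
            pw = align.global_align(prot[a + ".1"], prot[b + ".1"])
            assert pw.coverage > 0.75 and pw.similarity > 0.75
        for a, b in sim.truth.subthreshold_pairs:
            pw = align.global_align(prot[a + ".1"], prot[b + ".1"])
            assert not (pw.coverage > 0.75 and pw.similarity > 0.75)

    def test_segmental_targets_across_seeds(self):
        # planted at 0.85/0.85 the pair always passes the strict >0.75 rule;
        # planted at 0.5/0.5 it never does
        for seed in range(3):
            hi = simulate_family_genome(_small_config(100 + seed))
            prot = dict(hi.proteome)
            (a, b), = hi.truth.segmental_pairs
            pw = align.global_align(prot[a + ".1"], prot[b + ".1"])
            assert pw.coverage > 0.75 and pw.similarity > 0.75
            lo = simulate_family_genome(_small_config(
                200 + seed, segmental_specs=[SegmentalSpec(0.5, 0.5)]))
            prot = dict(lo.proteome)
            (a, b), = lo.truth.segmental_pairs
            pw = align.global_align(prot[a + ".1"], prot[b + ".1"])
            assert not (pw.coverage > 0.75 and pw.similarity > 0.75)

    def test_zero_family_genes_valid_gff3(self, tmp_path):
        cfg = FamilySimConfig(
            seed=5, n_chromosomes=2, n_background_genes=5,
            subfamily_sizes={}, tandem_specs=[], segmental_specs=[],
            subthreshold_segmental=None, include_truncated=False,
            include_splice_variant=False, n_promoter_genes=0)
        sim = simulate_family_genome(cfg)
        assert sim.truth.family_loci == []
        sim.write(tmp_path)
        ann = io.read_gff3(tmp_path / "genes.gff3")
        assert len(ann.loci) == 10

    def test_unsatisfiable_identity_rejected(self):
        with pytest.raises(ConfigError):
            simulate_family_genome(_small_config(
                9, tandem_specs=[TandemSpec(size=2, intervening=1,
                                            identity=0.05)]))

    def test_invalid_targets_rejected(self):
        with pytest.raises(ConfigError):
            _small_config(9, segmental_specs=[SegmentalSpec(1.2, 0.8)])

    def test_truth_round_trips_through_json(self, sim, tmp_path):
        p = tmp_path / "truth.json"
        sim.truth.to_json(p)
        again = TruthRecord.from_json(p)
        assert again == sim.truth


class TestProteinsWithBoxes:
    def test_zero_proteins(self):
        recs, truth = simulate_proteins_with_boxes("FAB2", 0, 150, seed=1)
        assert recs == [] and truth == {}

    def test_too_short_for_patterns_rejected(self):
        with pytest.raises(ConfigError):
            simulate_proteins_with_boxes("FAD3/7/8", 1, 40, seed=1)


class TestGenomeConsistency:
    def test_gff3_matches_genome_and_proteome(self, sim, annotation):
        # translated CDS from the genome equals the emitted protein
        from Bio.Seq import Seq
        prot = dict(sim.proteome)
        for m in annotation.models:
            seq = sim.genome[m.locus.chromosome]
            parts = [seq[s - 1:e] for s, e in sorted(m.cds)]
            cds = "".join(parts)
            if m.locus.strand == "-":
                cds = str(Seq(cds).reverse_complement())
            translated = str(Seq(cds).translate())
            assert translated.endswith("*") or m.mrna_id.endswith(".2")
            assert translated.rstrip("*") == prot[m.mrna_id]

    def test_every_family_gene_has_two_or_three_boxes(self, sim):
        for locus in sim.truth.family_loci:
            n = len(sim.truth.hbox_hits[locus])
            assert 2 <= n <= 3
        for locus in sim.truth.truncated:
            assert len(sim.truth.hbox_hits[locus]) == 2
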