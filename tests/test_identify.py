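import numpy as np
import pandas as pd
import pytest

from famsurvey import identify, io
from famsurvey.models import FamilyGene, GeneLocus, ProteinRecord


class TestDomainScreen:
    def test_hit_table_mode(self):
        hits = pd.DataFrame([{"protein_id": "LOC_Os01g00100.1",
                              "domain_id": "PF00487", "evalue": 1e-30}])
        loci, mode = identify.domain_screen([], domain_hits=hits)
        assert loci == {"LOC_Os01g00100"} and mode == "hit_table"

    def test_no_evidence_configuration_error(self):
        with pytest.raises(ValueError):
            identify.domain_screen([], domain_hits=None, hbox_fallback=False)

    def test_fallback_recovers_planted_family_exactly(self, sim, sim_dir):
        proteome = io.read_fasta(sim_dir / "proteome.fa")
        loci, mode = identify.domain_screen(proteome)
        assert mode == "hbox_fallback"
        assert loci == set(sim.truth.family_loci)


class TestHomologyScreen:
    def test_self_hit_kept(self):
        seq = "".join(np.random.default_rng(1).choice(
            list("ACDEFGHIKLMNPQRSTVWY"), size=300))
        ev = identify.homology_screen([("q", seq)], [("LOC_Os01g00100.1", seq)])
        assert len(ev) == 1
        assert ev[0].best_evalue < 1e-50
        assert ev[0].matched_query == "q"

    def test_empirical_null_no_random_hits(self):
        rng = np.random.default_rng(2)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        queries = [("q1", "".join(rng.choice(aa, size=350))),
                   ("q2", "".join(rng.choice(aa, size=350)))]
        proteome = [(f"p{i}.1", "".join(rng.choice(aa, size=100)))
                    for i in range(300)]
        assert identify.homology_screen(queries, proteome) == []

    def test_empty_query_set_rejected(self):
        with pytest.raises(ValueError):
            identify.homology_screen([], [("p", "MKV")])

    def test_lowering_threshold_never_adds_candidates(self, sim_dir):
        proteome = io.read_fasta(sim_dir / "proteome.fa")[:40]
        anchors = io.read_fasta(sim_dir / "anchors.fa")
        loose = {e.locus_id for e in identify.homology_screen(
            anchors, proteome, evalue_max=1e-5)}
        strict = {e.locus_id for e in identify.homology_screen(
            anchors, proteome, evalue_max=1e-30)}
        assert strict <= loose


class TestKeywordScreen:
    ANN = pd.DataFrame([
        {"locus_id": "L1", "description": "putative fatty acid desaturase 2"},
        {"locus_id": "L2", "description": "Fatty Acid Desaturase, chloroplastic"},
        {"locus_id": "L3", "description": "desaturase-like protein"},
        {"locus_id": "L4", "description": "expressed protein"},
    ])

    def test_case_insensitive_phrase_match(self):
        assert identify.keyword_screen(self.ANN) == {"L1", "L2"}

    def test_partial_phrase_does_not_match(self):
        assert "L3" not in identify.keyword_screen(self.ANN)


class TestMergeAndDeduplicate:
    def test_union_and_idempotence(self, sim, sim_dir, annotation):
        proteome = io.read_fasta(sim_dir / "proteome.fa")
        fam_loci = sim.truth.family_loci
        s1, s2 = set(fam_loci[:12]), set(fam_loci[8:])
        once = identify.merge_and_deduplicate([s1, s2], proteome, annotation)
        twice = identify.merge_and_deduplicate([s2, s1, s1], proteome, annotation)
        assert [g.locus.locus_id for g in once] == sorted(fam_loci)
        assert [g.locus.locus_id for g in once] == [g.locus.locus_id for g in twice]

    def test_longest_splice_variant_kept(self, sim, sim_dir, annotation):
        proteome = io.read_fasta(sim_dir / "proteome.fa")
        locus = next(iter(sim.truth.splice_variants))
        fam = identify.merge_and_deduplicate([{locus}], proteome, annotation)
        assert len(fam) == 1
        assert fam[0].protein.id == locus + ".1"  # .1 is the longer CDS

    def test_manual_include_flagged(self, sim_dir, annotation, sim):
        proteome = io.read_fasta(sim_dir / "proteome.fa")
        locus = sim.truth.family_loci[0]
        fam = identify.merge_and_deduplicate(
            [set()], proteome, annotation, manual_include=[locus])
        assert fam[0].flags == {"manual_include"}

    def test_unknown_manual_id_rejected(self, sim_dir, annotation):
        proteome = io.read_fasta(sim_dir / "proteome.fa")
        with pytest.raises(KeyError):
            identify.merge_and_deduplicate([set()], proteome, annotation,
                                           manual_include=["LOC_Os99g99999"])


def _candidate(locus_id, chrom, start, name=None):
    locus = GeneLocus(locus_id, chrom, start, start + 100, "+")
    return FamilyGene(name=name or locus_id, locus=locus,
                      protein=ProteinRecord(locus_id + ".1", "MKV"))


class TestNaming:
    def test_positional_numbering_across_chromosomes(self):
        c1 = _candidate("LOC_Os11g01340", 11, 1340)
        c2 = _candidate("LOC_Os12g01370", 12, 1370)
        named = identify.assign_family_names(
            [c2, c1], {c1.locus.locus_id: "FAD3/7/8",
                       c2.locus.locus_id: "FAD3/7/8"})
        assert [g.name for g in named] == ["OsFAD3-1", "OsFAD3-2"]

    def test_singleton_subfamily_unnumbered(self):
        c = _candidate("LOC_Os02g42660", 2, 42660)
        named = identify.assign_family_names([c], {c.locus.locus_id: "DES1"})
        assert named[0].name == "OsDES1"

    def test_nine_member_subfamily_positional(self):
        genes = [_candidate(f"LOC_Os{c:02d}g{1000 + i:05d}", c, 1000 + i)
                 for i, c in enumerate([1, 1, 2, 3, 3, 4, 6, 8, 8])]
        shuffled = list(reversed(genes))
        named = identify.assign_family_names(
            shuffled, {g.locus.locus_id: "FAB2" for g in genes})
        expect = [f"OsFAB2-{k}" for k in range(1, 10)]
        assert [g.name for g in named] == expect

    def test_override_map_applied_last(self):
        c1 = _candidate("LOC_Os03g18070", 3, 18070)
        c2 = _candidate("LOC_Os07g49310", 7, 49310)
        named = identify.assign_family_names(
            [c1, c2],
            {c1.locus.locus_id: "FAD3/7/8", c2.locus.locus_id: "FAD3/7/8"},
            overrides={c1.locus.locus_id: "OsFAD7",
                       c2.locus.locus_id: "OsFAD8"})
        assert [g.name for g in named] == ["OsFAD7", "OsFAD8"]

    def test_duplicate_override_names_rejected(self):
        c1 = _candidate("LOC_Os01g00100", 1, 100)
        c2 = _candidate("LOC_Os01g00200", 1, 200)
        with pytest.raises(ValueError):
            identify.assign_family_names(
                [c1, c2], {c1.locus.locus_id: "FAB2",
                           c2.locus.locus_id: "FAB2"},
                overrides={c1.locus.locus_id: "X", c2.locus.locus_id: "X"})


class TestEndToEndIdentification:
    def test_planted_family_recall_and_precision(self, sim, named_family):
        got = {g.protein.id.rsplit(".", 1)[0] for g in named_family}
        assert got == set(sim.truth.family_loci)

    def test_truncated_member_carries_flag(self, sim, named_family):
        # completeness-based flag is attached by the pipeline features stage;
        # here the H-box truth says which member lacks its final box
        from famsurvey import features
        by_locus = {g.protein.id.rsplit(".", 1)[0]: g for g in named_family}
        for locus in sim.truth.truncated:
            g = by_locus[locus]
            pats = features.subfamily_patterns(g.subfamily)
            _, complete = features.scan_hboxes(g.protein.sequence, pats)
            assert not complete
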