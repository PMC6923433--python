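import math

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from famsurvey import phylo
from oracles import random_additive_tree


class TestProgressiveAlign:
    def test_identical_sequences_align_gap_free(self):
        aln = phylo.progressive_align([("a", "MKVLIH"), ("b", "MKVLIH")])
        assert aln.rows == ["MKVLIH", "MKVLIH"]

    def test_deletion_creates_single_gap_column(self):
        aln = phylo.progressive_align([("a", "MKV"), ("b", "MV")])
        assert aln.rows[0] == "MKV"
        assert aln.rows[1].count("-") == 1

    def test_beats_naive_stack_left_alignment(self):
        rng = np.random.default_rng(15)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        base = "".join(rng.choice(aa, size=60))
        seqs = []
        for i in range(10):
            s = list(base)
            for j in rng.choice(60, size=8, replace=False):
                s[j] = str(rng.choice(aa))
            if i % 3 == 0:  # a small deletion
                del s[20:23]
            seqs.append((f"s{i}", "".join(s)))
        aln = phylo.progressive_align(seqs)
        width = max(len(s) for _, s in seqs)
        naive = phylo.MultipleAlignment(
            ids=[i for i, _ in seqs],
            rows=[s + "-" * (width - len(s)) for _, s in seqs])
        assert (phylo.sum_of_pairs_score(aln)
                >= phylo.sum_of_pairs_score(naive))

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            phylo.progressive_align([("a", "MKV")])


class TestPoissonDistance:
    def test_identical_rows_have_zero_distance(self):
        aln = phylo.MultipleAlignment(ids=["a", "b"], rows=["MKVL", "MKVL"])
        assert phylo.poisson_distance(aln)["a", "b"] == 0.0

    def test_analytic_correction(self):
        # p = 0.1 over 10 complete-deletion columns
        aln = phylo.MultipleAlignment(
            ids=["a", "b"], rows=["AAAAAAAAAA", "AAAAAAAAAC"])
        d = phylo.poisson_distance(aln)["a", "b"]
        assert d == pytest.approx(-math.log(0.9), abs=1e-9)
        assert d == pytest.approx(0.105360516, abs=1e-8)

    def test_gapped_columns_excluded_matches_hand_count(self):
        rng = np.random.default_rng(16)
        aa = list("ACDG-")
        for _ in range(20):
            rows = ["".join(rng.choice(aa, size=30)) for _ in range(4)]
            aln = phylo.MultipleAlignment(ids=list("abcd"), rows=rows)
            cols = [j for j in range(30) if all(r[j] != "-" for r in rows)]
            if not cols:
                continue
            dm = phylo.poisson_distance(aln)
            for i in range(4):
                for j in range(i + 1, 4):
                    p = sum(rows[i][c] != rows[j][c] for c in cols) / len(cols)
                    expect = phylo.D_MAX if p >= 1 - math.exp(-phylo.D_MAX) \
                        else -math.log(1 - p)
                    assert dm[i, j] == pytest.approx(expect)

    def test_saturation_capped(self):
        aln = phylo.MultipleAlignment(ids=["a", "b"], rows=["AAAA", "CCCC"])
        assert phylo.poisson_distance(aln)["a", "b"] == phylo.D_MAX

    def test_monotone_in_p(self):
        ds = []
        for k in range(0, 10):
            rows = ["A" * 10, "C" * k + "A" * (10 - k)]
            aln = phylo.MultipleAlignment(ids=["a", "b"], rows=rows)
            ds.append(phylo.poisson_distance(aln)["a", "b"])
        assert ds == sorted(ds)
        assert len(set(ds)) == len(ds)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix([[0, 5, 9], [5, 0, 10], [9, 10, 0]], list("abc"))
        tree = phylo.nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"a": 2.0, "b": 3.0, "c": 7.0})

    def test_recovers_additive_four_taxon_tree(self):
        dm = DistanceMatrix([[0, 3, 7, 8], [3, 0, 6, 7],
                             [7, 6, 0, 5], [8, 7, 5, 0]], list("abcd"))
        tree = phylo.nj_tree(dm)
        assert phylo.tree_bipartitions(tree) == {frozenset("cd")}
        for x in "abcd":
            for y in "abcd":
                if x < y:
                    assert phylo.path_distance(tree, x, y) == pytest.approx(
                        dm[x, y], abs=1e-9)

    def test_additive_matrices_reproduce_all_path_lengths(self):
        rng = np.random.default_rng(17)
        for _ in range(15):
            n = int(rng.integers(4, 12))
            _, names, mat = random_additive_tree(n, rng)
            tree = phylo.nj_tree(DistanceMatrix(mat, names))
            for i, x in enumerate(names):
                for j in range(i + 1, n):
                    assert phylo.path_distance(tree, x, names[j]) == pytest.approx(
                        mat[i, j], abs=1e-9)

    def test_agrees_with_skbio_nj_oracle(self):
        rng = np.random.default_rng(18)
        for _ in range(10):
            n = int(rng.integers(5, 10))
            src, names, mat = random_additive_tree(n, rng)
            dm = DistanceMatrix(mat, names)
            mine = phylo.tree_bipartitions(phylo.nj_tree(dm))
            theirs = phylo.tree_bipartitions(skbio_nj(dm))
            assert mine == theirs

    def test_asymmetric_matrix_rejected(self):
        class Fake:  # bypasses skbio's own symmetry validation
            ids = ("a", "b", "c")
            data = np.array([[0, 1.0, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError):
            phylo.nj_tree(Fake())


class TestBootstrap:
    def _alignment(self):
        return phylo.MultipleAlignment(
            ids=list("abcdef"),
            rows=["MKVAAAAKLVMKVA", "MKVAAAAKLVMKVC", "MKVAATAKLVMKVA",
                  "WRDCCCCDEWWRDC", "WRDCCCCDEWWRDG", "WRDCCGCDEWWRDC"])

    def test_clear_split_gets_full_support(self):
        tree = phylo.bootstrap_support(self._alignment(), 100, seed=1)
        supports = {frozenset(t.name for t in n.tips()): int(n.name)
                    for n in tree.non_tips(include_self=False) if n.name}
        split = [s for side, s in supports.items()
                 if side in (frozenset("abc"), frozenset("def"))]
        assert split and all(s == 100 for s in split)

    def test_single_replicate_supports_binary(self):
        tree = phylo.bootstrap_support(self._alignment(), 1, seed=2)
        vals = {int(n.name) for n in tree.non_tips(include_self=False) if n.name}
        assert vals <= {0, 100}

    def test_same_seed_reproducible(self):
        t1 = phylo.bootstrap_support(self._alignment(), 30, seed=7)
        t2 = phylo.bootstrap_support(self._alignment(), 30, seed=7)
        assert str(t1) == str(t2)

    def test_invariant_under_taxon_permutation(self):
        aln = self._alignment()
        perm = [3, 0, 5, 2, 4, 1]
        aln2 = phylo.MultipleAlignment(ids=[aln.ids[i] for i in perm],
                                       rows=[aln.rows[i] for i in perm])
        t1 = phylo.bootstrap_support(aln, 25, seed=9)
        t2 = phylo.bootstrap_support(aln2, 25, seed=9)

        def named(t):
            return {frozenset(x.name for x in n.tips()): n.name
                    for n in t.non_tips(include_self=False)}
        assert named(t1) == named(t2)


class TestSubfamilyAssignment:
    def test_identical_to_anchor(self):
        dm = DistanceMatrix([[0, 0, 2], [0, 0, 2], [2, 2, 0]],
                            ["gene1", "AT4G04930", "AT2G46210"])
        out = phylo.assign_subfamilies(
            dm, {"AT4G04930": "DES1", "AT2G46210": "SLD1"})
        assert out == {"gene1": "DES1"}

    def test_equidistant_gene_unassigned(self):
        dm = DistanceMatrix([[0, 1, 1], [1, 0, 2], [1, 2, 0]],
                            ["g", "a1", "a2"])
        out = phylo.assign_subfamilies(dm, {"a1": "FAB2", "a2": "FAD2"})
        assert out == {"g": "unassigned"}

    def test_missing_anchor_rejected(self):
        dm = DistanceMatrix([[0, 1], [1, 0]], ["g", "a1"])
        with pytest.raises(KeyError):
            phylo.assign_subfamilies(dm, {"missing": "FAB2"})

    def test_full_simulation_assignment_perfect(self, sim, named_family):
        by_locus = {g.protein.id.rsplit(".", 1)[0]: g for g in named_family}
        for locus, sub in sim.truth.subfamily.items():
            assert by_locus[locus].subfamily == sub
        sizes = {}
        for g in named_family:
            sizes[g.subfamily] = sizes.get(g.subfamily, 0) + 1
        assert sizes["FAB2"] == 9 and len(sizes) == 6
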