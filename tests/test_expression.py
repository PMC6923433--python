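import numpy as np
import pandas as pd
import pytest

from famsurvey import expression as expr
from famsurvey.simulate import (
    TISSUES, simulate_expression, simulate_qpcr, simulate_stress_arms,
)


def _matrix(values: dict, tissues: dict, n_rep=2):
    cols, meta = [], []
    for t in tissues:
        for r in range(1, n_rep + 1):
            cols.append(f"{t}_r{r}")
            meta.append({"sample": f"{t}_r{r}", "tissue": t,
                         "category": tissues[t], "replicate": r})
    data = {c: [values[g][c.rsplit('_', 1)[0]] for g in values] for c in cols}
    vals = pd.DataFrame(data, index=list(values))
    return expr.ExpressionMatrix(values=vals,
                                 samples=pd.DataFrame(meta).set_index("sample"))


TIS = {"root": "vegetative", "leaf": "vegetative",
       "flower": "reproductive", "seed": "reproductive"}


class TestAverageLog2:
    def test_identical_replicates(self):
        m = _matrix({"g": {"root": 4, "leaf": 4, "flower": 4, "seed": 4}}, TIS)
        assert (expr.average_log2(m).loc["g"] == 4).all()

    def test_mean_of_two(self):
        m = _matrix({"g": {"root": 5, "leaf": 5, "flower": 5, "seed": 5}}, TIS)
        m.values.loc["g", "root_r1"] = 4
        m.values.loc["g", "root_r2"] = 6
        assert expr.average_log2(m).loc["g", "root"] == 5

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(40)
        vals = pd.DataFrame(rng.normal(6, 2, size=(5, 8)),
                            index=[f"g{i}" for i in range(5)],
                            columns=[f"{t}_r{r}" for t in TIS for r in (1, 2)])
        meta = pd.DataFrame(
            [{"sample": f"{t}_r{r}", "tissue": t, "category": TIS[t],
              "replicate": r} for t in TIS for r in (1, 2)]).set_index("sample")
        m = expr.ExpressionMatrix(values=vals, samples=meta)
        means = expr.average_log2(m)
        for g in vals.index:
            for t in TIS:
                manual = (vals.loc[g, f"{t}_r1"] + vals.loc[g, f"{t}_r2"]) / 2
                assert means.loc[g, t] == pytest.approx(manual)


class TestClassifyGroups:
    def _means(self, rows):
        return pd.DataFrame(rows, columns=list(TIS)).set_axis(
            [f"g{i}" for i in range(len(rows))])

    def test_rule_order(self):
        means = pd.DataFrame(
            {"root": [9, 1, 9, 9], "leaf": [9, 1, 9, 5],
             "flower": [9, 1, 5, 9], "seed": [9, 1, 5, 5]},
            index=["all_high", "all_low", "veg_only", "mixed"])
        calls = {c.gene: c.group for c in expr.classify_groups(
            means, TIS, tau_high=8, tau_low=3)}
        assert calls == {"all_high": "I", "all_low": "IV",
                         "veg_only": "III", "mixed": "II"}

    def test_every_gene_gets_exactly_one_group(self):
        mat, _ = simulate_expression(seed=41, noise_sd=0.5)
        means = expr.average_log2(mat)
        calls = expr.classify_groups(means, TISSUES)
        assert len(calls) == len(means.index)
        assert all(c.group in {"I", "II", "III", "IV"} for c in calls)

    def test_noiseless_recovery_is_total(self):
        mat, truth = simulate_expression(seed=42, noise_sd=0.0)
        calls = expr.classify_groups(expr.average_log2(mat), TISSUES)
        assert all(c.group == truth[c.gene] for c in calls)

    def test_planted_group_iv_below_tau_low(self):
        mat, truth = simulate_expression(seed=43, noise_sd=0.0)
        means = expr.average_log2(mat)
        tau_high, tau_low = expr.default_thresholds(means)
        for gene, grp in truth.items():
            if grp == "IV":
                assert means.loc[gene].max() < tau_low


class TestStressDE:
    def test_identical_arms_called_none(self):
        control = pd.DataFrame([[5.0, 5.0, 5.0]], index=["g"])
        calls = expr.stress_de(control, control.copy())
        assert calls[0].direction == "none"

    def test_planted_downregulation_called(self):
        control, treated = simulate_stress_arms({"g1": -2.0, "g2": 0.0},
                                                sd=0.2, n_replicates=3, seed=44)
        calls = {c.gene: c for c in expr.stress_de(control, treated)}
        assert calls["g1"].direction == "down"
        assert calls["g1"].p_value < 0.05
        assert calls["g1"].log2_fold_change == pytest.approx(-2.0, abs=0.6)

    def test_single_replicate_rejected(self):
        one = pd.DataFrame([[5.0]], index=["g"])
        with pytest.raises(ValueError):
            expr.stress_de(one, one)


class TestHormoneResponse:
    def _rq(self, value, time=3.0):
        return pd.DataFrame([{"gene": "g", "condition": "ABA",
                              "time": time, "rq": value}])

    def test_unchanged_is_none(self):
        assert expr.hormone_response(self._rq(1.0))[0].direction == "none"

    def test_exact_twofold_boundary_is_none(self):
        assert expr.hormone_response(self._rq(2.0))[0].direction == "none"
        assert expr.hormone_response(self._rq(0.5))[0].direction == "none"

    def test_planted_fourfold_at_3h_flagged_early(self):
        call = expr.hormone_response(self._rq(4.0, time=3.0))[0]
        assert call.direction == "up" and call.early_responsive

    def test_late_response_not_flagged_early(self):
        call = expr.hormone_response(self._rq(4.0, time=24.0))[0]
        assert call.direction == "up" and not call.early_responsive

    def test_nonpositive_rq_rejected(self):
        with pytest.raises(ValueError):
            expr.hormone_response(self._rq(0.0))


class TestDdct:
    def test_calibrator_rq_is_one(self):
        table, _ = simulate_qpcr(seed=45, noise_sd=0.0)
        for r in expr.ddct(table):
            if r.sample == "control":
                assert r.rq == pytest.approx(1.0)

    def test_ddct_arithmetic(self):
        rows = []
        for sample, tgt in (("control", 28.0), ("treated", 25.0)):
            for rep in (1, 2):
                rows.append({"gene": "ref", "sample": sample, "replicate": rep,
                             "ct": 20.0})
                rows.append({"gene": "g", "sample": sample, "replicate": rep,
                             "ct": tgt})
        table = expr.QpcrTable(pd.DataFrame(rows), reference_gene="ref",
                               calibrator_sample="control")
        rq = {r.sample: r for r in expr.ddct(table)}
        assert rq["treated"].ddct == pytest.approx(-3.0)
        assert rq["treated"].rq == pytest.approx(8.0)

    def test_zero_noise_recovers_planted_folds_exactly(self):
        table, truth = simulate_qpcr(seed=46, noise_sd=0.0)
        for r in expr.ddct(table):
            assert r.rq == pytest.approx(truth[(r.gene, r.sample)], abs=1e-12)

    def test_shift_multiplicativity(self):
        table, _ = simulate_qpcr(seed=47, noise_sd=0.05)
        base = {(r.gene, r.sample): r.rq for r in expr.ddct(table)}
        shifted = table.data.copy()
        sample = "ABA_3h"
        mask = (shifted["sample"] == sample) & (shifted["gene"] != table.reference_gene)
        shifted.loc[mask, "ct"] -= 1.0
        t2 = expr.QpcrTable(shifted, reference_gene=table.reference_gene,
                            calibrator_sample=table.calibrator_sample)
        for r in expr.ddct(t2):
            if r.sample == sample:
                assert r.rq == pytest.approx(2 * base[(r.gene, r.sample)])

    def test_missing_reference_rejected(self):
        df = pd.DataFrame([{"gene": "g", "sample": "s", "replicate": 1,
                            "ct": 25.0}])
        with pytest.raises(ValueError, match="reference"):
            expr.QpcrTable(df, reference_gene="ref")

    def test_noisy_fold_two_centred(self):
        rqs = []
        for seed in range(60):
            table, _ = simulate_qpcr(
                spec={"g": {"t": 2.0}}, seed=seed, noise_sd=0.1,
                n_replicates=6)
            rqs.extend(r.rq for r in expr.ddct(table) if r.sample == "t")
        assert 1.8 <= float(np.mean(rqs)) <= 2.2
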