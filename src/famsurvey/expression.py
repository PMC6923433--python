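"""Expression analysis: tissue group classification, stress differential
expression, hormone response calls, and 2^-ddCt qPCR quantification.

Group archetypes over a vegetative/reproductive tissue panel:

* I   — high expression in (nearly) all tissues;
* II  — relatively high expression in particular tissues of both categories;
* III — abundant expression restricted to one category (vegetative or
        reproductive);
* IV  — low expression everywhere.

Thresholds tau_high/tau_low default to the 70th/30th percentiles of all
gene x tissue mean log2 values of the dataset and are recorded in every
call for auditability.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ExpressionMatrix:
    """genes x samples log2 signals plus per-sample metadata.

    ``values``: DataFrame indexed by gene, columns = sample ids.
    ``samples``: DataFrame indexed by sample id with at least columns
    ``tissue`` and ``category`` (vegetative/reproductive); ``replicate``,
    ``condition`` and ``time`` are optional.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        if "category" not in self.samples.columns:
            raise ValueError("sample metadata needs a 'category' column")


@dataclass
class GroupCall:
    gene: str
    group: str  # I..IV
    tissue_means: dict[str, float]
    tau_high: float
    tau_low: float
    f_high: float


@dataclass
class ResponseCall:
    gene: str
    condition: str
    direction: str          # up | down | none
    log2_fold_change: float
    p_value: float | None = None
    time: float | None = None
    early_responsive: bool = False


def average_log2(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Mean log2 signal per (gene, tissue) across replicates."""
    tissues = matrix.samples.loc[matrix.values.columns, "tissue"]
    if tissues.isna().any() or (tissues == "").any():
        raise ValueError("every sample needs a tissue label")
    return matrix.values.T.groupby(tissues.values).mean().T


def default_thresholds(means: pd.DataFrame, q_high: float = 0.70,
                       q_low: float = 0.30) -> tuple[float, float]:
    pool = means.to_numpy(dtype=float).ravel()
    return float(np.quantile(pool, q_high)), float(np.quantile(pool, q_low))


def classify_groups(means: pd.DataFrame, tissue_categories: dict[str, str],
                    tau_high: float | None = None, tau_low: float | None = None,
                    f_high: float = 0.8) -> list[GroupCall]:
    """Partition genes into groups I-IV from their per-tissue means.

    Rule order: IV if the max mean is below tau_low; I if at least f_high of
    tissues reach tau_high; III if every tissue reaching tau_high sits in
    exactly one category (and at least one does); otherwise II.
    """
    if tau_high is None or tau_low is None:
        th, tl = default_thresholds(means)
        tau_high = th if tau_high is None else tau_high
        tau_low = tl if tau_low is None else tau_low
    unknown = set(means.columns) - set(tissue_categories)
    if unknown:
        raise ValueError(f"tissues without category: {sorted(unknown)}")
    calls = []
    for gene, row in means.iterrows():
        vals = row.to_dict()
        high_tissues = [t for t, v in vals.items() if v >= tau_high]
        if max(vals.values()) < tau_low:
            group = "IV"
        elif len(high_tissues) / len(vals) >= f_high:
            group = "I"
        elif high_tissues and len({tissue_categories[t] for t in high_tissues}) == 1:
            group = "III"
        else:
            group = "II"
        calls.append(GroupCall(gene=gene, group=group, tissue_means=vals,
                               tau_high=tau_high, tau_low=tau_low, f_high=f_high))
    return calls


def stress_de(control: pd.DataFrame, treated: pd.DataFrame, condition: str = "stress",
              alpha: float = 0.05) -> list[ResponseCall]:
    """Welch two-sided t-test per gene on log2 values, called at raw p < alpha.

    ``control`` and ``treated`` are genes x replicate frames sharing an
    index.  No multiple-testing correction is applied (the survey convention
    of calling at raw P < 0.05).
    """
    if control.shape[1] < 2 or treated.shape[1] < 2:
        raise ValueError("need >=2 replicates per arm")
    calls = []
    for gene in control.index:
        c = control.loc[gene].to_numpy(dtype=float)
        t = treated.loc[gene].to_numpy(dtype=float)
        lfc = float(t.mean() - c.mean())
        if np.ptp(c) == 0 and np.ptp(t) == 0:
            p = 1.0 if lfc == 0 else 0.0
        else:
            p = float(sps.ttest_ind(t, c, equal_var=False).pvalue)
        if p < alpha and lfc != 0:
            direction = "up" if lfc > 0 else "down"
        else:
            direction = "none"
        calls.append(ResponseCall(gene=gene, condition=condition, direction=direction,
                                  log2_fold_change=lfc, p_value=p))
    return calls


def hormone_response(rq: pd.DataFrame, low: float = 0.5, high: float = 2.0,
                     early_time: float = 3.0) -> list[ResponseCall]:
    """Fold-change response calls from control-normalized RQ values.

    ``rq`` is long-format with columns gene, condition, time, rq (control
    normalized to 1).  up iff RQ > high, down iff RQ < low (both strict);
    a call at the early sampling time is flagged early_responsive.
    """
    required = {"gene", "condition", "time", "rq"}
    if not required <= set(rq.columns):
        raise ValueError(f"RQ table needs columns {sorted(required)}")
    if (rq["rq"].astype(float) <= 0).any():
        raise ValueError("RQ values must be positive")
    calls = []
    for row in rq.itertuples():
        val = float(row.rq)
        if val > high:
            direction = "up"
        elif val < low:
            direction = "down"
        else:
            direction = "none"
        calls.append(ResponseCall(
            gene=row.gene, condition=row.condition, direction=direction,
            log2_fold_change=math.log2(val), time=float(row.time),
            early_responsive=(direction != "none" and float(row.time) == early_time),
        ))
    return calls


@dataclass
class QpcrTable:
    """Long-format Ct table: gene, sample, replicate, ct (+ free metadata)."""

    data: pd.DataFrame
    reference_gene: str = "Os03g0234200"
    calibrator_sample: str = "control"

    def __post_init__(self):
        required = {"gene", "sample", "replicate", "ct"}
        if not required <= set(self.data.columns):
            raise ValueError(f"Ct table needs columns {sorted(required)}")
        if (self.data["ct"].astype(float) <= 0).any():
            raise ValueError("Ct values must be positive")
        for sample, grp in self.data.groupby("sample"):
            if self.reference_gene not in set(grp["gene"]):
                raise ValueError(f"reference gene missing in sample {sample!r}")


@dataclass
class RelativeQuantity:
    gene: str
    sample: str
    rq: float
    ddct: float
    rq_low: float
    rq_high: float


def ddct(table: QpcrTable) -> list[RelativeQuantity]:
    """Relative expression by the 2^-ddCt method.

    dCt = mean Ct(target) - mean Ct(reference) per sample; ddCt subtracts
    the calibrator sample's dCt; RQ = 2^-ddCt.  Replicate SDs are propagated
    (in quadrature over the four means) to an RQ range [rq_low, rq_high].
    """
    df = table.data.copy()
    df["ct"] = df["ct"].astype(float)
    stats = df.groupby(["gene", "sample"])["ct"].agg(["mean", "std", "count"])
    stats["std"] = stats["std"].fillna(0.0)

    def dct(gene, sample):
        t = stats.loc[(gene, sample)]
        r = stats.loc[(table.reference_gene, sample)]
        var = t["std"] ** 2 / t["count"] + r["std"] ** 2 / r["count"]
        return t["mean"] - r["mean"], var

    out = []
    genes = [g for g in df["gene"].unique() if g != table.reference_gene]
    samples = list(df["sample"].unique())
    if table.calibrator_sample not in samples:
        raise ValueError(f"calibrator sample {table.calibrator_sample!r} absent")
    for gene in genes:
        dct_cal, var_cal = dct(gene, table.calibrator_sample)
        for sample in samples:
            dct_s, var_s = dct(gene, sample)
            dd = dct_s - dct_cal
            sd = math.sqrt(var_s + var_cal)
            out.append(RelativeQuantity(
                gene=gene, sample=sample, rq=2.0 ** (-dd), ddct=float(dd),
                rq_low=2.0 ** (-(dd + sd)), rq_high=2.0 ** (-(dd - sd)),
            ))
    return out
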