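"""Relative qPCR quantification by the Livak 2^-ddCt method.

Target Ct values are normalized to a reference gene (beta-actin in the
motivating experiments) within each biological sample, then to the mean
delta-Ct of the control condition; the relative expression of sample s is
``2^-(dCt_s - mean control dCt)``.  Technical replicates are averaged on
the Ct scale before any differencing.  Group comparison uses a pooled-
variance two-tailed Student's t-test on the delta-Ct values, and primer
amplification efficiency is derived from the slope of a Ct vs
log10(dilution) standard curve.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "read_ct_table",
    "relative_expression",
    "ttest_two_tailed",
    "primer_efficiency",
]

CT_COLUMNS = ["sample_id", "condition", "gene", "replicate", "ct"]


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a Ct TSV with columns sample_id, condition, gene, replicate, ct."""
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return df


def relative_expression(
    ct_table: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    control_condition: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample 2^-ddCt fold changes relative to the control condition.

    Returns ``(per_sample, group_means)``.  ``per_sample`` has one row
    per biological sample with its condition, delta-Ct, delta-delta-Ct
    and fold change; ``group_means`` aggregates mean fold, geometric mean
    fold and delta-Ct mean per condition.  The control group's ddCt
    averages 0 by construction, so its geometric-mean fold is exactly 1.
    Samples missing the reference gene are dropped with a warning.
    """
    mean_ct = (
        ct_table.groupby(["sample_id", "condition", "gene"], sort=False)["ct"]
        .mean()
        .reset_index()
    )
    wide = mean_ct.pivot_table(
        index=["sample_id", "condition"], columns="gene", values="ct"
    ).reset_index()
    for gene in (target_gene, reference_gene):
        if gene not in wide.columns:
            raise ValueError(f"gene {gene!r} absent from the Ct table")
    bad = wide[reference_gene].isna()
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} sample(s) missing reference gene "
            f"{reference_gene!r}; dropped"
        )
        wide = wide.loc[~bad]
    wide = wide.dropna(subset=[target_gene])
    wide = wide.assign(delta_ct=wide[target_gene] - wide[reference_gene])
    control = wide.loc[wide["condition"] == control_condition, "delta_ct"]
    if control.empty:
        raise ValueError(f"no samples in control condition {control_condition!r}")
    baseline = control.mean()
    per_sample = wide[["sample_id", "condition", "delta_ct"]].copy()
    per_sample["ddct"] = per_sample["delta_ct"] - baseline
    per_sample["fold"] = 2.0 ** (-per_sample["ddct"])
    group = (
        per_sample.groupby("condition", sort=False)
        .agg(
            n=("fold", "size"),
            mean_fold=("fold", "mean"),
            geo_mean_fold=("fold", lambda f: float(np.exp(np.mean(np.log(f))))),
            mean_delta_ct=("delta_ct", "mean"),
        )
        .reset_index()
    )
    return per_sample.reset_index(drop=True), group


def ttest_two_tailed(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-tailed pooled-variance Student's t-test p-value.

    Zero pooled variance with equal means gives p = 1 (no evidence);
    with unequal means the difference is infinitely many pooled standard
    errors away, so p = 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def primer_efficiency(
    dilution_log10: Sequence[float], ct_values: Sequence[float]
) -> float:
    """Amplification efficiency (percent) from a dilution standard curve.

    Least-squares slope of Ct against log10(template dilution);
    efficiency% = (10^(-1/slope) - 1) * 100.  A slope of -3.3219
    (= -1/log10(2)) is a perfect doubling per cycle, i.e. 100%.
    """
    x = np.asarray(dilution_log10, dtype=float)
    y = np.asarray(ct_values, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 dilution points")
    slope = stats.linregress(x, y).slope
    if slope >= 0:
        raise ValueError(f"invalid standard curve: non-negative slope {slope:.3f}")
    return float((10.0 ** (-1.0 / slope) - 1.0) * 100.0)
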