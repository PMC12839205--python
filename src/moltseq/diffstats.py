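"""Differential accessibility and expression calling.

Differentially enriched peaks (DEPs) are called on replicate-averaged
FoldEnrich values: a peak is a DEP when its raw p-value is <= 0.05 and
|log2 fold-enrichment| >= 1 (both boundaries inclusive).  Differentially
expressed genes (DEGs) are called on a count matrix with median-of-ratios
normalization and a negative-binomial Wald test; a gene is a DEG when its
Benjamini-Hochberg adjusted p-value is <= 0.05 and |log2 fold change| >= 1.
The DEP filter deliberately uses the raw p-value and the DEG filter the
adjusted one — the two assays apply asymmetric criteria.

For a comparison named ``X_vs_Y`` the log2 fold change is ``log2(Y/X)``:
positive values mean higher in the second-named stage.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .peaks import PeakRecord

__all__ = [
    "benjamini_hochberg",
    "call_deps",
    "call_degs",
    "fpkm",
    "size_factors",
    "write_diff_table",
    "read_diff_table",
]

DIFF_COLUMNS = ["feature_id", "mean_a", "mean_b", "log2fc", "pvalue", "padj",
                "significant", "tested"]


def benjamini_hochberg(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    ``padj_(i) = min_{j >= i} m * p_(j) / j`` on the sorted p-values,
    capped at 1.  Monotone in p and invariant under input permutation.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def _welch_t_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch two-sample t-test p-values with degenerate handling."""
    with warnings.catch_warnings():
        # zero-variance rows trigger scipy's precision-loss warning; they
        # are resolved explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups: p = 1 if the means agree, else -> 0
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    degenerate = (va == 0) & (vb == 0)
    if degenerate.any():
        equal = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0
    return p


def call_deps(
    consensus_peaks: Sequence[PeakRecord],
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    p_thresh: float = 0.05,
    lfc_thresh: float = 1.0,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Call differentially enriched peaks between two conditions.

    ``samples_a``/``samples_b`` name the replicate FoldEnrich keys of the
    first- and second-named stage of the comparison.  Replicate means give
    ``mean_a``/``mean_b``; ``log2fc = log2((mean_b + pc) / (mean_a + pc))``;
    the p-value is a Welch two-sample t-test on ``log2(FE + pc)``.  A peak
    absent from every replicate of a condition is reported untested;
    otherwise missing replicates count as FoldEnrich 0.

    Returns a DataFrame in ``DIFF_COLUMNS`` order (``padj`` is NaN: the
    DEP decision rule uses the raw p-value).
    """
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("need >= 2 replicates per condition")
    n = len(consensus_peaks)
    fe_a = np.full((n, len(samples_a)), np.nan)
    fe_b = np.full((n, len(samples_b)), np.nan)
    ids = []
    for i, p in enumerate(consensus_peaks):
        ids.append(p.peak_id)
        for j, s in enumerate(samples_a):
            if s in p.fold_enrich:
                fe_a[i, j] = p.fold_enrich[s]
        for j, s in enumerate(samples_b):
            if s in p.fold_enrich:
                fe_b[i, j] = p.fold_enrich[s]

    tested = ~(np.isnan(fe_a).all(axis=1) | np.isnan(fe_b).all(axis=1))
    fe_a = np.nan_to_num(fe_a, nan=0.0)
    fe_b = np.nan_to_num(fe_b, nan=0.0)
    mean_a = fe_a.mean(axis=1)
    mean_b = fe_b.mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))

    pvalue = np.full(n, np.nan)
    if tested.any():
        la = np.log2(fe_a[tested] + pseudocount)
        lb = np.log2(fe_b[tested] + pseudocount)
        pvalue[tested] = _welch_t_rows(la, lb)

    significant = tested & (pvalue <= p_thresh) & (np.abs(log2fc) >= lfc_thresh)
    return pd.DataFrame(
        {
            "feature_id": ids, "mean_a": mean_a, "mean_b": mean_b,
            "log2fc": log2fc, "pvalue": pvalue, "padj": np.nan,
            "significant": significant, "tested": tested,
        },
        columns=DIFF_COLUMNS,
    )


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    The reference is the per-gene geometric mean over samples, computed on
    genes with all-positive counts; each sample's factor is the median
    ratio of its counts to that reference.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every sample")
    logs = np.log(mat[positive])
    log_gm = logs.mean(axis=1)
    sf = np.exp(np.median(logs - log_gm[:, None], axis=0))
    return pd.Series(sf, index=counts.columns)


def call_degs(
    counts: pd.DataFrame,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    padj_thresh: float = 0.05,
    lfc_thresh: float = 1.0,
    pseudocount: float = 0.5,
    dispersion_floor: float = 1e-8,
) -> pd.DataFrame:
    """Call differentially expressed genes between two conditions.

    Counts are normalized by median-of-ratios size factors computed on the
    samples of the comparison.  The log2 fold change is taken on the
    normalized condition means with a pseudocount, and the p-value is a
    Wald test of the log2 fold change under a negative-binomial model:
    per-gene dispersion is estimated by method of moments from the
    within-condition variances (floored at ``dispersion_floor``), the
    variance of each condition mean follows the NB mean-variance relation,
    and the statistic is referred to a t distribution with
    ``n_a + n_b - 2`` degrees of freedom to account for the handful of
    replicates behind the variance estimate.  P-values are BH-adjusted
    over all tested genes; all-zero genes are untested.
    """
    samples_a, samples_b = list(samples_a), list(samples_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("need >= 2 replicates per condition")
    sub = counts[samples_a + samples_b]
    arr = sub.to_numpy(dtype=float)
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be non-negative integers")

    sf = size_factors(sub)
    norm = arr / sf.to_numpy()[None, :]
    na, nb = len(samples_a), len(samples_b)
    norm_a, norm_b = norm[:, :na], norm[:, na:]
    mean_a = norm_a.mean(axis=1)
    mean_b = norm_b.mean(axis=1)
    tested = arr.sum(axis=1) > 0
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))

    # method-of-moments dispersion: var = mu + alpha * mu^2 per condition
    var_a = norm_a.var(axis=1, ddof=1)
    var_b = norm_b.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_a = np.where(mean_a > 0, (var_a - mean_a) / mean_a**2, np.nan)
        alpha_b = np.where(mean_b > 0, (var_b - mean_b) / mean_b**2, np.nan)
    stacked = np.stack([alpha_a, alpha_b])
    defined = ~np.isnan(stacked)
    alpha = np.where(
        defined.any(axis=0),
        np.nansum(np.where(defined, stacked, 0.0), axis=0)
        / np.maximum(defined.sum(axis=0), 1),
        dispersion_floor,
    )
    alpha = np.maximum(alpha, dispersion_floor)

    var_mean_a = (mean_a + alpha * mean_a**2) / na
    var_mean_b = (mean_b + alpha * mean_b**2) / nb
    ln2 = np.log(2.0)
    se_log2fc = np.sqrt(
        var_mean_a / (mean_a + pseudocount) ** 2
        + var_mean_b / (mean_b + pseudocount) ** 2
    ) / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = log2fc / se_log2fc
    pvalue = np.full(len(arr), np.nan)
    df = na + nb - 2
    ok = tested & np.isfinite(wald)
    pvalue[ok] = 2.0 * stats.t.sf(np.abs(wald[ok]), df)
    # zero spread and zero fold change (se == 0, lfc == 0) -> no evidence
    pvalue[tested & ~ok] = 1.0

    padj = np.full(len(arr), np.nan)
    padj[tested] = benjamini_hochberg(pvalue[tested])
    significant = tested & (padj <= padj_thresh) & (np.abs(log2fc) >= lfc_thresh)
    return pd.DataFrame(
        {
            "feature_id": counts.index, "mean_a": mean_a, "mean_b": mean_b,
            "log2fc": log2fc, "pvalue": pvalue, "padj": padj,
            "significant": significant, "tested": tested,
        },
        columns=DIFF_COLUMNS,
    ).reset_index(drop=True)


def fpkm(
    counts: pd.DataFrame,
    exonic_lengths: pd.Series,
    library_sizes: pd.Series,
) -> pd.DataFrame:
    """Fragments per kilobase of exon model per million mapped fragments.

    ``fpkm_ij = counts_ij * 1e9 / (exonic_length_i * library_size_j)``.
    """
    lengths = exonic_lengths.loc[counts.index].to_numpy(dtype=float)
    libs = library_sizes.loc[counts.columns].to_numpy(dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("exonic lengths must be positive")
    if np.any(libs <= 0):
        raise ValueError("library sizes must be positive")
    vals = counts.to_numpy(dtype=float) * 1e9 / (lengths[:, None] * libs[None, :])
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def write_diff_table(table: pd.DataFrame, path: str | Path) -> None:
    table[DIFF_COLUMNS].to_csv(path, sep="\t", index=False)


def read_diff_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
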