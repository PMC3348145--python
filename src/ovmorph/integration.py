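"""Morphology-expression integration.

Two analyses link the morphometric profile to the expression matrix:

* :func:`supervised_gene_analysis` — with patients split by a morphometric
  feature (e.g. the median of Std_Ar_Bin2), test each gene for differential
  expression between the low and high groups and report significant genes
  tagged by direction in the low group.
* :func:`feature_gene_correlation` — Pearson correlation of every
  (feature, gene) pair over shared samples, retaining highly correlated
  pairs (p < 0.005 by default, uncorrected per the screening design) with
  their sign.

Features are normalized toward approximate normality upstream (checked with
Jarque-Bera), which motivates Pearson; Spearman is available behind a flag.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats

from .signature import welch_t_p


def supervised_gene_analysis(
    matrix: pd.DataFrame,
    groups: pd.Series,
    p_max: float = 0.01,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene Welch t-test between a feature split's low and high groups.

    ``matrix`` is genes x samples (log2); ``groups`` maps sample to
    "low"/"high".  Returns genes with p < ``p_max``, each tagged "lower" or
    "higher" (expression in the low group relative to the high group),
    ordered by p.  Genes identical across groups are untestable and excluded.
    """
    g = groups.reindex(matrix.columns).dropna()
    low_ids = g.index[g == "low"]
    high_ids = g.index[g == "high"]
    if len(low_ids) < 2 or len(high_ids) < 2:
        raise ValueError("each group needs at least two samples")
    sub = matrix if genes is None else matrix.loc[genes]
    low = sub[low_ids].to_numpy(dtype=float)
    high = sub[high_ids].to_numpy(dtype=float)
    _, p = welch_t_p(low, high)
    mean_low = np.nanmean(low, axis=1)
    mean_high = np.nanmean(high, axis=1)
    sel = ~np.isnan(p) & (p < p_max)
    out = pd.DataFrame(
        {
            "gene": sub.index[sel],
            "p": p[sel],
            "direction": np.where(mean_low[sel] < mean_high[sel], "lower", "higher"),
            "mean_low": mean_low[sel],
            "mean_high": mean_high[sel],
        }
    ).sort_values("p", ignore_index=True)
    return out


def _pearson_with_nan(f: np.ndarray, genes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Correlate one feature vector against every gene row, pairwise-deleting
    entries where the feature (or gene) is missing.  Returns (r, n_used)."""
    out_r = np.full(genes.shape[0], np.nan)
    out_n = np.zeros(genes.shape[0], dtype=int)
    valid_f = ~np.isnan(f)
    gene_nan = np.isnan(genes)
    if not gene_nan.any():
        mask = valid_f
        x = f[mask]
        if len(x) >= 3 and np.ptp(x) > 0:
            y = genes[:, mask]
            xc = x - x.mean()
            yc = y - y.mean(axis=1, keepdims=True)
            denom = np.sqrt((xc**2).sum() * (yc**2).sum(axis=1))
            with np.errstate(invalid="ignore", divide="ignore"):
                out_r = (yc @ xc) / denom
            out_n[:] = len(x)
        return out_r, out_n
    for j in range(genes.shape[0]):
        mask = valid_f & ~gene_nan[j]
        x, y = f[mask], genes[j, mask]
        if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        out_r[j] = np.corrcoef(x, y)[0, 1]
        out_n[j] = len(x)
    return out_r, out_n


def feature_gene_correlation(
    features: pd.DataFrame,
    matrix: pd.DataFrame,
    p_max: float = 0.005,
    method: str = "pearson",
) -> pd.DataFrame:
    """Feature-gene correlation map over shared samples.

    ``features`` is samples x features, ``matrix`` genes x samples.  Each
    pair's correlation uses pairwise deletion of missing values; pairs with a
    zero-variance member are skipped (warned once).  Retains pairs with
    p < ``p_max``; the sign column separates positive from negative
    correlations.  ``method`` may be "pearson" (default) or "spearman"
    (rank-transform then Pearson machinery).
    """
    shared = features.index.intersection(matrix.columns)
    if len(shared) < 5:
        raise ValueError("need at least 5 shared samples")
    fmat = features.loc[shared].to_numpy(dtype=float)
    gmat = matrix[shared].to_numpy(dtype=float)
    if method == "spearman":
        fmat = np.apply_along_axis(_nan_rank, 0, fmat)
        gmat = np.apply_along_axis(_nan_rank, 1, gmat)
    elif method != "pearson":
        raise ValueError("method must be 'pearson' or 'spearman'")

    rows = []
    n_skipped = 0
    for i, fname in enumerate(features.columns):
        r, n = _pearson_with_nan(fmat[:, i], gmat)
        testable = (n >= 3) & ~np.isnan(r)
        n_skipped += int((~testable).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            rr = np.clip(r, -1.0, 1.0)
            t = rr * np.sqrt((n - 2) / (1.0 - rr**2))
            p = 2.0 * special.stdtr(n - 2.0, -np.abs(t))
            p = np.where(np.abs(rr) == 1.0, 0.0, p)
        sel = testable & (p < p_max)
        for j in np.nonzero(sel)[0]:
            rows.append(
                {
                    "feature": fname,
                    "gene": matrix.index[j],
                    "r": float(rr[j]),
                    "p": float(p[j]),
                    "sign": "positive" if rr[j] > 0 else "negative",
                    "n": int(n[j]),
                }
            )
    if n_skipped:
        warnings.warn(
            f"{n_skipped} feature-gene pairs untestable (missing or zero-variance)",
            stacklevel=2,
        )
    return pd.DataFrame(rows, columns=["feature", "gene", "r", "p", "sign", "n"])


def _nan_rank(v: np.ndarray) -> np.ndarray:
    out = np.full_like(v, np.nan, dtype=float)
    mask = ~np.isnan(v)
    out[mask] = stats.rankdata(v[mask])
    return out
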