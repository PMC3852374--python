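"""Mean-decoupled variability metrics.

Two plasticity metrics from the gene x condition matrix:

* ``plasticity_residual`` -- residual of the OLS regression (with
  intercept) of the across-condition SD on the across-condition mean.  By
  construction the residuals sum to zero and are Pearson-uncorrelated with
  the mean.
* ``plasticity_running_median`` -- distance of each gene's SD from the
  running median of SD over genes sorted by mean expression (window of 200
  genes by default).

And the mean-decoupled noise metric from single-cell summaries:

* ``noise_from_cv`` -- deviation of a gene's CV from a smoothed spline fit
  to the running median of the CV-vs-mean trend.  Real noise tables
  usually arrive with this column precomputed; the recomputation path
  exists for simulations and for completeness.

Running-median convention: genes are sorted by mean (ties broken by
gene_id, stable); the window is centered and truncated to available genes
at the edges; even-count medians average the two middle values.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import interpolate, stats

from noiseplast.io_formats import ExpressionMatrix, InputError

log = logging.getLogger(__name__)


def condition_summary(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene across-condition mean and sample SD (missing cells excluded).

    SD uses the n-1 denominator.  Genes with fewer than two observed values
    are a hard error (also guarded at read time).
    """
    vals = expr.values
    n_obs = np.sum(np.isfinite(vals), axis=1)
    bad = [g for g, n in zip(expr.gene_ids, n_obs) if n < 2]
    if bad:
        raise InputError(f"condition_summary: gene(s) with <2 observed values: {bad[:10]}")
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(vals, axis=1)
        sd = np.nanstd(vals, axis=1, ddof=1)
    return pd.DataFrame({"gene_id": expr.gene_ids, "mean_expr": mean, "sd_expr": sd})


def plasticity_residual(summary: pd.DataFrame, log_scale: bool = False) -> pd.Series:
    """OLS residual of sd_expr on mean_expr (with intercept).

    ``log_scale`` regresses on log-transformed axes instead (off by
    default: compendium intensities are already log-like).
    """
    if len(summary) < 3:
        raise InputError("plasticity_residual: need >= 3 genes")
    x = summary["mean_expr"].to_numpy(dtype=float)
    y = summary["sd_expr"].to_numpy(dtype=float)
    if log_scale:
        if np.any(x <= 0) or np.any(y <= 0):
            raise InputError("plasticity_residual: log scale needs positive mean and SD")
        x, y = np.log(x), np.log(y)
    if np.ptp(x) == 0:
        raise InputError("plasticity_residual: all mean_expr identical; regression degenerate")
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    return pd.Series(resid, index=summary.index, name="plasticity_resid")


def running_median(values, window: int) -> np.ndarray:
    """Centered running median with edge truncation.

    Position i covers indices [i - floor((window-1)/2), i + floor(window/2)]
    clipped to the array; even-count medians average the two middle values.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if window < 3:
        raise InputError("running_median: window must be >= 3")
    left = (window - 1) // 2
    right = window // 2
    out = np.empty(n)
    if n >= window:
        interior = np.lib.stride_tricks.sliding_window_view(values, window)
        out[left:n - right] = np.median(interior, axis=1)
        head = range(0, left)
        tail = range(n - right, n)
    else:
        head = range(0, n)
        tail = range(0)
    for i in head:
        out[i] = np.median(values[max(0, i - left): i + right + 1])
    for i in tail:
        out[i] = np.median(values[max(0, i - left): i + right + 1])
    return out


def _sort_order(summary: pd.DataFrame, by: str) -> np.ndarray:
    # stable sort by the key, ties broken by gene_id
    return np.lexsort((summary["gene_id"].to_numpy(),
                       summary[by].to_numpy(dtype=float)))


def plasticity_running_median(summary: pd.DataFrame, window: int = 200) -> pd.Series:
    """Distance of each gene's SD from the running median over the mean-sorted order."""
    if len(summary) < 3:
        raise InputError("plasticity_running_median: need >= 3 genes")
    if window < 3:
        raise InputError("plasticity_running_median: window must be >= 3")
    order = _sort_order(summary, "mean_expr")
    sd_sorted = summary["sd_expr"].to_numpy(dtype=float)[order]
    rm = running_median(sd_sorted, min(window, max(3, len(summary))))
    dist_sorted = sd_sorted - rm
    dist = np.empty(len(summary))
    dist[order] = dist_sorted
    return pd.Series(dist, index=summary.index, name="plasticity_rm")


def _cv_spline(x: np.ndarray, y: np.ndarray, smoothing: float | None):
    """Cubic smoothing spline through the running-median trend.

    When ``smoothing`` is None the factor is chosen by 5-fold
    cross-validation over a log-spaced grid (interleaved folds, so held-out
    points always sit inside the fitted range).
    """
    n = len(x)
    if smoothing is not None:
        return interpolate.UnivariateSpline(x, y, k=3, s=smoothing * n)
    # scale the candidate smoothing factors to the running median's own
    # step sizes: a noisy staircase gets real smoothing, an already-smooth
    # trend gets close to interpolation
    step2 = float(np.mean(np.diff(y) ** 2)) if n > 1 else 0.0
    if step2 == 0.0:
        return interpolate.UnivariateSpline(x, y, k=3, s=0.0)
    base = min(n * step2, n * np.var(y))
    grid = base * np.logspace(-2, 2, 5)
    best, best_err = base, np.inf
    for s in grid:
        err = 0.0
        ok = True
        for f in range(5):
            test = np.arange(f, n, 5)
            train = np.setdiff1d(np.arange(n), test)
            if len(train) <= 4:
                ok = False
                break
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    sp = interpolate.UnivariateSpline(x[train], y[train], k=3, s=s)
            except Exception:
                ok = False
                break
            err += float(np.mean((sp(x[test]) - y[test]) ** 2))
        if ok and err < best_err:
            best, best_err = s, err
    return interpolate.UnivariateSpline(x, y, k=3, s=best)


def noise_from_cv(noise_table: pd.DataFrame, trend_window: int = 100,
                  smoothing: float | None = None) -> pd.Series:
    """Mean-decoupled noise: deviation of the CV from the smoothed mean trend.

    Genes are sorted by single-cell mean; the CV's running median (same
    edge rule as the plasticity metric) is spline-smoothed on a log mean
    axis; noise_g = cv_g - spline(sc_mean_g).
    """
    m = noise_table["sc_mean"].to_numpy(dtype=float)
    cv = noise_table["cv"].to_numpy(dtype=float)
    if np.any(m <= 0):
        raise InputError("noise_from_cv: sc_mean must be > 0")
    if len(np.unique(m)) < 3:
        raise InputError("noise_from_cv: need >= 3 distinct sc_mean values")
    order = _sort_order(noise_table, "sc_mean")
    ms, cvs = m[order], cv[order]
    rm = running_median(cvs, min(trend_window, max(3, len(ms))))
    x = np.log10(ms)
    # collapse duplicated abscissae (splines need strictly increasing x)
    xu, inv = np.unique(x, return_inverse=True)
    yu = np.bincount(inv, weights=rm) / np.bincount(inv)
    spline = _cv_spline(xu, yu, smoothing)
    noise = cv - spline(np.log10(m))
    return pd.Series(noise, index=noise_table.index, name="noise")


def compute_metrics(expr: ExpressionMatrix, noise_table: pd.DataFrame,
                    window_plasticity: int = 200, window_noise: int = 100,
                    smoothing: float | None = None,
                    log_scale: bool = False) -> pd.DataFrame:
    """Joined per-gene metrics table.

    Assumes ``expr`` and ``noise_table`` already cover the same genes (see
    :func:`noiseplast.io_formats.intersect_datasets`).  A precomputed
    ``noise`` column is used as-is; genes with a missing value get the
    recomputed metric.
    """
    summary = condition_summary(expr)
    summary["plasticity_resid"] = plasticity_residual(summary, log_scale=log_scale)
    summary["plasticity_rm"] = plasticity_running_median(summary, window_plasticity)
    nt = noise_table.set_index("gene_id").loc[summary["gene_id"]].reset_index()
    out = summary.merge(nt, on="gene_id", validate="one_to_one")
    if out["noise"].isna().any():
        computed = noise_from_cv(out, trend_window=window_noise, smoothing=smoothing)
        n_missing = int(out["noise"].isna().sum())
        log.info("compute_metrics: recomputed noise for %d gene(s)", n_missing)
        out["noise"] = out["noise"].fillna(computed)
    return out
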