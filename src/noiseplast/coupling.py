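"""Noise-plasticity coupling: global, binned, and class-stratified.

Correlation conventions
-----------------------
Spearman: average ranks for ties; rho is the Pearson correlation of the
ranks; the two-sided p comes from the t approximation
t = rho * sqrt((n-2)/(1-rho^2)) with n-2 degrees of freedom.  |rho| = 1
reports the smallest representable positive p.  Every reported class in
practice has n >= 30, where the approximation is adequate; a permutation
p is available for small-n checks.  Constant input is an undefined
correlation and raises (binned/stratified callers flag it instead).

Class results carry raw P values (no multiple-testing correction, matching
the convention of reporting each class on its own); a Benjamini-Hochberg
column can be appended as a clearly separate extra.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from noiseplast.io_formats import AnalysisConfig, InputError

log = logging.getLogger(__name__)

_TINY = float(np.finfo(float).tiny)


class UndefinedCorrelationError(InputError):
    """Correlation undefined (constant input vector)."""


def _validate_pair(x, y, min_n: int = 3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("correlation inputs must be 1-D vectors of equal length")
    if len(x) < min_n:
        raise InputError(f"correlation needs n >= {min_n}, got {len(x)}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InputError("correlation inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant vector: correlation undefined")
    return x, y


def _corr_and_t_p(x: np.ndarray, y: np.ndarray):
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    n = len(x)
    if abs(r) >= 1.0:
        return r, _TINY
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return r, min(p, 1.0)


def pearson(x, y):
    """Product-moment correlation with two-sided t-approximation p."""
    x, y = _validate_pair(x, y)
    return _corr_and_t_p(x, y)


def spearman(x, y, permutations: int | None = None, rng=None):
    """Rank correlation (average ranks for ties) with two-sided p.

    ``permutations`` switches to a permutation p (for small-n checks);
    default is the t approximation.
    """
    x, y = _validate_pair(x, y)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho, p = _corr_and_t_p(rx, ry)
    if permutations:
        rng = np.random.default_rng(0) if rng is None else rng
        count = 0
        for _ in range(permutations):
            perm = rng.permutation(ry)
            r_perm, _ = _corr_and_t_p(rx, perm)
            if abs(r_perm) >= abs(rho) - 1e-15:
                count += 1
        p = (count + 1) / (permutations + 1)
    return rho, p


def welch_t_test(a, b):
    """Welch's unequal-variance t test, two-sided (Welch-Satterthwaite df).

    Convention: zero variance in both groups with equal means gives
    (0.0, 1.0); with different means the p underflows to the smallest
    positive value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InputError("welch_t_test: each group needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 0.0, 1.0
        return math.copysign(math.inf, a[0] - b[0]), _TINY
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Expression bins
# ---------------------------------------------------------------------------

def bin_by_expression(metrics: pd.DataFrame, n_bins: int = 5,
                      alpha: float = 0.01, value_cols=("noise", "plasticity_resid"),
                      by: str = "mean_expr") -> pd.DataFrame:
    """Spearman coupling within equally populated, nonoverlapping expression bins.

    Genes are sorted by ``by`` (ties broken by gene_id, stable) and split
    into ``n_bins`` contiguous groups; when the size is not divisible the
    remainder genes go one each to the lowest-index bins.  Bin 1 holds the
    lowest-expression genes.
    """
    n = len(metrics)
    if n < n_bins:
        raise InputError(f"bin_by_expression: need >= {n_bins} genes, got {n}")
    order = np.lexsort((metrics["gene_id"].to_numpy(),
                        metrics[by].to_numpy(dtype=float)))
    base, rem = divmod(n, n_bins)
    sizes = [base + (1 if i < rem else 0) for i in range(n_bins)]
    rows = []
    start = 0
    xcol, ycol = value_cols
    for i, size in enumerate(sizes, start=1):
        idx = order[start:start + size]
        start += size
        sub = metrics.iloc[idx]
        row = {"bin_index": i,
               "expr_lo": float(sub[by].min()),
               "expr_hi": float(sub[by].max()),
               "n": size}
        try:
            rho, p = spearman(sub[xcol], sub[ycol])
            row.update(rho=rho, p_value=p, significant=p < alpha, undefined=False)
        except (UndefinedCorrelationError, InputError):
            row.update(rho=np.nan, p_value=np.nan, significant=False, undefined=True)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gene classes
# ---------------------------------------------------------------------------

def derive_slow_growth(annot: pd.DataFrame, fraction: float = 0.10) -> pd.DataFrame:
    """Flag the slowest ``fraction`` of non-essential deletion growth rates.

    Essential genes are never flagged.  The threshold is the k-th smallest
    growth value (k = max(1, floor(fraction * m)) over the m non-essential
    genes with growth data); ties at the boundary are all included.
    """
    if not (0 < fraction < 1):
        raise InputError("derive_slow_growth: fraction must be in (0,1)")
    out = annot.copy()
    eligible = (~out["essential"]) & out["growth_rate"].notna()
    m = int(eligible.sum())
    if m == 0:
        raise InputError("derive_slow_growth: no growth data for non-essential genes")
    vals = np.sort(out.loc[eligible, "growth_rate"].to_numpy(dtype=float))
    k = max(1, int(math.floor(fraction * m)))
    threshold = vals[k - 1]
    out["slow_growth"] = eligible & (out["growth_rate"] <= threshold)
    return out


def filter_regulons(reg_map: dict, analyzed_genes, min_targets: int = 30) -> dict:
    """Keep regulators with >= min_targets targets among the analyzed genes."""
    analyzed = set(analyzed_genes)
    out = {}
    for r, targets in reg_map.items():
        joined = targets & analyzed
        if len(joined) >= min_targets:
            out[r] = joined
        else:
            log.info("filter_regulons: dropped %s (%d joined targets < %d)",
                     r, len(joined), min_targets)
    return out


@dataclasses.dataclass
class ClassSpec:
    """A labelled gene set to correlate over (supports set algebra upstream)."""
    label: str
    genes: set


def build_class_specs(metrics: pd.DataFrame, annot: pd.DataFrame,
                      regulons: pd.DataFrame, cfg: AnalysisConfig) -> list:
    """Assemble the stratification classes for the class-coupling table.

    Produces: all genes; highly expressed (top fraction by expression);
    essential; slow-growth; dosage-sensitive; the complement "other" (none
    of the three); highly expressed & other; each retained regulator and
    its per-mode slices; stress response; stress minus Sigma38 targets and
    vice versa.  Set algebra beyond these is available directly through
    :class:`ClassSpec`.
    """
    genes = set(metrics["gene_id"])
    ann = annot[annot["gene_id"].isin(genes)]
    if "slow_growth" not in ann.columns:
        ann = derive_slow_growth(ann, cfg.slow_growth_fraction)
    ess = set(ann.loc[ann["essential"], "gene_id"])
    slow = set(ann.loc[ann["slow_growth"], "gene_id"])
    dosage = set(ann.loc[ann["dosage_sensitive"], "gene_id"])
    stress = set(ann.loc[ann["stress_response"], "gene_id"])

    basis = cfg.highly_expressed_basis
    ordered = metrics.sort_values([basis, "gene_id"], ascending=[False, True],
                                  kind="stable")
    top_n = int(round(cfg.top_expression_fraction * len(metrics)))
    highly = set(ordered["gene_id"].iloc[:top_n])
    other = genes - ess - slow - dosage

    specs = [
        ClassSpec("all", genes),
        ClassSpec("highly_expressed", highly),
        ClassSpec("essential", ess),
        ClassSpec("slow_growth", slow),
        ClassSpec("dosage_sensitive", dosage),
        ClassSpec("other", other),
        ClassSpec("highly_expressed_other", highly & other),
    ]

    reg_joined = regulons[regulons["target_gene"].isin(genes)]
    full_map = {r: set(g["target_gene"]) for r, g in reg_joined.groupby("regulator")}
    retained = filter_regulons(full_map, genes, cfg.min_regulon_targets)
    for r in sorted(retained):
        specs.append(ClassSpec(r, retained[r]))
        sub = reg_joined[reg_joined["regulator"] == r]
        for mode, grp in sub.groupby("mode"):
            specs.append(ClassSpec(f"{r}:{mode}", set(grp["target_gene"])))

    specs.append(ClassSpec("stress", stress))
    if "Sigma38" in retained:
        specs.append(ClassSpec("stress_minus_Sigma38", stress - retained["Sigma38"]))
        specs.append(ClassSpec("Sigma38_minus_stress", retained["Sigma38"] - stress))
    return specs


def coupling_by_class(metrics: pd.DataFrame, class_specs, cfg: AnalysisConfig,
                      noise_col: str = "noise",
                      plast_col: str = "plasticity_resid") -> pd.DataFrame:
    """One Spearman coupling result per class.

    Classes below ``min_class_n`` are emitted with significant=False and an
    underpowered flag, never silently dropped; constant-input classes are
    flagged undefined.  ``cfg.add_bh`` appends a Benjamini-Hochberg column.
    """
    by_gene = metrics.set_index("gene_id")
    rows = []
    for spec in class_specs:
        present = sorted(spec.genes & set(by_gene.index))
        sub = by_gene.loc[present]
        n = len(sub)
        row = {"class_label": spec.label, "n": n}
        underpowered = n < cfg.min_class_n
        if n < 3:
            row.update(rho=np.nan, p_value=np.nan, significant=False,
                       underpowered=True, undefined=True)
        else:
            try:
                rho, p = spearman(sub[noise_col], sub[plast_col])
                row.update(rho=rho, p_value=p,
                           significant=(not underpowered) and p < cfg.signif_alpha,
                           underpowered=underpowered, undefined=False)
            except UndefinedCorrelationError:
                row.update(rho=np.nan, p_value=np.nan, significant=False,
                           underpowered=underpowered, undefined=True)
        rows.append(row)
    out = pd.DataFrame(rows, columns=["class_label", "rho", "p_value", "n",
                                      "significant", "underpowered", "undefined"])
    if cfg.add_bh:
        out["p_bh"] = _benjamini_hochberg(out["p_value"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    mask = np.isfinite(p)
    q = np.full_like(p, np.nan, dtype=float)
    pm = p[mask]
    m = len(pm)
    order = np.argsort(pm)
    ranked = pm[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    vals = np.empty(m)
    vals[order] = np.minimum(ranked, 1.0)
    q[mask] = vals
    return q


# ---------------------------------------------------------------------------
# Expression-matched confound control
# ---------------------------------------------------------------------------

class NotMatchableError(InputError):
    """Expression matching failed within the removal cap."""


def expression_matched_subset(focal_genes, background_genes, means: pd.Series,
                              side: str, alpha: float = 0.05,
                              max_removed_fraction: float = 0.5):
    """Trim a focal class until its mean expression matches the background.

    Iteratively removes the single most extreme focal gene on the stated
    ``side`` ("low" removes the lowest-expressed first, "high" the
    highest), re-running the Welch t test of focal vs background means
    after each removal, and stops once p >= alpha.  At most half the focal
    genes may be removed, else :class:`NotMatchableError`.

    Returns (trimmed gene list, number removed, final p).
    """
    if side not in ("low", "high"):
        raise InputError("side must be 'low' or 'high'")
    focal = [g for g in focal_genes if g in means.index]
    background = [g for g in background_genes if g in means.index]
    if len(focal) < 10:
        raise InputError("expression_matched_subset: focal class needs n >= 10")
    if len(background) < 2:
        raise InputError("expression_matched_subset: background needs n >= 2")
    # sort so the extreme to remove sits at the end of the list
    focal = sorted(focal, key=lambda g: (means[g], g), reverse=(side == "low"))
    bg_vals = means.loc[background].to_numpy(dtype=float)
    cap = int(math.floor(max_removed_fraction * len(focal)))
    removed = 0
    while True:
        _, p = welch_t_test(means.loc[focal].to_numpy(dtype=float), bg_vals)
        if p >= alpha:
            return sorted(focal), removed, p
        if removed >= cap or len(focal) <= 2:
            raise NotMatchableError(
                f"classes not matchable: removed {removed} (cap {cap}), p={p:.3g}")
        focal.pop()
        removed += 1


def matched_controls(metrics: pd.DataFrame, class_specs, cfg: AnalysisConfig,
                     noise_col: str = "noise",
                     plast_col: str = "plasticity_resid") -> pd.DataFrame:
    """Expression-matched re-analysis for classes with biased expression.

    For every class (except "all") whose mean expression differs from the
    remaining genes (Welch p < match_alpha), the extreme tail on the biased
    side is trimmed until the difference is non-significant, and the
    coupling is recomputed on the trimmed class.
    """
    by_gene = metrics.set_index("gene_id")
    means = by_gene["mean_expr"]
    all_genes = set(by_gene.index)
    rows = []
    for spec in class_specs:
        if spec.label == "all":
            continue
        focal = spec.genes & all_genes
        background = all_genes - focal
        if len(focal) < 10 or len(background) < 10:
            continue
        fv = means.loc[sorted(focal)].to_numpy(dtype=float)
        bv = means.loc[sorted(background)].to_numpy(dtype=float)
        _, p0 = welch_t_test(fv, bv)
        row = {"class_label": spec.label, "n_before": len(focal),
               "mean_p_before": p0}
        try:
            rho0, pr0 = spearman(by_gene.loc[sorted(focal), noise_col],
                                 by_gene.loc[sorted(focal), plast_col])
        except UndefinedCorrelationError:
            rho0, pr0 = np.nan, np.nan
        row.update(rho_before=rho0, p_before=pr0)
        if p0 >= cfg.match_alpha:
            row.update(side="none", n_removed=0, n_after=len(focal),
                       mean_p_after=p0, rho_after=rho0, p_after=pr0, matchable=True)
        else:
            side = "low" if fv.mean() < bv.mean() else "high"
            try:
                trimmed, n_removed, p_after = expression_matched_subset(
                    focal, background, means, side, alpha=cfg.match_alpha)
                try:
                    rho1, pr1 = spearman(by_gene.loc[trimmed, noise_col],
                                         by_gene.loc[trimmed, plast_col])
                except (UndefinedCorrelationError, InputError):
                    rho1, pr1 = np.nan, np.nan
                row.update(side=side, n_removed=n_removed, n_after=len(trimmed),
                           mean_p_after=p_after, rho_after=rho1, p_after=pr1,
                           matchable=True)
            except NotMatchableError:
                row.update(side=side, n_removed=np.nan, n_after=np.nan,
                           mean_p_after=np.nan, rho_after=np.nan, p_after=np.nan,
                           matchable=False)
        rows.append(row)
    cols = ["class_label", "n_before", "rho_before", "p_before", "mean_p_before",
            "side", "n_removed", "n_after", "rho_after", "p_after",
            "mean_p_after", "matchable"]
    return pd.DataFrame(rows, columns=cols)
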