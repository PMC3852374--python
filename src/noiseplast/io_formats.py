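"""Flat-file I/O for every table the pipeline touches.

All interchange is tab-separated UTF-8 text with ``NA`` for missing values,
matching the flat exports of microbial expression compendia and regulatory
network databases.  Gene identifiers are opaque strings matched exactly
(case-sensitive).

Schemas
-------
expression : gene_id + one column per condition (values: normalized
    log-scale intensities, unitless; missing cells allowed)
noise      : gene_id, sc_mean, cv, noise (noise may be NA, to be computed)
annotations: gene_id, essential, growth_rate, dosage_sensitive,
    stress_response  (booleans written as 0/1; growth_rate may be NA;
    alternatively `overexpression_toxic` + `dosage_curated` columns may
    replace `dosage_sensitive` and are combined per the config)
regulons   : regulator, target_gene, mode  (mode in {activation,
    repression, dual, unknown}; anything else maps to unknown with a
    logged warning)
config     : flat key: value YAML
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

NA_REP = "NA"
VALID_MODES = ("activation", "repression", "dual", "unknown")


class InputError(ValueError):
    """Invalid or inconsistent input data/configuration."""


def _read_tsv(path) -> pd.DataFrame:
    # keep_default_na=False so gene ids like "nan" survive; only "NA"/"" are missing
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                       na_values=[NA_REP, ""])


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required column(s) {missing}")


def _check_unique(ids, what, path) -> None:
    s = pd.Series(ids)
    dup = s[s.duplicated()].unique()
    if len(dup):
        raise InputError(f"{path}: duplicate {what} id(s): {', '.join(map(str, dup[:5]))}")


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ExpressionMatrix:
    """Gene x condition matrix of normalized log-scale expression values.

    ``values`` is a float array with NaN for missing cells.  Invariants:
    unique gene and condition ids, matching dimensions, and at least two
    observed values per gene (an across-condition SD needs n >= 2).
    """

    gene_ids: list
    condition_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.gene_ids = list(self.gene_ids)
        self.condition_ids = list(self.condition_ids)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene", "ExpressionMatrix")
        _check_unique(self.condition_ids, "condition", "ExpressionMatrix")
        if self.values.shape != (len(self.gene_ids), len(self.condition_ids)):
            raise InputError(
                f"ExpressionMatrix: values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.condition_ids)} conditions")
        n_obs = np.sum(np.isfinite(self.values), axis=1)
        bad = [g for g, n in zip(self.gene_ids, n_obs) if n < 2]
        if bad:
            raise InputError(
                "ExpressionMatrix: gene(s) with fewer than 2 observed values: "
                + ", ".join(map(str, bad[:10])))

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.gene_ids, name="gene_id"),
                            columns=self.condition_ids)

    def subset(self, genes) -> "ExpressionMatrix":
        """Row-subset preserving this matrix's gene order."""
        keep = set(genes)
        idx = [i for i, g in enumerate(self.gene_ids) if g in keep]
        return ExpressionMatrix([self.gene_ids[i] for i in idx],
                                self.condition_ids, self.values[idx])


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a gene x condition TSV (header = condition ids, first column gene ids)."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise InputError(f"{path}: expression matrix needs a gene_id column and >=1 condition")
    gene_col = df.columns[0]
    genes = df[gene_col].tolist()
    _check_unique(genes, "gene", path)
    conds = list(df.columns[1:])
    _check_unique(conds, "condition", path)
    try:
        values = df[conds].astype(float).to_numpy()
    except ValueError as e:
        raise InputError(f"{path}: non-numeric expression value ({e})") from e
    return ExpressionMatrix(genes, conds, values)


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    expr.to_frame().to_csv(path, sep="\t", na_rep=NA_REP)


# ---------------------------------------------------------------------------
# NoiseTable
# ---------------------------------------------------------------------------

def read_noise_table(path) -> pd.DataFrame:
    """Read the per-gene single-cell noise table.

    Columns: gene_id, sc_mean (mean single-cell expression, arbitrary
    fluorescence units, > 0), cv (coefficient of variation, >= 0), noise
    (mean-decoupled noise; NA if left to be computed by the metrics stage).
    """
    df = _read_tsv(path)
    _require_columns(df, ["gene_id", "sc_mean", "cv", "noise"], path)
    _check_unique(df["gene_id"], "gene", path)
    out = pd.DataFrame({
        "gene_id": df["gene_id"],
        "sc_mean": df["sc_mean"].astype(float),
        "cv": df["cv"].astype(float),
        "noise": df["noise"].astype(float),
    })
    if not np.all(out["sc_mean"] > 0):
        bad = out.loc[~(out["sc_mean"] > 0), "gene_id"].tolist()
        raise InputError(f"{path}: nonpositive sc_mean for gene(s): {bad[:10]}")
    if not np.all(out["cv"] >= 0):
        bad = out.loc[~(out["cv"] >= 0), "gene_id"].tolist()
        raise InputError(f"{path}: negative cv for gene(s): {bad[:10]}")
    return out


def write_noise_table(noise: pd.DataFrame, path) -> None:
    noise.to_csv(path, sep="\t", index=False, na_rep=NA_REP)


# ---------------------------------------------------------------------------
# GeneAnnotation
# ---------------------------------------------------------------------------

def _as_bool(col: pd.Series, path, name) -> pd.Series:
    mapping = {"0": False, "1": True, "true": True, "false": False,
               "True": True, "False": False}
    out = col.map(lambda v: mapping.get(str(v), None) if pd.notna(v) else False)
    if out.isna().any():
        raise InputError(f"{path}: column {name} must be boolean (0/1)")
    return out.astype(bool)


def read_annotations(path, dosage_source: str = "union") -> pd.DataFrame:
    """Read per-gene class annotations.

    ``dosage_source`` selects how dosage sensitivity is assembled when the
    file carries the two separate source columns (``overexpression_toxic``
    and ``dosage_curated``): "union" (default), "toxicity", or "curated".
    A precomputed ``dosage_sensitive`` column takes precedence.
    """
    df = _read_tsv(path)
    _require_columns(df, ["gene_id", "essential", "growth_rate", "stress_response"], path)
    _check_unique(df["gene_id"], "gene", path)
    out = pd.DataFrame({"gene_id": df["gene_id"]})
    out["essential"] = _as_bool(df["essential"], path, "essential")
    out["growth_rate"] = df["growth_rate"].astype(float)
    if "dosage_sensitive" in df.columns:
        out["dosage_sensitive"] = _as_bool(df["dosage_sensitive"], path, "dosage_sensitive")
    else:
        _require_columns(df, ["overexpression_toxic", "dosage_curated"], path)
        tox = _as_bool(df["overexpression_toxic"], path, "overexpression_toxic")
        cur = _as_bool(df["dosage_curated"], path, "dosage_curated")
        if dosage_source == "union":
            out["dosage_sensitive"] = tox | cur
        elif dosage_source == "toxicity":
            out["dosage_sensitive"] = tox
        elif dosage_source == "curated":
            out["dosage_sensitive"] = cur
        else:
            raise InputError(f"unknown dosage_source {dosage_source!r}")
    out["stress_response"] = _as_bool(df["stress_response"], path, "stress_response")
    return out


def write_annotations(annot: pd.DataFrame, path) -> None:
    df = annot.copy()
    for c in df.columns:
        if df[c].dtype == bool:
            df[c] = df[c].astype(int)
    df.to_csv(path, sep="\t", index=False, na_rep=NA_REP)


# ---------------------------------------------------------------------------
# Regulon table
# ---------------------------------------------------------------------------

def read_regulon_table(path, known_genes=None) -> pd.DataFrame:
    """Read the regulator -> target network (columns regulator, target_gene, mode).

    Unknown mode strings map to "unknown" with a logged warning.  Targets
    absent from ``known_genes`` (if given) are kept but logged.
    """
    df = _read_tsv(path)
    _require_columns(df, ["regulator", "target_gene", "mode"], path)
    mode = df["mode"].fillna("unknown")
    bad = sorted(set(mode) - set(VALID_MODES))
    if bad:
        log.warning("%s: unknown regulation mode(s) %s mapped to 'unknown'", path, bad)
        mode = mode.where(mode.isin(VALID_MODES), "unknown")
    out = pd.DataFrame({"regulator": df["regulator"],
                        "target_gene": df["target_gene"],
                        "mode": mode})
    if known_genes is not None:
        unknown = sorted(set(out["target_gene"]) - set(known_genes))
        if unknown:
            log.info("%s: %d regulon target(s) absent from annotations (kept): %s...",
                     path, len(unknown), unknown[:5])
    return out


def write_regulon_table(reg: pd.DataFrame, path) -> None:
    reg.to_csv(path, sep="\t", index=False, na_rep=NA_REP)


def regulon_map(reg: pd.DataFrame) -> dict:
    """regulator -> set of target genes."""
    return {r: set(g["target_gene"]) for r, g in reg.groupby("regulator")}


# ---------------------------------------------------------------------------
# AnalysisConfig
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AnalysisConfig:
    """Tunable parameters of the coupling analysis.

    window_plasticity : running-median window (genes) for the alternate
        plasticity metric; 200 by default.
    window_noise : running-median window for the CV-vs-mean trend when the
        noise column must be recomputed; 100 by default.
    n_bins : number of equally populated expression bins (5).
    min_class_n : classes below this size are flagged underpowered (30).
    min_regulon_targets : regulators kept only with >= this many analyzed
        targets (30).
    bin_signif_alpha : significance level for bins and class results (0.01).
    match_alpha : Welch-test level for expression matching (0.05).
    top_expression_fraction : "highly expressed" = top fraction by
        across-condition mean (0.20).
    slow_growth_fraction : slow-growth = slowest fraction of non-essential
        deletion growth rates (0.10).
    spline_smoothing : smoothing factor for the CV trend spline; None
        selects it by cross-validation.
    log_scale_regression : regress SD on mean after log transform (off:
        compendium values are already log-like).
    highly_expressed_basis : "mean_expr" (microarray mean, default) or
        "sc_mean" (single-cell mean) for the highly-expressed class.
    dosage_source : how two dosage-sensitivity sources combine ("union").
    add_bh : append a Benjamini-Hochberg adjusted-p column to class reports
        (extra, non-default output; raw P is the primary report).
    """

    window_plasticity: int = 200
    window_noise: int = 100
    n_bins: int = 5
    min_class_n: int = 30
    min_regulon_targets: int = 30
    bin_signif_alpha: float = 0.01
    match_alpha: float = 0.05
    top_expression_fraction: float = 0.20
    slow_growth_fraction: float = 0.10
    spline_smoothing: float | None = None
    log_scale_regression: bool = False
    highly_expressed_basis: str = "mean_expr"
    dosage_source: str = "union"
    add_bh: bool = False
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("top_expression_fraction", "slow_growth_fraction"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise InputError(f"{name} must be in (0,1), got {v}")
        for name in ("bin_signif_alpha", "match_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise InputError(f"{name} must be in (0,1), got {v}")
        if self.window_plasticity < 3 or self.window_noise < 3:
            raise InputError("running-median windows must be >= 3")
        if self.n_bins < 2:
            raise InputError("n_bins must be >= 2")
        if self.highly_expressed_basis not in ("mean_expr", "sc_mean"):
            raise InputError("highly_expressed_basis must be 'mean_expr' or 'sc_mean'")

    # class-level significance reuses the bin alpha (the P<0.01 convention)
    @property
    def signif_alpha(self) -> float:
        return self.bin_signif_alpha


def read_config(path) -> AnalysisConfig:
    """Load an AnalysisConfig from a flat key: value YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise InputError(f"{path}: config must be a flat key: value mapping")
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise InputError(f"{path}: unknown config key(s): {sorted(unknown)}")
    return AnalysisConfig(**raw)


def write_config(cfg: AnalysisConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Dataset intersection
# ---------------------------------------------------------------------------

def intersect_datasets(expr: ExpressionMatrix, noise: pd.DataFrame,
                       annot: pd.DataFrame):
    """Inner-join the three datasets on gene_id.

    Returns (expr_subset, noise_subset, annot_subset, genes) where ``genes``
    is the common gene list in the expression matrix's order.  Logs counts
    kept/dropped per source; an empty intersection is a hard error.
    """
    sets = {
        "expression": set(expr.gene_ids),
        "noise": set(noise["gene_id"]),
        "annotations": set(annot["gene_id"]),
    }
    common = sets["expression"] & sets["noise"] & sets["annotations"]
    if not common:
        raise InputError("intersect_datasets: empty gene intersection across inputs")
    for name, s in sets.items():
        log.info("intersect: %s kept %d / %d genes", name, len(common), len(s))
    genes = [g for g in expr.gene_ids if g in common]
    noise_f = noise[noise["gene_id"].isin(common)].reset_index(drop=True)
    annot_f = annot[annot["gene_id"].isin(common)].reset_index(drop=True)
    return expr.subset(genes), noise_f, annot_f, genes
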