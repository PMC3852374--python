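"""Orchestration: simulate -> metrics -> couple, with manifest and report.

A run directory contains:

* ``sim/`` (simulated runs) -- the four input TSVs plus the truth tables
* ``metrics.tsv`` -- per-gene metrics (mean, SD, both plasticities, noise)
* ``table1.tsv`` -- class-stratified coupling results
* ``bins.tsv`` -- expression-binned coupling
* ``matched_controls.tsv`` -- expression-matched confound re-analysis
* ``report.md`` -- human-readable summary
* ``manifest.json`` -- config snapshot, seed, checksums, row counts

Result TSVs are byte-identical across runs with the same config and seed;
the manifest (which carries a timestamp) is the only file that differs.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

import noiseplast
from noiseplast import coupling as cp
from noiseplast import io_formats as io
from noiseplast import metrics as mt
from noiseplast import synthetic as syn

log = logging.getLogger(__name__)

Z99 = 2.5758293035489004  # two-sided 99% normal quantile


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def analyze(expr: io.ExpressionMatrix, noise: pd.DataFrame, annot: pd.DataFrame,
            regulons: pd.DataFrame, cfg: io.AnalysisConfig):
    """Core analysis on in-memory inputs.

    Returns (metrics_df, table1_df, bins_df, matched_df).
    """
    expr_f, noise_f, annot_f, genes = io.intersect_datasets(expr, noise, annot)
    metrics = mt.compute_metrics(
        expr_f, noise_f, window_plasticity=cfg.window_plasticity,
        window_noise=cfg.window_noise, smoothing=cfg.spline_smoothing,
        log_scale=cfg.log_scale_regression)
    annot_f = cp.derive_slow_growth(annot_f, cfg.slow_growth_fraction)
    specs = cp.build_class_specs(metrics, annot_f, regulons, cfg)
    table1 = cp.coupling_by_class(metrics, specs, cfg)
    bins = cp.bin_by_expression(metrics, cfg.n_bins, alpha=cfg.bin_signif_alpha)
    matched = cp.matched_controls(metrics, specs, cfg)
    return metrics, table1, bins, matched


def simulate_and_couple(seed: int, sim_cfg: syn.SimulationConfig | None = None,
                        cfg: io.AnalysisConfig | None = None):
    """Fast in-memory path: simulate a dataset and run the full analysis.

    Returns a dict with expr/noise/annot/regulons/truth/metrics/table1/
    bins/matched.  Used by the acceptance harness and Monte Carlo tests.
    """
    cfg = io.AnalysisConfig() if cfg is None else cfg
    expr, noise, annot, regulons, truth = syn.generate_dataset(sim_cfg, seed=seed)
    metrics, table1, bins, matched = analyze(expr, noise, annot, regulons, cfg)
    return {"expr": expr, "noise": noise, "annot": annot, "regulons": regulons,
            "truth": truth, "metrics": metrics, "table1": table1, "bins": bins,
            "matched": matched}


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def _report_md(table1: pd.DataFrame, bins: pd.DataFrame,
               matched: pd.DataFrame, seed) -> str:
    def fmt(v):
        if isinstance(v, (float, np.floating)):
            return "NA" if not np.isfinite(v) else f"{v:.4g}"
        return str(v)

    def tab(df):
        cols = list(df.columns)
        body = [[fmt(v) for v in row] for row in df.itertuples(index=False)]
        widths = [max(len(c), *(len(r[i]) for r in body)) if body else len(c)
                  for i, c in enumerate(cols)]
        def line(cells):
            return "| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) + " |"
        sep = "|" + "|".join("-" * (w + 2) for w in widths) + "|"
        return "\n".join([line(cols), sep] + [line(r) for r in body])
    lines = [
        "# Noise-plasticity coupling report",
        "",
        f"Seed: {seed}",
        "",
        "## Coupling by gene class",
        "",
        tab(table1),
        "",
        "## Coupling by expression bin (bin 1 = lowest expression)",
        "",
        tab(bins),
        "",
        "## Expression-matched controls",
        "",
        tab(matched) if len(matched) else "(no class required matching)",
        "",
    ]
    return "\n".join(lines)


def run_all(outdir, cfg: io.AnalysisConfig | None = None, simulate: bool = False,
            seed: int = 0, sim_cfg: syn.SimulationConfig | None = None,
            expression=None, noise=None, annotations=None, regulons=None) -> dict:
    """Run the full pipeline and write all outputs; returns the manifest.

    Either ``simulate=True`` (with a seed) or the four input TSV paths must
    be provided.
    """
    cfg = io.AnalysisConfig() if cfg is None else cfg
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = {}
    if simulate:
        simdir = outdir / "sim"
        expr, noise_df, annot, reg, truth = syn.generate_dataset(
            sim_cfg, seed=seed, outdir=simdir)
        inputs = {str(p.name): _sha256(p) for p in sorted(simdir.iterdir())}
    else:
        for name, p in [("expression", expression), ("noise", noise),
                        ("annotations", annotations), ("regulons", regulons)]:
            if p is None or not Path(p).exists():
                raise io.InputError(f"missing {name} input file: {p}")
        expr = io.read_expression_matrix(expression)
        noise_df = io.read_noise_table(noise)
        annot = io.read_annotations(annotations, dosage_source=cfg.dosage_source)
        reg = io.read_regulon_table(regulons, known_genes=annot["gene_id"])
        truth = None
        inputs = {str(Path(p).name): _sha256(Path(p))
                  for p in [expression, noise, annotations, regulons]}

    metrics, table1, bins, matched = analyze(expr, noise_df, annot, reg, cfg)

    _write_tsv(metrics, outdir / "metrics.tsv")
    _write_tsv(table1, outdir / "table1.tsv")
    _write_tsv(bins, outdir / "bins.tsv")
    _write_tsv(matched, outdir / "matched_controls.tsv")
    (outdir / "report.md").write_text(_report_md(table1, bins, matched, seed))

    outputs = {name: _sha256(outdir / name)
               for name in ["metrics.tsv", "table1.tsv", "bins.tsv",
                            "matched_controls.tsv", "report.md"]}
    manifest = {
        "package_version": noiseplast.__version__,
        "seed": seed,
        "simulated": simulate,
        "config": dataclasses.asdict(cfg),
        "sim_config": (dataclasses.asdict(sim_cfg) if sim_cfg else
                       (dataclasses.asdict(syn.SimulationConfig()) if simulate else None)),
        "input_checksums": inputs,
        "output_checksums": outputs,
        "row_counts": {"metrics": len(metrics), "table1": len(table1),
                       "bins": len(bins), "matched_controls": len(matched)},
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    log.info("run_all: wrote results to %s", outdir)
    return manifest


def fisher_band(rho: float, n: int, level_z: float = Z99) -> float:
    """Half-width (on the z scale) of the Fisher confidence band for Spearman rho."""
    if n <= 3:
        return np.inf
    return level_z * np.sqrt((1.0 + rho ** 2 / 2.0) / (n - 3))


def recovery_report(truth_classes: pd.DataFrame, table1: pd.DataFrame) -> pd.DataFrame:
    """Join planted class correlations with pipeline estimates.

    ``covered`` marks estimates whose 99% Fisher-z band contains the
    planted rho (Bonett-Wright standard error for Spearman).  Classes in
    the results without a planted value are listed with covered = NA.
    """
    if len(table1) == 0:
        raise io.InputError("recovery_report: empty results")
    est = table1[["class_label", "rho", "p_value", "n"]].rename(
        columns={"rho": "rho_est", "p_value": "p_est", "n": "n_est"})
    out = est.merge(truth_classes, on="class_label", how="left")
    covered = []
    for _, r in out.iterrows():
        if not np.isfinite(r.get("rho_planted", np.nan)):
            covered.append(np.nan)
        elif not np.isfinite(r["rho_est"]):
            covered.append(False)
        elif r["rho_est"] == r["rho_planted"]:
            covered.append(True)  # degenerate exact match (e.g. planted rho = 1)
        else:
            half = fisher_band(r["rho_est"], int(r["n_est"]))
            covered.append(bool(abs(np.arctanh(np.clip(r["rho_est"], -1 + 1e-15, 1 - 1e-15))
                                    - np.arctanh(np.clip(r["rho_planted"], -1 + 1e-15, 1 - 1e-15)))
                                <= half))
    out["covered"] = covered
    return out
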