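"""Planted-truth synthetic datasets for the coupling pipeline.

The generator emits the four tables the pipeline consumes (expression
matrix, single-cell noise table, annotations, regulon network) from known
per-gene latent noise/plasticity pairs with class-specific planted rank
correlation, so every downstream stage is testable by parameter recovery.

Model sketch
------------
* Each gene g carries a latent noise propensity z_g and a latent
  responsiveness w_g, standard normal.  Within a gene's governing class c
  the pair is drawn from a bivariate Gaussian copula whose Pearson
  correlation is 2*sin(pi*rho_s/6) so that the *Spearman* correlation of
  the pair equals the planted rho_s (exact for Gaussians).
* Single-cell summaries: sc_mean log-uniform; cv = CV(sc_mean) *
  exp(sigma_z * z_g) around the mean trend CV(m) = sqrt(a/m + b^2)
  (intrinsic 1/m variance component plus an extrinsic CV floor).
* Expression across conditions: x_gc = mu_g + r_g * f_c + eps_gc with
  per-condition environmental factor f_c ~ N(0,1), responsiveness r_g
  increasing in w_g, and a residual scale increasing in mu_g, calibrated so
  the across-gene Pearson correlation of SD with mean sits near the
  configured target (0.40 by default).
* In ``coupling_mode="extrinsic"`` the z-effect enters only through the
  extrinsic CV component and sc_mean tracks mu_g, so noise-plasticity
  coupling strengthens with expression level (the intrinsic component,
  dominant for lowly expressed genes, carries an uncorrelated latent).

Class structure: marginal class sizes follow the default table below and
overlap (they sum to well over n_genes); each gene's (z,w) correlation is
that of its governing class, assigned by priority essential > slow-growth >
dosage-sensitive > (regulons & stress, strongest planted |rho| first) >
background, and classes whose quota exceeds the remaining unassigned pool
recruit members from genes whose governing rho is nearest their own, so the
marginal rank correlation of every class stays close to its planted value.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from noiseplast.io_formats import (
    ExpressionMatrix,
    InputError,
    write_annotations,
    write_expression_matrix,
    write_noise_table,
    write_regulon_table,
)

log = logging.getLogger(__name__)

#: Default marginal class sizes (genes) in a 1456-gene universe.
DEFAULT_CLASS_SIZES = {
    "essential": 99,
    "slow_growth": 312,
    "dosage_sensitive": 562,
    "H-NS": 42,
    "Fis": 53,
    "IHF": 47,
    "CRP": 147,
    "ArcA": 47,
    "FNR": 74,
    "FUR": 31,
    "Sigma70": 634,
    "Sigma38": 100,
    "Sigma24": 153,
    "Sigma28": 51,
    "Sigma54": 30,
    "Sigma32": 120,
    "stress": 155,
}

#: Default planted Spearman correlations per class.
DEFAULT_CLASS_RHO = {
    "essential": -0.01,
    "slow_growth": 0.07,
    "dosage_sensitive": 0.10,
    "H-NS": 0.65,
    "Fis": 0.35,
    "IHF": 0.12,
    "CRP": 0.31,
    "ArcA": 0.25,
    "FNR": -0.01,
    "FUR": 0.31,
    "Sigma70": 0.20,
    "Sigma38": 0.41,
    "Sigma24": 0.10,
    "Sigma28": 0.30,
    "Sigma54": -0.01,
    "Sigma32": -0.11,
    "stress": 0.38,
}

GROWTH_CLASSES = ("essential", "slow_growth", "dosage_sensitive")
REGULATORS = ("H-NS", "Fis", "IHF", "CRP", "ArcA", "FNR", "FUR",
              "Sigma70", "Sigma38", "Sigma24", "Sigma28", "Sigma54", "Sigma32")


@dataclasses.dataclass
class SimulationConfig:
    """Generator settings; defaults emulate the study conditions."""

    n_genes: int = 1456
    n_conditions: int = 466
    n_cells: int = 50_000          # cells summarized per gene (documentation only;
                                   # only mean and CV are emitted)
    class_sizes: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CLASS_SIZES))
    class_rho: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CLASS_RHO))
    background_rho: float = 0.14
    sd_mean_target_r: float = 0.40
    coupling_mode: str = "latent"  # "latent" or "extrinsic"

    # single-cell noise model: CV(m) = sqrt(cv_a/m + cv_b^2)
    sc_mean_range: tuple = (10.0, 1.0e4)
    cv_a: float = 1.0
    cv_b: float = 0.2
    sigma_z: float = 0.3           # log-CV perturbation scale carrying z
    sigma_intrinsic: float = 0.4   # extrinsic mode: log-scale intrinsic jitter
    extr_a: float = 1.0            # extrinsic mode intrinsic variance scale
    extr_b: float = 0.10           # extrinsic mode extrinsic CV floor

    # expression model
    mu_range: tuple = (6.0, 13.0)  # gene baselines (log-like intensity units)
    sd_intercept: float = 0.7      # SD(mu, w) = sd_intercept + sd_slope*mu + ...
    sd_slope: float = 0.05
    resp_scale: float = 0.383      # scale of the w-driven SD component
    resp_shape: float = 0.5        # responsiveness ~ exp(resp_shape * w)
    eps_floor: float = 0.08        # residual scale = eps_floor + eps_slope*(mu-mu_lo)
    eps_slope: float = 0.01

    # regulation modes (activation/repression/dual probabilities)
    mode_probs: tuple = (0.6, 0.3, 0.1)

    seed: int = 0

    def __post_init__(self):
        if self.coupling_mode not in ("latent", "extrinsic"):
            raise InputError("coupling_mode must be 'latent' or 'extrinsic'")
        if any(s < 0 for s in self.class_sizes.values()):
            raise InputError("class sizes must be >= 0")
        if any(s > self.n_genes for s in self.class_sizes.values()):
            raise InputError("class size exceeds n_genes")
        for name, r in {**self.class_rho, "background": self.background_rho}.items():
            if not -1.0 <= r <= 1.0:
                raise InputError(f"planted rho for {name} outside [-1,1]")
        if self.cv_a < 0 or self.cv_b < 0 or self.extr_a < 0 or self.extr_b < 0:
            raise InputError("noise-model parameters a, b must be >= 0")
        unknown = set(self.class_sizes) - set(DEFAULT_CLASS_SIZES)
        if unknown:
            raise InputError(f"unknown class name(s): {sorted(unknown)}")


@dataclasses.dataclass
class SimulationTruth:
    """Per-gene latents and class structure of one simulation."""

    genes: pd.DataFrame        # gene_id, mu, z, w, governing_class, governing_rho
    memberships: dict          # class name -> set of gene ids (marginal)
    class_rho: dict            # class name -> planted Spearman rho
    config: SimulationConfig

    def classes_frame(self) -> pd.DataFrame:
        """Planted (class, rho, size) table for recovery reports."""
        rows = [{"class_label": c, "rho_planted": self.class_rho[c],
                 "n_planted": len(m)}
                for c, m in sorted(self.memberships.items())]
        return pd.DataFrame(rows)


def _spearman_to_pearson(rho_s: float) -> float:
    """Pearson correlation of a Gaussian pair whose Spearman is rho_s."""
    return float(np.clip(2.0 * np.sin(np.pi * rho_s / 6.0), -1.0, 1.0))


def _class_priority(cfg: SimulationConfig):
    """Assignment order: growth classes first, then regulons/stress by |rho| desc."""
    rest = [c for c in cfg.class_sizes if c not in GROWTH_CLASSES]
    rest.sort(key=lambda c: (-abs(cfg.class_rho.get(c, 0.0)), c))
    return [c for c in GROWTH_CLASSES if c in cfg.class_sizes] + rest


def generate_latents(cfg: SimulationConfig, rng=None) -> SimulationTruth:
    """Draw per-gene latent (z, w) pairs and the overlapping class structure."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = cfg.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n)]

    order = _class_priority(cfg)
    pool = list(rng.permutation(n))          # unassigned genes, random order
    governing = np.array(["background"] * n, dtype=object)
    gov_rho = np.full(n, cfg.background_rho)
    memberships: dict = {}
    for cname in order:
        size = cfg.class_sizes[cname]
        rho_c = cfg.class_rho.get(cname, 0.0)
        take = min(size, len(pool))
        members = pool[:take]
        pool = pool[take:]
        for i in members:
            governing[i] = cname
            gov_rho[i] = rho_c
        extra = size - take
        if extra > 0:
            own = set(members)
            assigned = [i for i in range(n) if governing[i] != "background"
                        and i not in own]
            # recruit overlap members with the most similar governing coupling
            key = rng.random(n)
            assigned.sort(key=lambda i: (abs(gov_rho[i] - rho_c), key[i]))
            members = members + assigned[:extra]
        memberships[cname] = {gene_ids[i] for i in members}

    # draw (z, w) per governing class through the Gaussian copula
    z = np.empty(n)
    w = np.empty(n)
    for cname in list(cfg.class_sizes) + ["background"]:
        idx = np.flatnonzero(governing == cname)
        if idx.size == 0:
            continue
        rho_s = cfg.background_rho if cname == "background" \
            else cfg.class_rho.get(cname, 0.0)
        rho_p = _spearman_to_pearson(rho_s)
        e1 = rng.standard_normal(idx.size)
        e2 = rng.standard_normal(idx.size)
        z[idx] = e1
        w[idx] = rho_p * e1 + np.sqrt(max(0.0, 1.0 - rho_p ** 2)) * e2

    mu = rng.uniform(*cfg.mu_range, size=n)
    genes = pd.DataFrame({
        "gene_id": gene_ids, "mu": mu, "z": z, "w": w,
        "governing_class": governing, "governing_rho": gov_rho,
    })
    class_rho = {c: cfg.class_rho.get(c, 0.0) for c in cfg.class_sizes}
    return SimulationTruth(genes, memberships, class_rho, cfg)


def cv_trend(sc_mean, a: float, b: float):
    """Mean trend of the CV: intrinsic (a/m) variance plus extrinsic floor b."""
    m = np.asarray(sc_mean, dtype=float)
    return np.sqrt(a / m + b ** 2)


def generate_noise_table(truth: SimulationTruth, cfg: SimulationConfig | None = None,
                         rng=None) -> pd.DataFrame:
    """Emit (gene_id, sc_mean, cv, noise=NA); the noise column is left for metrics."""
    cfg = truth.config if cfg is None else cfg
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    g = truth.genes
    n = len(g)
    lo, hi = cfg.sc_mean_range
    if cfg.coupling_mode == "extrinsic":
        # single-cell mean tracks the condition-average expression baseline
        mu_lo, mu_hi = cfg.mu_range
        expo = (np.log10(lo) + (np.log10(hi) - np.log10(lo))
                * (g["mu"].to_numpy() - mu_lo) / (mu_hi - mu_lo))
        sc_mean = 10.0 ** expo * np.exp(0.1 * rng.standard_normal(n))
        u = rng.standard_normal(n)  # uncorrelated intrinsic latent
        var = (cfg.extr_a / sc_mean * np.exp(2 * cfg.sigma_intrinsic * u)
               + cfg.extr_b ** 2 * np.exp(2 * cfg.sigma_z * g["z"].to_numpy()))
        cv = np.sqrt(var)
    else:
        sc_mean = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), size=n)
        cv = cv_trend(sc_mean, cfg.cv_a, cfg.cv_b) \
            * np.exp(cfg.sigma_z * g["z"].to_numpy())
    return pd.DataFrame({"gene_id": g["gene_id"], "sc_mean": sc_mean,
                         "cv": cv, "noise": np.nan})


def planned_sd(truth: SimulationTruth, cfg: SimulationConfig | None = None):
    """Target across-condition SD per gene: linear mean trend + w-driven part."""
    cfg = truth.config if cfg is None else cfg
    g = truth.genes
    resp = np.exp(cfg.resp_shape * g["w"].to_numpy())
    resp_centered = resp - np.exp(cfg.resp_shape ** 2 / 2.0)  # E[exp(s*w)]
    sd = (cfg.sd_intercept + cfg.sd_slope * g["mu"].to_numpy()
          + cfg.resp_scale * resp_centered)
    return np.maximum(sd, 0.05)


def generate_expression_matrix(truth: SimulationTruth,
                               cfg: SimulationConfig | None = None,
                               rng=None) -> ExpressionMatrix:
    """Simulate the gene x condition matrix x_gc = mu_g + r_g * f_c + eps_gc."""
    cfg = truth.config if cfg is None else cfg
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    g = truth.genes
    n, k = len(g), cfg.n_conditions
    mu = g["mu"].to_numpy()
    sd_target = planned_sd(truth, cfg)
    sigma_eps = cfg.eps_floor + cfg.eps_slope * (mu - cfg.mu_range[0])
    # responsiveness absorbs whatever the residual scale does not carry,
    # so the realized SD tracks the planned mean trend + w component
    r = np.sqrt(np.maximum(sd_target ** 2 - sigma_eps ** 2, 1e-4))
    f = rng.standard_normal(k)                       # environmental factors
    eps = rng.standard_normal((n, k)) * sigma_eps[:, None]
    values = mu[:, None] + r[:, None] * f[None, :] + eps
    cond_ids = [f"c{j:03d}" for j in range(k)]
    return ExpressionMatrix(list(g["gene_id"]), cond_ids, values)


def generate_annotations(truth: SimulationTruth,
                         cfg: SimulationConfig | None = None, rng=None):
    """Emit the annotation table and the regulon network consistent with truth.

    Growth rates for non-essential genes are drawn from a unimodal
    distribution with a low tail, then reassigned so that the planted
    slow-growth genes hold exactly the slowest values (essential genes get
    no growth measurement).  Regulation modes are drawn per target with the
    configured activation/repression/dual probabilities.
    """
    cfg = truth.config if cfg is None else cfg
    rng = np.random.default_rng(cfg.seed + 3) if rng is None else rng
    g = truth.genes
    gene_ids = list(g["gene_id"])
    ess = truth.memberships.get("essential", set())
    slow = truth.memberships.get("slow_growth", set()) - ess
    dosage = truth.memberships.get("dosage_sensitive", set())
    stress = truth.memberships.get("stress", set())

    non_ess = [gid for gid in gene_ids if gid not in ess]
    growth = pd.Series(np.nan, index=gene_ids)
    if non_ess:
        vals = np.sort(1.2 - rng.gamma(3.0, 0.05, size=len(non_ess)))
        slow_list = [gid for gid in non_ess if gid in slow]
        fast_list = [gid for gid in non_ess if gid not in slow]
        rng.shuffle(slow_list)
        rng.shuffle(fast_list)
        k = len(slow_list)
        growth.loc[slow_list] = vals[:k]
        growth.loc[fast_list] = vals[k:]

    annot = pd.DataFrame({
        "gene_id": gene_ids,
        "essential": [gid in ess for gid in gene_ids],
        "growth_rate": growth.to_numpy(),
        "dosage_sensitive": [gid in dosage for gid in gene_ids],
        "stress_response": [gid in stress for gid in gene_ids],
    })

    rows = []
    probs = np.asarray(cfg.mode_probs, dtype=float)
    probs = probs / probs.sum()
    modes = ("activation", "repression", "dual")
    for reg in REGULATORS:
        targets = sorted(truth.memberships.get(reg, set()))
        if not targets:
            continue
        drawn = rng.choice(modes, size=len(targets), p=probs)
        rows.extend({"regulator": reg, "target_gene": t, "mode": m}
                    for t, m in zip(targets, drawn))
    regulons = pd.DataFrame(rows, columns=["regulator", "target_gene", "mode"])
    return annot, regulons


def generate_dataset(cfg: SimulationConfig | None = None, seed: int | None = None,
                     outdir=None):
    """Generate a full dataset; optionally write the five TSVs to ``outdir``.

    Returns (expr, noise, annot, regulons, truth).  Deterministic given
    (config, seed): the same inputs produce byte-identical files.
    """
    cfg = SimulationConfig() if cfg is None else cfg
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    truth = generate_latents(cfg)
    noise = generate_noise_table(truth)
    expr = generate_expression_matrix(truth)
    annot, regulons = generate_annotations(truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_expression_matrix(expr, outdir / "expression.tsv")
        write_noise_table(noise, outdir / "noise.tsv")
        write_annotations(annot, outdir / "annotations.tsv")
        write_regulon_table(regulons, outdir / "regulons.tsv")
        truth_df = truth.genes.copy()
        truth_df.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False, na_rep="NA")
        truth.classes_frame().to_csv(outdir / "truth_classes.tsv", sep="\t",
                                     index=False, na_rep="NA")
    return expr, noise, annot, regulons, truth
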