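"""Seeded generators emulating breeding-trial field books.

The default configuration mirrors a typical rainfed-rice screening trial: an
alpha-lattice (resolvable incomplete block) design with 200 unique genotypes,
two complete replications each split into six incomplete blocks, laid out on
a 20 x 20 row-column grid, with genotype effects, block effects, and plot
error that is separably autocorrelated (AR1 x AR1) across field rows and
columns.  Multi-environment books add environment main effects and
genotype-by-environment effects drawn from a compound-symmetry or
factor-analytic covariance across environments.  Marker panels are sampled
as biallelic dosages at given allele-frequency bounds with additive effects
scaled to a target heritability.

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import covstruct

__all__ = [
    "SimConfig",
    "make_alpha_lattice",
    "simulate_trial",
    "simulate_met",
    "simulate_markers",
    "inject_missing",
    "inject_outliers",
]


@dataclass
class SimConfig:
    """Study-condition parameters for the generators (defaults = demo design)."""

    n_geno: int = 200
    n_rep: int = 2
    n_block: int = 6              # incomplete blocks per replicate
    rows: int = 20
    cols: int = 20
    n_env: int = 1
    mu: float = 10.0
    sigma2_g: float = 1.0         # genotype (genetic main) variance
    sigma2_e: float = 1.0         # plot error variance
    sigma2_block: float = 0.1
    sigma2_env: float = 0.25      # environment main-effect variance
    sigma2_ge: float = 0.25       # CS-style genotype x environment variance
    rho_r: float = 0.4            # AR1 autocorrelation along rows
    rho_c: float = 0.4            # along columns
    rep_effects: Optional[Sequence[float]] = None
    fa_loadings: Optional[np.ndarray] = None  # (n_env, k) -> FA G x E instead of CS
    fa_psi: Optional[np.ndarray] = None
    missing_rate: float = 0.0
    n_outliers: int = 0
    outlier_sd: float = 8.0
    n_markers: int = 200
    maf_bounds: tuple = (0.05, 0.5)
    h2: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows * self.cols < self.n_geno * self.n_rep:
            raise ValueError(
                f"grid {self.rows}x{self.cols} too small: need at least "
                f"{self.n_geno * self.n_rep} plots"
            )
        for name in ("sigma2_g", "sigma2_e", "sigma2_block", "sigma2_env", "sigma2_ge"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("rho_r", "rho_c"):
            if not abs(getattr(self, name)) < 1:
                raise ValueError(f"{name} must satisfy |rho| < 1")


def _genotype_names(n: int) -> np.ndarray:
    width = len(str(n))
    return np.array([f"G{i + 1:0{width}d}" for i in range(n)])


def make_alpha_lattice(config: SimConfig, env: str = "E1", rng=None) -> pd.DataFrame:
    """Design skeleton: every genotype once per replicate, blocks nested in reps.

    Genotypes are randomized to incomplete blocks within each replicate and
    plots are assigned serpentine-wise along the row-column grid (left to
    right on odd rows, right to left on even), replicates occupying
    consecutive runs of plots.  Block sizes are as equal as possible when
    ``n_geno`` does not divide evenly (the padding rule).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    genos = _genotype_names(cfg.n_geno)
    # serpentine enumeration of the grid
    coords = []
    for r in range(1, cfg.rows + 1):
        cs = range(1, cfg.cols + 1) if r % 2 == 1 else range(cfg.cols, 0, -1)
        coords.extend((r, c) for c in cs)
    records = []
    pos = 0
    for rep in range(1, cfg.n_rep + 1):
        order = rng.permutation(cfg.n_geno)
        sizes = np.full(cfg.n_block, cfg.n_geno // cfg.n_block)
        sizes[: cfg.n_geno % cfg.n_block] += 1
        start = 0
        for b, size in enumerate(sizes, start=1):
            for j in range(start, start + size):
                r, c = coords[pos]
                records.append(
                    {
                        "env": env,
                        "genotype": genos[order[j]],
                        "rep": f"R{rep}",
                        "block": f"B{b}",
                        "row": r,
                        "col": c,
                    }
                )
                pos += 1
            start += size
    return pd.DataFrame(records)


def _spatial_error(cfg: SimConfig, rng) -> np.ndarray:
    """Plot error field with separable AR1 x AR1 correlation, as a rows x cols grid."""
    l_r = np.linalg.cholesky(
        covstruct.build_ar1(cfg.rho_r, cfg.rows) + 1e-10 * np.eye(cfg.rows)
    )
    l_c = np.linalg.cholesky(
        covstruct.build_ar1(cfg.rho_c, cfg.cols) + 1e-10 * np.eye(cfg.cols)
    )
    z = rng.standard_normal((cfg.rows, cfg.cols))
    return np.sqrt(cfg.sigma2_e) * (l_r @ z @ l_c.T)


def simulate_trial(
    design: pd.DataFrame,
    config: SimConfig,
    trait: str = "yield",
    rng=None,
    genetic_values: Optional[dict] = None,
    return_truth: bool = False,
):
    """Overlay a simulated trait on a design skeleton.

    y = mu + g + rep + block(rep) + eps with g ~ N(0, sigma2_g) and eps drawn
    from the AR1 x AR1 field process.  ``genetic_values`` (genotype -> value)
    overrides the iid genotype draw, which is how the MET generator injects
    environment-specific genetic effects.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 1 if rng is None else rng)
    out = design.copy()
    genos = np.unique(out["genotype"].to_numpy())
    if genetic_values is None:
        g = dict(zip(genos, np.sqrt(cfg.sigma2_g) * rng.standard_normal(len(genos))))
    else:
        g = genetic_values
    reps = np.unique(out["rep"].to_numpy())
    if cfg.rep_effects is not None:
        rep_eff = dict(zip(reps, cfg.rep_effects))
    else:
        rep_eff = dict(zip(reps, 0.25 * rng.standard_normal(len(reps))))
    blocks = out[["rep", "block"]].drop_duplicates()
    b_eff = {
        (r, b): np.sqrt(cfg.sigma2_block) * rng.standard_normal()
        for r, b in blocks.itertuples(index=False)
    }
    eps = _spatial_error(cfg, rng)
    y = (
        cfg.mu
        + out["genotype"].map(g).to_numpy()
        + out["rep"].map(rep_eff).to_numpy()
        + np.array([b_eff[(r, b)] for r, b in zip(out["rep"], out["block"])])
        + eps[out["row"].to_numpy() - 1, out["col"].to_numpy() - 1]
    )
    out[trait] = y
    if return_truth:
        truth = {"genetic": dict(g), "rep": rep_eff, "block": b_eff, "eps_grid": eps}
        return out, truth
    return out


def met_genetic_covariance(config: SimConfig) -> np.ndarray:
    """True across-environment genetic covariance implied by the config."""
    if config.fa_loadings is not None:
        lam = np.atleast_2d(np.asarray(config.fa_loadings, dtype=float))
        if lam.shape[0] != config.n_env:
            lam = lam.T
        psi = (
            np.full(config.n_env, 0.0)
            if config.fa_psi is None
            else np.broadcast_to(np.asarray(config.fa_psi, dtype=float), (config.n_env,))
        )
        return covstruct.build_fa(lam, psi)
    p = config.n_env
    return np.full((p, p), config.sigma2_g) + config.sigma2_ge * np.eye(p)


def simulate_met(config: SimConfig, trait: str = "yield", return_truth: bool = False):
    """Multi-environment book: shared genotypes, env-specific genetic values.

    Genetic values per genotype across environments are multivariate normal
    with covariance Lambda Lambda' + diag(Psi) when FA parameters are given,
    and compound symmetry (sigma2_g common + sigma2_ge specific) otherwise.
    Each environment gets its own randomized layout and AR1 x AR1 error draw.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    sigma = met_genetic_covariance(cfg)
    chol = np.linalg.cholesky(sigma + 1e-10 * np.eye(cfg.n_env))
    genos = _genotype_names(cfg.n_geno)
    gvals = rng.standard_normal((cfg.n_geno, cfg.n_env)) @ chol.T
    env_eff = np.sqrt(cfg.sigma2_env) * rng.standard_normal(cfg.n_env)
    books = []
    for j in range(cfg.n_env):
        env = f"E{j + 1}"
        design = make_alpha_lattice(cfg, env=env, rng=rng)
        gmap = dict(zip(genos, gvals[:, j] + env_eff[j]))
        books.append(simulate_trial(design, cfg, trait=trait, rng=rng, genetic_values=gmap))
    out = pd.concat(books, ignore_index=True)
    if return_truth:
        truth = {
            "genetic_values": pd.DataFrame(
                gvals, index=genos, columns=[f"E{j + 1}" for j in range(cfg.n_env)]
            ),
            "env_effects": env_eff,
            "genetic_covariance": sigma,
        }
        return out, truth
    return out


def simulate_markers(config: SimConfig):
    """Biallelic dosage panel plus true breeding values at heritability h2.

    Allele frequencies are uniform on ``maf_bounds``; dosages are
    Binomial(2, p) per individual; additive marker effects are drawn iid
    normal on the centered/scaled dosages and rescaled so that
    Var(TBV) / (Var(TBV) + sigma2_e) = h2 in the sampled population.

    Returns ``(frame, tbv)`` where ``frame`` is individuals x markers with a
    ``genotype`` index and ``tbv`` a Series of true breeding values.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 7)
    lo, hi = cfg.maf_bounds
    freqs = rng.uniform(lo, hi, size=cfg.n_markers)
    dosage = rng.binomial(2, freqs[None, :], size=(cfg.n_geno, cfg.n_markers)).astype(float)
    keep = dosage.std(axis=0) > 0
    dosage = dosage[:, keep]
    x = (dosage - dosage.mean(axis=0)) / dosage.std(axis=0, ddof=1)
    beta = rng.standard_normal(x.shape[1])
    tbv = x @ beta
    var_g = float(np.var(tbv, ddof=1))
    target = cfg.h2 * cfg.sigma2_e / max(1.0 - cfg.h2, 1e-9)
    tbv = tbv * np.sqrt(target / max(var_g, 1e-12))
    genos = _genotype_names(cfg.n_geno)
    frame = pd.DataFrame(
        dosage, index=pd.Index(genos, name="genotype"),
        columns=[f"M{k + 1}" for k in range(dosage.shape[1])],
    )
    return frame, pd.Series(tbv, index=genos, name="tbv")


def inject_missing(table: pd.DataFrame, trait: str, rate: float, seed: int = 0):
    """Blank an exact count round(rate * n) of trait values; returns (table, ids)."""
    out = table.copy()
    n = len(out)
    count = int(round(rate * n))
    rng = np.random.default_rng(seed)
    ids = np.sort(rng.choice(out.index.to_numpy(), size=count, replace=False))
    out.loc[ids, trait] = np.nan
    return out, ids


def inject_outliers(
    table: pd.DataFrame, trait: str, count: int, magnitude_sd: float = 8.0, seed: int = 0
):
    """Shift ``count`` records by ``magnitude_sd`` trait standard deviations."""
    out = table.copy()
    rng = np.random.default_rng(seed)
    ok = out.index[out[trait].notna()].to_numpy()
    ids = np.sort(rng.choice(ok, size=count, replace=False))
    sd = float(out[trait].std(ddof=1))
    signs = rng.choice([-1.0, 1.0], size=count)
    out.loc[ids, trait] = out.loc[ids, trait] + signs * magnitude_sd * sd
    return out, ids
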