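"""Single-trial analysis: five candidate models, AIC selection, extractors.

Each environment is analyzed on its own.  All five models share the same
fixed part (intercept + replicate) and random genotype and block-within-
replicate effects; they differ in how the plot error is structured:

  model1  iid error
  model2  iid error + independent random row and column factors
  model3  separable AR1(col) x AR1(row) error
  model4  AR1 correlation along rows within a column (independent columns)
  model5  AR1 correlation along columns within a row (independent rows)

The best model (lowest AIC among converged fits, ties to the simpler model)
supplies genotype BLUPs, the generalized (Cullis) heritability, and the
residual semivariogram used to diagnose remaining spatial trend.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .covstruct import CovarianceSpec
from .reml import FitResult, ModelSpec, RandomTerm, ResidualSpec, fit, model_compare

logger = logging.getLogger(__name__)

__all__ = [
    "SingleTrialResult",
    "model_specs",
    "fit_models",
    "fit_blues",
    "heritability_cullis",
    "variogram",
]

MODEL_KEYS = ("model1", "model2", "model3", "model4", "model5")

_RESIDUALS = {
    "model1": "iid",
    "model3": "ar1xar1",
    "model4": "ar1_rows",
    "model5": "ar1_cols",
}


def _iid(name: str) -> CovarianceSpec:
    return CovarianceSpec("identity", 1, {"sigma2": 1.0})


def model_specs(trait: str, genotype_random: bool = True) -> dict:
    """The five single-trial model specifications for a trait."""
    g_term = RandomTerm("genotype", ("genotype",), _iid("genotype"))
    b_term = RandomTerm("block", ("rep", "block"), _iid("block"))
    base_random = (g_term, b_term) if genotype_random else (b_term,)
    fixed = ("rep",)
    cell = None if genotype_random else "genotype"
    specs = {}
    for key in MODEL_KEYS:
        random = base_random
        if key == "model2":
            random = base_random + (
                RandomTerm("rowf", ("row",), _iid("rowf")),
                RandomTerm("colf", ("col",), _iid("colf")),
            )
            resid = ResidualSpec("iid")
        else:
            resid = ResidualSpec(_RESIDUALS[key])
        specs[key] = ModelSpec(
            response=trait,
            fixed=(("genotype",) + fixed) if not genotype_random else fixed,
            random=random,
            residual=resid,
            cell_means=cell,
        )
    return specs


@dataclass
class SingleTrialResult:
    env: str
    trait: str
    fits: dict                      # model key -> FitResult
    skipped: dict                   # model key -> reason
    comparison: pd.DataFrame
    best: str
    heritability: float
    variogram: Optional[pd.DataFrame]
    genotype_ranking: pd.DataFrame

    @property
    def best_fit(self) -> FitResult:
        return self.fits[self.best]


def fit_models(
    table: pd.DataFrame,
    trait: str,
    env: Optional[str] = None,
    models=MODEL_KEYS,
    **fit_options,
) -> SingleTrialResult:
    """Fit the candidate models for one environment and select by AIC."""
    sub = table if env is None else table[table["env"] == env]
    if env is None:
        envs = np.unique(sub["env"].to_numpy()) if "env" in sub.columns else ["?"]
        if len(envs) > 1:
            raise ValueError("single-trial analysis expects one environment; pass env=")
        env = str(envs[0])
    have_layout = {"row", "col"}.issubset(sub.columns)
    specs = model_specs(trait)
    fits, skipped = {}, {}
    for key in models:
        if key != "model1" and not have_layout:
            skipped[key] = "missing row/col layout columns"
            continue
        try:
            fits[key] = fit(specs[key], sub, **fit_options)
        except Exception as exc:  # model1 must always be attempted; others may fail
            if key == "model1":
                raise
            skipped[key] = str(exc)
            logger.warning("%s skipped for %s: %s", key, env, exc)
    comparison = model_compare(fits)
    converged = comparison[comparison["converged"]]
    best = str((converged if len(converged) else comparison).iloc[0]["model"])
    best_fit = fits[best]
    h_c = heritability_cullis(best_fit)
    vg = variogram(best_fit) if have_layout else None
    ranking = best_fit.blups["genotype"].copy()
    ranking = ranking.sort_values(
        ["blup", "genotype"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    ranking.insert(0, "rank", np.arange(1, len(ranking) + 1))
    return SingleTrialResult(
        env=env, trait=trait, fits=fits, skipped=skipped, comparison=comparison,
        best=best, heritability=h_c, variogram=vg, genotype_ranking=ranking,
    )


def fit_blues(
    table: pd.DataFrame, trait: str, model_key: str = "model1", env: Optional[str] = None,
    **fit_options,
) -> FitResult:
    """Refit a single-trial model with genotype fixed (cell means).

    Used to extract per-genotype adjusted means (BLUEs) with standard errors
    for downstream genomic prediction or two-stage analysis, avoiding the
    double shrinkage that re-using BLUPs as responses would cause.
    """
    sub = table if env is None else table[table["env"] == env]
    spec = model_specs(trait, genotype_random=False)[model_key]
    return fit(spec, sub, **fit_options)


def genotype_blue_table(blue_fit: FitResult) -> pd.DataFrame:
    """Per-genotype BLUE and SE from a cell-means fit."""
    b = blue_fit.blues
    out = b[b["term"] == "genotype"][["level", "estimate", "se"]].copy()
    out.columns = ["genotype", "blue", "se"]
    return out.reset_index(drop=True)


def heritability_cullis(fit_result: FitResult, term: str = "genotype") -> float:
    """Generalized heritability H_c = 1 - Vbar_BLUP / (2 sigma2_g).

    ``Vbar_BLUP`` is the mean variance of a difference of two genotype BLUPs,
    computed from the prediction error variances and covariances
    mean_{i<j}(PEV_i + PEV_j - 2 PEC_ij).  In a balanced design with iid
    errors this reduces to the line-mean form sigma2_g / (sigma2_g +
    sigma2_e / n_rep).  Returns 0 when the genotype variance collapses;
    values escaping [0, 1] are clamped with a warning.
    """
    spec = fit_result.varcomp.get(term)
    if spec is None:
        raise ValueError(f"fit has no random term {term!r}")
    sigma2_g = float(spec.params.get("sigma2", 0.0))
    if sigma2_g <= 1e-8:  # collapsed genotype variance (boundary estimate)
        return 0.0
    C = fit_result.pec.get(term)
    if C is None:
        raise ValueError(f"prediction error covariances unavailable for term {term!r}")
    m = C.shape[0]
    if m < 2:
        raise ValueError("need at least two genotypes")
    tr = float(np.trace(C))
    s = float(C.sum())
    vbar = 2.0 * (m * tr - s) / (m * (m - 1))
    h = 1.0 - vbar / (2.0 * sigma2_g)
    if h < 0.0 or h > 1.0:
        logger.warning("Cullis heritability %.4f outside [0, 1]; clamping", h)
    return float(np.clip(h, 0.0, 1.0))


def variogram(fit_result: FitResult, max_lag: Optional[int] = None) -> pd.DataFrame:
    """Sample semivariogram of conditional residuals over field displacements.

    gamma(dr, dc) = half the mean squared residual difference across all plot
    pairs separated by |row| displacement dr and |column| displacement dc
    (both shift directions pooled, each unordered pair counted once).
    Entries with no pair are empty (NaN); gamma(0, 0) = 0 by definition.
    """
    tab = fit_result.table
    rows = tab["row"].to_numpy(dtype=int)
    cols = tab["col"].to_numpy(dtype=int)
    grid = np.full((rows.max(), cols.max()), np.nan)
    grid[rows - 1, cols - 1] = fit_result.residuals
    nr, nc = grid.shape
    max_r = nr - 1 if max_lag is None else min(max_lag, nr - 1)
    max_c = nc - 1 if max_lag is None else min(max_lag, nc - 1)
    records = []
    for dr in range(max_r + 1):
        for dc in range(max_c + 1):
            if dr == 0 and dc == 0:
                records.append({"d_row": 0, "d_col": 0, "gamma": 0.0, "n_pairs": len(tab)})
                continue
            diffs = []
            a = grid[dr:, dc:] - grid[: nr - dr, : nc - dc]
            diffs.append(a.ravel())
            if dr > 0 and dc > 0:  # the opposite-sign quadrant
                b = grid[dr:, : nc - dc] - grid[: nr - dr, dc:]
                diffs.append(b.ravel())
            d = np.concatenate(diffs)
            d = d[~np.isnan(d)]
            gamma = 0.5 * float(np.mean(d**2)) if len(d) >= 2 else np.nan
            records.append({"d_row": dr, "d_col": dc, "gamma": gamma, "n_pairs": len(d)})
    return pd.DataFrame(records)
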