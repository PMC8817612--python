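"""Multi-environment trial (MET) analysis.

Ten single-stage models differing in the genetic (G) covariance across
environments and the residual (R) structure:

  1   genotype main + iid G x E effects, iid error (compound symmetry by
      the classic variance-component identity)
  2   explicit compound-symmetry G over environments, iid error (must agree
      with model 1 in likelihood -- a built-in cross-check)
  3   CS G, heterogeneous (per-environment) error variances
  4   CS G, common AR1 x AR1 spatial error across environments
  5   CS G, per-environment best spatial error (imported from the
      single-trial selection)
  6   diagonal G: heterogeneous genetic variance, zero correlation
  7   uniform-correlation heterogeneous-variance G (corh)
  8   factor-analytic FA(1) G
  9   FA(2) G
  10  FA(1) G + common AR1 x AR1 error

plus the two-stage route: per-environment genotype-fixed BLUEs (stage 1,
best spatial model per trial), then a weighted across-environment mixed
model on the BLUEs with weights 1/SE^2 and the residual variance constrained
to one.

Replicates within environments (and hence environment means) are fixed;
blocks within replicates are random.  Stability extractors: environment
correlation/covariance of the fitted G structure, genotype-by-environment
BLUPs, latent regression on first-factor loadings, and an FA biplot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import single_trial as st
from .covstruct import CovarianceSpec, sign_fix_loadings
from .reml import FitResult, ModelSpec, RandomTerm, ResidualSpec, fit, model_compare

logger = logging.getLogger(__name__)

__all__ = [
    "METResult",
    "StageOneSummary",
    "met_model_spec",
    "fit_met_single_stage",
    "two_stage",
    "env_correlation",
    "gxe_blup_table",
    "latent_regression",
    "fa_biplot",
]

MET_MODEL_IDS = tuple(range(1, 11))

_G_KIND = {
    1: "iid_pair", 2: "cs", 3: "cs", 4: "cs", 5: "cs",
    6: "diagonal", 7: "uniform_corr", 8: "fa1", 9: "fa2", 10: "fa1",
}
_R_KIND = {
    1: "iid", 2: "iid", 3: "diag_by_group", 4: "ar1xar1", 5: "per_group",
    6: "diag_by_group", 7: "diag_by_group", 8: "diag_by_group",
    9: "diag_by_group", 10: "ar1xar1",
}


def _prepare(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    out["env_rep"] = out["env"].astype(str) + ":" + out["rep"].astype(str)
    return out


def met_model_spec(
    trait: str, n_env: int, model_id: int, per_env_residual: Optional[dict] = None
) -> ModelSpec:
    """Build the ModelSpec for one of the ten single-stage MET models."""
    if model_id not in MET_MODEL_IDS:
        raise ValueError(f"unknown MET model id {model_id}")
    gk = _G_KIND[model_id]
    iid = CovarianceSpec("identity", 1, {"sigma2": 1.0})
    block = RandomTerm("block", ("env", "rep", "block"), iid)
    if gk == "iid_pair":
        random = (
            RandomTerm("genotype", ("genotype",), iid),
            RandomTerm("ge", ("env", "genotype"), iid),
            block,
        )
    else:
        if gk == "cs":
            g_spec = CovarianceSpec("cs", n_env, {"variance": 1.0, "covariance": 0.3})
        elif gk == "diagonal":
            g_spec = CovarianceSpec("diagonal", n_env, {"sigma2": np.ones(n_env)})
        elif gk == "uniform_corr":
            g_spec = CovarianceSpec(
                "uniform_corr", n_env, {"sigma2": np.ones(n_env), "rho": 0.3}
            )
        elif gk in ("fa1", "fa2"):
            k = 1 if gk == "fa1" else 2
            g_spec = CovarianceSpec(
                "fa", n_env,
                {"loadings": np.full((n_env, k), 0.5), "psi": np.full(n_env, 0.5)},
            )
        else:  # pragma: no cover
            raise ValueError(gk)
        random = (RandomTerm("ge", ("env", "genotype"), g_spec), block)
    rk = _R_KIND[model_id]
    if rk == "per_group":
        resid = ResidualSpec("per_group", by="env", per_group=per_env_residual or {})
    else:
        resid = ResidualSpec(rk, by="env")
    return ModelSpec(response=trait, fixed=("env_rep",), random=random, residual=resid)


@dataclass
class METResult:
    trait: str
    envs: list
    fits: dict                       # model id -> FitResult
    skipped: dict
    comparison: pd.DataFrame
    best: int
    env_cov: pd.DataFrame
    env_cor: pd.DataFrame
    loadings: Optional[np.ndarray]   # sign-fixed FA loadings of the best FA fit
    psi: Optional[np.ndarray]
    gxe_blups: pd.DataFrame          # genotype x environment predictions (wide)

    @property
    def best_fit(self) -> FitResult:
        return self.fits[self.best]

    def fa_fit(self) -> FitResult:
        """Best-AIC FA fit (needed by the stability extractors)."""
        fa_ids = [i for i in self.fits if self.fits[i].varcomp.get("ge") is not None
                  and self.fits[i].varcomp["ge"].kind == "fa"]
        if not fa_ids:
            raise ValueError("no factor-analytic model was fitted")
        return self.fits[min(fa_ids, key=lambda i: self.fits[i].aic)]


def fit_met_single_stage(
    table: pd.DataFrame,
    trait: str,
    model_ids: Sequence[int] = MET_MODEL_IDS,
    per_env_residual: Optional[dict] = None,
    fa_retry_starts: int = 3,
    **fit_options,
) -> METResult:
    """Fit the requested single-stage MET models and select by AIC.

    ``per_env_residual`` maps environment -> residual kind for model 5; when
    absent and model 5 is requested, the per-environment best spatial model
    is determined by running the single-trial selection first.
    """
    data = _prepare(table)
    envs = list(np.unique(data["env"].to_numpy()))
    if len(envs) < 2:
        raise ValueError("MET analysis needs at least 2 environments")
    if 5 in model_ids and per_env_residual is None:
        per_env_residual = {}
        for env in envs:
            res = st.fit_models(
                data, trait, env=env, models=("model1", "model3", "model4", "model5"),
                **fit_options,
            )
            per_env_residual[env] = st._RESIDUALS[res.best]
            logger.info("model 5 residual for %s: %s", env, per_env_residual[env])
    fits, skipped = {}, {}
    for mid in model_ids:
        spec = met_model_spec(trait, len(envs), mid, per_env_residual)
        try:
            f = fit(spec, data, **fit_options)
            if not f.converged and _G_KIND[mid] in ("fa1", "fa2") and fa_retry_starts:
                retry = dict(fit_options)
                retry["starts"] = fit_options.get("starts", 3) + fa_retry_starts
                retry["seed"] = fit_options.get("seed", 0) + 1
                f2 = fit(spec, data, **retry)
                if f2.loglik > f.loglik:
                    f = f2
            fits[mid] = f
        except Exception as exc:
            skipped[mid] = str(exc)
            logger.warning("MET model %d skipped: %s", mid, exc)
    if not fits:
        raise ValueError("no MET model could be fitted")
    comparison = model_compare(fits)
    converged = comparison[comparison["converged"]]
    best = int((converged if len(converged) else comparison).iloc[0]["model"])
    env_cov, env_cor = env_correlation(fits[best], envs)
    loadings = psi = None
    try:
        fa = METResult(trait, envs, fits, skipped, comparison, best,
                       env_cov, env_cor, None, None, pd.DataFrame()).fa_fit()
        spec_fa = fa.varcomp["ge"]
        loadings = sign_fix_loadings(np.asarray(spec_fa.params["loadings"]))
        psi = np.asarray(spec_fa.params["psi"])
    except ValueError:
        pass
    gxe = gxe_blup_table(fits[best])
    return METResult(
        trait=trait, envs=envs, fits=fits, skipped=skipped, comparison=comparison,
        best=best, env_cov=env_cov, env_cor=env_cor, loadings=loadings, psi=psi,
        gxe_blups=gxe,
    )


def _implied_env_cov(fit_result: FitResult, n_env: int) -> np.ndarray:
    """Across-environment genetic covariance implied by a fitted G structure."""
    vc = fit_result.varcomp
    if "ge" in vc and vc["ge"].dim == n_env:
        return vc["ge"].realize()
    # model 1: iid genotype main + iid interaction
    s_g = float(vc["genotype"].params["sigma2"])
    s_ge = float(vc["ge"].params["sigma2"])
    return np.full((n_env, n_env), s_g) + s_ge * np.eye(n_env)


def env_correlation(fit_result: FitResult, envs: Optional[list] = None):
    """Environment covariance and correlation matrices of the fitted G structure.

    Environments with (numerically) zero genetic variance get an undefined
    (NaN) correlation row/column.
    """
    if envs is None:
        envs = list(fit_result.blups["ge"]["env"].unique())
    p = len(envs)
    cov = _implied_env_cov(fit_result, p)
    sd = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        cor = cov / np.outer(sd, sd)
    cor[~np.isfinite(cor)] = np.nan
    ok = sd > 1e-10
    cor[np.ix_(ok, ok)] = np.clip(cor[np.ix_(ok, ok)], -1.0, 1.0)
    np.fill_diagonal(cor, np.where(ok, 1.0, np.nan))
    env_cov = pd.DataFrame(cov, index=envs, columns=envs)
    env_cor = pd.DataFrame(cor, index=envs, columns=envs)
    return env_cov, env_cor


def gxe_blup_table(fit_result: FitResult) -> pd.DataFrame:
    """Genotype x environment predicted genetic values, wide (genotype rows).

    For model 1 the prediction is the genotype main BLUP plus the
    interaction BLUP; structured models carry the whole genetic effect on
    the genotype-within-environment term.
    """
    ge = fit_result.blups["ge"]
    wide = ge.pivot(index="genotype", columns="env", values="blup")
    if "genotype" in fit_result.blups and "ge" in fit_result.blups:
        g_main = fit_result.blups.get("genotype")
        if g_main is not None and set(g_main.columns[:-2]) == {"genotype"}:
            main = g_main.set_index("genotype")["blup"]
            wide = wide.add(main, axis=0)
    wide.columns.name = None
    return wide


def latent_regression(met_result: METResult, top_n: Optional[int] = 10) -> pd.DataFrame:
    """Per-genotype regression of env-specific genetic values on factor-1 loadings.

    The slope measures sensitivity to the latent environmental gradient
    (stability); under an FA(1) structure with vanishing specific variances
    the fitted values decompose exactly as value_ij = score_i * loading_j.
    Returns slope, intercept, mean value and 95% CI half-widths; when
    ``top_n`` is given, only the genotypes with the highest mean predicted
    value are returned.
    """
    fa = met_result.fa_fit()
    lam = sign_fix_loadings(np.asarray(fa.varcomp["ge"].params["loadings"]))[:, 0]
    values = gxe_blup_table(fa)
    lam = pd.Series(lam, index=met_result.envs).reindex(values.columns).to_numpy()
    rows = []
    for geno, vals in values.iterrows():
        y = vals.to_numpy(dtype=float)
        res = stats.linregress(lam, y)
        df = len(y) - 2
        half = stats.t.ppf(0.975, df) * res.stderr if df > 0 else np.nan
        rows.append(
            {
                "genotype": geno, "slope": res.slope, "intercept": res.intercept,
                "mean_value": float(np.mean(y)), "ci_half_width": half,
            }
        )
    out = pd.DataFrame(rows).sort_values("mean_value", ascending=False, kind="mergesort")
    if top_n is not None:
        out = out.head(top_n)
    return out.reset_index(drop=True)


def fa_biplot(
    met_result: METResult,
    selected: Optional[Sequence[str]] = None,
    allow_k1_fallback: bool = True,
) -> dict:
    """Biplot coordinates: environment vectors and genotype scores.

    Environment vectors are the first two columns of the principal-axis
    rotation of the FA loadings; genotype scores come from regressing each
    genotype's G x E BLUPs on those rotated loadings.  For an FA(1) fit the
    second axis falls back to the specific-variance scale (sqrt(psi)) when
    ``allow_k1_fallback`` is set, otherwise an error is raised.  The
    ``selected`` list flags genotypes (default: top decile by overall BLUP).
    """
    fa = met_result.fa_fit()
    spec = fa.varcomp["ge"]
    lam = sign_fix_loadings(np.asarray(spec.params["loadings"]))
    psi = np.asarray(spec.params["psi"])
    if lam.shape[1] >= 2:
        u, s, vt = np.linalg.svd(lam, full_matrices=False)
        axes = u[:, :2] * s[:2]
    elif allow_k1_fallback:
        axes = np.column_stack([lam[:, 0], np.sqrt(psi)])
    else:
        raise ValueError("biplot needs an FA order of at least 2 (or the k=1 fallback)")
    values = gxe_blup_table(fa)
    axes_df = pd.DataFrame(axes, index=met_result.envs, columns=["axis1", "axis2"])
    axes_df = axes_df.reindex(values.columns)
    A = axes_df.to_numpy()
    scores, *_ = np.linalg.lstsq(A, values.to_numpy().T, rcond=None)
    score_df = pd.DataFrame(scores.T, index=values.index, columns=["axis1", "axis2"])
    mean_val = values.mean(axis=1)
    if selected is None:
        k = max(1, int(np.ceil(len(score_df) / 10)))
        selected = mean_val.sort_values(ascending=False).head(k).index
    score_df["selected"] = score_df.index.isin(set(selected))
    score_df["mean_value"] = mean_val
    return {"env_vectors": axes_df, "genotype_scores": score_df}


@dataclass
class StageOneSummary:
    """Per (environment, genotype) adjusted means and weights from stage one."""

    table: pd.DataFrame             # env, genotype, blue, se, weight
    best_models: dict               # env -> single-trial model key
    excluded: list = field(default_factory=list)


def two_stage(
    table: pd.DataFrame,
    trait: str,
    stage1_models=("model1", "model3", "model4", "model5"),
    **fit_options,
) -> tuple:
    """Two-stage weighted MET analysis.

    Stage one fits, per environment, the best spatial single-trial model with
    genotype fixed, extracting BLUEs and their standard errors; stage two
    fits ``blue = mu + genotype + env + genotype:env`` across environments
    with diagonal weights 1/SE^2 and the residual variance fixed at one.
    """
    envs = list(np.unique(table["env"].to_numpy()))
    rows = []
    best_models = {}
    excluded = []
    for env in envs:
        sel = st.fit_models(table, trait, env=env, models=stage1_models, **fit_options)
        best_models[env] = sel.best
        blue_fit = st.fit_blues(table, trait, model_key=sel.best, env=env, **fit_options)
        blues = st.genotype_blue_table(blue_fit)
        for _, r in blues.iterrows():
            if not np.isfinite(r["se"]) or r["se"] <= 1e-10:
                excluded.append({"env": env, "genotype": r["genotype"], "reason": "degenerate SE"})
                logger.info("stage 1: dropping %s in %s (degenerate SE)", r["genotype"], env)
                continue
            rows.append(
                {
                    "env": env, "genotype": r["genotype"], "blue": r["blue"],
                    "se": r["se"], "weight": 1.0 / r["se"] ** 2,
                }
            )
    stage1 = StageOneSummary(pd.DataFrame(rows), best_models, excluded)
    iid = CovarianceSpec("identity", 1, {"sigma2": 1.0})
    spec2 = ModelSpec(
        response="blue",
        fixed=(),
        random=(
            RandomTerm("genotype", ("genotype",), iid),
            RandomTerm("env", ("env",), iid),
            RandomTerm("ge", ("env", "genotype"), iid),
        ),
        residual=ResidualSpec("iid", fixed_sigma2=1.0),
        weights="weight",
    )
    stage2 = fit(spec2, stage1.table, **fit_options)
    return stage1, stage2
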