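"""End-to-end analysis pipeline: QC, single-trial, MET, gBLUP, report.

Stages run in the workflow order (import, pre-processing, modeling, result
extraction).  A failing stage is annotated in the bundle and the report is
still emitted with whatever completed; the caller decides the exit code.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import gblup as gb
from . import met as met_mod
from . import qc as qc_mod
from . import report as rpt
from . import single_trial as st
from .io import RunConfig, TrialTable, read_marker_csv, read_trial_csv
from .qc import QCConfig, QCReport

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class TraitResult:
    trait: str
    qc_report: Optional[QCReport] = None
    qc_table: Optional[pd.DataFrame] = None       # the cleaned data
    single: dict = field(default_factory=dict)    # env -> SingleTrialResult
    met: object = None
    stage1: object = None
    stage2: object = None
    gblup_fit: object = None
    failures: dict = field(default_factory=dict)  # stage -> message


@dataclass
class PipelineResult:
    config: RunConfig
    traits: dict                                  # trait -> TraitResult
    outdir: Path
    report_path: Optional[Path] = None

    @property
    def ok(self) -> bool:
        return all(not t.failures for t in self.traits.values())


def _qc_stage(data: pd.DataFrame, trait: str, cfg: RunConfig, fit_opts: dict):
    qcc = QCConfig(
        missing_threshold=cfg.missing_threshold,
        reliability_threshold=cfg.reliability_threshold,
        outlier_alpha=cfg.outlier_alpha,
    )
    kept, report = qc_mod.missingness_filter(data, trait, qcc)
    report.descriptives = qc_mod.descriptive_stats(kept, trait)
    # outlier screen on the baseline design model, per environment
    flags = []
    for env in np.unique(kept["env"].to_numpy()):
        base = st.fit_models(kept, trait, env=env, models=("model1",), **fit_opts)
        out = qc_mod.holm_outliers(base.fits["model1"], qcc.outlier_alpha)
        out.insert(0, "env", env)
        flags.append(out)
    outliers = pd.concat(flags, ignore_index=True)
    report.outliers = outliers[outliers["flagged"]].reset_index(drop=True)
    drop_records = set(report.outliers["record"].tolist())
    if drop_records:
        kept = kept.copy()
        kept.loc[kept.index.isin(drop_records), trait] = np.nan
        logger.info("masked %d outlier responses", len(drop_records))
    # reliability screen after outlier masking
    rel_rows = []
    keep_envs = []
    for env in np.unique(kept["env"].to_numpy()):
        base = st.fit_models(kept, trait, env=env, models=("model1",), **fit_opts)
        value, keep = qc_mod.trial_reliability(base.fits["model1"], qcc)
        rel_rows.append({"env": env, "reliability": value, "kept": keep})
        report.decisions.append(
            {"env": str(env), "action": "keep" if keep else "drop",
             "reason": "reliability", "value": float(value)}
        )
        if keep:
            keep_envs.append(env)
    report.reliability = pd.DataFrame(rel_rows)
    kept = kept[kept["env"].isin(keep_envs)]
    if kept.empty:
        raise qc_mod.QCError("no data survives QC: every trial fails the reliability screen")
    return kept, report


def run_pipeline(
    config: RunConfig,
    table: Optional[TrialTable] = None,
    markers: Optional[pd.DataFrame] = None,
    write: bool = True,
) -> PipelineResult:
    """Run the full workflow for every configured trait and emit the bundle."""
    cfg = config
    outdir = Path(cfg.out)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
    if table is None:
        if cfg.input is None:
            raise ValueError("no input table given (config.input or table=)")
        table = read_trial_csv(cfg.input, cfg.traits, cfg.column_map, cfg.metadata)
    if markers is None and cfg.markers:
        markers = read_marker_csv(cfg.markers)

    fit_opts = {"seed": cfg.seed, "starts": cfg.starts}
    results = {}
    for trait in cfg.traits:
        tr = TraitResult(trait=trait)
        results[trait] = tr
        data = table.data
        try:
            data, tr.qc_report = _qc_stage(data, trait, cfg, fit_opts)
            tr.qc_table = data
        except Exception as exc:
            tr.failures["qc"] = str(exc)
            logger.exception("QC failed for %s", trait)
            continue
        envs = list(np.unique(data["env"].to_numpy()))
        try:
            for env in envs:
                tr.single[env] = st.fit_models(
                    data, trait, env=env, models=cfg.single_trial_models, **fit_opts
                )
        except Exception as exc:
            tr.failures["single_trial"] = str(exc)
            logger.exception("single-trial stage failed for %s", trait)
        if len(envs) >= 2:
            try:
                per_env = {
                    e: st._RESIDUALS.get(r.best, "iid") for e, r in tr.single.items()
                }
                tr.met = met_mod.fit_met_single_stage(
                    data, trait, model_ids=cfg.met_models,
                    per_env_residual=per_env or None, **fit_opts,
                )
            except Exception as exc:
                tr.failures["met"] = str(exc)
                logger.exception("MET stage failed for %s", trait)
            if cfg.two_stage:
                try:
                    tr.stage1, tr.stage2 = met_mod.two_stage(data, trait, **fit_opts)
                except Exception as exc:
                    tr.failures["two_stage"] = str(exc)
        if markers is not None:
            try:
                ms = gb.encode_markers(markers)
                tr.gblup_fit = gb.fit_gblup(data, gb.grm(ms), trait, **fit_opts)
            except Exception as exc:
                tr.failures["gblup"] = str(exc)
                logger.exception("gBLUP stage failed for %s", trait)
        if write:
            _write_artifacts(outdir, tr)
    result = PipelineResult(config=cfg, traits=results, outdir=outdir)
    if write:
        html_text = build_report(result, table)
        result.report_path = outdir / "report.html"
        result.report_path.write_text(html_text)
    return result


def _write_artifacts(outdir: Path, tr: TraitResult) -> None:
    d = outdir / tr.trait
    d.mkdir(parents=True, exist_ok=True)
    if tr.qc_report is not None:
        tr.qc_report.decisions_frame().to_csv(d / "qc_decisions.csv", index=False)
        with open(d / "qc_report.json", "w") as fh:
            json.dump(tr.qc_report.to_json_dict(), fh, indent=1, default=str)
    for env, res in tr.single.items():
        res.genotype_ranking.to_csv(d / f"blups_{env}.csv", index=False)
        res.comparison.to_csv(d / f"model_selection_{env}.csv", index=False)
        if res.variogram is not None:
            res.variogram.to_csv(d / f"variogram_{env}.csv", index=False)
    if tr.met is not None:
        tr.met.env_cor.to_csv(d / "env_correlation.csv")
        tr.met.env_cov.to_csv(d / "env_covariance.csv")
        tr.met.gxe_blups.to_csv(d / "gxe_blups.csv")
        tr.met.comparison.to_csv(d / "met_model_selection.csv", index=False)
        try:
            met_mod.latent_regression(tr.met, top_n=None).to_csv(
                d / "latent_slopes.csv", index=False
            )
            bp = met_mod.fa_biplot(tr.met)
            bp["env_vectors"].to_csv(d / "biplot_env.csv")
            bp["genotype_scores"].to_csv(d / "biplot_genotypes.csv")
        except ValueError:
            pass
    if tr.stage1 is not None:
        tr.stage1.table.to_csv(d / "stage1_blues.csv", index=False)
    if tr.stage2 is not None:
        tr.stage2.blups["genotype"].to_csv(d / "stage2_blups.csv", index=False)
    if tr.gblup_fit is not None:
        gb.gebv_table(tr.gblup_fit).to_csv(d / "gebv.csv", index=False)


def build_report(result: PipelineResult, table: TrialTable) -> str:
    """Assemble the HTML report from a pipeline bundle."""
    cfg = result.config
    sections = []
    meta = {
        "traits": ", ".join(cfg.traits),
        "environments": ", ".join(table.envs),
        "records": len(table.data),
        "seed": cfg.seed,
        **{str(k): v for k, v in (cfg.metadata or {}).items()},
    }
    for trait, tr in result.traits.items():
        pre = f"{trait}-"
        if tr.failures:
            msgs = "".join(
                f"<p class='fail'>stage {html_escape(k)} failed: {html_escape(v)}</p>"
                for k, v in tr.failures.items()
            )
            sections.append((f"{pre}failures", f"{trait}: failures", msgs))
        if tr.qc_report is not None:
            body = "<h3>QC decisions</h3>" + rpt.df_to_html(tr.qc_report.decisions_frame())
            body += "<h3>Descriptive statistics</h3>" + rpt.df_to_html(tr.qc_report.descriptives)
            if len(tr.qc_report.outliers):
                body += "<h3>Outliers removed</h3>" + rpt.df_to_html(tr.qc_report.outliers)
            if tr.qc_table is not None:
                for env in list(tr.qc_table["env"].unique()):
                    grid = qc_mod.field_heatmap_matrix(tr.qc_table, trait, env)
                    uri = rpt.fig_to_data_uri(rpt.heatmap_figure(grid, f"{env} field map"))
                    body += f"<img src='{uri}'>"
                vals = tr.qc_table[trait].to_numpy(dtype=float)
                body += "<img src='{}'>".format(
                    rpt.fig_to_data_uri(rpt.distribution_figure(vals, trait))
                )
            sections.append((f"{pre}qc", f"{trait}: quality control", body))
        if tr.single:
            body = ""
            for env, res in tr.single.items():
                body += f"<h3>{html_escape(env)}</h3>"
                body += rpt.df_to_html(res.comparison)
                body += (
                    f"<p>best model: <b>{html_escape(res.best)}</b>; generalized "
                    f"heritability H<sub>c</sub> = {res.heritability:.3f}</p>"
                )
                body += "<h4>top genotypes</h4>" + rpt.df_to_html(res.genotype_ranking.head(15))
                if res.variogram is not None:
                    body += "<img src='{}'>".format(
                        rpt.fig_to_data_uri(
                            rpt.variogram_figure(res.variogram, f"{env} variogram")
                        )
                    )
            sections.append((f"{pre}single", f"{trait}: single-trial analysis", body))
        if tr.met is not None:
            body = "<h3>Model selection</h3>" + rpt.df_to_html(tr.met.comparison)
            body += "<h3>Environment correlations</h3>" + rpt.df_to_html(
                tr.met.env_cor.reset_index()
            )
            try:
                slopes = met_mod.latent_regression(tr.met)
                body += "<h3>Latent regression (top 10)</h3>" + rpt.df_to_html(slopes)
                fa = tr.met.fa_fit()
                gxe = met_mod.gxe_blup_table(fa)
                body += "<img src='{}'>".format(
                    rpt.fig_to_data_uri(
                        rpt.latent_regression_figure(slopes, tr.met.loadings, gxe)
                    )
                )
                bp = met_mod.fa_biplot(tr.met)
                body += "<img src='{}'>".format(rpt.fig_to_data_uri(rpt.biplot_figure(bp)))
            except ValueError:
                body += "<p>no factor-analytic model available for stability plots</p>"
            sections.append((f"{pre}met", f"{trait}: multi-environment analysis", body))
        if tr.stage2 is not None:
            body = rpt.df_to_html(
                tr.stage2.blups["genotype"].sort_values("blup", ascending=False).head(20)
            )
            sections.append((f"{pre}twostage", f"{trait}: two-stage analysis", body))
        if tr.gblup_fit is not None:
            body = rpt.df_to_html(gb.gebv_table(tr.gblup_fit).head(20))
            sections.append((f"{pre}gblup", f"{trait}: genomic breeding values", body))
    return rpt.render_report(sections, cfg.title, meta)


def html_escape(s) -> str:
    import html as _h

    return _h.escape(str(s))
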