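"""Pre-processing and quality control of trial books.

The screening order is: missingness filter (trials with more than the
threshold proportion of missing responses are dropped), descriptive
statistics and distribution/field summaries for eyeballing, outlier
filtering by the Bonferroni-Holm test on standardized conditional residuals
of the baseline design model, and a trial-reliability screen based on the
generalized heritability of each trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .reml import FitResult
from .single_trial import heritability_cullis

logger = logging.getLogger(__name__)

__all__ = [
    "QCConfig",
    "QCReport",
    "missingness_filter",
    "descriptive_stats",
    "field_heatmap_matrix",
    "distribution_summaries",
    "holm_outliers",
    "trial_reliability",
]


class QCError(ValueError):
    pass


@dataclass
class QCConfig:
    missing_threshold: float = 0.20     # strictly-greater rule drops trials
    reliability_threshold: float = 0.2
    outlier_alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("missing_threshold", "reliability_threshold", "outlier_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise QCError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class QCReport:
    """Machine-readable record of every QC decision."""

    missingness: pd.DataFrame = field(default_factory=pd.DataFrame)
    decisions: list = field(default_factory=list)   # dicts: env, action, reason code
    descriptives: pd.DataFrame = field(default_factory=pd.DataFrame)
    outliers: pd.DataFrame = field(default_factory=pd.DataFrame)
    reliability: pd.DataFrame = field(default_factory=pd.DataFrame)

    def decisions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.decisions, columns=["env", "action", "reason", "value"])

    def to_json_dict(self) -> dict:
        return {
            "missingness": self.missingness.to_dict(orient="records"),
            "decisions": self.decisions,
            "descriptives": self.descriptives.to_dict(orient="records"),
            "outliers": self.outliers.to_dict(orient="records"),
            "reliability": self.reliability.to_dict(orient="records"),
        }


def missingness_filter(
    table: pd.DataFrame, trait: str, config: Optional[QCConfig] = None,
    report: Optional[QCReport] = None,
):
    """Drop trials whose missing-response proportion strictly exceeds the threshold."""
    cfg = config or QCConfig()
    rep = report or QCReport()
    if trait not in table.columns:
        raise QCError(f"trait column {trait!r} not found")
    by = table.groupby("env", sort=True)[trait]
    prop = (by.apply(lambda s: s.isna().mean())).round(4)
    rep.missingness = prop.rename("missing_proportion").reset_index()
    keep_envs = prop.index[prop <= cfg.missing_threshold]
    for env, p in prop.items():
        if p > cfg.missing_threshold:
            rep.decisions.append(
                {"env": str(env), "action": "drop", "reason": "missingness", "value": float(p)}
            )
        else:
            rep.decisions.append(
                {"env": str(env), "action": "keep", "reason": "missingness", "value": float(p)}
            )
    kept = table[table["env"].isin(keep_envs)].copy()
    if kept.empty:
        raise QCError("no data survives QC: every trial exceeds the missingness threshold")
    return kept, rep


def descriptive_stats(table: pd.DataFrame, trait: str, by="env") -> pd.DataFrame:
    """Per-group n, mean, sd, CV (percent), min, quartiles, max.

    CV = 100 * sd / mean with the sample (n-1) standard deviation; a zero
    mean yields an undefined (NaN) CV rather than an infinity.
    """
    rows = []
    for g, s in table.groupby(by, sort=True)[trait]:
        v = s.dropna().to_numpy(dtype=float)
        if len(v) == 0:
            logger.info("descriptive stats: group %r empty, skipped", g)
            continue
        mean = float(np.mean(v))
        sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        cv = 100.0 * sd / mean if abs(mean) > 1e-12 else np.nan
        q1, med, q3 = (np.percentile(v, q) for q in (25, 50, 75))
        rows.append(
            {
                by: g, "n": len(v), "mean": mean, "sd": sd, "cv": cv,
                "min": float(v.min()), "q1": float(q1), "median": float(med),
                "q3": float(q3), "max": float(v.max()),
            }
        )
    return pd.DataFrame(rows)


def field_heatmap_matrix(table: pd.DataFrame, trait: str, env) -> np.ndarray:
    """Row x column grid of trait values for one environment (NaN = absent plot)."""
    sub = table[table["env"] == env]
    if sub.empty:
        raise QCError(f"no records for environment {env!r}")
    for c in ("row", "col"):
        if c not in sub.columns:
            raise QCError(f"field heatmap needs a {c!r} column")
    dup = sub.duplicated(subset=["row", "col"], keep=False)
    if dup.any():
        bad = sub.loc[dup, ["row", "col"]].iloc[0]
        raise QCError(
            f"duplicate plot coordinates in {env!r} at row={bad['row']}, col={bad['col']}"
        )
    rows = sub["row"].to_numpy(dtype=int)
    cols = sub["col"].to_numpy(dtype=int)
    grid = np.full((rows.max(), cols.max()), np.nan)
    grid[rows - 1, cols - 1] = sub[trait].to_numpy(dtype=float)
    return grid


def distribution_summaries(table: pd.DataFrame, trait: str) -> Optional[dict]:
    """Histogram bins, five-number boxplot stats with 1.5 IQR outliers, QQ pairs.

    QQ plotting positions are (i - 0.5) / n against standard-normal quantiles.
    Returns None (with a log entry) when fewer than 4 values are available.
    """
    v = table[trait].dropna().to_numpy(dtype=float)
    if len(v) < 4:
        logger.info("distribution summaries omitted: only %d values", len(v))
        return None
    counts, edges = np.histogram(v, bins="auto")
    q1, med, q3 = (float(np.percentile(v, q)) for q in (25, 50, 75))
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    whisker_lo, whisker_hi = float(inside.min()), float(inside.max())
    outliers = np.sort(v[(v < lo_fence) | (v > hi_fence)])
    srt = np.sort(v)
    pp = (np.arange(1, len(v) + 1) - 0.5) / len(v)
    theo = stats.norm.ppf(pp, loc=np.mean(v), scale=np.std(v, ddof=1))
    return {
        "histogram": {"counts": counts, "edges": edges},
        "boxplot": {
            "median": med, "q1": q1, "q3": q3, "iqr": iqr,
            "whisker_low": whisker_lo, "whisker_high": whisker_hi,
            "outliers": outliers,
        },
        "qq": {"sample": srt, "theoretical": theo},
    }


def holm_outliers(fit_result: FitResult, alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni-Holm outlier flags from standardized conditional residuals.

    Residuals are standardized by their sample standard deviation, given
    two-sided normal p-values, and tested with the Holm step-down procedure
    at family-wise level ``alpha``.
    """
    e = fit_result.residuals
    sd = float(np.std(e, ddof=1))
    if sd < 1e-12:
        logger.warning("degenerate residual variance; no outliers flagged")
        return pd.DataFrame(
            columns=["record", "residual", "std_residual", "p_raw", "p_holm", "flagged"]
        )
    z = (e - np.mean(e)) / sd
    p_raw = 2.0 * stats.norm.sf(np.abs(z))
    flag, p_holm, *_ = multipletests(p_raw, alpha=alpha, method="holm")
    out = pd.DataFrame(
        {
            "record": fit_result.table.index.to_numpy(),
            "residual": e,
            "std_residual": z,
            "p_raw": p_raw,
            "p_holm": p_holm,
            "flagged": flag,
        }
    )
    return out


def trial_reliability(
    fit_result: FitResult, config: Optional[QCConfig] = None
):
    """Trial reliability = generalized heritability of the trial's fit.

    Returns ``(value, keep)``; trials below the threshold are marked for
    dropping.  A collapsed genotype variance gives reliability 0.
    """
    cfg = config or QCConfig()
    value = heritability_cullis(fit_result)
    return value, bool(value >= cfg.reliability_threshold)
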