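"""Readers, writers and run configuration.

Trial books are plain CSV with the canonical columns ``env, genotype, rep,
block, row, col`` plus one or more numeric trait columns; row/column
coordinates are 1-based field-book positions.  A column map lets differently
named books be ingested without editing the file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dfield
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["TrialTable", "RunConfig", "read_trial_csv", "write_trial_csv", "read_marker_csv"]

REQUIRED_COLUMNS = ("env", "genotype", "rep", "block", "row", "col")
MISSING_MARKERS = ("", "NA", "NaN", "nan", ".", "na")


class TrialDataError(ValueError):
    pass


@dataclass
class TrialTable:
    """A tidy plot-level trial book plus free-form metadata."""

    data: pd.DataFrame
    traits: list
    metadata: dict = dfield(default_factory=dict)

    def __post_init__(self) -> None:
        validate_trial_frame(self.data, self.traits)

    @property
    def envs(self) -> list:
        return list(np.unique(self.data["env"].to_numpy()))


def validate_trial_frame(df: pd.DataFrame, traits) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrialDataError(f"missing required columns: {missing}")
    for t in traits:
        if t not in df.columns:
            raise TrialDataError(f"trait column {t!r} not found")
    for c in ("row", "col"):
        v = df[c]
        if v.isna().any() or (v.astype(float) < 1).any() or (v.astype(float) % 1 != 0).any():
            raise TrialDataError(f"{c!r} must hold positive 1-based integers")
    dup = df.duplicated(subset=["env", "rep", "row", "col"], keep=False)
    if dup.any():
        first = df.loc[dup, ["env", "rep", "row", "col"]].iloc[0].to_dict()
        raise TrialDataError(f"duplicate plot {first}")


def read_trial_csv(
    path, traits, column_map: Optional[dict] = None, metadata: Optional[dict] = None
) -> TrialTable:
    """Read a plot-level CSV into a validated TrialTable.

    ``column_map`` renames file columns to the canonical names (e.g.
    ``{"location": "env"}``).  Empty cells and the usual NA markers are
    unified to missing; factor columns are coerced to strings and row/col
    to integers.
    """
    path = Path(path)
    if not path.exists():
        raise TrialDataError(f"file not found: {path}")
    df = pd.read_csv(path, na_values=list(MISSING_MARKERS), keep_default_na=True)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrialDataError(f"{path.name}: missing required columns {missing}")
    for c in ("env", "genotype", "rep", "block"):
        df[c] = df[c].astype(str)
    for c in ("row", "col"):
        df[c] = pd.to_numeric(df[c], errors="raise")
    for t in traits:
        if t not in df.columns:
            raise TrialDataError(f"{path.name}: trait column {t!r} not found")
        df[t] = pd.to_numeric(df[t], errors="coerce")
    validate_trial_frame(df, traits)
    df["row"] = df["row"].astype(int)
    df["col"] = df["col"].astype(int)
    return TrialTable(data=df, traits=list(traits), metadata=metadata or {})


def write_trial_csv(table, path) -> None:
    df = table.data if isinstance(table, TrialTable) else table
    df.to_csv(path, index=False)


def read_marker_csv(path) -> pd.DataFrame:
    """Marker CSV: first column = individual id, remaining columns = dosages."""
    df = pd.read_csv(path, na_values=list(MISSING_MARKERS))
    df = df.set_index(df.columns[0])
    df.index.name = "genotype"
    df.index = df.index.astype(str)
    return df


_KNOWN_KEYS = {
    "input", "markers", "traits", "trait", "seed", "out",
    "missing_threshold", "reliability_threshold", "outlier_alpha",
    "single_trial_models", "met_models", "fa_order", "two_stage", "starts",
    "column_map", "metadata", "title",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (unknown keys are rejected)."""

    input: Optional[str] = None
    markers: Optional[str] = None
    traits: list = dfield(default_factory=list)
    seed: int = 0
    out: str = "trialkit_out"
    missing_threshold: float = 0.20
    reliability_threshold: float = 0.2
    outlier_alpha: float = 0.05
    single_trial_models: tuple = ("model1", "model2", "model3", "model4", "model5")
    met_models: tuple = tuple(range(1, 11))
    fa_order: int = 1
    two_stage: bool = True
    starts: int = 3
    column_map: Optional[dict] = None
    metadata: dict = dfield(default_factory=dict)
    title: str = "Breeding trial analysis"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise TrialDataError(f"unknown configuration keys: {sorted(unknown)}")
        raw = dict(raw)
        if "trait" in raw:
            raw.setdefault("traits", [raw.pop("trait")])
        if "single_trial_models" in raw:
            raw["single_trial_models"] = tuple(raw["single_trial_models"])
        if "met_models" in raw:
            raw["met_models"] = tuple(int(m) for m in raw["met_models"])
        cfg = cls(**raw)
        if not cfg.traits:
            raise TrialDataError("configuration must name at least one trait")
        for k in ("missing_threshold", "reliability_threshold", "outlier_alpha"):
            v = getattr(cfg, k)
            if not 0.0 <= v <= 1.0:
                raise TrialDataError(f"{k} must lie in [0, 1]")
        return cfg

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
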