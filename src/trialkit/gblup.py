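"""Marker-based analysis: dosage encoding, genomic relationship matrix, gBLUP.

The genomic relationship matrix is G = X X' / n where X is the
individuals x markers dosage matrix with each marker column centered to
mean zero and scaled to unit sample (n-1) variance, and n is the number of
markers.  gBLUP replaces the iid genotype covariance of the phenotypic
model with sigma2_g * G, so genotype BLUPs become genomic estimated
breeding values (GEBVs) informed by relatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .covstruct import CovarianceSpec
from .reml import FitResult, ModelSpec, RandomTerm, ResidualSpec, fit

logger = logging.getLogger(__name__)

__all__ = ["MarkerSet", "GRM", "encode_markers", "read_vcf_markers", "grm", "fit_gblup", "gebv_table"]


@dataclass
class MarkerSet:
    """Dosage-coded biallelic marker panel (entries 0/1/2, NaN = missing)."""

    dosage: pd.DataFrame          # individuals x markers

    @property
    def individuals(self) -> list:
        return list(self.dosage.index)

    @property
    def markers(self) -> list:
        return list(self.dosage.columns)

    @property
    def n(self) -> int:
        return self.dosage.shape[1]


@dataclass
class GRM:
    matrix: np.ndarray
    individuals: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.individuals, columns=self.individuals)


def encode_markers(raw: pd.DataFrame) -> MarkerSet:
    """Validate and clean a raw dosage table (rows = individuals).

    Monomorphic markers are dropped (their scaling is undefined); missing
    entries are imputed to the marker mean dosage, logged per marker.
    """
    d = raw.astype(float).copy()
    if d.index.duplicated().any():
        raise ValueError("duplicate individual identifiers in marker table")
    vals = d.to_numpy()
    ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
    if not ok.all():
        raise ValueError("marker dosages must be 0, 1, 2 or missing")
    n_missing = d.isna().sum()
    for m, cnt in n_missing[n_missing > 0].items():
        mean = d[m].mean()
        d[m] = d[m].fillna(mean)
        logger.info("marker %s: imputed %d missing entries to mean %.3f", m, cnt, mean)
    poly = d.std(axis=0, ddof=1) > 0
    dropped = int((~poly).sum())
    if dropped:
        logger.info("dropping %d monomorphic markers", dropped)
    return MarkerSet(d.loc[:, poly])


def read_vcf_markers(path: str) -> MarkerSet:
    """Read biallelic records from a VCF into minor-allele dosages.

    Multi-allelic records are skipped with a warning.  Requires cyvcf2.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(path)
    samples = list(vcf.samples)
    cols = {}
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("skipping multi-allelic record %s:%s", var.CHROM, var.POS)
            continue
        name = var.ID if var.ID else f"{var.CHROM}_{var.POS}"
        gt = np.asarray(var.gt_types, dtype=float)  # 0=hom ref,1=het,2=unknown,3=hom alt
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        # orient to the minor allele
        freq = np.nanmean(dos) / 2.0
        if freq > 0.5:
            dos = 2.0 - dos
        cols[name] = dos
    frame = pd.DataFrame(cols, index=samples)
    return encode_markers(frame)


def grm(markers: MarkerSet) -> GRM:
    """Genomic relationship matrix G = X X' / n on centered, unit-variance markers."""
    d = markers.dosage
    if d.shape[1] < 2:
        raise ValueError("need at least 2 polymorphic markers")
    if d.shape[0] < 2:
        raise ValueError("need at least 2 individuals")
    x = d.to_numpy(dtype=float)
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    g = x @ x.T / x.shape[1]
    return GRM(matrix=g, individuals=markers.individuals)


def _bend(k: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue-floor a kernel that is indefinite beyond tolerance."""
    w, v = np.linalg.eigh((k + k.T) / 2)
    if w.min() >= -1e-8:
        return k
    logger.warning("GRM not PSD (min eigenvalue %.2e); bending to floor %.0e", w.min(), floor)
    return (v * np.maximum(w, floor)) @ v.T


def fit_gblup(
    table: pd.DataFrame,
    kinship: GRM,
    trait: str,
    extra_random: Optional[tuple] = None,
    **fit_options,
) -> FitResult:
    """Fit the gBLUP model on plot-level phenotypes.

    Genotype covariance is sigma2_g * G (bent to PSD if needed); replicates
    (within environments, when present) are fixed; blocks, and for
    multi-environment tables the non-genetic genotype-by-environment
    effects, are iid random.  Phenotyped genotypes missing from the GRM are
    dropped with a log entry.  GEBVs are the genotype BLUPs of this fit.
    """
    data = table.copy()
    known = set(kinship.individuals)
    mask = data["genotype"].isin(known)
    if (~mask).any():
        logger.info("dropping %d records whose genotype is absent from the GRM",
                    int((~mask).sum()))
        data = data[mask]
    k = _bend(kinship.matrix + 1e-8 * np.eye(len(kinship.individuals)))
    g_spec = CovarianceSpec("scaled", len(kinship.individuals), {"sigma2": 1.0}, base=k)
    g_term = RandomTerm("genotype", ("genotype",), g_spec, kernel_levels=kinship.individuals)
    iid = CovarianceSpec("identity", 1, {"sigma2": 1.0})
    multi_env = "env" in data.columns and data["env"].nunique() > 1
    random = [g_term]
    if extra_random is not None:
        random.extend(extra_random)
    else:
        if {"rep", "block"}.issubset(data.columns):
            bf = ("env", "rep", "block") if multi_env else ("rep", "block")
            random.append(RandomTerm("block", bf, iid))
        if multi_env:
            random.append(RandomTerm("ge", ("env", "genotype"), iid))
    if multi_env:
        data["env_rep"] = data["env"].astype(str) + ":" + data["rep"].astype(str)
        fixed = ("env_rep",)
    elif "rep" in data.columns:
        fixed = ("rep",)
    else:
        fixed = ()
    spec = ModelSpec(
        response=trait, fixed=fixed, random=tuple(random), residual=ResidualSpec("iid")
    )
    return fit(spec, data, **fit_options)


def gebv_table(gblup_fit: FitResult) -> pd.DataFrame:
    """Genomic estimated breeding values (genotype BLUPs) with PEV."""
    out = gblup_fit.blups["genotype"].copy()
    out = out.rename(columns={"blup": "gebv"})
    return out.sort_values("gebv", ascending=False, kind="mergesort").reset_index(drop=True)
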