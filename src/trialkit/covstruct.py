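"""Parameterized variance-covariance structures for mixed-model terms.

Every structure used by the trial models lives here: identity and diagonal
variances, compound symmetry (CS), uniform-correlation heterogeneous-variance
(corh), general-correlation (corgh), first-order autoregressive (AR1),
separable Kronecker products such as AR1(col) x AR1(row) plot error,
factor-analytic (FA(k), realized as Lambda Lambda' + diag(Psi)) and a
fixed-kernel structure sigma2 * K used for genomic relationship matrices.

Each structure knows how to realize its matrix, and how to map its parameters
to and from an unconstrained real vector (log for variances, atanh for
correlations, identity for FA loadings) so a quasi-Newton optimizer can work
on an open box.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "CovarianceSpec",
    "build_ar1",
    "build_kron",
    "build_fa",
    "realize",
    "n_free_params",
    "to_unconstrained",
    "from_unconstrained",
    "sign_fix_loadings",
]

#: structures whose realization is guaranteed symmetric PD for valid params
KINDS = (
    "identity",
    "diagonal",
    "cs",
    "uniform_corr",
    "general_corr",
    "ar1",
    "kron",
    "fa",
    "scaled",
)

#: guard against accidentally materializing enormous Kronecker products
MAX_KRON_DIM = 20_000


class InvalidParameterError(ValueError):
    """A structure parameter is outside its valid domain."""


@dataclass
class CovarianceSpec:
    """A named, parameterized variance structure of a fixed dimension.

    ``params`` holds kind-specific entries:

    - identity: ``sigma2`` (scalar, shared across all levels)
    - diagonal: ``sigma2`` (length-``dim`` vector)
    - cs: ``variance`` (diagonal value), ``covariance`` (common off-diagonal)
    - uniform_corr: ``sigma2`` (vector), ``rho`` (shared correlation)
    - general_corr: ``sigma2`` (vector), ``corr`` (dim x dim correlation)
    - ar1: ``sigma2`` (scalar), ``rho``
    - kron: ``sigma2``; sub-structures in ``col``/``row`` (correlation parts)
    - fa: ``loadings`` (dim x k), ``psi`` (length-``dim`` specific variances)
    - scaled: ``sigma2``; fixed kernel in ``base`` (e.g. a GRM)
    """

    kind: str
    dim: int
    params: dict = field(default_factory=dict)
    col: Optional["CovarianceSpec"] = None
    row: Optional["CovarianceSpec"] = None
    base: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise InvalidParameterError(f"unknown covariance kind {self.kind!r}")
        if self.dim < 1:
            raise InvalidParameterError("dimension must be >= 1")

    @property
    def order(self) -> int:
        """FA order k (0 for non-FA kinds)."""
        if self.kind != "fa":
            return 0
        return int(np.asarray(self.params["loadings"]).shape[1])

    def realize(self) -> np.ndarray:
        return realize(self)

    def n_free(self) -> int:
        return n_free_params(self)


def build_ar1(rho: float, n: int) -> np.ndarray:
    """AR1 correlation matrix: entry (i, j) = rho^|i-j| with unit diagonal."""
    if not abs(rho) < 1:
        raise InvalidParameterError(f"AR1 autocorrelation must satisfy |rho| < 1, got {rho}")
    if n < 1:
        raise InvalidParameterError("AR1 dimension must be >= 1")
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def build_kron(col_spec: CovarianceSpec, row_spec: CovarianceSpec, sigma2: float) -> np.ndarray:
    """Separable plot-error structure sigma2 * (Sigma_col kron Sigma_row).

    Plots are assumed ordered column-major (sorted by column, then row), so
    the left factor varies across columns and the right across rows.
    """
    if sigma2 <= 0:
        raise InvalidParameterError("sigma2 must be > 0")
    dim = col_spec.dim * row_spec.dim
    if dim > MAX_KRON_DIM:
        raise InvalidParameterError(
            f"Kronecker dimension {dim} exceeds the configured maximum {MAX_KRON_DIM}"
        )
    return sigma2 * np.kron(_corr_part(col_spec), _corr_part(row_spec))


def build_fa(loadings: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Factor-analytic covariance Lambda Lambda' + diag(Psi)."""
    lam = np.atleast_2d(np.asarray(loadings, dtype=float))
    psi = np.asarray(psi, dtype=float)
    if np.any(psi < 0):
        raise InvalidParameterError("specific variances psi must be >= 0")
    if lam.shape[1] >= lam.shape[0]:
        raise InvalidParameterError("FA order k must be smaller than the dimension")
    if psi.shape[0] != lam.shape[0]:
        raise InvalidParameterError("psi length must match the loading rows")
    return lam @ lam.T + np.diag(psi)


def _corr_part(spec: CovarianceSpec) -> np.ndarray:
    """Correlation factor of a sub-structure inside a Kronecker product."""
    if spec.kind == "identity":
        return np.eye(spec.dim)
    if spec.kind == "ar1":
        return build_ar1(float(spec.params["rho"]), spec.dim)
    raise InvalidParameterError(
        f"Kronecker sub-structures must be identity or ar1, got {spec.kind!r}"
    )


def realize(spec: CovarianceSpec) -> np.ndarray:
    """Materialize the dim x dim covariance matrix of a spec."""
    p = spec.params
    d = spec.dim
    if spec.kind == "identity":
        return float(p["sigma2"]) * np.eye(d)
    if spec.kind == "diagonal":
        v = np.asarray(p["sigma2"], dtype=float)
        if v.shape != (d,):
            raise InvalidParameterError("diagonal needs one variance per level")
        return np.diag(v)
    if spec.kind == "cs":
        v, c = float(p["variance"]), float(p["covariance"])
        return np.full((d, d), c) + (v - c) * np.eye(d)
    if spec.kind == "uniform_corr":
        sd = np.sqrt(np.asarray(p["sigma2"], dtype=float))
        rho = float(p["rho"])
        m = rho * np.outer(sd, sd)
        np.fill_diagonal(m, sd**2)
        return m
    if spec.kind == "general_corr":
        sd = np.sqrt(np.asarray(p["sigma2"], dtype=float))
        corr = np.asarray(p["corr"], dtype=float)
        return corr * np.outer(sd, sd)
    if spec.kind == "ar1":
        return float(p["sigma2"]) * build_ar1(float(p["rho"]), d)
    if spec.kind == "kron":
        return build_kron(spec.col, spec.row, float(p["sigma2"]))
    if spec.kind == "fa":
        return build_fa(p["loadings"], p["psi"])
    if spec.kind == "scaled":
        if spec.base is None:
            raise InvalidParameterError("scaled structure needs a base kernel")
        return float(p["sigma2"]) * spec.base
    raise InvalidParameterError(spec.kind)


def fa_free_loading_mask(dim: int, k: int) -> np.ndarray:
    """Boolean mask of free FA loadings (upper triangle pinned to zero)."""
    mask = np.ones((dim, k), dtype=bool)
    for i in range(dim):
        for j in range(k):
            if j > i:
                mask[i, j] = False
    return mask


def n_free_params(spec: CovarianceSpec) -> int:
    d = spec.dim
    if spec.kind in ("identity", "scaled"):
        return 1
    if spec.kind == "diagonal":
        return d
    if spec.kind in ("cs", "ar1"):
        return 2
    if spec.kind == "uniform_corr":
        return d + 1
    if spec.kind == "general_corr":
        return d + d * (d - 1) // 2
    if spec.kind == "kron":
        n = 1
        for sub in (spec.col, spec.row):
            if sub is not None and sub.kind == "ar1":
                n += 1
        return n
    if spec.kind == "fa":
        k = spec.order
        return int(fa_free_loading_mask(d, k).sum()) + d
    raise InvalidParameterError(spec.kind)


_ATANH_CLIP = 1 - 1e-12


def _atanh(x: float) -> float:
    return float(np.arctanh(np.clip(x, -_ATANH_CLIP, _ATANH_CLIP)))


def _log(x: float) -> float:
    return float(np.log(max(float(x), 1e-300)))


def to_unconstrained(spec: CovarianceSpec) -> np.ndarray:
    """Map a spec's parameters to an unconstrained real vector.

    Variances map by log, correlations by atanh, FA loadings by identity
    (the zero-constrained upper triangle is omitted).  The CS covariance maps
    through the ratio covariance/variance, which is a correlation in (-1, 1).
    """
    p = spec.params
    if spec.kind in ("identity", "scaled"):
        return np.array([_log(p["sigma2"])])
    if spec.kind == "diagonal":
        return np.log(np.maximum(np.asarray(p["sigma2"], dtype=float), 1e-300))
    if spec.kind == "cs":
        v, c = float(p["variance"]), float(p["covariance"])
        return np.array([_log(v), _atanh(c / v)])
    if spec.kind == "ar1":
        return np.array([_log(p["sigma2"]), _atanh(float(p["rho"]))])
    if spec.kind == "uniform_corr":
        v = np.asarray(p["sigma2"], dtype=float)
        return np.concatenate([np.log(np.maximum(v, 1e-300)), [_atanh(float(p["rho"]))]])
    if spec.kind == "general_corr":
        v = np.asarray(p["sigma2"], dtype=float)
        corr = np.asarray(p["corr"], dtype=float)
        iu = np.triu_indices(spec.dim, k=1)
        return np.concatenate(
            [np.log(np.maximum(v, 1e-300)), np.arctanh(np.clip(corr[iu], -_ATANH_CLIP, _ATANH_CLIP))]
        )
    if spec.kind == "kron":
        out = [_log(p["sigma2"])]
        for sub in (spec.col, spec.row):
            if sub is not None and sub.kind == "ar1":
                out.append(_atanh(float(sub.params["rho"])))
        return np.array(out)
    if spec.kind == "fa":
        lam = np.asarray(p["loadings"], dtype=float)
        psi = np.asarray(p["psi"], dtype=float)
        mask = fa_free_loading_mask(spec.dim, spec.order)
        return np.concatenate([lam[mask], np.log(np.maximum(psi, 1e-300))])
    raise InvalidParameterError(spec.kind)


def from_unconstrained(
    kind: str,
    dim: int,
    vector: np.ndarray,
    *,
    k: int = 1,
    base: Optional[np.ndarray] = None,
    col_dim: Optional[int] = None,
    row_dim: Optional[int] = None,
    col_ar1: bool = True,
    row_ar1: bool = True,
) -> CovarianceSpec:
    """Inverse of :func:`to_unconstrained` for every structure kind."""
    v = np.asarray(vector, dtype=float)

    def check(n: int) -> None:
        if v.shape != (n,):
            raise InvalidParameterError(
                f"{kind}(dim={dim}) expects {n} parameters, got {v.shape}"
            )

    if kind in ("identity", "scaled"):
        check(1)
        return CovarianceSpec(kind, dim, {"sigma2": float(np.exp(v[0]))}, base=base)
    if kind == "diagonal":
        check(dim)
        return CovarianceSpec(kind, dim, {"sigma2": np.exp(v)})
    if kind == "cs":
        check(2)
        var = float(np.exp(v[0]))
        return CovarianceSpec(kind, dim, {"variance": var, "covariance": var * float(np.tanh(v[1]))})
    if kind == "ar1":
        check(2)
        return CovarianceSpec(kind, dim, {"sigma2": float(np.exp(v[0])), "rho": float(np.tanh(v[1]))})
    if kind == "uniform_corr":
        check(dim + 1)
        return CovarianceSpec(kind, dim, {"sigma2": np.exp(v[:dim]), "rho": float(np.tanh(v[dim]))})
    if kind == "general_corr":
        m = dim * (dim - 1) // 2
        check(dim + m)
        corr = np.eye(dim)
        iu = np.triu_indices(dim, k=1)
        corr[iu] = np.tanh(v[dim:])
        corr[(iu[1], iu[0])] = corr[iu]
        return CovarianceSpec(kind, dim, {"sigma2": np.exp(v[:dim]), "corr": corr})
    if kind == "kron":
        if col_dim is None or row_dim is None:
            raise InvalidParameterError("kron needs col_dim and row_dim")
        n = 1 + int(col_ar1) + int(row_ar1)
        check(n)
        i = 1
        if col_ar1:
            col = CovarianceSpec("ar1", col_dim, {"sigma2": 1.0, "rho": float(np.tanh(v[i]))})
            i += 1
        else:
            col = CovarianceSpec("identity", col_dim, {"sigma2": 1.0})
        if row_ar1:
            row = CovarianceSpec("ar1", row_dim, {"sigma2": 1.0, "rho": float(np.tanh(v[i]))})
        else:
            row = CovarianceSpec("identity", row_dim, {"sigma2": 1.0})
        return CovarianceSpec(
            "kron", col_dim * row_dim, {"sigma2": float(np.exp(v[0]))}, col=col, row=row
        )
    if kind == "fa":
        mask = fa_free_loading_mask(dim, k)
        n_lam = int(mask.sum())
        check(n_lam + dim)
        lam = np.zeros((dim, k))
        lam[mask] = v[:n_lam]
        return CovarianceSpec(kind, dim, {"loadings": lam, "psi": np.exp(v[n_lam:])})
    raise InvalidParameterError(kind)


def sign_fix_loadings(loadings: np.ndarray) -> np.ndarray:
    """Flip each factor so its largest-magnitude loading is positive.

    FA models are invariant to column sign changes; fixing the sign makes
    reported loadings reproducible across optimizer starts.
    """
    lam = np.array(loadings, dtype=float, copy=True)
    for j in range(lam.shape[1]):
        i = int(np.argmax(np.abs(lam[:, j])))
        if lam[i, j] < 0:
            lam[:, j] = -lam[:, j]
    return lam
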