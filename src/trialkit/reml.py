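"""General REML engine for linear mixed models with structured covariances.

Fits models of the form ``y = X beta + sum_i Z_i u_i + eps`` where each
random effect ``u_i`` carries one of the covariance structures from
:mod:`trialkit.covstruct` and the residual can be iid, heterogeneous by
environment, or spatially correlated (separable AR1 across field rows and
columns, possibly different per environment).

The restricted log-likelihood is evaluated on the dense phenotypic
covariance ``V = sum_i Z_i G_i Z_i' + R`` (trial sizes here are a few
hundred to a couple of thousand plots, where dense Cholesky factorizations
are fast and numerically robust).  Variance parameters are optimized on an
unconstrained scale (log variances, atanh correlations) by L-BFGS with
gradients computed from the standard REML score

    d l / d theta_i = -1/2 [ tr(P dV/dtheta_i) - y'P (dV/dtheta_i) P y ]

where ``dV/dtheta_i`` is obtained by central differencing the (cheap) matrix
construction only; for variance parameters V is linear in the parameter so
this is exact up to rounding.

BLUEs, BLUPs, prediction error variances (PEV) and pairwise prediction error
covariances (PEC, needed for generalized heritability) are solved at the
optimum from the equivalent V-inverse identities of the mixed-model
equations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from . import covstruct
from .covstruct import CovarianceSpec

logger = logging.getLogger(__name__)

__all__ = [
    "RandomTerm",
    "ResidualSpec",
    "ModelSpec",
    "FitResult",
    "build_design",
    "reml_loglik",
    "fit",
    "model_compare",
]

LOG2PI = float(np.log(2.0 * np.pi))


class DesignError(ValueError):
    """The model cannot be built from the supplied table."""


# --------------------------------------------------------------------------
# model description
# --------------------------------------------------------------------------


@dataclass
class RandomTerm:
    """One random effect: a factor (or interaction) plus its G-structure.

    ``factors`` lists table columns; an interaction enumerates the full
    cartesian product of each factor's observed levels.  When ``spec`` has a
    dimension equal to the number of levels of ``factors[0]`` and further
    factors are present, the realized covariance is ``Sigma kron I`` with
    ``factors[0]`` as the outer (slowest-varying) index -- this is how
    CS / corh / FA structures over environments apply to genotype-within-
    environment effects.
    """

    name: str
    factors: tuple
    spec: CovarianceSpec
    #: map level names of factors[0] to kernel rows for 'scaled' structures
    kernel_levels: Optional[Sequence] = None

    def __post_init__(self) -> None:
        self.factors = tuple(self.factors)


@dataclass
class ResidualSpec:
    """Residual (R-structure) description.

    kind:
      - ``iid``            sigma2 * I (one variance, optionally fixed)
      - ``diag_by_group``  a separate iid variance per group (environment)
      - ``ar1xar1``        sigma2 * AR1(col) x AR1(row), shared over groups
      - ``ar1_rows``       correlation along rows within a column only
      - ``ar1_cols``       correlation along columns within a row only
      - ``per_group``      an independent kind (with its own parameters)
                           for each group, given in ``per_group``
    ``by`` names the grouping column (usually ``env``); residuals are
    independent between groups.  ``fixed_sigma2`` pins the iid variance (used
    by the second stage of the two-stage analysis, where weights carry the
    stage-one precision and the residual variance is constrained to one).
    """

    kind: str = "iid"
    by: Optional[str] = None
    per_group: Optional[dict] = None
    fixed_sigma2: Optional[float] = None

    KINDS = ("iid", "diag_by_group", "ar1xar1", "ar1_rows", "ar1_cols", "per_group")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise DesignError(f"unknown residual kind {self.kind!r}")
        if self.fixed_sigma2 is not None and self.kind != "iid":
            raise DesignError("fixed residual variance is only supported for iid residuals")


@dataclass
class ModelSpec:
    """Declarative mixed-model description over a trial table."""

    response: str
    fixed: tuple = ()
    random: tuple = ()
    residual: ResidualSpec = field(default_factory=ResidualSpec)
    weights: Optional[str] = None
    #: fixed factor encoded one-hot without intercept (cell means), e.g. the
    #: genotype in BLUE-extraction mode
    cell_means: Optional[str] = None

    def __post_init__(self) -> None:
        self.fixed = tuple(self.fixed)
        self.random = tuple(self.random)


# --------------------------------------------------------------------------
# design construction
# --------------------------------------------------------------------------


@dataclass
class TermDesign:
    name: str
    spec: CovarianceSpec
    idx: np.ndarray               # row -> level index
    q: int                        # number of levels
    levels: pd.DataFrame          # level index -> factor values
    outer_idx: Optional[np.ndarray] = None   # row -> outer level (structured)
    inner_same: Optional[np.ndarray] = None  # (n, n) inner-factor equality
    n_outer: int = 0
    n_inner: int = 0
    kernel_rows: Optional[np.ndarray] = None  # (n, n) K[g_a, g_b] gather
    same: Optional[np.ndarray] = None         # (n, n) level equality (iid)

    @property
    def n_free(self) -> int:
        return self.spec.n_free()


@dataclass
class ResidualDesign:
    spec: ResidualSpec
    groups: list                  # group labels
    rows: list                    # list of row-index arrays per group
    d_row: list                   # per group: |row_a - row_b| int matrix or None
    d_col: list
    inv_weights: np.ndarray       # 1/weight per record (ones if no weights)
    group_kinds: list             # effective kind per group

    def n_free(self) -> int:
        return sum(_RESID_NPAR[k] for k in self._param_blocks())

    def param_labels(self) -> list:
        """Human-readable residual parameter names, matching theta order."""
        s = self.spec
        if s.kind == "iid":
            return [] if s.fixed_sigma2 is not None else ["sigma2"]
        if s.kind == "diag_by_group":
            return [f"sigma2[{g}]" for g in self.groups]
        base = {"ar1xar1": ["sigma2", "rho_c", "rho_r"],
                "ar1_rows": ["sigma2", "rho_r"], "ar1_cols": ["sigma2", "rho_c"],
                "iid": ["sigma2"]}
        if s.kind in base:
            return list(base[s.kind])
        out = []
        for g, k in zip(self.groups, self.group_kinds):
            out += [f"{n}[{g}]" for n in base[k]]
        return out

    def transform_params(self, th: np.ndarray) -> dict:
        """Map unconstrained residual parameters to natural scale by label."""
        labels = self.param_labels()
        out = {}
        for lab, v in zip(labels, th):
            out[lab] = float(np.exp(v)) if lab.startswith("sigma2") else float(np.tanh(v))
        return out

    def _param_blocks(self) -> list:
        s = self.spec
        if s.kind == "iid":
            return [] if s.fixed_sigma2 is not None else ["iid"]
        if s.kind == "diag_by_group":
            return ["iid"] * len(self.groups)
        if s.kind in ("ar1xar1", "ar1_rows", "ar1_cols"):
            return [s.kind]
        if s.kind == "per_group":
            return [self.group_kinds[i] for i in range(len(self.groups))]
        raise DesignError(s.kind)


_RESID_NPAR = {"iid": 1, "ar1xar1": 3, "ar1_rows": 2, "ar1_cols": 2}


@dataclass
class DesignBundle:
    y: np.ndarray
    X: np.ndarray
    x_names: list
    terms: list
    resid: ResidualDesign
    table: pd.DataFrame           # the rows actually used, original index kept
    n: int
    p: int
    fixed_factors: tuple
    response: str


def _interaction_levels(table: pd.DataFrame, factors: Sequence[str]):
    """Full cartesian product of observed per-factor levels, factors[0] outermost."""
    per = [np.unique(table[f].to_numpy()) for f in factors]
    grids = np.meshgrid(*per, indexing="ij")
    levels = pd.DataFrame({f: g.ravel() for f, g in zip(factors, grids)})
    # row index for each record
    codes = np.zeros(len(table), dtype=np.int64)
    stride = 1
    strides = []
    for vals in reversed(per):
        strides.append(stride)
        stride *= len(vals)
    strides = list(reversed(strides))
    for f, vals, s in zip(factors, per, strides):
        pos = pd.Categorical(table[f], categories=vals).codes.astype(np.int64)
        codes += pos * s
    return codes, levels, [len(v) for v in per]


def build_design(table: pd.DataFrame, spec: ModelSpec) -> DesignBundle:
    """Assemble response, fixed design, random-term indicators and residual maps."""
    needed = set(spec.fixed) | {spec.response}
    if spec.cell_means:
        needed.add(spec.cell_means)
    for t in spec.random:
        needed.update(t.factors)
    if spec.residual.by:
        needed.add(spec.residual.by)
    if spec.weights:
        needed.add(spec.weights)
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise DesignError(f"model refers to missing columns: {missing}")

    factor_cols = set(needed) - {spec.response, spec.weights}
    bad = [c for c in factor_cols if table[c].isna().any()]
    if bad:
        raise DesignError(f"missing values in model factors: {sorted(bad)}")

    keep = table[spec.response].notna()
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropping %d records with missing %s", n_drop, spec.response)
    used = table.loc[keep].copy()
    if len(used) < 2:
        raise DesignError("fewer than 2 usable records")
    y = used[spec.response].to_numpy(dtype=float)
    n = len(used)

    # fixed design: intercept + drop-first dummies (or cell means, no intercept)
    cols = []
    names = []
    fixed_terms = list(spec.fixed)
    if spec.cell_means:
        lv = np.unique(used[spec.cell_means].to_numpy())
        codes = pd.Categorical(used[spec.cell_means], categories=lv).codes
        onehot = np.eye(len(lv))[codes]
        cols.append(onehot)
        names += [(spec.cell_means, str(v)) for v in lv]
        fixed_terms = [f for f in fixed_terms if f != spec.cell_means]
    else:
        cols.append(np.ones((n, 1)))
        names.append(("intercept", ""))
    for f in fixed_terms:
        lv = np.unique(used[f].to_numpy())
        if len(lv) < 2:
            continue
        codes = pd.Categorical(used[f], categories=lv).codes
        onehot = np.eye(len(lv))[codes][:, 1:]  # drop-first contrasts
        cols.append(onehot)
        names += [(f, str(v)) for v in lv[1:]]
    X = np.hstack(cols)
    p = X.shape[1]
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
        aliased = sorted({names[j][0] for j in piv[rank:]})
        raise DesignError(
            f"fixed design is rank deficient (rank {rank} < {p}); aliased terms: {aliased}"
        )

    terms = []
    for t in spec.random:
        codes, levels, sizes = _interaction_levels(used, t.factors)
        q = len(levels)
        td = TermDesign(name=t.name, spec=t.spec, idx=codes, q=q, levels=levels)
        if t.spec.kind == "scaled":
            if t.spec.base is None or t.kernel_levels is None:
                raise DesignError(f"term {t.name}: scaled structure needs base kernel + levels")
            kl = list(t.kernel_levels)
            pos = {v: i for i, v in enumerate(kl)}
            lev_vals = levels[t.factors[0]].tolist()
            unknown = [v for v in lev_vals if v not in pos]
            if unknown:
                raise DesignError(f"term {t.name}: levels missing from kernel: {unknown[:5]}")
            perm = np.array([pos[v] for v in lev_vals])
            td.spec = replace(t.spec, dim=q, base=t.spec.base[np.ix_(perm, perm)])
            td.kernel_rows = None  # filled lazily in the builder cache
        elif t.spec.kind == "identity":
            pass  # one shared variance, G = sigma2 * I_q for any level count
        elif t.spec.dim == q:
            pass  # structure directly over the term's levels
        elif len(t.factors) >= 2 and t.spec.dim == sizes[0]:
            td.n_outer = sizes[0]
            td.n_inner = q // sizes[0]
            td.outer_idx = codes // td.n_inner
            inner = codes % td.n_inner
            td.inner_same = inner[:, None] == inner[None, :]
        else:
            raise DesignError(
                f"term {t.name}: structure dimension {t.spec.dim} matches neither the "
                f"{q} term levels nor the {sizes[0]} levels of {t.factors[0]}"
            )
        if td.outer_idx is None and t.spec.kind == "identity":
            td.same = (codes[:, None] == codes[None, :])
        terms.append(td)

    # residual grouping and field geometry
    rs = spec.residual
    if rs.by is not None and rs.by in used.columns and rs.kind != "iid":
        glabels = list(np.unique(used[rs.by].to_numpy()))
        rows = [np.flatnonzero((used[rs.by] == g).to_numpy()) for g in glabels]
    else:
        glabels = [None]
        rows = [np.arange(n)]
    spatial_kinds = ("ar1xar1", "ar1_rows", "ar1_cols")
    group_kinds = []
    for i, g in enumerate(glabels):
        if rs.kind == "per_group":
            if rs.per_group is None or g not in rs.per_group:
                raise DesignError(f"per_group residual missing a kind for group {g!r}")
            group_kinds.append(rs.per_group[g])
        elif rs.kind == "diag_by_group":
            group_kinds.append("iid")
        else:
            group_kinds.append(rs.kind)
    d_row, d_col = [], []
    for gi, ridx in enumerate(rows):
        if group_kinds[gi] in spatial_kinds:
            for c in ("row", "col"):
                if c not in used.columns:
                    raise DesignError(f"spatial residuals need a {c!r} column")
            r = used["row"].to_numpy(dtype=np.int64)[ridx]
            c = used["col"].to_numpy(dtype=np.int64)[ridx]
            d_row.append(np.abs(r[:, None] - r[None, :]))
            d_col.append(np.abs(c[:, None] - c[None, :]))
        else:
            d_row.append(None)
            d_col.append(None)
    if spec.weights:
        w = used[spec.weights].to_numpy(dtype=float)
        if np.any(~np.isfinite(w)) or np.any(w <= 0):
            raise DesignError("weights must be strictly positive and finite")
        if any(k in spatial_kinds for k in group_kinds):
            raise DesignError("weights cannot be combined with spatial residuals")
        inv_w = 1.0 / w
    else:
        inv_w = np.ones(n)

    resid = ResidualDesign(
        spec=rs, groups=glabels, rows=rows, d_row=d_row, d_col=d_col,
        inv_weights=inv_w, group_kinds=group_kinds,
    )
    return DesignBundle(
        y=y, X=X, x_names=names, terms=terms, resid=resid, table=used,
        n=n, p=p, fixed_factors=tuple(fixed_terms), response=spec.response,
    )


# --------------------------------------------------------------------------
# V construction and likelihood
# --------------------------------------------------------------------------


class _VBuilder:
    """Caches per-term gather maps and assembles V(theta)."""

    def __init__(self, design: DesignBundle):
        self.d = design
        self.n = design.n
        self.slices = []
        pos = 0
        for t in design.terms:
            k = t.n_free
            self.slices.append(slice(pos, pos + k))
            pos += k
        self.resid_slice = slice(pos, pos + design.resid.n_free())
        self.n_theta = pos + design.resid.n_free()
        self._caches = {}
        self._pairs = {}  # flat gather index into G.ravel() per structured term
        for t in design.terms:
            if t.spec.kind == "scaled":
                K = t.spec.base
                self._caches[t.name] = K[np.ix_(t.idx, t.idx)]
            elif t.same is not None:
                self._caches[t.name] = t.same.astype(float)
            elif t.outer_idx is not None:
                p = t.spec.dim
                self._pairs[t.name] = t.outer_idx[:, None] * p + t.outer_idx[None, :]
                self._caches[t.name] = t.inner_same.astype(float)
            else:
                self._pairs[t.name] = t.idx[:, None] * t.q + t.idx[None, :]

    def term_spec(self, t: TermDesign, theta_t: np.ndarray) -> CovarianceSpec:
        s = t.spec
        return covstruct.from_unconstrained(
            s.kind, s.dim, theta_t, k=s.order if s.kind == "fa" else 1, base=s.base
        )

    def build(self, theta: np.ndarray) -> np.ndarray:
        V = np.zeros((self.n, self.n))
        for ti in range(len(self.d.terms)):
            self._add_term(V, ti, theta[self.slices[ti]])
        self._add_residual(V, theta[self.resid_slice])
        return V

    def _term_matrix(self, ti: int, th: np.ndarray) -> np.ndarray:
        """Realized q x q (or p x p outer) structure of one term."""
        return covstruct.realize(self.term_spec(self.d.terms[ti], th))

    def _add_term(self, V: np.ndarray, ti: int, th: np.ndarray) -> None:
        t = self.d.terms[ti]
        s = t.spec
        if s.kind in ("identity", "scaled") and t.outer_idx is None:
            V += np.exp(th[0]) * self._caches[t.name]
        elif t.outer_idx is not None:
            sigma = self._term_matrix(ti, th)
            V += np.take(sigma.ravel(), self._pairs[t.name]) * self._caches[t.name]
        else:
            G = self._term_matrix(ti, th)
            V += np.take(G.ravel(), self._pairs[t.name])

    def vdot(self, theta: np.ndarray, i: int, h: float = 1e-5):
        """dV/dtheta_i, differencing only the component that owns parameter i.

        Contributions of other terms cancel exactly in the central
        difference, so they are never rebuilt; for structured terms only the
        small level-covariance matrix is differenced before gathering.  For
        shared-variance terms (identity / scaled kernels) V is linear in
        sigma2 = exp(theta) and the derivative is exact.  Returns either a
        dense matrix or ``("diag", vector)`` for diagonal derivatives.
        """
        for ti, sl in enumerate(self.slices):
            if sl.start <= i < sl.stop:
                t = self.d.terms[ti]
                th = theta[sl]
                if t.spec.kind in ("identity", "scaled") and t.outer_idx is None:
                    return np.exp(th[0]) * self._caches[t.name]
                tp = th.copy(); tp[i - sl.start] += h
                tm = th.copy(); tm[i - sl.start] -= h
                dG = (self._term_matrix(ti, tp) - self._term_matrix(ti, tm)) / (2 * h)
                grab = np.take(dG.ravel(), self._pairs[t.name])
                if t.outer_idx is not None:
                    grab = grab * self._caches[t.name]
                return grab
        sl = self.resid_slice
        rd = self.d.resid
        j = i - sl.start
        s = rd.spec
        # iid-style residual parameters have diagonal derivatives
        if s.kind == "iid":
            return "diag", np.exp(theta[sl][0]) * rd.inv_weights
        if s.kind == "diag_by_group":
            vec = np.zeros(self.n)
            ridx = rd.rows[j]
            vec[ridx] = np.exp(theta[sl][j]) * rd.inv_weights[ridx]
            return "diag", vec
        vp = np.zeros((self.n, self.n))
        vm = np.zeros((self.n, self.n))
        tp = theta[sl].copy(); tp[j] += h
        tm = theta[sl].copy(); tm[j] -= h
        self._add_residual(vp, tp)
        self._add_residual(vm, tm)
        return (vp - vm) / (2 * h)

    def _add_residual(self, V: np.ndarray, th: np.ndarray) -> None:
        rd = self.d.resid
        s = rd.spec
        diag = np.arange(self.n)
        if s.kind == "iid":
            s2 = s.fixed_sigma2 if s.fixed_sigma2 is not None else np.exp(th[0])
            V[diag, diag] += s2 * rd.inv_weights
            return
        if s.kind == "diag_by_group":
            for gi, ridx in enumerate(rd.rows):
                V[ridx, ridx] += np.exp(th[gi]) * rd.inv_weights[ridx]
            return
        pos = 0
        for gi, ridx in enumerate(rd.rows):
            kind = rd.group_kinds[gi]
            npar = _RESID_NPAR[kind]
            if s.kind in ("ar1xar1", "ar1_rows", "ar1_cols"):
                th_g = th[:npar]          # shared parameters across groups
            else:
                th_g = th[pos:pos + npar]
                pos += npar
            self._add_group_block(V, ridx, kind, th_g, gi)

    @staticmethod
    def _rho_pow(rho: float, d: np.ndarray) -> np.ndarray:
        # lookup-table gather: far cheaper than element-wise float powers
        pows = rho ** np.arange(int(d.max()) + 1, dtype=float)
        return pows[d]

    def _add_group_block(self, V, ridx, kind, th_g, gi) -> None:
        rd = self.d.resid
        s2 = np.exp(th_g[0])
        if kind == "iid":
            V[ridx, ridx] += s2 * rd.inv_weights[ridx]
            return
        dr, dc = rd.d_row[gi], rd.d_col[gi]
        if kind == "ar1xar1":
            rho_c, rho_r = np.tanh(th_g[1]), np.tanh(th_g[2])
            block = s2 * self._rho_pow(rho_c, dc) * self._rho_pow(rho_r, dr)
        elif kind == "ar1_rows":
            rho_r = np.tanh(th_g[1])
            block = s2 * (dc == 0) * self._rho_pow(rho_r, dr)
        else:  # ar1_cols
            rho_c = np.tanh(th_g[1])
            block = s2 * (dr == 0) * self._rho_pow(rho_c, dc)
        if len(ridx) == self.n and ridx[0] == 0 and ridx[-1] == self.n - 1:
            V += block
        else:
            V[np.ix_(ridx, ridx)] += block


def _factorize(V: np.ndarray, X: np.ndarray, y: np.ndarray):
    """Cholesky-based REML quantities; None if V or X'V^-1 X not PD."""
    try:
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return None
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
    vi_x = linalg.cho_solve((c, low), X, check_finite=False)
    vi_y = linalg.cho_solve((c, low), y, check_finite=False)
    xtvix = X.T @ vi_x
    try:
        cx = linalg.cho_factor(xtvix, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return None
    logdet_x = 2.0 * float(np.sum(np.log(np.diag(cx[0]))))
    xtviy = X.T @ vi_y
    beta = linalg.cho_solve(cx, xtviy, check_finite=False)
    quad = float(y @ vi_y - xtviy @ beta)
    return {
        "chol": (c, low), "chol_x": cx, "vi_x": vi_x, "vi_y": vi_y,
        "beta": beta, "quad": quad, "logdet_v": logdet_v, "logdet_x": logdet_x,
    }


def reml_loglik(theta: np.ndarray, design: DesignBundle, builder: Optional[_VBuilder] = None) -> float:
    """Restricted log-likelihood at an unconstrained parameter vector.

    Includes the -(n - p)/2 log(2 pi) constant so values line up with
    standard mixed-model software; returns -inf when V is not PD.
    """
    b = builder or _VBuilder(design)
    f = _factorize(b.build(np.asarray(theta, dtype=float)), design.X, design.y)
    if f is None:
        return -np.inf
    n, p = design.n, design.p
    return -0.5 * (f["logdet_v"] + f["logdet_x"] + f["quad"] + (n - p) * LOG2PI)


def _neg_loglik_grad(theta, design, builder, fd_step=1e-5):
    V = builder.build(theta)
    f = _factorize(V, design.X, design.y)
    if f is None:
        return 1e10, np.zeros_like(theta)
    n, p = design.n, design.p
    ll = -0.5 * (f["logdet_v"] + f["logdet_x"] + f["quad"] + (n - p) * LOG2PI)
    c = f["chol"]
    vinv = linalg.cho_solve(c, np.eye(n), check_finite=False)
    py = f["vi_y"] - f["vi_x"] @ f["beta"]
    w_inv = linalg.cho_solve(f["chol_x"], np.eye(p), check_finite=False)
    vi_x = f["vi_x"]
    grad = np.empty_like(theta)
    for i in range(len(theta)):
        vd = builder.vdot(theta, i, fd_step)
        if isinstance(vd, tuple):  # diagonal derivative fast path
            dvec = vd[1]
            a = (vi_x * dvec[:, None]).T @ vi_x
            tr_p_vd = float(np.diag(vinv) @ dvec) - float(np.sum(w_inv * a))
            grad[i] = -0.5 * (tr_p_vd - float((py * py) @ dvec))
        else:
            a = vi_x.T @ vd @ vi_x
            tr_p_vd = float(np.sum(vinv * vd)) - float(np.sum(w_inv * a))
            grad[i] = -0.5 * (tr_p_vd - float(py @ vd @ py))
    return -ll, -grad


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


@dataclass
class FitResult:
    """Fitted mixed model: variance components, BLUEs, BLUPs, diagnostics."""

    spec: ModelSpec
    varcomp: dict                     # term name -> fitted CovarianceSpec
    varcomp_names: list               # flat parameter labels
    theta: np.ndarray                 # optimum, unconstrained scale
    loglik: float
    n_varparams: int
    aic: float
    converged: bool
    iterations: int
    blues: pd.DataFrame               # fixed-effect estimates +- SE
    blups: dict                       # term name -> DataFrame(level cols, blup, pev)
    pec: dict                         # term name -> (q, q) PEC matrix or None
    residuals: np.ndarray             # conditional residuals, aligned to table
    fitted: np.ndarray
    table: pd.DataFrame               # records used (original index preserved)
    n_obs: int
    beta_cov: np.ndarray
    design: DesignBundle
    residual_estimates: dict = field(default_factory=dict)

    def blup_frame(self, term: str) -> pd.DataFrame:
        return self.blups[term]

    def genotype_blups(self, term: str = "genotype") -> pd.DataFrame:
        return self.blups[term]

    def residual_variance(self) -> float:
        """Residual variance (first residual parameter, or the fixed value)."""
        rs = self.spec.residual
        if rs.kind == "iid" and rs.fixed_sigma2 is not None:
            return float(rs.fixed_sigma2)
        vals = list(self.residual_estimates.values())
        return vals[0] if vals else float("nan")

    def wald_tests(self) -> pd.DataFrame:
        """Approximate Wald chi-square tests for each fixed factor."""
        rows = []
        names = self.design.x_names
        for f in dict.fromkeys(n[0] for n in names if n[0] != "intercept"):
            j = [i for i, n in enumerate(names) if n[0] == f]
            b = self.blues["estimate"].to_numpy()[j]
            cov = self.beta_cov[np.ix_(j, j)]
            stat = float(b @ np.linalg.solve(cov, b))
            df = len(j)
            rows.append({"term": f, "wald_chi2": stat, "df": df,
                        "p_value": float(stats.chi2.sf(stat, df))})
        return pd.DataFrame(rows)


def _start_values(design: DesignBundle, builder: _VBuilder, rng) -> np.ndarray:
    """Equal-partition heuristic: split the OLS residual variance over components."""
    X, y = design.X, design.y
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    vtot = max(float(np.var(resid, ddof=min(design.p, len(y) - 1))), 1e-6)
    n_comp = len(design.terms) + (1 if builder.resid_slice.stop > builder.resid_slice.start else 0)
    share = vtot / max(n_comp, 1)
    theta = np.zeros(builder.n_theta)
    for t, sl in zip(design.terms, builder.slices):
        s = t.spec
        if s.kind == "fa":
            k = s.order
            mask = covstruct.fa_free_loading_mask(s.dim, k)
            lam = np.zeros((s.dim, k))
            lam[:, 0] = np.sqrt(share / 2)
            if k > 1:
                lam[:, 1:] = 0.05 * np.sqrt(share)
            vec = np.concatenate([lam[mask], np.full(s.dim, np.log(share / 2))])
            theta[sl] = vec
        elif s.kind in ("identity", "scaled"):
            theta[sl] = np.log(share)
        elif s.kind == "diagonal":
            theta[sl] = np.log(share)
        elif s.kind == "cs":
            theta[sl] = [np.log(share), np.arctanh(0.3)]
        elif s.kind == "ar1":
            theta[sl] = [np.log(share), 0.0]
        elif s.kind == "uniform_corr":
            theta[sl] = np.concatenate([np.full(s.dim, np.log(share)), [np.arctanh(0.3)]])
        elif s.kind == "general_corr":
            v = np.full(s.dim, np.log(share))
            theta[sl] = np.concatenate([v, np.zeros(s.dim * (s.dim - 1) // 2)])
        else:
            theta[sl] = 0.0
    rsl = builder.resid_slice
    if rsl.stop > rsl.start:
        blocks = design.resid._param_blocks()
        vals = []
        for k in blocks:
            vals.append(np.log(share))
            vals.extend([0.0] * (_RESID_NPAR[k] - 1))
        theta[rsl] = vals
    return theta


def fit(
    spec: ModelSpec,
    table: pd.DataFrame,
    *,
    starts: int = 3,
    max_iter: int = 300,
    tol: float = 1e-14,
    gtol: float = 1e-8,
    seed: int = 0,
    pec_max: int = 600,
    theta0: Optional[np.ndarray] = None,
) -> FitResult:
    """Fit a mixed model by REML and extract BLUEs / BLUPs / PEV / PEC.

    Multi-start L-BFGS from a variance-partition heuristic (the first start)
    plus ``starts - 1`` jittered restarts; the best restricted likelihood
    wins.  Non-convergence is flagged, never raised: the best point found is
    still returned.
    """
    design = build_design(table, spec)
    if design.n - design.p < 2:
        raise DesignError("fewer than 2 residual degrees of freedom")
    builder = _VBuilder(design)
    rng = np.random.default_rng(seed)
    base = _start_values(design, builder, rng) if theta0 is None else np.asarray(theta0, float)
    bounds = [(-30.0, 30.0)] * builder.n_theta

    best = None
    total_iter = 0
    for s in range(max(starts, 1)):
        x0 = base if s == 0 else base + rng.uniform(-0.7, 0.7, size=base.shape)
        if builder.n_theta == 0:
            best = (None, x0)
            break
        res = optimize.minimize(
            _neg_loglik_grad, x0, args=(design, builder), jac=True,
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": max_iter, "ftol": tol, "gtol": gtol},
        )
        total_iter += res.nit
        if best is None or res.fun < best[0].fun:
            best = (res, res.x)
    res, theta = best
    # restart polish: a fresh L-BFGS state escapes the narrow curved valleys
    # of correlated parameterizations (e.g. CS variance/covariance) where a
    # single run can satisfy its f-tolerance away from the optimum
    if res is not None:
        for _ in range(3):
            if res.jac is not None and float(np.max(np.abs(res.jac))) < 1e-5:
                break
            res2 = optimize.minimize(
                _neg_loglik_grad, res.x, args=(design, builder), jac=True,
                method="L-BFGS-B", bounds=bounds,
                options={"maxiter": max_iter, "ftol": tol, "gtol": gtol},
            )
            total_iter += res2.nit
            if res2.fun >= res.fun - 1e-10:
                res = res2 if res2.fun < res.fun else res
                break
            res = res2
        theta = res.x
    if res is not None:
        # line-search breakdown at a flat optimum (e.g. a variance at its
        # boundary) is still convergence if the projected gradient is tiny
        grad_ok = res.jac is not None and float(np.max(np.abs(res.jac))) < 1e-3
        converged = bool(res.success) or res.status == 0 or grad_ok
        loglik = -float(res.fun)
    else:
        converged, loglik = True, reml_loglik(theta, design, builder)
    if res is not None and not converged:
        logger.warning("REML did not converge after %d iterations: %s", total_iter, res.message)

    n_vp = builder.n_theta
    aic = -2.0 * loglik + 2.0 * n_vp

    # solutions at the optimum
    V = builder.build(theta)
    f = _factorize(V, design.X, design.y)
    if f is None:
        raise DesignError("V is not positive definite at the reported optimum")
    n, p = design.n, design.p
    beta = f["beta"]
    beta_cov = linalg.cho_solve(f["chol_x"], np.eye(p), check_finite=False)
    blues = pd.DataFrame(
        {
            "term": [t for t, _ in design.x_names],
            "level": [l for _, l in design.x_names],
            "estimate": beta,
            "se": np.sqrt(np.maximum(np.diag(beta_cov), 0.0)),
        }
    )
    py = f["vi_y"] - f["vi_x"] @ beta
    vinv = linalg.cho_solve(f["chol"], np.eye(n), check_finite=False)
    P = vinv - f["vi_x"] @ beta_cov @ f["vi_x"].T

    varcomp = {}
    blups = {}
    pec = {}
    varcomp_names = []
    fitted_random = np.zeros(n)
    for t, sl in zip(design.terms, builder.slices):
        fitted_spec = builder.term_spec(t, theta[sl])
        if fitted_spec.kind == "fa":
            fitted_spec.params["loadings"] = covstruct.sign_fix_loadings(
                fitted_spec.params["loadings"]
            )
        varcomp[t.name] = fitted_spec
        varcomp_names += [f"{t.name}[{i}]" for i in range(t.n_free)]
        G_full = _term_g_full(t, fitted_spec)
        s_vec = np.bincount(t.idx, weights=py, minlength=t.q)
        u = G_full @ s_vec
        E = np.zeros((n, t.q))
        E[np.arange(n), t.idx] = 1.0
        M = E.T @ P @ E
        C = G_full - G_full @ M @ G_full
        pev = np.maximum(np.diag(C), 0.0)
        # PEC matrices are only retained for terms of modest size; PEV always is
        pec[t.name] = C if t.q <= pec_max else None
        frame = t.levels.copy()
        frame["blup"] = u
        frame["pev"] = pev
        blups[t.name] = frame
        fitted_random += u[t.idx]
    varcomp_names += [f"residual[{i}]" for i in range(design.resid.n_free())]
    varcomp["residual"] = design.resid.spec

    fitted = design.X @ beta + fitted_random
    residuals = design.y - fitted

    return FitResult(
        spec=spec, varcomp=varcomp, varcomp_names=varcomp_names, theta=theta,
        loglik=loglik, n_varparams=n_vp, aic=aic, converged=converged,
        iterations=total_iter, blues=blues, blups=blups, pec=pec,
        residuals=residuals, fitted=fitted, table=design.table, n_obs=n,
        beta_cov=beta_cov, design=design,
        residual_estimates=design.resid.transform_params(theta[builder.resid_slice]),
    )


def _term_g_full(t: TermDesign, fitted_spec: CovarianceSpec) -> np.ndarray:
    G = covstruct.realize(fitted_spec)
    if t.outer_idx is not None:
        return np.kron(G, np.eye(t.n_inner))
    if G.shape[0] == t.q:
        return G
    if fitted_spec.kind == "identity":
        return float(fitted_spec.params["sigma2"]) * np.eye(t.q)
    raise DesignError(f"cannot expand structure for term {t.name}")


def model_compare(fits: dict) -> pd.DataFrame:
    """Rank fits by AIC (ascending); ties broken by fewer variance parameters.

    All fits must share the same fixed-effect structure: REML likelihoods are
    only comparable when the fixed part is identical.
    """
    items = list(fits.items())
    ref = items[0][1].design.x_names
    for k, f in items[1:]:
        if f.design.x_names != ref:
            raise DesignError(
                "AIC comparison requires identical fixed effects in every model "
                "(REML likelihoods are not comparable across fixed structures); "
                f"model {k!r} differs"
            )
    rows = [
        {
            "model": k,
            "loglik": f.loglik,
            "n_varparams": f.n_varparams,
            "aic": f.aic,
            "converged": f.converged,
        }
        for k, f in items
    ]
    out = pd.DataFrame(rows).sort_values(
        ["aic", "n_varparams"], kind="mergesort"
    ).reset_index(drop=True)
    return out
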