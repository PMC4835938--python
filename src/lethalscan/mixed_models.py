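"""Pedigree relationship algebra and weighted-residual REML mixed models.

The model is

    y = X beta + sum_k Z_k u_k + e,   u_k ~ N(0, sigma_k^2 A_k),
    e ~ N(0, W^-1 sigma_e^2)

with W a diagonal matrix of reliability-derived weights.  The restricted
log-likelihood is maximised over the variance ratios gamma_k =
sigma_k^2/sigma_e^2 on the log scale (which enforces non-negativity), with
sigma_e^2 profiled out analytically.  Two algebraically equivalent evaluation
routes are used depending on problem shape: a dense-V route (Cholesky of the
n x n marginal covariance) when the number of random-effect levels exceeds n,
and a mixed-model-equations route (Cholesky of the (p+q) x (p+q) coefficient
matrix) when there are many observations but few levels, as in the mating
model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

_LOG2PI = math.log(2.0 * math.pi)
_THETA_LO, _THETA_HI = -25.0, 15.0  # log variance-ratio bounds (gamma in [1e-11, 3e6])


class PedigreeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Additive relationship matrix
# ---------------------------------------------------------------------------

@dataclass
class RelationshipMatrix:
    """Dense additive (numerator) relationship matrix with its id order."""

    ids: list[str]
    A: np.ndarray

    def __post_init__(self) -> None:
        self._index = {ident: i for i, ident in enumerate(self.ids)}

    def subset(self, ids) -> "RelationshipMatrix":
        idx = [self._index[i] for i in ids]
        return RelationshipMatrix(ids=list(ids), A=self.A[np.ix_(idx, idx)])

    def inbreeding(self) -> np.ndarray:
        return np.diag(self.A) - 1.0


def build_A(pedigree: pd.DataFrame) -> RelationshipMatrix:
    """Additive relationship matrix by the recursive tabular method.

    ``pedigree`` needs columns id, sire, dam; empty/NaN parent means unknown
    (founder side).  Founders are taken as unrelated and non-inbred.  Raises
    :class:`PedigreeError` on unknown parent ids or pedigree cycles (the
    cycle is listed in the message).
    """
    ids = pedigree["id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise PedigreeError("duplicate ids in pedigree")
    index = {ident: i for i, ident in enumerate(ids)}

    def parent(v) -> int:
        if pd.isna(v) or v == "" or v == "0":
            return -1
        v = str(v)
        if v not in index:
            raise PedigreeError(f"unknown parent id {v!r}")
        return index[v]

    sire = np.array([parent(v) for v in pedigree["sire"]])
    dam = np.array([parent(v) for v in pedigree["dam"]])

    # Kahn topological sort (parents before offspring)
    n = len(ids)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=int)
    for i in range(n):
        for par in (sire[i], dam[i]):
            if par >= 0:
                children[par].append(i)
                indeg[i] += 1
    order = [i for i in range(n) if indeg[i] == 0]
    head = 0
    while head < len(order):
        for c in children[order[head]]:
            indeg[c] -= 1
            if indeg[c] == 0:
                order.append(c)
        head += 1
    if len(order) < n:
        cyc = [ids[i] for i in range(n) if indeg[i] > 0]
        raise PedigreeError(f"pedigree contains a cycle involving: {', '.join(cyc)}")

    pos = np.empty(n, dtype=int)
    pos[order] = np.arange(n)
    A = np.zeros((n, n))
    for k, i in enumerate(order):
        s, d = sire[i], dam[i]
        sp = pos[s] if s >= 0 else -1
        dp = pos[d] if d >= 0 else -1
        row = np.zeros(k)
        if sp >= 0:
            row += 0.5 * A[sp, :k]
        if dp >= 0:
            row += 0.5 * A[dp, :k]
        A[k, :k] = row
        A[:k, k] = row
        A[k, k] = 1.0 + (0.5 * A[sp, dp] if sp >= 0 and dp >= 0 else 0.0)
    # back to input order
    A = A[np.ix_(pos, pos)]
    return RelationshipMatrix(ids=ids, A=A)


# ---------------------------------------------------------------------------
# Model specification and fit result
# ---------------------------------------------------------------------------

@dataclass
class RandomTerm:
    """One random effect: incidence matrix Z (n x q) and a q x q covariance
    structure among levels (None = identity)."""

    name: str
    Z: np.ndarray
    cov: np.ndarray | None = None
    levels: list | None = None


@dataclass
class ModelSpec:
    """Declarative model: response column, fixed covariates (categoricals are
    dummy-coded with the first level as reference), random grouping columns
    with optional covariance structures, and an optional weight column."""

    response: str
    fixed: list[str] = field(default_factory=list)
    random: list[tuple] = field(default_factory=list)  # (name, group_col, RelationshipMatrix|None)
    weights: str | None = None

    def build(self, data: pd.DataFrame):
        y = data[self.response].to_numpy(dtype=float)
        cols = [np.ones(len(data))]
        names = ["(intercept)"]
        for c in self.fixed:
            col = data[c]
            if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
                dummies = pd.get_dummies(col.astype(str), prefix=c, drop_first=True)
                cols.extend(dummies[c2].to_numpy(dtype=float) for c2 in dummies)
                names.extend(dummies.columns.tolist())
            else:
                cols.append(col.to_numpy(dtype=float))
                names.append(c)
        X = np.column_stack(cols)
        terms = []
        for name, group_col, struct in self.random:
            groups = data[group_col].astype(str).to_numpy()
            if struct is None:
                levels = sorted(set(groups))
                cov = None
            else:
                levels = [l for l in struct.ids if l in set(groups)]
                cov = struct.subset(levels).A
            lvl_index = {l: j for j, l in enumerate(levels)}
            Z = np.zeros((len(data), len(levels)))
            for i, gval in enumerate(groups):
                Z[i, lvl_index[gval]] = 1.0
            terms.append(RandomTerm(name=name, Z=Z, cov=cov, levels=levels))
        w = data[self.weights].to_numpy(dtype=float) if self.weights else None
        return y, X, terms, w, names


@dataclass
class FitResult:
    fixed_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    cov_beta: np.ndarray
    varcomp: dict
    loglik: float
    converged: bool
    n: int
    p: int
    blups: dict = field(default_factory=dict)

    def coef(self, name: str) -> tuple[float, float]:
        i = self.fixed_names.index(name)
        return float(self.beta[i]), float(self.se[i])


class SingularDesignError(np.linalg.LinAlgError):
    pass


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    q, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        aliased = [names[j] for j in piv[rank:]]
        raise SingularDesignError(
            f"design matrix is rank deficient; aliased columns: {', '.join(aliased)}")


class _RemlProblem:
    """Profiled REML objective, evaluated by the cheaper of two exact routes."""

    def __init__(self, y, X, terms, w):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.terms = terms
        self.n, self.p = self.X.shape
        self.w = np.ones(self.n) if w is None else np.asarray(w, dtype=float)
        if np.any(self.w <= 0):
            raise ValueError("weights must be > 0")
        self.q = [t.Z.shape[1] for t in terms]
        self.q_total = int(sum(self.q))
        self.use_mme = (self.p + self.q_total) < self.n
        if self.use_mme:
            self._setup_mme()
        else:
            self._setup_v()

    # ----- dense-V route --------------------------------------------------
    def _setup_v(self):
        self.K = []
        for t in self.terms:
            ZA = t.Z if t.cov is None else t.Z @ t.cov
            self.K.append(ZA @ t.Z.T)
        self.winv = 1.0 / self.w

    def _eval_v(self, gammas):
        n, p = self.n, self.p
        Vs = np.diag(self.winv).copy()
        for g, K in zip(gammas, self.K):
            Vs += g * K
        c, low = linalg.cho_factor(Vs, lower=True)
        logdetV = 2.0 * np.log(np.diag(c)).sum()
        ViX = linalg.cho_solve((c, low), self.X)
        Viy = linalg.cho_solve((c, low), self.y)
        XtViX = self.X.T @ ViX
        XtViy = self.X.T @ Viy
        cf = linalg.cho_factor(XtViX)
        beta = linalg.cho_solve(cf, XtViy)
        yPy = float(self.y @ Viy - XtViy @ beta)
        logdetXVX = 2.0 * np.log(np.diag(cf[0])).sum()
        sigma_e2 = max(yPy / (n - p), 1e-300)
        m2ll = ((n - p) * math.log(sigma_e2) + logdetV + logdetXVX
                + (n - p) * (1.0 + _LOG2PI))
        return m2ll, beta, XtViX, sigma_e2, (c, low)

    # ----- mixed-model-equations route ------------------------------------
    def _setup_mme(self):
        X, y, w = self.X, self.y, self.w
        Z = np.hstack([t.Z for t in self.terms]) if self.terms else np.zeros((self.n, 0))
        Xw = X * w[:, None]
        self.XtRX = X.T @ Xw
        self.XtRZ = Xw.T @ Z
        self.ZtRZ = (Z * w[:, None]).T @ Z
        self.XtRy = Xw.T @ y
        self.ZtRy = (Z * w[:, None]).T @ y
        self.ytRy = float(y @ (w * y))
        self.sum_log_w = float(np.log(w).sum())
        self.cov_inv = []
        self.cov_logdet = []
        for t in self.terms:
            if t.cov is None:
                self.cov_inv.append(None)
                self.cov_logdet.append(0.0)
            else:
                cf = linalg.cho_factor(t.cov)
                self.cov_inv.append(linalg.cho_solve(cf, np.eye(t.cov.shape[0])))
                self.cov_logdet.append(2.0 * np.log(np.diag(cf[0])).sum())

    def _eval_mme(self, gammas):
        n, p, q = self.n, self.p, self.q_total
        C = np.zeros((p + q, p + q))
        C[:p, :p] = self.XtRX
        C[:p, p:] = self.XtRZ
        C[p:, :p] = self.XtRZ.T
        C[p:, p:] = self.ZtRZ
        log_detG = 0.0
        off = p
        for g, t, ci, cld, qk in zip(gammas, self.terms, self.cov_inv,
                                     self.cov_logdet, self.q):
            sl = slice(off, off + qk)
            if ci is None:
                C[sl, sl] += np.eye(qk) / g
            else:
                C[sl, sl] += ci / g
            log_detG += qk * math.log(g) + cld
            off += qk
        rhs = np.concatenate([self.XtRy, self.ZtRy])
        cf = linalg.cho_factor(C)
        sol = linalg.cho_solve(cf, rhs)
        logdetC = 2.0 * np.log(np.diag(cf[0])).sum()
        yPy = float(self.ytRy - rhs @ sol)
        sigma_e2 = max(yPy / (n - p), 1e-300)
        m2ll = ((n - p) * math.log(sigma_e2) - self.sum_log_w + log_detG
                + logdetC + (n - p) * (1.0 + _LOG2PI))
        return m2ll, sol, cf, sigma_e2

    # ----- objective -------------------------------------------------------
    def neg2_restricted_ll(self, theta) -> float:
        gammas = np.exp(np.clip(theta, _THETA_LO, _THETA_HI))
        try:
            if self.use_mme:
                return self._eval_mme(gammas)[0]
            return self._eval_v(gammas)[0]
        except np.linalg.LinAlgError:
            return 1e30

    def finalize(self, theta, fixed_names, converged) -> FitResult:
        gammas = np.exp(np.clip(theta, _THETA_LO, _THETA_HI))
        blups: dict = {}
        if self.use_mme:
            m2ll, sol, cf, sigma_e2 = self._eval_mme(gammas)
            beta = sol[: self.p]
            Cinv = linalg.cho_solve(cf, np.eye(self.p + self.q_total))
            cov_beta = sigma_e2 * Cinv[: self.p, : self.p]
            off = self.p
            for t, qk in zip(self.terms, self.q):
                blups[t.name] = sol[off: off + qk].copy()
                off += qk
        else:
            m2ll, beta, XtViX, sigma_e2, chol = self._eval_v(gammas)
            cov_beta = sigma_e2 * np.linalg.inv(XtViX)
            resid = self.y - self.X @ beta
            Vir = linalg.cho_solve(chol, resid)
            for g, t in zip(gammas, self.terms):
                u = g * (t.Z.T @ Vir)
                if t.cov is not None:
                    u = t.cov @ u
                blups[t.name] = u
        # clamp effectively-zero ratios to exact zero in the report
        varcomp = {"residual": float(sigma_e2)}
        for g, t in zip(gammas, self.terms):
            varcomp[t.name] = float(g * sigma_e2) if g > 2e-11 else 0.0
        se = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))
        return FitResult(
            fixed_names=list(fixed_names), beta=np.asarray(beta), se=se,
            cov_beta=cov_beta, varcomp=varcomp, loglik=-0.5 * m2ll,
            converged=bool(converged), n=self.n, p=self.p, blups=blups,
        )


def reml_fit(y, X, random_terms=(), weights=None, fixed_names=None) -> FitResult:
    """Fit the weighted linear mixed model by REML.

    Parameters are the response vector, fixed-effect design matrix, a
    sequence of :class:`RandomTerm`, and optional positive residual weights.
    Non-convergence is reported through ``FitResult.converged`` rather than
    an exception; a rank-deficient design raises
    :class:`SingularDesignError` naming the aliased columns.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    n, p = X.shape
    if fixed_names is None:
        fixed_names = [f"b{j}" for j in range(p)]
    _check_full_rank(X, list(fixed_names))
    terms = list(random_terms)
    for t in terms:
        if n - p < 2:
            raise ValueError("too few observations to estimate variance components")

    # degenerate response: all variance components are zero
    resid0 = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    if len(y) == 0 or float(np.var(y)) < 1e-28 or float(resid0 @ resid0) < 1e-24:
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        varcomp = {"residual": 0.0, **{t.name: 0.0 for t in terms}}
        return FitResult(fixed_names=list(fixed_names), beta=beta,
                         se=np.zeros(p), cov_beta=np.zeros((p, p)),
                         varcomp=varcomp, loglik=float("inf"), converged=True,
                         n=n, p=p,
                         blups={t.name: np.zeros(t.Z.shape[1]) for t in terms})

    prob = _RemlProblem(y, X, terms, weights)
    k = len(terms)
    if k == 0:
        return prob.finalize(np.empty(0), fixed_names, True)
    if k == 1:
        res = optimize.minimize_scalar(
            lambda t: prob.neg2_restricted_ll([t]),
            bounds=(_THETA_LO, _THETA_HI), method="bounded",
            options={"xatol": 1e-10})
        theta = np.array([res.x])
        ok = res.success
    else:
        res = optimize.minimize(
            prob.neg2_restricted_ll, np.zeros(k), method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000,
                     "maxfev": 6000})
        theta = np.asarray(res.x)
        ok = res.success
    return prob.finalize(theta, fixed_names, ok)


# ---------------------------------------------------------------------------
# Tests on fitted models
# ---------------------------------------------------------------------------

@dataclass
class WaldResult:
    statistic: float
    p: float
    mlog10p: float


def wald_test(fit: FitResult, coefficient) -> WaldResult:
    """Two-sided Wald test of H0: coefficient = 0.

    With thousands of observations the reference t distribution is
    indistinguishable from normal, so the standard normal is used.  The
    -log10 p is computed in log space and is consistent with p far beyond
    floating-point underflow.
    """
    if isinstance(coefficient, str):
        est, se = fit.coef(coefficient)
    else:
        est, se = float(fit.beta[coefficient]), float(fit.se[coefficient])
    if est == 0.0:
        return WaldResult(statistic=0.0, p=1.0, mlog10p=0.0)
    if se == 0.0:
        return WaldResult(statistic=math.copysign(math.inf, est), p=0.0,
                          mlog10p=math.inf)
    z = est / se
    log_p = math.log(2.0) + stats.norm.logsf(abs(z))
    p = min(math.exp(log_p), 1.0)
    mlog10p = max(-log_p / math.log(10.0), 0.0)
    return WaldResult(statistic=z, p=p, mlog10p=mlog10p)


def lrt(full: FitResult, null: FitResult) -> tuple[float, float]:
    """Likelihood-ratio test of a nested null: statistic = 2 * (ll_full -
    ll_null) clipped at zero, referred to chi-square with 1 df (conservative
    on the variance boundary)."""
    stat = max(2.0 * (full.loglik - null.loglik), 0.0)
    p = float(stats.chi2.sf(stat, df=1))
    if stat == 0.0:
        p = 1.0
    return stat, p
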