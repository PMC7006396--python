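"""Restricted-likelihood (adjusted profile likelihood) mixed-model fitting.

The QTL models are Gaussian mixed models

    y = X beta + sum_k u_k + e,   u_k ~ N(0, sigma2_k V_k),  e ~ N(0, sigma2_e I)

where the V_k are a pedigree kinship matrix and/or locus-specific IBD
matrices.  The adjusted profile log-likelihood profiled over the random
effects of a Gaussian hierarchical GLM coincides with the restricted (REML)
log-likelihood, which is what this module maximizes: average-information
(AI) updates with an EM fallback and step halving, variance components
constrained non-negative at a small positive floor.

Covariance matrices may be supplied dense or in low-rank-plus-diagonal form
(V = F F' + d I), which makes the trace terms of the AI algorithm cheap for
the gametic and pedigree structures of a two-generation cross.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class VarComponent:
    """One random-effect covariance structure, sigma2 * (F F' + diag  |  M).

    ``diag`` may be a scalar or a length-n vector; the factor/diag form keeps
    the AI-REML trace terms cheap for low-rank gametic structures.
    """

    name: str
    matrix: np.ndarray | None = None
    factor: np.ndarray | None = None
    diag: float | np.ndarray = 0.0

    def dense(self, n: int) -> np.ndarray:
        if self.matrix is not None:
            return self.matrix
        V = self.factor @ self.factor.T
        d = np.asarray(self.diag)
        if np.any(d != 0):
            V = V + np.diag(np.broadcast_to(d, (n,)).astype(float))
        return V


@dataclass
class VarCompFit:
    """Result of a restricted-likelihood fit."""

    beta: np.ndarray
    beta_names: list[str]
    varcomps: dict[str, float]
    sds: dict[str, float]
    loglik: float
    n: int
    converged: bool
    n_iter: int
    boundary: set[str] = field(default_factory=set)

    def __getitem__(self, name: str) -> float:
        return self.varcomps[name]

    @property
    def h2(self) -> float:
        """Va/(Va+Ve) when the fit has a single genetic component."""
        genetic = [v for k, v in self.varcomps.items() if k != "Ve"]
        if len(genetic) != 1:
            raise ValueError("h2 defined for single-genetic-component fits")
        return genetic[0] / (genetic[0] + self.varcomps["Ve"])


def likelihood_ratio(fit1: VarCompFit, fit0: VarCompFit) -> float:
    """2*(APL1 - APL0) for nested fits on the same individuals, floored at 0."""
    if fit1.n != fit0.n:
        raise ValueError(f"fits use different sample sizes ({fit1.n} vs {fit0.n})")
    return max(0.0, 2.0 * (fit1.loglik - fit0.loglik))


def _check_psd_input(components: list[VarComponent], n: int) -> None:
    for comp in components:
        if comp.matrix is not None:
            w = np.linalg.eigvalsh((comp.matrix + comp.matrix.T) / 2.0)
            if w.min() < -1e-7 * max(1.0, w.max()):
                raise ValueError(
                    f"covariance {comp.name!r} is not positive semidefinite "
                    f"(min eigenvalue {w.min():.3g}); apply PSD repair first"
                )


class _REMLWork:
    """Per-theta REML quantities shared by score/AI/loglik computations."""

    def __init__(self, y, X, Vks, factors, diags, theta):
        n, p = X.shape
        V = theta[-1] * np.eye(n)
        for t, Vk in zip(theta[:-1], Vks):
            V += t * Vk
        cf = linalg.cho_factor(V, lower=True, check_finite=False)
        self.cf = cf
        ViX = linalg.cho_solve(cf, X, check_finite=False)
        Viy = linalg.cho_solve(cf, y, check_finite=False)
        XtViX = X.T @ ViX
        cfx = linalg.cho_factor(XtViX, lower=True, check_finite=False)
        self.Py = Viy - ViX @ linalg.cho_solve(cfx, X.T @ Viy, check_finite=False)
        self.ViX = ViX
        self.cfx = cfx
        self.X = X
        self.n, self.p = n, p
        logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
        logdetX = 2.0 * np.sum(np.log(np.diag(cfx[0])))
        self.loglik = -0.5 * (logdetV + logdetX + float(y @ self.Py)
                              + (n - p) * _LOG2PI)
        self._diagP = None

    def project(self, U: np.ndarray) -> np.ndarray:
        """P @ U for a matrix of columns U."""
        ViU = linalg.cho_solve(self.cf, U, check_finite=False)
        return ViU - self.ViX @ linalg.cho_solve(
            self.cfx, self.X.T @ ViU, check_finite=False)

    @property
    def diagP(self) -> np.ndarray:
        if self._diagP is None:
            L = self.cf[0]
            Linv = linalg.solve_triangular(L, np.eye(self.n), lower=True,
                                           check_finite=False)
            diagVi = np.sum(Linv ** 2, axis=0)
            S = linalg.cho_solve(self.cfx, self.ViX.T, check_finite=False)
            self._diagP = diagVi - np.sum(self.ViX * S.T, axis=1)
        return self._diagP

    @property
    def trP(self) -> float:
        return float(self.diagP.sum())

    def trace_PV(self, k: int, Vks, factors, diags) -> float:
        if factors[k] is not None:
            F = factors[k]
            PF = self.project(F)
            t = float(np.sum(F * PF))
            d = diags[k]
            if np.any(np.asarray(d) != 0):
                t += float(np.sum(np.broadcast_to(d, (self.n,)) * self.diagP))
            return t
        PV = self.project(Vks[k])
        return float(np.trace(PV))


def reml_fit(y, X, components: list[VarComponent], beta_names=None,
             max_iter: int = 100, tol: float = 1e-6,
             verbose: bool = False) -> VarCompFit:
    """Maximize the restricted likelihood over the variance components.

    Average-information updates with step halving; an EM-flavoured
    multiplicative step is used whenever the AI step leaves the parameter
    space or decreases the likelihood.  Components that shrink to the
    non-negativity floor are flagged in ``fit.boundary`` (the floor is
    1e-8 times the phenotypic variance).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design matrix is rank deficient")
    _check_psd_input(components, n)
    Vks = [c.dense(n) for c in components]
    factors = [c.factor for c in components]
    diags = [c.diag for c in components]
    names = [c.name for c in components] + ["Ve"]
    K = len(components)

    vary = float(np.var(y))
    floor = 1e-8 * vary
    theta = np.full(K + 1, vary / (K + 1))
    work = _REMLWork(y, X, Vks, factors, diags, theta)
    ll = work.loglik
    converged = False
    it = 0
    AI = None
    for it in range(1, max_iter + 1):
        Py = work.Py
        # scores and AI matrix
        U = np.empty((n, K + 1))
        for k in range(K):
            if factors[k] is not None:
                F = factors[k]
                U[:, k] = F @ (F.T @ Py)
                d = np.asarray(diags[k])
                if np.any(d != 0):
                    U[:, k] += np.broadcast_to(d, (n,)) * Py
            else:
                U[:, k] = Vks[k] @ Py
        U[:, K] = Py
        yPVPy = Py @ U
        trs = np.array([work.trace_PV(k, Vks, factors, diags) for k in range(K)]
                       + [work.trP])
        score = 0.5 * (yPVPy - trs)
        PU = work.project(U)
        AI = 0.5 * (U.T @ PU)
        AI = (AI + AI.T) / 2.0

        if np.max(np.abs(score)) < tol * max(1.0, n / 2.0) and it > 1:
            converged = True
            break

        pinned = (theta <= floor * 1.01) & (score < 0)
        free = ~pinned
        step = np.zeros(K + 1)
        if free.any():
            Af = AI[np.ix_(free, free)]
            try:
                step[free] = np.linalg.solve(
                    Af + 1e-8 * np.eye(free.sum()) * np.trace(Af), score[free])
            except np.linalg.LinAlgError:
                step[free] = score[free] / np.maximum(np.diag(Af), 1e-12)

        accepted = False
        for _ in range(12):
            cand = np.maximum(theta + step, floor)
            try:
                wk = _REMLWork(y, X, Vks, factors, diags, cand)
            except np.linalg.LinAlgError:
                step *= 0.5
                continue
            if wk.loglik >= ll - 1e-10:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            # EM-flavoured multiplicative fallback (monotone, keeps positivity)
            ratio = np.sqrt(np.maximum(yPVPy, 1e-300)
                            / np.maximum(trs, 1e-300))
            cand = np.maximum(theta * ratio, floor)
            wk = _REMLWork(y, X, Vks, factors, diags, cand)
            if wk.loglik < ll - 1e-8:
                break   # stuck: report non-convergence
        dll = wk.loglik - ll
        theta, work, ll = cand, wk, wk.loglik
        if verbose:
            print(f"iter {it}: ll={ll:.6f} theta={theta}")
        if abs(dll) < tol:
            converged = True
            break

    beta = linalg.cho_solve(work.cfx, work.X.T @ linalg.cho_solve(
        work.cf, y, check_finite=False), check_finite=False)
    sds = {}
    if AI is not None:
        cov = np.linalg.pinv(AI)
        sds = {nm: float(np.sqrt(max(cov[k, k], 0.0)))
               for k, nm in enumerate(names)}
    boundary = {nm for nm, t in zip(names, theta) if t <= floor * 1.01}
    if beta_names is None:
        beta_names = [f"b{j}" for j in range(p)]
    return VarCompFit(beta=np.asarray(beta).ravel(), beta_names=list(beta_names),
                      varcomps=dict(zip(names, map(float, theta))), sds=sds,
                      loglik=float(ll), n=n, converged=converged, n_iter=it,
                      boundary=boundary)


# ---------------------------------------------------------------------------
# Exact two-component REML via eigendecomposition
# ---------------------------------------------------------------------------

def _profile_ll_2comp(logdelta, lam, yt, Xt):
    """REML loglik at ratio delta = sigma2_g/sigma2_e with sigma2_e profiled."""
    delta = np.exp(logdelta)
    n, p = Xt.shape
    w = delta * lam + 1.0
    Xw = Xt / w[:, None]
    XtWX = Xt.T @ Xw
    sign, logdetX = np.linalg.slogdet(XtWX)
    bw = np.linalg.solve(XtWX, Xw.T @ yt)
    r = yt - Xt @ bw
    rss = float(r @ (r / w))
    s2 = rss / (n - p)
    return -0.5 * (np.sum(np.log(w)) + logdetX + (n - p) * (1.0 + np.log(s2) + _LOG2PI))


def reml_2comp(y, X, K: np.ndarray, beta_names=None) -> VarCompFit:
    """Exact REML for y = X beta + g + e with cov(g) = Va*K, cov(e) = Ve*I.

    One eigendecomposition of K reduces the problem to a one-dimensional
    profile over the variance ratio, optimized by bracketed grid search plus
    Brent refinement.  Used for the no-QTL polygenic model (heritability) and
    as the first stage of the fast genome scan.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    lam, Uk = np.linalg.eigh((K + K.T) / 2.0)
    lam = np.clip(lam, 0.0, None)
    yt = Uk.T @ y
    Xt = Uk.T @ X

    grid = np.linspace(-12.0, 12.0, 49)
    vals = np.array([_profile_ll_2comp(g, lam, yt, Xt) for g in grid])
    j = int(np.argmax(vals))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda g: -_profile_ll_2comp(g, lam, yt, Xt),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-7})
    best = res.x if -res.fun >= vals[j] else grid[j]
    ll = _profile_ll_2comp(best, lam, yt, Xt)
    # boundary: compare against delta -> 0
    ll0 = _profile_ll_2comp(-30.0, lam, yt, Xt)
    if ll0 >= ll:
        best, ll = -30.0, ll0
    delta = np.exp(best)
    w = delta * lam + 1.0
    Xw = Xt / w[:, None]
    XtWX = Xt.T @ Xw
    beta = np.linalg.solve(XtWX, Xw.T @ yt)
    r = yt - Xt @ beta
    ve = float(r @ (r / w)) / (n - p)
    va = delta * ve
    if beta_names is None:
        beta_names = [f"b{j}" for j in range(p)]
    boundary = {"Va"} if best <= -29.0 else set()
    return VarCompFit(beta=beta, beta_names=list(beta_names),
                      varcomps={"Va": va, "Ve": ve}, sds={},
                      loglik=float(ll), n=n, converged=True, n_iter=1,
                      boundary=boundary)
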