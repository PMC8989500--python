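"""GRE/SRE decomposition of cross-level recombination rates.

The recombination rate of a cross (i, j) is modelled as
``c_ij = mu + GRE_i + GRE_j + SRE_ij + e``: each parent contributes a
general recombination effect (GRE) and the particular combination a
specific effect (SRE).  In mixed-model form

    c = X b + Z_GRE u_GRE + Z_SRE u_SRE + e,

with u_GRE ~ N(0, A sigma2_a), u_SRE ~ N(0, D sigma2_d), e ~ N(0, I
sigma2_e).  Identity A/D yield the phenotypic estimates (GRE_P/SRE_P);
genomic relationship matrices turn the fit into GBLUP (GRE_G/SRE_G).
Variance components are estimated by average-information REML with an EM
fallback and non-negativity enforced by projection.

Identifiability note: when every cross is phenotyped exactly once and D is
the identity, Z_SRE D Z_SRE' equals I and the SRE variance cannot be
separated from the residual.  The fitter detects this, folds the SRE into
the residual (reported as sigma2_d = 0 with ``confounded=True``).  Supplying
replicated observations per cross — e.g. the seven chromosome-wise rates —
restores identifiability and is what the genome-level decomposition uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CrossDesign, DesignError, RecombkitError, ValidationError

import warnings


class ConvergenceError(RecombkitError):
    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


class NotPSDError(RecombkitError):
    pass


@dataclass
class IncidenceSet:
    """Design matrices linking observations to parents and crosses."""

    parents: list[str]
    pop_ids: list[str]
    Z_gre: np.ndarray  # (n_obs, n_parents), two 1s per row
    Z_sre: np.ndarray  # (n_obs, n_pops)
    obs_pop: list[str]  # pop id per observation row


def build_incidence(design: CrossDesign, obs_pop: list[str] | None = None) -> IncidenceSet:
    """Build Z_GRE and Z_SRE for the given design.

    ``obs_pop`` lists the population of each observation row (default: one
    observation per cross, giving an identity-ordered Z_SRE).  Parents that
    appear in no cross keep an all-zero column with a warning.
    """
    parents = design.parents
    pops = design.pop_ids
    obs_pop = list(obs_pop) if obs_pop is not None else list(pops)
    p_index = {p: k for k, p in enumerate(parents)}
    c_index = {c: k for k, c in enumerate(pops)}
    n = len(obs_pop)
    Z1 = np.zeros((n, len(parents)))
    Z2 = np.zeros((n, len(pops)))
    for row, pop in enumerate(obs_pop):
        cross = design.cross(pop)
        Z1[row, p_index[cross.parent_i]] = 1.0
        Z1[row, p_index[cross.parent_j]] = 1.0
        Z2[row, c_index[pop]] = 1.0
    unused = np.flatnonzero(Z1.sum(axis=0) == 0)
    if unused.size:
        warnings.warn(
            f"parents with no phenotyped cross: {[parents[i] for i in unused]}",
            stacklevel=2,
        )
    return IncidenceSet(parents=parents, pop_ids=pops, Z_gre=Z1, Z_sre=Z2, obs_pop=obs_pop)


@dataclass
class VarianceComponents:
    sigma2_a: float  # GRE (additive) variance
    sigma2_d: float  # SRE (dominance) variance
    sigma2_e: float  # residual
    iterations: int = 0
    gradient_norm: float = float("nan")
    loglik: float = float("nan")
    confounded: bool = False

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.sigma2_a, self.sigma2_d, self.sigma2_e)


@dataclass
class GREFit:
    mu: np.ndarray  # fixed-effect estimates (intercept first)
    u_gre: pd.Series  # per-parent BLUPs
    u_sre: pd.Series  # per-cross BLUPs
    vc: VarianceComponents
    h2: float
    mode: str  # "identity" or "genomic"
    fitted: np.ndarray = field(default=None, repr=False)
    residual: np.ndarray = field(default=None, repr=False)

    @property
    def intercept(self) -> float:
        return float(self.mu[0])


def _check_psd(M: np.ndarray, name: str, tol: float = 1e-8) -> None:
    if not np.allclose(M, M.T, atol=1e-10):
        raise NotPSDError(f"{name} is not symmetric")
    w = np.linalg.eigvalsh(M)
    if w.min() < -tol * max(1.0, w.max()):
        raise NotPSDError(f"{name} has negative eigenvalue {w.min():.3e}")


def _reml_loglik(theta: np.ndarray, y: np.ndarray, X: np.ndarray,
                 Gs: list[np.ndarray]) -> float:
    n, p = X.shape
    V = sum(t * G for t, G in zip(theta, Gs))
    sign, logdetV = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    sign2, logdetX = np.linalg.slogdet(XtViX)
    if sign2 <= 0:
        return -np.inf
    P = Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
    return float(-0.5 * (logdetV + logdetX + y @ P @ y))


def _reml(y: np.ndarray, X: np.ndarray, Gs: list[np.ndarray],
          tol: float = 1e-8, max_iter: int = 200,
          grad_tol: float = 1e-6) -> tuple[np.ndarray, dict]:
    """AI-REML with EM warm-up/fallback for an arbitrary set of covariance
    structures ``Gs`` (the last one is conventionally the residual I).

    Returns the component vector and convergence metadata.  Components are
    kept non-negative by projection; a component pinned at zero with a
    negative score stays at the boundary.
    """
    n, p = X.shape
    k = len(Gs)
    vary = float(np.var(y, ddof=1)) or 1.0
    theta = np.full(k, vary / k)
    floor = 0.0
    # the residual keeps a tiny floor so V stays invertible at the boundary
    resid_floor = 1e-8 * vary
    trace: list[tuple[np.ndarray, float]] = []

    def quantities(th):
        V = sum(t * G for t, G in zip(th, Gs))
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        P = Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
        Py = P @ y
        return P, Py

    def em_step(th, P, Py):
        new = np.empty_like(th)
        for i, G in enumerate(Gs):
            q = n - p if i == k - 1 else G.shape[0]
            GP = G @ P
            yPGPy = Py @ G @ Py
            new[i] = (th[i] ** 2 * yPGPy + th[i] * q - th[i] ** 2 * np.trace(GP)) / q
        return project(new)

    def project(th):
        th = np.maximum(th, floor)
        th[-1] = max(th[-1], resid_floor)
        return th

    ll = _reml_loglik(theta, y, X, Gs)
    it = 0
    grad_norm = np.inf
    stall = 0
    for it in range(1, max_iter + 1):
        P, Py = quantities(theta)
        score = np.array([
            -0.5 * (np.trace(P @ G) - Py @ G @ Py) for G in Gs
        ])
        free = ~((theta <= floor + 1e-14) & (score < 0))
        grad_norm = float(np.linalg.norm(score[free])) if free.any() else 0.0
        if grad_norm < grad_tol:
            break
        if it <= 2:
            cand = em_step(theta, P, Py)
        else:
            PG = [P @ G for G in Gs]
            AI = np.zeros((k, k))
            for i in range(k):
                for j in range(i, k):
                    AI[i, j] = AI[j, i] = 0.5 * (Py @ Gs[i] @ P @ Gs[j] @ Py)
            idx = np.flatnonzero(free)
            cand = theta.copy()
            try:
                delta = np.linalg.solve(AI[np.ix_(idx, idx)], score[idx])
            except np.linalg.LinAlgError:
                delta = None
            accepted = False
            if delta is not None:
                step = 1.0
                for _ in range(12):
                    trial = theta.copy()
                    trial[idx] = theta[idx] + step * delta
                    trial = project(trial)
                    ll_trial = _reml_loglik(trial, y, X, Gs)
                    if ll_trial >= ll - 1e-10:
                        cand, accepted = trial, True
                        break
                    step *= 0.5
            if not accepted:
                cand = em_step(theta, P, Py)
        ll_cand = _reml_loglik(cand, y, X, Gs)
        if not np.isfinite(ll_cand):
            cand = em_step(theta, P, Py)
            ll_cand = _reml_loglik(cand, y, X, Gs)
        rel = np.max(np.abs(cand - theta) / (np.abs(theta) + 1e-10))
        # EM crawls near the boundary: treat a flat likelihood as converged
        stall = stall + 1 if abs(ll_cand - ll) < 1e-7 * max(1.0, abs(ll)) else 0
        theta, ll = cand, ll_cand
        trace.append((theta.copy(), ll))
        if rel < tol or stall >= 3:
            P, Py = quantities(theta)
            score = np.array([-0.5 * (np.trace(P @ G) - Py @ G @ Py) for G in Gs])
            free = ~((theta <= floor + 1e-14) & (score < 0))
            grad_norm = float(np.linalg.norm(score[free])) if free.any() else 0.0
            break
    else:
        # ridge in the likelihood (e.g. nearly collinear covariance
        # structures): finish with a bounded quasi-Newton polish
        from scipy.optimize import minimize

        res = minimize(
            lambda th: -_reml_loglik(project(np.asarray(th)), y, X, Gs),
            theta,
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 2000},
        )
        cand = project(np.asarray(res.x))
        ll_cand = _reml_loglik(cand, y, X, Gs)
        if not np.isfinite(ll_cand) or ll_cand < ll - 1e-6:
            raise ConvergenceError(
                f"REML did not converge in {max_iter} iterations (|grad|={grad_norm:.3g})",
                trace,
            )
        theta, ll = cand, ll_cand
        trace.append((theta.copy(), ll))
        P, Py = quantities(theta)
        score = np.array([-0.5 * (np.trace(P @ G) - Py @ G @ Py) for G in Gs])
        free = ~((theta <= floor + 1e-14) & (score < 0))
        grad_norm = float(np.linalg.norm(score[free])) if free.any() else 0.0
    meta = {"iterations": it, "gradient_norm": grad_norm, "loglik": ll, "trace": trace}
    return theta, meta


def fit_gre_sre(
    c: np.ndarray,
    inc: IncidenceSet,
    A: np.ndarray | None = None,
    D: np.ndarray | None = None,
    X: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    mode: str | None = None,
) -> GREFit:
    """REML fit of the GRE/SRE mixed model and BLUP effect extraction.

    ``A`` (parents x parents) and ``D`` (crosses x crosses) default to
    identity (phenotypic estimates GRE_P/SRE_P); pass genomic matrices for
    GRE_G/SRE_G.  ``X`` defaults to an intercept column; pass e.g.
    chromosome dummies when fitting replicated observations.
    """
    y = np.asarray(c, dtype=float)
    n = y.size
    Z1, Z2 = inc.Z_gre, inc.Z_sre
    if Z1.shape[0] != n:
        raise ValidationError("c length does not match incidence rows")
    identity_mode = A is None and D is None
    A = np.eye(Z1.shape[1]) if A is None else np.asarray(A, dtype=float)
    D = np.eye(Z2.shape[1]) if D is None else np.asarray(D, dtype=float)
    _check_psd(A, "A")
    _check_psd(D, "D")
    X = np.ones((n, 1)) if X is None else np.asarray(X, dtype=float)

    G1 = Z1 @ A @ Z1.T
    G2 = Z2 @ D @ Z2.T
    confounded = np.allclose(G2, np.eye(n), atol=1e-12)
    if confounded:
        theta, meta = _reml(y, X, [G1, np.eye(n)], tol=tol, max_iter=max_iter)
        s2a, s2d, s2e = theta[0], 0.0, theta[1]
    else:
        theta, meta = _reml(y, X, [G1, G2, np.eye(n)], tol=tol, max_iter=max_iter)
        s2a, s2d, s2e = theta

    V = s2a * G1 + s2d * G2 + s2e * np.eye(n)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    b = np.linalg.solve(XtViX, X.T @ Vi @ y)
    resid_fixed = y - X @ b
    u1 = s2a * A @ Z1.T @ Vi @ resid_fixed
    u2 = s2d * D @ Z2.T @ Vi @ resid_fixed
    fitted = X @ b + Z1 @ u1 + Z2 @ u2
    vc = VarianceComponents(
        sigma2_a=float(s2a), sigma2_d=float(s2d), sigma2_e=float(s2e),
        iterations=meta["iterations"], gradient_norm=meta["gradient_norm"],
        loglik=meta["loglik"], confounded=confounded,
    )
    return GREFit(
        mu=b,
        u_gre=pd.Series(u1, index=inc.parents),
        u_sre=pd.Series(u2, index=inc.pop_ids),
        vc=vc,
        h2=heritability(vc),
        mode=mode or ("identity" if identity_mode else "genomic"),
        fitted=fitted,
        residual=y - fitted,
    )


def heritability(vc: VarianceComponents | tuple[float, float, float]) -> float:
    """Broad-sense H2 = (s2_a + s2_d) / (s2_a + s2_d + s2_e)."""
    s2a, s2d, s2e = vc.as_tuple() if isinstance(vc, VarianceComponents) else vc
    if min(s2a, s2d, s2e) < 0:
        raise ValidationError("variance components must be non-negative")
    total = s2a + s2d + s2e
    if total <= 0:
        raise ValidationError("all variance components are zero")
    return float((s2a + s2d) / total)


def gre_sre_variance_ratio(fit: GREFit | tuple[float, float]) -> float:
    """sigma2_GRE / sigma2_SRE; +inf when the SRE component is at zero."""
    if isinstance(fit, GREFit):
        s2a, s2d = fit.vc.sigma2_a, fit.vc.sigma2_d
    else:
        s2a, s2d = fit
    if s2d <= 0:
        warnings.warn("SRE variance at boundary 0; ratio is +inf", stacklevel=2)
        return float("inf")
    return float(s2a / s2d)


def fit_genomewide(
    chrom_rates: pd.DataFrame,
    design: CrossDesign,
    A: np.ndarray | None = None,
    D: np.ndarray | None = None,
    **kwargs,
) -> GREFit:
    """Genome-level GRE/SRE fit using chromosome rates as replicates.

    ``chrom_rates`` is a population x chromosome DataFrame (as produced by
    ``WindowRates.chromosome_means``).  Chromosome enters as a fixed effect;
    with seven replicate observations per cross all three variance
    components are identifiable even with identity A/D.
    """
    pops = [p for p in design.pop_ids if p in chrom_rates.index]
    chroms = list(chrom_rates.columns)
    obs_pop, y, chrom_of = [], [], []
    for pop in pops:
        for ch in chroms:
            v = chrom_rates.loc[pop, ch]
            if np.isnan(v):
                continue
            obs_pop.append(pop)
            y.append(float(v))
            chrom_of.append(ch)
    inc = build_incidence(design, obs_pop=obs_pop)
    X = np.zeros((len(y), len(chroms)))
    for row, ch in enumerate(chrom_of):
        X[row, chroms.index(ch)] = 1.0
    return fit_gre_sre(np.asarray(y), inc, A=A, D=D, X=X, **kwargs)
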