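"""Genomic relationship matrices, GBLUP/RR-BLUP prediction and the
cross-validation designs used to benchmark recombination-rate prediction.

The additive GRM follows VanRaden's first method (markers centred by twice
the training allele frequency, scaled by 2*sum p(1-p)).  The cross-level
dominance matrix relates crosses through pairwise products of parental
relationships, D[(i,j),(k,l)] = (A_ik A_jl + A_il A_jk)/4, rescaled to unit
mean diagonal.  GBLUP and RR-BLUP are dual formulations of the same ridge
problem and their predictions must agree to numerical precision — a
property the test suite checks rather than assumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CrossDesign, DesignError, ValidationError
from .remodel import GREFit, IncidenceSet, _reml, build_incidence, fit_gre_sre


@dataclass
class GRM:
    ids: list[str]
    values: np.ndarray
    kind: str  # "additive" | "dominance"
    n_markers: int

    def loc(self, rows: list[str], cols: list[str] | None = None) -> np.ndarray:
        cols = rows if cols is None else cols
        ri = [self.ids.index(r) for r in rows]
        ci = [self.ids.index(c) for c in cols]
        return self.values[np.ix_(ri, ci)]


def additive_grm(
    calls: np.ndarray,
    ids: list[str],
    freqs: np.ndarray | None = None,
    ridge: float = 1e-8,
) -> GRM:
    """VanRaden method-1 additive GRM from dose-coded genotypes.

    ``calls`` is (n_ind, n_markers) with doses 0/1/2 (missing -1 doses are
    mean-imputed per marker).  ``freqs`` lets a training set's allele
    frequencies be reused when relating new individuals to it.
    """
    M = np.asarray(calls, dtype=float)
    if M.shape[0] < 2:
        raise ValidationError("GRM needs >= 2 individuals")
    miss = M < 0
    if miss.any():
        col_mean = np.where(
            miss.all(axis=0), 1.0,
            np.nanmean(np.where(miss, np.nan, M), axis=0),
        )
        M = np.where(miss, col_mean[None, :], M)
    p = M.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, dtype=float)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValidationError("all markers monomorphic: zero GRM denominator")
    W = M - 2.0 * p[None, :]
    G = W @ W.T / denom
    G[np.diag_indices_from(G)] += ridge
    return GRM(ids=list(ids), values=G, kind="additive", n_markers=M.shape[1])


def cross_relationship(
    new_calls: np.ndarray,
    train_calls: np.ndarray,
    freqs: np.ndarray | None = None,
) -> np.ndarray:
    """Relationships of new individuals to a training set (VanRaden scale).

    Frequencies default to the training set's, per the training-centred
    convention of :func:`additive_grm`.
    """
    T = np.asarray(train_calls, dtype=float)
    N = np.asarray(new_calls, dtype=float)
    p = T.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, dtype=float)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValidationError("all markers monomorphic: zero GRM denominator")
    Wn = np.where(N < 0, 0.0, N - 2.0 * p[None, :])
    Wt = T - 2.0 * p[None, :]
    return Wn @ Wt.T / denom


def dominance_grm(design: CrossDesign, A: GRM) -> GRM:
    """Cross-level dominance relationships from the parental additive GRM.

    D[(i,j),(k,l)] = (A_ik A_jl + A_il A_jk) / 4, rescaled so the mean
    diagonal equals 1.  With A = I over unrelated parents this reproduces
    the identity ordering over crosses.
    """
    for c in design.crosses:
        for p in (c.parent_i, c.parent_j):
            if p not in A.ids:
                raise DesignError(f"cross {c.pop_id} parent {p} missing from GRM")
    idx = {p: A.ids.index(p) for p in design.parents}
    n = len(design.crosses)
    D = np.empty((n, n))
    Av = A.values
    for a, ca in enumerate(design.crosses):
        i, j = idx[ca.parent_i], idx[ca.parent_j]
        for b in range(a, n):
            cb = design.crosses[b]
            k, l = idx[cb.parent_i], idx[cb.parent_j]
            val = (Av[i, k] * Av[j, l] + Av[i, l] * Av[j, k]) / 4.0
            D[a, b] = D[b, a] = val
    mean_diag = float(np.mean(np.diag(D)))
    if mean_diag > 0:
        D = D / mean_diag
    return GRM(ids=design.pop_ids, values=D, kind="dominance", n_markers=A.n_markers)


def fit_gblup(
    c: np.ndarray,
    inc: IncidenceSet,
    A_genomic: GRM,
    D_genomic: GRM,
    **kwargs,
) -> GREFit:
    """GRE/SRE fit with genomic relationship matrices (GRE_G/SRE_G)."""
    A = A_genomic.loc(inc.parents)
    D = D_genomic.loc(inc.pop_ids)
    return fit_gre_sre(c, inc, A=A, D=D, mode="genomic", **kwargs)


@dataclass
class MarkerEffects:
    intercept: float
    effects: np.ndarray  # per-marker additive effect
    ridge: float

    def predict(self, calls: np.ndarray, freqs: np.ndarray) -> np.ndarray:
        W = np.where(calls < 0, 0.0, np.asarray(calls, dtype=float) - 2.0 * freqs[None, :])
        return self.intercept + W @ self.effects


def rrblup_marker_effects(
    targets: np.ndarray,
    calls: np.ndarray,
    ridge: float | None = None,
    freqs: np.ndarray | None = None,
) -> MarkerEffects:
    """Ridge-regression BLUP of marker effects for an inbred-level target.

    Solves the ridge system (W'W + lambda I) a = W'(y - mu) with markers
    centred as in the GRM.  When ``ridge`` is None the variance components
    are estimated by REML on the equivalent GBLUP model and lambda =
    sigma2_e / sigma2_marker with sigma2_marker = sigma2_g / (2 sum p(1-p)).
    """
    y = np.asarray(targets, dtype=float)
    M = np.asarray(calls, dtype=float)
    p = M.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, dtype=float)
    W = M - 2.0 * p[None, :]
    k = 2.0 * np.sum(p * (1.0 - p))
    if ridge is None:
        G = W @ W.T / k
        G[np.diag_indices_from(G)] += 1e-8
        theta, _ = _reml(y, np.ones((y.size, 1)), [G, np.eye(y.size)])
        s2g, s2e = theta
        if s2g <= 0:
            return MarkerEffects(intercept=float(y.mean()),
                                 effects=np.zeros(M.shape[1]), ridge=np.inf)
        ridge = s2e / (s2g / k)
    n, m = W.shape
    # solve in the (smaller) individual dimension: a = W'(WW' + lambda I)^-1 (y-mu)
    K = W @ W.T + ridge * np.eye(n)
    ones = np.ones(n)
    Ki = np.linalg.inv(K)
    mu = float((ones @ Ki @ y) / (ones @ Ki @ ones))
    alpha = Ki @ (y - mu)
    return MarkerEffects(intercept=mu, effects=W.T @ alpha, ridge=float(ridge))


def predict_gre_new(
    fit: GREFit, A_cross: np.ndarray, A_train: np.ndarray,
    train_parents: list[str] | None = None,
) -> np.ndarray:
    """Extend GRE BLUPs to unphenotyped individuals.

    ``A_cross`` holds relationships of the new individuals (rows) to the
    training parents (columns, in ``fit.u_gre`` order unless
    ``train_parents`` reorders them); u_new = A_cross A_train^+ u_train.
    """
    parents = train_parents or list(fit.u_gre.index)
    if A_cross.shape[1] != len(parents):
        raise ValidationError("A_cross columns do not match training parents")
    u = fit.u_gre.loc[parents].to_numpy()
    return predict_gre_from_matrix(u, A_train, A_cross)


def predict_gre_from_matrix(
    u_train: np.ndarray, A_train: np.ndarray, A_cross: np.ndarray
) -> np.ndarray:
    """u_new = A_cross A_train^+ u_train (standard BLUP extension)."""
    return np.asarray(A_cross, dtype=float) @ np.linalg.pinv(np.asarray(A_train)) @ np.asarray(u_train)


def n_hybrid_combinations(n_lines: int) -> int:
    """Number of unordered pairs with self-pairs: n(n+1)/2."""
    return n_lines * (n_lines + 1) // 2


def predict_cross_gebv(
    gre_values: pd.Series,
    mu: float,
    pairs: list[tuple[str, str]] | None = None,
    sre_lookup=None,
) -> pd.DataFrame:
    """GEBVs of (possible) crosses: mu + GRE_G(i) + GRE_G(j) (+ SRE term).

    With ``pairs=None`` all unordered combinations including self-pairs are
    enumerated.  ``sre_lookup`` may map an (i, j) pair to a predicted SRE.
    """
    ids = list(gre_values.index)
    if pairs is None:
        n = len(ids)
        iu, ju = np.triu_indices(n)
        pairs = [(ids[a], ids[b]) for a, b in zip(iu, ju)]
    g = gre_values
    recs = []
    for i, j in pairs:
        v = mu + float(g[i]) + float(g[j])
        if sre_lookup is not None:
            v += float(sre_lookup(i, j))
        recs.append((i, j, v))
    return pd.DataFrame(recs, columns=["parent_i", "parent_j", "gebv"])


def prediction_ability(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Pearson correlation between observed and predicted values."""
    x = np.asarray(observed, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("prediction ability needs >= 3 aligned pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance in observed or predicted values", stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(x, y)[0])


def zou_correlation_diff(
    r1: float, r2: float, n1: int, n2: int,
    overlap_r: float | None = None,
    conf: float = 0.95,
) -> tuple[float, float]:
    """Zou's modified-asymptotic confidence interval for r1 - r2.

    With ``overlap_r=None`` the two correlations come from independent
    samples; otherwise they are overlapping-dependent correlations sharing
    one variable, with ``overlap_r`` the correlation between the two
    non-shared variables (both computed on the same n = n1 sample).  The
    difference is "significant" when the interval excludes 0.
    """
    for r in (r1, r2):
        if not -1.0 < r < 1.0:
            raise ValidationError("correlations must be in (-1, 1)")
    if min(n1, n2) < 4:
        raise ValidationError("need n >= 4")
    z = stats.norm.ppf(0.5 + conf / 2.0)

    def fisher_ci(r, n):
        zr = np.arctanh(r)
        half = z / np.sqrt(n - 3)
        return np.tanh(zr - half), np.tanh(zr + half)

    l1, u1 = fisher_ci(r1, n1)
    l2, u2 = fisher_ci(r2, n2)
    if overlap_r is None:
        corr = 0.0
    else:
        rj = overlap_r
        num = (rj - r1 * r2 / 2.0) * (1.0 - r1**2 - r2**2 - rj**2) + rj**3
        den = (1.0 - r1**2) * (1.0 - r2**2)
        corr = num / den
    d = r1 - r2
    lo = d - np.sqrt((r1 - l1) ** 2 + (u2 - r2) ** 2 - 2 * corr * (r1 - l1) * (u2 - r2))
    hi = d + np.sqrt((u1 - r1) ** 2 + (r2 - l2) ** 2 - 2 * corr * (u1 - r1) * (r2 - l2))
    return float(lo), float(hi)


def thin_markers(panel: pd.DataFrame, spacing_mbp: float, rng) -> np.ndarray:
    """One marker sampled uniformly per non-empty spacing bin.

    Returns indices into ``panel``; empty bins are skipped.
    """
    if spacing_mbp <= 0:
        raise ValidationError("spacing must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    spacing = int(spacing_mbp * 1e6)
    chosen = []
    chroms = panel["chrom"].to_numpy()
    pos = panel["pos"].to_numpy()
    for chrom in dict.fromkeys(chroms):
        cidx = np.flatnonzero(chroms == chrom)
        bins = pos[cidx] // spacing
        for b in np.unique(bins):
            members = cidx[bins == b]
            chosen.append(int(rng.choice(members)))
    return np.sort(np.asarray(chosen, dtype=int))


@dataclass
class CVResult:
    scenario: str
    runs: pd.DataFrame  # columns: repeat, fold/run, r_pg, r_gre, n_vs
    seed: int

    @property
    def median_r_pg(self) -> float:
        return float(self.runs["r_pg"].median())

    @property
    def median_r_gre(self) -> float:
        return float(self.runs["r_gre"].median())


def _gblup_run(
    rates: pd.Series,
    design: CrossDesign,
    A: GRM,
    D: GRM,
    ts_pops: list[str],
    vs_pops: list[str],
    gre_p: pd.Series,
    include_sre: bool = False,
) -> tuple[float, float]:
    """One training/validation split: fit on TS, score on VS."""
    with warnings.catch_warnings():
        # leaving parents out of the TS is the point of the CV scheme, so the
        # unused-parent warning is expected here
        warnings.simplefilter("ignore")
        inc = build_incidence(design, obs_pop=ts_pops)
        fit = fit_gblup(rates.loc[ts_pops].to_numpy(), inc, A, D)
    gebv = []
    for pop in vs_pops:
        cr = design.cross(pop)
        v = fit.intercept + float(fit.u_gre[cr.parent_i]) + float(fit.u_gre[cr.parent_j])
        if include_sre:
            d_cross = D.loc([pop], list(dict.fromkeys(ts_pops)))
            d_train = D.loc(list(dict.fromkeys(ts_pops)))
            u_sre = fit.u_sre.loc[list(dict.fromkeys(ts_pops))].to_numpy()
            v += float(predict_gre_from_matrix(u_sre, d_train, d_cross))
        gebv.append(v)
    r_pg = prediction_ability(rates.loc[vs_pops].to_numpy(), np.asarray(gebv))
    vs_parents = sorted({p for pop in vs_pops for p in
                         (design.cross(pop).parent_i, design.cross(pop).parent_j)})
    r_gre = prediction_ability(
        gre_p.loc[vs_parents].to_numpy(), fit.u_gre.loc[vs_parents].to_numpy()
    )
    return r_pg, r_gre


def cv_fivefold(
    rates: pd.Series,
    design: CrossDesign,
    A: GRM,
    D: GRM,
    gre_p: pd.Series,
    n_subsets_in_ts: int = 4,
    repeats: int = 100,
    seed: int = 0,
    include_sre: bool = False,
) -> CVResult:
    """Fivefold CV over populations with configurable training-set size.

    Each repeat partitions the populations into five disjoint near-equal
    subsets; each subset serves once as validation set while
    ``n_subsets_in_ts`` of the remaining four (subsampled when < 4) form
    the training set.  Reports per-run Pearson correlations and medians.
    """
    if n_subsets_in_ts not in (1, 2, 3, 4):
        raise ValidationError("n_subsets_in_ts must be in 1..4")
    pops = [p for p in design.pop_ids if p in rates.index]
    if len(pops) < 5:
        raise ValidationError("fivefold CV needs >= 5 populations")
    rng = np.random.default_rng(seed)
    recs = []
    for rep in range(repeats):
        perm = list(rng.permutation(pops))
        folds = [perm[i::5] for i in range(5)]
        for f, vs_pops in enumerate(folds):
            others = [k for k in range(5) if k != f]
            pick = list(rng.choice(others, size=n_subsets_in_ts, replace=False))
            ts_pops = [p for k in pick for p in folds[k]]
            r_pg, r_gre = _gblup_run(rates, design, A, D, ts_pops, vs_pops,
                                     gre_p, include_sre)
            recs.append((rep, f, r_pg, r_gre, len(vs_pops), len(ts_pops)))
    runs = pd.DataFrame(recs, columns=["repeat", "fold", "r_pg", "r_gre", "n_vs", "n_ts"])
    return CVResult(scenario=f"fivefold_ts{n_subsets_in_ts}", runs=runs, seed=seed)


def cv_leave_parents_out(
    rates: pd.Series,
    design: CrossDesign,
    A: GRM,
    D: GRM,
    gre_p: pd.Series,
    n_par: int = 3,
    repeats: int = 1000,
    seed: int = 0,
    include_sre: bool = False,
) -> CVResult:
    """Leave-parents-out CV: predict populations of unseen parents.

    Each run removes every population involving ``n_par`` randomly chosen
    parents; those form the validation set and the remainder the training
    set, so VS and TS share no parents.
    """
    parents = design.parents
    if n_par >= len(parents):
        raise ValidationError("removing all parents leaves an empty training set")
    pops = [p for p in design.pop_ids if p in rates.index]
    rng = np.random.default_rng(seed)
    recs = []
    for rep in range(repeats):
        sel = set(rng.choice(parents, size=n_par, replace=False))
        vs_pops = [p for p in pops
                   if design.cross(p).parent_i in sel or design.cross(p).parent_j in sel]
        ts_pops = [p for p in pops if p not in vs_pops]
        if len(vs_pops) < 3 or len(ts_pops) == 0:
            continue
        ts_parents = {q for p in ts_pops
                      for q in (design.cross(p).parent_i, design.cross(p).parent_j)}
        assert not (sel & ts_parents), "VS parents leaked into TS"
        r_pg, r_gre = _gblup_run(rates, design, A, D, ts_pops, vs_pops, gre_p, include_sre)
        recs.append((rep, 0, r_pg, r_gre, len(vs_pops), len(ts_pops)))
    runs = pd.DataFrame(recs, columns=["repeat", "fold", "r_pg", "r_gre", "n_vs", "n_ts"])
    return CVResult(scenario=f"leave{n_par}parents", runs=runs, seed=seed)
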