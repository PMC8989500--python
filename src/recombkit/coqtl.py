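"""Crossover counting per RIL and a multi-population QTL scan of CO counts.

Counting scans each chromosome's markers in physical order and counts
transitions between opposite homozygous parental-origin states; missing and
heterozygous calls are skipped (a residual heterozygote at S4 is ambiguous
between 0 and 1 extra crossover, so the minimal-transition convention is
used).  Outlier RILs — counts more than 2 above the end of the first
contiguous occupied run of the population's count histogram — are excluded.
The scan fits, at each position, a cross-specific marker-effect model
(CO ~ population + population:marker-dose) and compares the maximal F
statistic against a permutation null built by permuting phenotypes within
populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeTable, ValidationError
from .simkit import transition_counts_matrix


def count_crossovers(geno: GenotypeTable) -> pd.DataFrame:
    """Per-RIL, per-chromosome crossover counts plus the genome-wide sum.

    Requires origin-coded genotypes.  Chromosomes with fewer than two
    informative (homozygous, non-missing) markers for a RIL give a NaN
    count; the genome-wide sum ignores NaN chromosomes.
    """
    if geno.coding != "origin":
        raise ValidationError("crossover counting requires origin-coded genotypes")
    chroms = list(dict.fromkeys(geno.panel["chrom"]))
    chrom_arr = geno.panel["chrom"].to_numpy()
    out = pd.DataFrame(index=geno.individuals)
    out.insert(0, "pop", geno.populations)
    for chrom in chroms:
        cidx = np.flatnonzero(chrom_arr == chrom)
        calls = geno.calls[:, cidx]
        counts = transition_counts_matrix(calls).astype(float)
        informative = ((calls == 0) | (calls == 2)).sum(axis=1)
        counts[informative < 2] = np.nan
        out[chrom] = counts
    out["genome"] = out[chroms].sum(axis=1, skipna=True)
    return out


def filter_co_outliers(counts: np.ndarray, margin: int = 2) -> np.ndarray:
    """Flag RILs whose CO count exceeds the population's histogram run.

    Builds a unit-width integer histogram from the minimum count, finds the
    last bin K of the first contiguous run of occupied bins, and flags
    counts > K + ``margin``.  Needs at least 5 RILs.
    """
    c = np.asarray(counts, dtype=float)
    ok = ~np.isnan(c)
    if ok.sum() < 5:
        raise ValidationError("outlier rule needs >= 5 RILs with counts")
    vals = c[ok].astype(int)
    lo = vals.min()
    occupied = np.zeros(vals.max() - lo + 1, dtype=bool)
    occupied[vals - lo] = True
    k = 0
    while k + 1 < occupied.size and occupied[k + 1]:
        k += 1
    threshold = lo + k + margin
    flags = np.zeros(c.shape, dtype=bool)
    flags[ok] = vals > threshold
    return flags


def flag_outliers_by_population(counts: pd.DataFrame, phenotype: str = "genome",
                                margin: int = 2) -> pd.Series:
    """Apply the outlier rule within each population."""
    flags = pd.Series(False, index=counts.index)
    for pop, sub in counts.groupby("pop"):
        flags.loc[sub.index] = filter_co_outliers(sub[phenotype].to_numpy(), margin)
    return flags


@dataclass
class QTLScanResult:
    positions: pd.DataFrame  # chrom, pos, stat (-log10 p), df1
    threshold: float  # 0.95 quantile of permutation-max null
    intervals: pd.DataFrame  # chrom, start, end, peak_pos, peak_stat
    per_population_effects: pd.DataFrame | None = None

    @property
    def significant(self) -> pd.DataFrame:
        return self.positions[self.positions["stat"] > self.threshold]


def _scan_stats(y: np.ndarray, X: np.ndarray, pop_codes: np.ndarray,
                n_pops: int) -> np.ndarray:
    """-log10 p of the cross-specific marker F test at every position.

    ``X`` is (n_ind, n_pos) with origin doses centred within population and
    NaN for missing; ``y`` is the phenotype.  After within-population
    centring of y, adding population-specific slopes is a set of separate
    within-population simple regressions, so the sum-of-squares reduction
    has the closed form sum_p Sxy^2 / Sxx.
    """
    n = y.size
    yc = y.copy()
    for p in range(n_pops):
        sel = pop_codes == p
        yc[sel] -= yc[sel].mean()
    sst = float(yc @ yc)
    ok = ~np.isnan(X)
    Xz = np.where(ok, X, 0.0)
    stats_out = np.zeros(X.shape[1])
    order = np.argsort(pop_codes, kind="stable")
    bounds = np.searchsorted(pop_codes[order], np.arange(n_pops))
    Xs, ys, oks = Xz[order], yc[order], ok[order]
    yo = ys[:, None] * oks
    sxy = np.add.reduceat(Xs * yo, bounds, axis=0)
    sxx = np.add.reduceat(Xs * Xs, bounds, axis=0)
    sx = np.add.reduceat(Xs, bounds, axis=0)
    sy = np.add.reduceat(yo, bounds, axis=0)
    npm = np.add.reduceat(oks.astype(float), bounds, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        # centre within (population, position) on the non-missing subset
        sxy_c = sxy - sx * sy / np.maximum(npm, 1)
        sxx_c = sxx - sx * sx / np.maximum(npm, 1)
        contrib = np.where(sxx_c > 1e-12, sxy_c**2 / sxx_c, 0.0)
    delta = contrib.sum(axis=0)
    df1 = (sxx_c > 1e-12).sum(axis=0)
    df2 = n - n_pops - df1
    rss = np.maximum(sst - delta, 1e-12)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (delta / np.maximum(df1, 1)) / (rss / np.maximum(df2, 1))
        pvals = stats.f.sf(F, np.maximum(df1, 1), np.maximum(df2, 1))
    out = -np.log10(np.maximum(pvals, 1e-300))
    out[df1 == 0] = np.nan
    return out


def multipop_qtl_scan(
    counts: pd.DataFrame,
    geno: GenotypeTable,
    phenotype: str = "genome",
    positions_spacing_mbp: float = 10.0,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    exclude_outliers: bool = True,
) -> QTLScanResult:
    """Cross-specific multi-population QTL scan of crossover counts.

    The scan grid takes one marker per ``positions_spacing_mbp`` Mbp.  The
    genome-wide threshold is the (1 - alpha) quantile of the maximal
    statistic over ``n_perm`` within-population phenotype permutations;
    positions above it merge into QTL intervals.
    """
    if geno.coding != "origin":
        raise ValidationError("QTL scan requires origin-coded genotypes")
    from .gpred import thin_markers

    rng = np.random.default_rng(seed)
    keep = counts[phenotype].notna()
    if exclude_outliers:
        keep &= ~flag_outliers_by_population(counts, phenotype)
    kept = set(counts.index[keep])
    pos_of = {r: i for i, r in enumerate(geno.individuals)}
    ril_ids = [r for r in geno.individuals if r in kept]
    ridx = np.array([pos_of[r] for r in ril_ids])
    y = counts.loc[ril_ids, phenotype].to_numpy(dtype=float)
    pops = counts.loc[ril_ids, "pop"].to_numpy()
    pop_names = list(dict.fromkeys(pops))
    pop_codes = np.array([pop_names.index(p) for p in pops])

    midx = thin_markers(geno.panel, positions_spacing_mbp, rng)
    X = geno.calls[np.ix_(ridx, midx)].astype(float)
    X[X < 0] = np.nan
    X -= 1.0  # origin dose -1/0/+1

    obs = _scan_stats(y, X, pop_codes, len(pop_names))

    # permutation null: permute phenotype within populations
    maxima = np.empty(n_perm)
    for b in range(n_perm):
        yp = y.copy()
        for p in range(len(pop_names)):
            sel = np.flatnonzero(pop_codes == p)
            yp[sel] = yp[rng.permutation(sel)]
        maxima[b] = np.nanmax(_scan_stats(yp, X, pop_codes, len(pop_names)))
    threshold = float(np.quantile(maxima, 1.0 - alpha))

    pos_tab = pd.DataFrame({
        "chrom": geno.panel["chrom"].to_numpy()[midx],
        "pos": geno.panel["pos"].to_numpy()[midx],
        "stat": obs,
    })
    sig = pos_tab["stat"] > threshold
    intervals = []
    run = None
    for i in range(len(pos_tab) + 1):
        inside = i < len(pos_tab) and bool(sig.iat[i]) and \
            (run is None or pos_tab["chrom"].iat[i] == pos_tab["chrom"].iat[run])
        if inside and run is None:
            run = i
        elif run is not None and not inside:
            seg = pos_tab.iloc[run:i]
            peak = seg["stat"].idxmax()
            intervals.append((
                seg["chrom"].iat[0], int(seg["pos"].min()), int(seg["pos"].max()),
                int(pos_tab["pos"].loc[peak]), float(seg["stat"].max()),
            ))
            run = i if (i < len(pos_tab) and bool(sig.iat[i])) else None
    intervals_df = pd.DataFrame(
        intervals, columns=["chrom", "start", "end", "peak_pos", "peak_stat"]
    )

    effects = None
    if not intervals_df.empty:
        rows = []
        for _, iv in intervals_df.iterrows():
            col = np.flatnonzero(
                (pos_tab["chrom"] == iv["chrom"]) & (pos_tab["pos"] == iv["peak_pos"])
            )[0]
            x = X[:, col]
            for p, name in enumerate(pop_names):
                sel = (pop_codes == p) & ~np.isnan(x)
                if sel.sum() < 3 or np.nanstd(x[sel]) == 0:
                    slope = np.nan
                else:
                    slope = float(np.polyfit(x[sel], y[sel], 1)[0])
                rows.append((iv["chrom"], iv["peak_pos"], name, slope))
        effects = pd.DataFrame(rows, columns=["chrom", "peak_pos", "pop", "slope"])

    return QTLScanResult(
        positions=pos_tab, threshold=threshold, intervals=intervals_df,
        per_population_effects=effects,
    )
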