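"""Marey maps, monotone spline fits and windowed recombination rates.

A Marey map pairs each marker bin's physical position (bp) with its genetic
position (cM); its local slope is the recombination rate c in cM/Mbp.  The
pipeline filters non-monotone points (2 cM diversions tolerated), fits a
cubic smoothing spline, escalates the smoothing until the fitted curve is
non-decreasing, and reads off window rates as mean slopes on a 10 Mbp grid.
Chromosome rates are unweighted means of window rates and the genome-wide
rate is the unweighted mean of the chromosome means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator, UnivariateSpline

from .containers import Chromosome, RecombkitError, ValidationError, WindowRates
from .qcmap import LinkageMap

WINDOW_BP = 10_000_000
_DERIV_EPS = 1e-6


class SplineInfeasibleError(RecombkitError):
    pass


@dataclass
class MareyMap:
    """Monotonicity-filtered (bp, cM) points per chromosome."""

    points: dict[str, pd.DataFrame]  # chrom -> DataFrame(bp, cm)
    removed: dict[str, list[int]]  # chrom -> indices of dropped input points


def assemble_marey(linkmap: LinkageMap, tolerance_cm: float = 2.0) -> MareyMap:
    """Filter bin coordinates to a near-monotone Marey map.

    A point is removed when its cM value falls more than ``tolerance_cm``
    below the running maximum of the retained points; diversions within the
    tolerance are kept unmodified.
    """
    points: dict[str, pd.DataFrame] = {}
    removed: dict[str, list[int]] = {}
    for chrom, df in linkmap.bins.items():
        bp = df["anchor_bp"].to_numpy(dtype=float)
        cm = df["cm"].to_numpy(dtype=float)
        keep, drop = _running_max_filter(cm, tolerance_cm)
        if keep.size < 4:
            raise SplineInfeasibleError(
                f"{chrom}: only {keep.size} Marey points retained; spline needs >= 4"
            )
        points[chrom] = pd.DataFrame({"bp": bp[keep], "cm": cm[keep]})
        removed[chrom] = drop.tolist()
    return MareyMap(points=points, removed=removed)


def _running_max_filter(cm: np.ndarray, tol: float) -> tuple[np.ndarray, np.ndarray]:
    keep = []
    run_max = -np.inf
    for i, v in enumerate(cm):
        if run_max - v > tol:
            continue
        keep.append(i)
        run_max = max(run_max, v)
    keep_arr = np.asarray(keep, dtype=int)
    drop_arr = np.setdiff1d(np.arange(cm.size), keep_arr)
    return keep_arr, drop_arr


@dataclass
class SplineFit:
    """A monotone cubic fit of genetic (cM) on physical (Mbp) position."""

    chrom: str
    x_mbp: np.ndarray  # input points, Mbp
    y_cm: np.ndarray
    _eval: object  # callable spline
    smoothing: float
    escalations: int
    fallback: bool  # True when the PAVA+PCHIP monotone fallback was used

    @property
    def support(self) -> tuple[float, float]:
        return float(self.x_mbp[0]), float(self.x_mbp[-1])

    def predict(self, bp: np.ndarray | float) -> np.ndarray:
        """Fitted cM at physical position(s) in bp, clamped to the support."""
        x = np.clip(np.asarray(bp, dtype=float) / 1e6, *self.support)
        return np.asarray(self._eval(x), dtype=float)

    def derivative(self, bp: np.ndarray | float) -> np.ndarray:
        """Fitted slope in cM/Mbp, clipped at 0, clamped to the support."""
        x = np.clip(np.asarray(bp, dtype=float) / 1e6, *self.support)
        d = np.asarray(self._eval(x, 1), dtype=float)
        return np.maximum(d, 0.0)

    def total_span_cm(self) -> float:
        lo, hi = self.support
        return float(self._call(hi) - self._call(lo))

    def _call(self, x_mbp: float) -> float:
        return float(np.asarray(self._eval(x_mbp)))


def _pava_increasing(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators: least-squares non-decreasing fit."""
    y = np.asarray(y, dtype=float)
    level = y.copy()
    weight = np.ones_like(y)
    j = 0
    idx = np.zeros(y.size, dtype=int)
    for i in range(1, y.size):
        j += 1
        level[j], weight[j] = y[i], 1.0
        while j > 0 and level[j - 1] > level[j]:
            tot = weight[j - 1] + weight[j]
            level[j - 1] = (weight[j - 1] * level[j - 1] + weight[j] * level[j]) / tot
            weight[j - 1] = tot
            j -= 1
    out = np.empty_like(y)
    pos = 0
    for k in range(j + 1):
        n = int(weight[k])
        out[pos : pos + n] = level[k]
        pos += n
    return out


def fit_marey_spline(
    marey: MareyMap | pd.DataFrame,
    chrom: str | None = None,
    max_escalations: int = 25,
) -> SplineFit | dict[str, SplineFit]:
    """Fit monotone cubic smoothing splines to Marey coordinates.

    The initial smoothing factor comes from a second-difference noise
    estimate; whenever the fitted derivative dips below -1e-6 cM/Mbp the
    factor is escalated (x4).  If no smoothing level yields a monotone
    curve, a guaranteed-monotone fallback (isotonic regression followed by a
    PCHIP interpolant) is used and flagged on the result.
    """
    if isinstance(marey, MareyMap):
        return {c: fit_marey_spline(df, chrom=c, max_escalations=max_escalations)
                for c, df in marey.points.items()}
    df = marey
    x = df["bp"].to_numpy(dtype=float) / 1e6
    y = df["cm"].to_numpy(dtype=float)
    if x.size < 4:
        raise SplineInfeasibleError(f"{chrom}: need >= 4 points, got {x.size}")
    order = np.argsort(x)
    x, y = x[order], y[order]
    if np.any(np.diff(x) <= 0):
        keep = np.concatenate([[True], np.diff(x) > 0])
        x, y = x[keep], y[keep]

    d2 = np.diff(y, 2)
    sigma2 = float(np.sum(d2**2) / (6.0 * max(d2.size, 1)))
    s = x.size * sigma2
    grid = np.linspace(x[0], x[-1], max(4 * x.size, 256))
    for esc in range(max_escalations + 1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spl = UnivariateSpline(x, y, k=3, s=s, ext=3)
        if np.min(spl(grid, 1)) >= -_DERIV_EPS:
            return SplineFit(chrom=chrom or "", x_mbp=x, y_cm=y, _eval=spl,
                             smoothing=s, escalations=esc, fallback=False)
        s = max(s, 1e-8) * 4.0
    iso = _pava_increasing(y)
    # PCHIP needs strictly increasing y steps to stay strictly monotone;
    # plateaus are fine (derivative 0 there).
    pch = PchipInterpolator(x, iso, extrapolate=False)

    class _Wrap:
        def __call__(self, xx, nu=0):
            xx = np.clip(xx, x[0], x[-1])
            return pch(xx) if nu == 0 else pch.derivative()(xx)

        def derivative(self):
            return pch.derivative()

    return SplineFit(chrom=chrom or "", x_mbp=x, y_cm=iso, _eval=_Wrap(),
                     smoothing=float("inf"), escalations=max_escalations, fallback=True)


def window_grid(chrom: Chromosome | int, window_bp: int = WINDOW_BP) -> pd.DataFrame:
    """Half-open 0-based windows [k*w, (k+1)*w) covering one chromosome."""
    length = chrom.length_bp if isinstance(chrom, Chromosome) else int(chrom)
    if length <= 0:
        raise ValidationError("chromosome length must be positive")
    starts = np.arange(0, length, window_bp, dtype=np.int64)
    ends = np.minimum(starts + window_bp, length)
    return pd.DataFrame({"start": starts, "end": ends, "width_bp": ends - starts})


def window_recombination_rates(
    spline: SplineFit,
    chrom_length_bp: int,
    window_bp: int = WINDOW_BP,
    n_edge_snps: int = 5,
    method: str = "mean_slope",
) -> pd.DataFrame:
    """Per-window recombination rates (cM/Mbp) from a fitted Marey spline.

    The default ``method='mean_slope'`` uses the cM difference across the
    window divided by its width (evaluation clamped to the spline support),
    which makes rate x width exactly additive to the chromosome's cM span;
    ``'midpoint'`` evaluates the derivative at the window centre instead.
    An extreme window containing no input points takes the derivative at
    the mean position of the ``n_edge_snps`` nearest points.  The last
    partial window is normalized by its true width.
    """
    if method not in ("mean_slope", "midpoint"):
        raise ValidationError(f"unknown window-rate method {method!r}")
    grid = window_grid(chrom_length_bp, window_bp)
    if grid.empty:
        raise ValidationError("empty window grid")
    lo_mbp, hi_mbp = spline.support
    lo_bp, hi_bp = lo_mbp * 1e6, hi_mbp * 1e6
    pts_bp = spline.x_mbp * 1e6
    rates = np.empty(len(grid))
    eff_width = np.empty(len(grid))
    for w in range(len(grid)):
        a, b = float(grid["start"].iat[w]), float(grid["end"].iat[w])
        has_snp = np.any((pts_bp >= a) & (pts_bp < b))
        extreme = w == 0 or w == len(grid) - 1
        a_eff, b_eff = max(a, lo_bp), min(b, hi_bp)
        if extreme and not has_snp:
            nearest = np.argsort(np.abs(pts_bp - (a + b) / 2))[:n_edge_snps]
            anchor = float(pts_bp[nearest].mean())
            rates[w] = float(spline.derivative(anchor))
            eff_width[w] = b - a
            continue
        if b_eff <= a_eff:
            rates[w] = np.nan
            eff_width[w] = 0.0
            continue
        if method == "midpoint":
            rates[w] = float(spline.derivative((a_eff + b_eff) / 2.0))
        else:
            dc = float(spline.predict(b_eff) - spline.predict(a_eff))
            width_mbp = (b_eff - a_eff) / 1e6
            rates[w] = max(dc / width_mbp, 0.0)
        eff_width[w] = b_eff - a_eff
    grid = grid.copy()
    grid["rate"] = rates
    grid["eff_width_bp"] = eff_width
    return grid


def population_window_rates(
    linkmap: LinkageMap,
    chromosomes: list[Chromosome],
    tolerance_cm: float = 2.0,
    window_bp: int = WINDOW_BP,
) -> pd.DataFrame:
    """Full per-population chain: Marey filter, spline, window rates."""
    marey = assemble_marey(linkmap, tolerance_cm)
    fits = fit_marey_spline(marey)
    frames = []
    for chrom in chromosomes:
        if chrom.name not in fits:
            continue
        wr = window_recombination_rates(fits[chrom.name], chrom.length_bp, window_bp)
        wr.insert(0, "chrom", chrom.name)
        frames.append(wr)
    return pd.concat(frames, ignore_index=True)


def collect_window_rates(per_pop: dict[str, pd.DataFrame]) -> WindowRates:
    """Stack per-population window tables into a WindowRates container."""
    pops = list(per_pop)
    first = per_pop[pops[0]]
    windows = first[["chrom", "start", "end", "width_bp", "eff_width_bp"]].copy()
    rates = np.vstack([per_pop[p]["rate"].to_numpy() for p in pops])
    return WindowRates(pop_ids=pops, windows=windows, rates=rates)


def aggregate_rates(wr: WindowRates) -> pd.DataFrame:
    """Chromosome means and the genome-wide mean per population.

    Chromosome mean = arithmetic mean of that chromosome's window rates;
    genome-wide = mean of the chromosome means.  NA windows are excluded and
    counted.
    """
    cm = wr.chromosome_means()
    out = cm.copy()
    out["genome"] = cm.mean(axis=1)
    out["n_na_windows"] = np.isnan(wr.rates).sum(axis=1)
    return out


@dataclass
class ConsensusMap:
    """Marker positions in consensus cM built from mean window rates."""

    table: pd.DataFrame  # marker, chrom, pos, cm

    def total_length_cm(self, chrom: str) -> float:
        sub = self.table[self.table["chrom"] == chrom]
        return float(sub["cm"].max())


def consensus_map(wr: WindowRates, panel: pd.DataFrame) -> ConsensusMap:
    """Convert physical marker positions to consensus cM.

    Uses the cross-population mean rate per window as a piecewise-constant
    intensity: a marker's cM is the integral of that intensity from the
    chromosome start, so increments between adjacent markers equal
    delta-bp (Mbp) x mean window rate.
    """
    mean_rates = wr.consensus_window_rates()
    frames = []
    for chrom in wr.chrom_names:
        sel = wr.windows["chrom"].to_numpy() == chrom
        starts = wr.windows["start"].to_numpy()[sel].astype(float)
        ends = wr.windows["end"].to_numpy()[sel].astype(float)
        rates = np.nan_to_num(mean_rates[sel], nan=0.0)
        cum = np.concatenate([[0.0], np.cumsum(rates * (ends - starts) / 1e6)])
        sub = panel[panel["chrom"] == chrom]
        pos = sub["pos"].to_numpy(dtype=float)
        widx = np.clip(np.searchsorted(ends, pos, side="right"), 0, len(starts) - 1)
        cm = cum[widx] + rates[widx] * (pos - starts[widx]) / 1e6
        frames.append(pd.DataFrame({
            "marker": sub["marker"].to_numpy(),
            "chrom": chrom,
            "pos": sub["pos"].to_numpy(),
            "cm": cm,
        }))
    return ConsensusMap(table=pd.concat(frames, ignore_index=True))


@dataclass
class PericentromereSet:
    """Per-chromosome pericentromeric interval (bp), empty when absent."""

    intervals: dict[str, tuple[int, int] | None]

    def is_pericentromeric(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        iv = self.intervals.get(chrom)
        pos = np.asarray(pos)
        if iv is None:
            return np.zeros(pos.shape, dtype=bool)
        return (pos >= iv[0]) & (pos < iv[1])


def pericentromeric_region(
    wr: WindowRates,
    centromeres: dict[str, int],
    fold: float = 20.0,
) -> PericentromereSet:
    """Delineate the low-recombining interval around each centromere.

    The interval is the maximal contiguous run of windows containing the
    centromere whose cross-population mean rate is at most the genome-wide
    mean divided by ``fold``.  If the centromere's own window exceeds the
    threshold the chromosome gets an empty interval with a warning.
    """
    mean_rates = wr.consensus_window_rates()
    chrom_means = [np.nanmean(mean_rates[wr.windows["chrom"].to_numpy() == c])
                   for c in wr.chrom_names]
    genome_mean = float(np.mean(chrom_means))
    threshold = genome_mean / fold
    intervals: dict[str, tuple[int, int] | None] = {}
    for chrom in wr.chrom_names:
        sel = np.flatnonzero(wr.windows["chrom"].to_numpy() == chrom)
        starts = wr.windows["start"].to_numpy()[sel]
        ends = wr.windows["end"].to_numpy()[sel]
        rates = mean_rates[sel]
        cen = centromeres[chrom]
        w0 = int(np.searchsorted(ends, cen, side="right"))
        w0 = min(w0, len(sel) - 1)
        if not (rates[w0] <= threshold):
            warnings.warn(
                f"{chrom}: centromere window rate {rates[w0]:.4g} exceeds threshold "
                f"{threshold:.4g}; empty pericentromere",
                stacklevel=2,
            )
            intervals[chrom] = None
            continue
        lo = w0
        while lo > 0 and rates[lo - 1] <= threshold:
            lo -= 1
        hi = w0
        while hi < len(sel) - 1 and rates[hi + 1] <= threshold:
            hi += 1
        intervals[chrom] = (int(starts[lo]), int(ends[hi]))
    return PericentromereSet(intervals=intervals)


def window_fold_range(wr: WindowRates, floor: float = 0.001) -> pd.DataFrame:
    """Across-population fold variation and CV per window.

    fold = max / max(min, floor); the floor guards near-zero windows and
    such windows are flagged.  Also returns the median fold across windows
    via the ``median_fold`` attribute on the frame.
    """
    if len(wr.pop_ids) < 2:
        raise ValidationError("fold range needs >= 2 populations")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mx = np.nanmax(wr.rates, axis=0)
        mn = np.nanmin(wr.rates, axis=0)
        mean = np.nanmean(wr.rates, axis=0)
        sd = np.nanstd(wr.rates, axis=0, ddof=1)
    floored = mn < floor
    fold = mx / np.maximum(mn, floor)
    out = wr.windows.copy()
    out["fold"] = fold
    out["floored"] = floored
    with np.errstate(divide="ignore", invalid="ignore"):
        out["cv"] = np.where(mean > 0, sd / mean, np.nan)
    out.attrs["median_fold"] = float(np.nanmedian(fold))
    return out


def parental_similarity_windows(
    parent_i_calls: np.ndarray,
    parent_j_calls: np.ndarray,
    panel: pd.DataFrame,
    windows: pd.DataFrame,
    min_markers: int = 5,
) -> np.ndarray:
    """Fraction of shared alleles between two inbreds per physical window.

    Only markers where both parents are homozygous are compared; windows
    with fewer than ``min_markers`` comparable markers get NaN.
    """
    pi = np.asarray(parent_i_calls)
    pj = np.asarray(parent_j_calls)
    ok = np.isin(pi, [0, 2]) & np.isin(pj, [0, 2])
    chroms = panel["chrom"].to_numpy()
    pos = panel["pos"].to_numpy()
    out = np.full(len(windows), np.nan)
    for w in range(len(windows)):
        sel = ok & (chroms == windows["chrom"].iat[w]) & \
            (pos >= windows["start"].iat[w]) & (pos < windows["end"].iat[w])
        n = int(sel.sum())
        if n >= min_markers:
            out[w] = float(np.mean(pi[sel] == pj[sel]))
    return out


def similarity_rate_correlation(
    similarity: np.ndarray, wr: WindowRates, basis: str = "genome"
) -> tuple[float, float]:
    """Pearson correlation of parental similarity with recombination rates.

    ``basis='genome'`` correlates across windows (rates averaged over
    populations per window against a per-window similarity profile);
    ``basis='population'`` correlates across populations (rates averaged
    over windows per population against per-population mean similarity,
    with ``similarity`` then an (n_pop, n_windows) matrix).
    """
    from scipy.stats import pearsonr

    if basis == "genome":
        x = np.asarray(similarity, dtype=float)
        y = wr.consensus_window_rates()
    elif basis == "population":
        sim = np.atleast_2d(np.asarray(similarity, dtype=float))
        x = np.nanmean(sim, axis=1)
        y = wr.genome_means().to_numpy()
    else:
        raise ValidationError(f"unknown basis {basis!r}")
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        raise ValidationError("fewer than 3 paired values for correlation")
    r, p = pearsonr(x[ok], y[ok])
    return float(r), float(p)
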