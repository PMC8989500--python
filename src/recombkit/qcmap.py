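"""Genotype cleaning, segregation-distortion scan and linkage-map assembly.

Cleaning mirrors array-genotyping practice: markers failing a clustering
quality score (GenTrain-style, < 0.7) or with > 10% missing calls are
dropped first, then RILs with > 10% missing or residual-heterozygous calls.
Maps are anchored to the physical marker order (no de novo ordering): the
observed recombinant fraction R between adjacent markers in selfed RILs is
corrected back to the per-meiosis recombination fraction r via
R = 2r/(1+2r) and converted to centimorgans with a map function.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .containers import GenotypeTable, RecombkitError, ValidationError

logger = logging.getLogger(__name__)


class EmptyPopulationError(RecombkitError):
    def __init__(self, message: str, report: "CleanReport | None" = None):
        super().__init__(message)
        self.report = report


class DisconnectedMapError(RecombkitError):
    pass


@dataclass
class CleanReport:
    """Bookkeeping of what cleaning removed and why."""

    thresholds: dict[str, float]
    n_markers_in: int = 0
    n_rils_in: int = 0
    markers_removed: dict[str, int] = field(default_factory=dict)
    rils_removed: dict[str, int] = field(default_factory=dict)

    @property
    def n_markers_removed(self) -> int:
        return sum(self.markers_removed.values())

    @property
    def n_rils_removed(self) -> int:
        return sum(self.rils_removed.values())

    @property
    def n_markers_retained(self) -> int:
        return self.n_markers_in - self.n_markers_removed

    @property
    def n_rils_retained(self) -> int:
        return self.n_rils_in - self.n_rils_removed

    def to_dict(self) -> dict:
        return {
            "thresholds": self.thresholds,
            "markers": {
                "input": self.n_markers_in,
                "removed": self.markers_removed,
                "retained": self.n_markers_retained,
            },
            "rils": {
                "input": self.n_rils_in,
                "removed": self.rils_removed,
                "retained": self.n_rils_retained,
            },
        }


def clean_population(
    geno: GenotypeTable,
    quality_min: float = 0.7,
    marker_missing_max: float = 0.10,
    ril_missing_max: float = 0.10,
    ril_het_max: float = 0.10,
) -> tuple[GenotypeTable, CleanReport]:
    """Apply the marker-then-individual quality filters.

    Markers with quality < ``quality_min`` or missing fraction strictly
    greater than ``marker_missing_max`` are removed, then RILs with missing
    or heterozygous fractions strictly greater than their thresholds.
    """
    for name, v in (("quality_min", quality_min), ("marker_missing_max", marker_missing_max),
                    ("ril_missing_max", ril_missing_max), ("ril_het_max", ril_het_max)):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1]")
    report = CleanReport(
        thresholds={
            "quality_min": quality_min,
            "marker_missing_max": marker_missing_max,
            "ril_missing_max": ril_missing_max,
            "ril_het_max": ril_het_max,
        },
        n_markers_in=geno.n_markers,
        n_rils_in=geno.n_individuals,
    )
    bad_quality = geno.quality < quality_min
    miss_frac = (geno.calls == -1).mean(axis=0)
    bad_missing = (miss_frac > marker_missing_max) & ~bad_quality
    report.markers_removed = {
        "quality": int(bad_quality.sum()),
        "missingness": int(bad_missing.sum()),
    }
    keep_markers = np.flatnonzero(~(bad_quality | bad_missing))
    if keep_markers.size == 0:
        raise EmptyPopulationError("all markers removed by cleaning", report)
    calls = geno.calls[:, keep_markers]
    ril_miss = (calls == -1).mean(axis=1)
    ril_het = (calls == 1).mean(axis=1)
    bad_ril_miss = ril_miss > ril_missing_max
    bad_ril_het = (ril_het > ril_het_max) & ~bad_ril_miss
    report.rils_removed = {
        "missingness": int(bad_ril_miss.sum()),
        "heterozygosity": int(bad_ril_het.sum()),
    }
    keep_rils = np.flatnonzero(~(bad_ril_miss | bad_ril_het))
    if keep_rils.size == 0:
        raise EmptyPopulationError("all RILs removed by cleaning", report)
    return geno.subset(keep_rils, keep_markers), report


def to_parental_origin(
    geno: GenotypeTable, parent_i_calls: np.ndarray, parent_j_calls: np.ndarray
) -> GenotypeTable:
    """Convert allele-dose calls to population-local parental-origin codes.

    0 means homozygous for the parent_i allele, 2 homozygous for the
    parent_j allele, 1 heterozygous, -1 missing.  Markers where either
    parent is heterozygous or missing, or where both parents carry the same
    allele (uninformative), are dropped.
    """
    pi = np.asarray(parent_i_calls)
    pj = np.asarray(parent_j_calls)
    informative = np.isin(pi, [0, 2]) & np.isin(pj, [0, 2]) & (pi != pj)
    idx = np.flatnonzero(informative)
    sub = geno.subset(marker_idx=idx)
    flip = pi[idx] == 2  # markers where parent_i carries the '2' allele
    calls = sub.calls
    flipped = np.where(calls >= 0, 2 - calls, -1).astype(np.int8)
    sub.calls = np.where(flip[None, :], flipped, calls).astype(np.int8)
    sub.coding = "origin"
    return sub


@dataclass
class SDRegion:
    """A maximal run of adjacent markers with distorted segregation."""

    chrom: str
    start_bp: int
    end_bp: int
    favoured_parent: str
    min_p: float
    n_markers: int


def segregation_distortion_scan(
    geno: GenotypeTable,
    parent_i: str = "parent_i",
    parent_j: str = "parent_j",
    alpha: float = 0.05,
) -> list[SDRegion]:
    """Exact two-sided binomial test of parental-allele counts against 0.5.

    Operates on origin-coded calls; only homozygous calls enter the test.
    Adjacent significant markers favouring the same parent merge into one
    region.  Monomorphic markers are skipped with a log notice.
    """
    if geno.coding != "origin":
        raise ValidationError("segregation scan requires origin-coded genotypes")
    calls = geno.calls
    n_i = (calls == 0).sum(axis=0)
    n_j = (calls == 2).sum(axis=0)
    total = n_i + n_j
    pvals = np.ones(geno.n_markers)
    for m in range(geno.n_markers):
        if total[m] == 0:
            logger.info(
                "marker %s has no homozygous calls (monomorphic/uncalled), skipped",
                geno.panel["marker"].iat[m],
            )
            continue
        pvals[m] = binomtest(int(n_i[m]), int(total[m]), 0.5).pvalue
    flagged = (pvals < alpha) & (total > 0)
    favoured = np.where(n_i >= n_j, parent_i, parent_j)

    regions: list[SDRegion] = []
    chroms = geno.panel["chrom"].to_numpy()
    pos = geno.panel["pos"].to_numpy()
    run_start = None
    for m in range(geno.n_markers + 1):
        open_run = run_start is not None
        extend = (
            m < geno.n_markers
            and flagged[m]
            and (not open_run or (chroms[m] == chroms[run_start] and favoured[m] == favoured[run_start]))
        )
        if extend and not open_run:
            run_start = m
        elif open_run and not extend:
            span = slice(run_start, m)
            regions.append(
                SDRegion(
                    chrom=str(chroms[run_start]),
                    start_bp=int(pos[span][0]),
                    end_bp=int(pos[span][-1]),
                    favoured_parent=str(favoured[run_start]),
                    min_p=float(pvals[span].min()),
                    n_markers=m - run_start,
                )
            )
            run_start = m if (m < geno.n_markers and flagged[m]) else None
    return regions


def selfing_observed_fraction(r: np.ndarray | float, generations: int) -> np.ndarray:
    """Recombinant fraction among doubly homozygous lines after selfing.

    Exact two-locus recursion: starting from the F1 diplotype AB/ab, each of
    ``generations`` rounds of self-fertilization draws two independent
    gametes (recombination probability r between the loci) from the current
    plant.  Returns P(recombinant homozygote | both loci homozygous), which
    converges to the Haldane-Waddington limit 2r/(1+2r) as generations grow
    but sits well below it at S4 for small r.
    """
    scalar = np.isscalar(r) or np.ndim(r) == 0
    r = np.atleast_1d(np.asarray(r, dtype=float))
    # haplotypes: 0=AB 1=Ab 2=aB 3=ab; unordered diplotype pairs (i<=j)
    pairs = [(i, j) for i in range(4) for j in range(i, 4)]
    pair_idx = {p: k for k, p in enumerate(pairs)}
    n_r = r.size
    dist = np.zeros((n_r, len(pairs)))
    dist[:, pair_idx[(0, 3)]] = 1.0  # AB/ab
    recomb_of = {(0, 3): (1, 2), (1, 2): (0, 3), (0, 1): (0, 1), (0, 2): (0, 2),
                 (1, 3): (1, 3), (2, 3): (2, 3)}
    for _ in range(generations):
        new = np.zeros_like(dist)
        for (h1, h2), k in pair_idx.items():
            # gamete distribution from diplotype (h1, h2)
            gam = np.zeros((n_r, 4))
            if h1 == h2:
                gam[:, h1] = 1.0
            else:
                ra, rb = recomb_of.get((h1, h2), (h1, h2)) if h1 < h2 else (h1, h2)
                gam[:, h1] += (1 - r) / 2
                gam[:, h2] += (1 - r) / 2
                gam[:, ra] += r / 2
                gam[:, rb] += r / 2
            for a in range(4):
                for b in range(a, 4):
                    w = gam[:, a] * gam[:, b] * (2.0 if a != b else 1.0)
                    new[:, pair_idx[(a, b)]] += dist[:, k] * w
        dist = new
    hom = [pair_idx[(h, h)] for h in range(4)]
    den = dist[:, hom].sum(axis=1)
    num = dist[:, pair_idx[(1, 1)]] + dist[:, pair_idx[(2, 2)]]
    out = num / den
    return float(out[0]) if scalar else out


_INVERSE_CACHE: dict[int, object] = {}


def invert_ril_fraction(
    R: np.ndarray | float, generations: int | None = None
) -> np.ndarray | float:
    """Per-meiosis r from the observed selfed-RIL recombinant fraction.

    With ``generations=None`` inverts the fully inbred limit R = 2r/(1+2r).
    Passing the actual number of selfing meioses (5 for S4 material)
    inverts the exact finite-generation relation instead, which matters: at
    S4 the observed R is ~16% below the asymptote for tightly linked
    markers, so the asymptotic inversion underestimates r by the same
    amount.  Results are clamped to [0, 0.5).
    """
    R = np.clip(np.asarray(R, dtype=float), 0.0, 0.499999)
    if generations is None:
        r = R / (2.0 - 2.0 * R)
        return np.clip(r, 0.0, 0.499999)
    inv = _INVERSE_CACHE.get(generations)
    if inv is None:
        from scipy.interpolate import PchipInterpolator

        grid = np.linspace(0.0, 0.499999, 512)
        Rg = selfing_observed_fraction(grid, generations)
        inv = PchipInterpolator(Rg, grid, extrapolate=False)
        _INVERSE_CACHE[generations] = inv
    na = np.isnan(R)
    R_max = float(inv.x[-1])
    out = np.asarray(inv(np.clip(np.where(na, 0.0, R), 0.0, R_max)), dtype=float)
    out = np.where(na, np.nan, out)
    return np.clip(out, 0.0, 0.499999)


def _pair_rf(calls: np.ndarray, a: int, b: int, min_informative: int = 10) -> tuple[float, int]:
    """Observed recombinant fraction between marker columns a and b.

    Uses only RILs homozygous and non-missing at both markers; returns
    (R, n_informative) with R = NaN when too few informative lines.
    """
    ca, cb = calls[:, a], calls[:, b]
    inf = np.isin(ca, [0, 2]) & np.isin(cb, [0, 2])
    n = int(inf.sum())
    if n < min_informative:
        return np.nan, n
    R = float(np.mean(ca[inf] != cb[inf]))
    return R, n


def pairwise_recombination_fraction(
    geno: GenotypeTable, chrom: str, min_informative: int = 10,
    generations: int | None = None,
) -> np.ndarray:
    """Adjusted per-meiosis r between adjacent markers of one chromosome.

    Returns an array of length (n_markers_on_chrom - 1); entries with fewer
    than ``min_informative`` doubly homozygous RILs are NaN (with a warning).
    """
    if geno.coding != "origin":
        raise ValidationError("recombination fractions require origin-coded genotypes")
    cidx = np.flatnonzero(geno.panel["chrom"].to_numpy() == chrom)
    if cidx.size < 2:
        raise ValidationError(f"chromosome {chrom} has fewer than 2 markers")
    calls = geno.calls[:, cidx]
    a = calls[:, :-1]
    b = calls[:, 1:]
    inf = np.isin(a, [0, 2]) & np.isin(b, [0, 2])
    n_inf = inf.sum(axis=0)
    with np.errstate(invalid="ignore"):
        R = np.where(n_inf > 0, np.sum((a != b) & inf, axis=0) / np.maximum(n_inf, 1), np.nan)
    R = np.where(n_inf >= min_informative, R, np.nan)
    if np.isnan(R).any():
        warnings.warn(
            f"{int(np.isnan(R).sum())} adjacent pairs on {chrom} have <{min_informative} "
            "informative RILs; r set to NA",
            stacklevel=2,
        )
    return np.asarray(invert_ril_fraction(R, generations))


def haldane_cm(r: np.ndarray | float) -> np.ndarray | float:
    """Haldane map distance in cM: d = -50 ln(1 - 2r)."""
    r = np.clip(np.asarray(r, dtype=float), 0.0, 0.499999)
    return -50.0 * np.log1p(-2.0 * r)


def kosambi_cm(r: np.ndarray | float) -> np.ndarray | float:
    """Kosambi map distance in cM: d = 25 ln((1+2r)/(1-2r))."""
    r = np.clip(np.asarray(r, dtype=float), 0.0, 0.499999)
    return 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


_MAP_FUNCTIONS = {"haldane": haldane_cm, "kosambi": kosambi_cm}


@dataclass
class LinkageMap:
    """Per-chromosome marker-bin maps: cumulative cM anchored to bp."""

    bins: dict[str, pd.DataFrame]  # chrom -> DataFrame(bin, cm, anchor_bp, members)

    def total_length_cm(self, chrom: str | None = None) -> float:
        if chrom is not None:
            return float(self.bins[chrom]["cm"].iloc[-1])
        return float(sum(df["cm"].iloc[-1] for df in self.bins.values()))

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for chrom, df in self.bins.items():
            out = df.copy()
            out.insert(0, "chrom", chrom)
            out["members"] = out["members"].map(lambda ms: ",".join(ms))
            frames.append(out)
        return pd.concat(frames, ignore_index=True)


def build_linkage_map(
    rf: dict[str, np.ndarray] | np.ndarray,
    panel: pd.DataFrame,
    map_function: str = "haldane",
    geno: GenotypeTable | None = None,
    min_informative: int = 10,
    generations: int | None = None,
) -> LinkageMap:
    """Collapse cosegregating markers into bins and accumulate map distance.

    ``rf`` holds adjusted adjacent-pair r values per chromosome (a bare
    array is accepted for a single-chromosome panel).  NA gaps are chained
    through the nearest informative neighbour using ``geno`` when supplied;
    an unbridgeable gap raises :class:`DisconnectedMapError` naming it.
    """
    if map_function not in _MAP_FUNCTIONS:
        raise ValidationError(f"unknown map function {map_function!r}")
    dist = _MAP_FUNCTIONS[map_function]
    chrom_names = list(dict.fromkeys(panel["chrom"]))
    if isinstance(rf, np.ndarray):
        if len(chrom_names) != 1:
            raise ValidationError("bare rf array only valid for a single-chromosome panel")
        rf = {chrom_names[0]: rf}

    bins: dict[str, pd.DataFrame] = {}
    for chrom in chrom_names:
        cidx = np.flatnonzero(panel["chrom"].to_numpy() == chrom)
        markers = panel["marker"].to_numpy()[cidx]
        pos = panel["pos"].to_numpy()[cidx]
        r = np.asarray(rf[chrom], dtype=float)
        if r.shape != (cidx.size - 1,):
            raise ValidationError(f"rf length mismatch on {chrom}")
        r = _chain_na(r, cidx, geno, chrom, pos, min_informative, generations)
        # collapse r == 0 runs into bins
        bin_ids = np.concatenate([[0], np.cumsum(r > 0)])
        records = []
        cm = 0.0
        for b in range(bin_ids.max() + 1):
            members = np.flatnonzero(bin_ids == b)
            if b > 0:
                cm += float(dist(r[members[0] - 1]))
            records.append(
                {
                    "bin": b,
                    "cm": cm,
                    "anchor_bp": float(pos[members].mean()),
                    "members": [str(m) for m in markers[members]],
                }
            )
        bins[chrom] = pd.DataFrame(records)
    return LinkageMap(bins=bins)


def _chain_na(
    r: np.ndarray,
    cidx: np.ndarray,
    geno: GenotypeTable | None,
    chrom: str,
    pos: np.ndarray,
    min_informative: int,
    generations: int | None = None,
) -> np.ndarray:
    """Resolve NA adjacent r values by re-estimating across wider gaps."""
    r = r.copy()
    na = np.flatnonzero(np.isnan(r))
    if na.size == 0:
        return r
    if geno is None:
        raise DisconnectedMapError(
            f"{chrom}: NA recombination fraction at gaps {na.tolist()} and no genotypes "
            "supplied for chaining"
        )
    calls = geno.calls
    for gap in na:
        resolved = False
        # widen: pair marker 'left' with increasingly distant right markers
        for left in range(gap, -1, -1):
            for right in range(gap + 1, len(pos)):
                R, n = _pair_rf(calls, int(cidx[left]), int(cidx[right]), min_informative)
                if not np.isnan(R):
                    r[gap] = float(np.asarray(invert_ril_fraction(R, generations)))
                    resolved = True
                    break
            if resolved:
                break
        if not resolved:
            raise DisconnectedMapError(
                f"{chrom}: cannot bridge gap between {pos[gap]} and {pos[gap + 1]} bp"
            )
    return r
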