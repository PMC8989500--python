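"""Synthetic double round-robin (DRR) generator with known ground truth.

The generator emulates a barley-like experiment: ~23 homozygous spring-type
founders crossed in a double round-robin ring, each biparental family selfed
by single-seed descent to S4 and genotyped with a dense SNP panel.  The
recombination landscape is U-shaped along each chromosome (suppressed
pericentromere, active distal ends) and every cross modulates it
multiplicatively through per-parent general effects (GRE) and a per-cross
specific effect (SRE) on the log scale, so that realized rates remain
non-negative while the analysis-side decomposition stays additive.

Meiosis is modelled without crossover interference: per chromosome the
crossover count is Poisson with mean equal to the cross's genetic length in
Morgans and breakpoint positions are drawn proportionally to the local
landscape intensity.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    Chromosome,
    ConfigurationError,
    Cross,
    CrossDesign,
    DesignError,
    FounderSet,
    GenotypeTable,
    TrueRecombinationModel,
    ValidationError,
    make_panel,
)

# Barley-like chromosome preset: 7 chromosomes, lengths and rough centromere
# placements in Mbp.  Values are a stylized caricature of the cultivated
# barley reference, not a copy of any particular assembly.
BARLEY_CHROMOSOMES = [
    Chromosome("1H", 558_000_000, 205_000_000),
    Chromosome("2H", 768_000_000, 349_000_000),
    Chromosome("3H", 700_000_000, 271_000_000),
    Chromosome("4H", 647_000_000, 283_000_000),
    Chromosome("5H", 670_000_000, 217_000_000),
    Chromosome("6H", 583_000_000, 259_000_000),
    Chromosome("7H", 657_000_000, 329_000_000),
]

WINDOW_BP = 10_000_000

# Genome-wide mean rate target for the barley-like baseline (cM/Mbp) and the
# shape of the U: rate(s) ~ floor + s^power with s the normalized distance
# from the centromere.  floor/power are chosen so the pericentromeric windows
# sit more than 20-fold below the genome mean.
BASELINE_MEAN_RATE = 0.45
LANDSCAPE_FLOOR = 0.008
LANDSCAPE_POWER = 3.0

# Log-scale effect variances giving a GRE:SRE variance ratio of 8:1 with a
# GRE standard deviation of ~10% of the mean rate, matching the magnitudes a
# DRR experiment of this size exhibits.
TAU2_G = 0.106**2
TAU2_S = TAU2_G / 8.0


def _child_seed(seed: int, *tokens: str) -> int:
    """Deterministic per-stream seed below 2**31 derived from a master seed."""
    h = hashlib.sha256(("%d|" % seed + "|".join(tokens)).encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def generate_founders(
    n_parents: int,
    chrom_spec: list[Chromosome] | None = None,
    marker_spacing: int = 1_000_000,
    seed: int = 0,
    maf_range: tuple[float, float] = (0.15, 0.85),
) -> FounderSet:
    """Draw fully homozygous founder inbreds on a regular marker grid.

    Markers are placed every ``marker_spacing`` bp from position 0 up to the
    chromosome end (inclusive).  Each marker's founder allele frequency is
    drawn uniformly from ``maf_range`` and founder alleles are independent
    Bernoulli draws, so nearly all markers segregate among the founders.
    """
    if n_parents < 2:
        raise ConfigurationError("need at least 2 parents")
    if marker_spacing <= 0:
        raise ConfigurationError("marker_spacing must be positive")
    chrom_spec = chrom_spec or BARLEY_CHROMOSOMES
    for c in chrom_spec:
        if marker_spacing >= c.length_bp:
            raise ConfigurationError(
                f"marker_spacing {marker_spacing} leaves too few markers on {c.name}"
            )
    rng = np.random.default_rng(seed)
    positions = {
        c.name: np.arange(0, c.length_bp + 1, marker_spacing, dtype=np.int64)
        for c in chrom_spec
    }
    panel = make_panel(chrom_spec, positions)
    n_markers = len(panel)
    p = rng.uniform(*maf_range, size=n_markers)
    haplo = (rng.random((n_parents, n_markers)) < p).astype(np.int8) * 2
    parents = [f"P{i + 1:02d}" for i in range(n_parents)]
    return FounderSet(parents=parents, chromosomes=list(chrom_spec), panel=panel, haplotypes=haplo)


def barley_baseline(chromosomes: list[Chromosome], window_bp: int = WINDOW_BP,
                    mean_rate: float = BASELINE_MEAN_RATE) -> dict[str, np.ndarray]:
    """U-shaped per-window baseline landscape, scaled to a genome mean rate.

    The shape is ``floor + s**power`` with s the distance from the centromere
    normalized by the longer arm, rescaled so the unweighted mean across all
    windows of all chromosomes equals ``mean_rate``.  The pericentromeric
    windows then fall >20-fold below the genome mean.
    """
    raw: dict[str, np.ndarray] = {}
    for chrom in chromosomes:
        n_win = int(np.ceil(chrom.length_bp / window_bp))
        edges = np.minimum(np.arange(n_win + 1) * window_bp, chrom.length_bp)
        centers = (edges[:-1] + edges[1:]) / 2.0
        arm = max(chrom.centromere_bp, chrom.length_bp - chrom.centromere_bp)
        s = np.abs(centers - chrom.centromere_bp) / arm
        raw[chrom.name] = LANDSCAPE_FLOOR + s**LANDSCAPE_POWER
    grand_mean = float(np.mean(np.concatenate(list(raw.values()))))
    scale = mean_rate / grand_mean
    return {k: v * scale for k, v in raw.items()}


def make_truth(
    founders: FounderSet,
    design: CrossDesign,
    seed: int = 0,
    tau2_g: float = TAU2_G,
    tau2_s: float = TAU2_S,
    gre_mode: str = "marker",
    window_bp: int = WINDOW_BP,
    mean_rate: float = BASELINE_MEAN_RATE,
) -> TrueRecombinationModel:
    """Draw ground-truth GRE/SRE effects on top of the barley-like baseline.

    ``gre_mode='marker'`` makes each parent's g_i a centred sum of random
    marker effects over its genotype (an infinitesimal genetic architecture,
    so genomic prediction has signal to find); ``'iid'`` draws g_i as
    independent normals instead.
    """
    rng = np.random.default_rng(_child_seed(seed, "truth"))
    n_par = founders.n_parents
    if gre_mode == "marker":
        m = founders.haplotypes.shape[1]
        beta = rng.normal(0.0, 1.0, size=m)
        raw = founders.haplotypes @ beta
        raw = raw - raw.mean()
        sd = raw.std()
        g = raw * (np.sqrt(tau2_g) / sd) if sd > 0 else np.zeros(n_par)
    elif gre_mode == "iid":
        g = rng.normal(0.0, np.sqrt(tau2_g), size=n_par)
    else:
        raise ConfigurationError(f"unknown gre_mode {gre_mode!r}")
    s = rng.normal(0.0, np.sqrt(tau2_s), size=len(design.crosses))
    return TrueRecombinationModel(
        chromosomes=list(founders.chromosomes),
        window_bp=window_bp,
        baseline=barley_baseline(founders.chromosomes, window_bp, mean_rate),
        gre={p: float(v) for p, v in zip(founders.parents, g)},
        sre={c.pop_id: float(v) for c, v in zip(design.crosses, s)},
        tau2_g=tau2_g,
        tau2_s=tau2_s,
    )


def simulate_drr_design(
    founders: FounderSet,
    n_rils_range: tuple[int, int] = (35, 146),
    seed: int = 0,
    layout: str = "double",
) -> CrossDesign:
    """Build the round-robin crossing design over the founder ring.

    ``layout='single'`` mates each parent with its next ring neighbour
    (n crosses); ``'double'`` adds the distance-2 ring (2n crosses);
    ``'paper'`` is the double layout minus the final distance-2 cross,
    mirroring the realized experiment in which 23 parents produced 45 of the
    46 nominal families.
    """
    n = founders.n_parents
    if n < 3:
        raise DesignError("a round-robin needs at least 3 parents")
    pairs: list[tuple[int, int]] = [(i, (i + 1) % n) for i in range(n)]
    if layout in ("double", "paper"):
        pairs += [(i, (i + 2) % n) for i in range(n)]
        if layout == "paper":
            pairs = pairs[:-1]
    elif layout != "single":
        raise DesignError(f"unknown layout {layout!r}")
    rng = np.random.default_rng(_child_seed(seed, "design"))
    lo, hi = n_rils_range
    crosses = [
        Cross(
            parent_i=founders.parents[i],
            parent_j=founders.parents[j],
            pop_id=f"DRR{k + 1:02d}",
            n_rils=int(rng.integers(lo, hi + 1)),
        )
        for k, (i, j) in enumerate(pairs)
    ]
    return CrossDesign(crosses=crosses)


@dataclass
class TrueCrossovers:
    """Ground-truth record of a simulated population's recombination.

    ``origins`` is the final (n_rils, 2, n_markers) parental-origin matrix
    (0 = parent_i, 1 = parent_j).  ``detectable_counts`` holds, per RIL and
    chromosome, the number of opposite-homozygote origin transitions over the
    population's informative markers — exactly what an observer of the allele
    calls can see, and hence the oracle for crossover counting.
    """

    pop_id: str
    counts: pd.DataFrame  # columns: ril, chrom, count; plus chrom == "genome"
    origins: np.ndarray | None = None

    def genome_counts(self) -> pd.Series:
        sub = self.counts[self.counts["chrom"] == "genome"]
        return pd.Series(sub["count"].to_numpy(), index=sub["ril"].to_numpy())


def _sample_breakpoints(rng, k: int, edges: np.ndarray, cum_w: np.ndarray,
                        sort: bool = True) -> np.ndarray:
    """Sample k breakpoint positions proportional to window weights."""
    u = rng.random(k) * cum_w[-1]
    w_idx = np.searchsorted(cum_w, u, side="right")
    w_idx = np.minimum(w_idx, len(cum_w) - 1)
    left = np.where(w_idx > 0, cum_w[w_idx - 1], 0.0)
    frac = (u - left) / (cum_w[w_idx] - left)
    pos = edges[w_idx] + frac * (edges[w_idx + 1] - edges[w_idx])
    return np.sort(pos) if sort else pos


def _transition_count(states: np.ndarray) -> int:
    """Transitions between opposite homozygous states, skipping het/missing."""
    v = states[(states == 0) | (states == 2)]
    if v.size < 2:
        return 0
    return int(np.sum(v[1:] != v[:-1]))


def transition_counts_matrix(states: np.ndarray) -> np.ndarray:
    """Row-wise opposite-homozygote transition counts for a (n, m) matrix.

    Values other than 0 and 2 (heterozygous, missing) are skipped, i.e. a
    0 . 2 run counts as one transition regardless of what sits in between.
    """
    states = np.atleast_2d(states)
    n, m = states.shape
    hom = (states == 0) | (states == 2)
    col = np.arange(m)
    idx = np.where(hom, col[None, :], -1)
    last_before = np.maximum.accumulate(idx, axis=1)
    last_before = np.concatenate([np.full((n, 1), -1), last_before[:, :-1]], axis=1)
    valid = hom & (last_before >= 0)
    rows = np.repeat(np.arange(n), m).reshape(n, m)
    prev_vals = states[rows, np.maximum(last_before, 0)]
    return np.sum(valid & (states != prev_vals), axis=1).astype(np.int64)


def simulate_population(
    cross: Cross,
    founders: FounderSet,
    truth: TrueRecombinationModel,
    generations: int = 5,
    seed: int = 0,
    obligate_co: bool = False,
    record_truth: bool = True,
) -> tuple[GenotypeTable, TrueCrossovers | None]:
    """Simulate one RIL family by single-seed descent.

    ``generations`` counts rounds of meiosis after the F1: 1 produces the F2
    and the default 5 corresponds to F2 plus four selfing generations (S4),
    leaving ~0.5**5 residual heterozygosity per locus.  Crossover counts per
    meiosis and chromosome are Poisson with mean equal to the cross's genetic
    length in Morgans (``obligate_co`` replaces a draw of 0 with 1), and
    breakpoints land proportionally to the windowed landscape.
    """
    if generations < 1:
        raise DesignError("need at least one meiosis round (F2)")
    for p in (cross.parent_i, cross.parent_j):
        if p not in founders.parents:
            raise DesignError(f"cross {cross.pop_id} references unknown parent {p}")
    rng = np.random.default_rng(_child_seed(seed, "pop", cross.pop_id))
    n = cross.n_rils
    panel = founders.panel
    chrom_arr = panel["chrom"].to_numpy()
    pos_arr = panel["pos"].to_numpy()
    n_markers = len(panel)

    # Origin haplotypes per line: (n, 2, m) with 0 = from parent_i, 1 = parent_j
    origins = np.empty((n, 2, n_markers), dtype=np.int8)
    origins[:, 0, :] = 0
    origins[:, 1, :] = 1

    for chrom in founders.chromosomes:
        cidx = np.flatnonzero(chrom_arr == chrom.name)
        mpos = pos_arr[cidx].astype(float)
        lam = truth.genetic_length_morgans(cross, chrom)
        rates = truth.cross_landscape(cross, chrom.name)
        edges = truth.window_edges(chrom)
        weights = rates * np.diff(edges)
        if weights.sum() <= 0:
            # no recombination possible on this chromosome
            if obligate_co:
                raise ConfigurationError(
                    f"obligate crossover requested but landscape is 0 on {chrom.name}"
                )
            continue
        cum_w = np.cumsum(weights)
        H = origins[:, :, cidx].copy()  # (n, 2, m_c)
        m_c = len(cidx)
        n_gam = 2 * n
        for _gen in range(generations):
            ks = rng.poisson(lam, size=n_gam)
            if obligate_co:
                ks = np.maximum(ks, 1)
            starts = rng.integers(0, 2, size=n_gam).astype(np.int32)
            # all breakpoints of the generation at once, tagged by gamete
            k_tot = int(ks.sum())
            gidx = np.repeat(np.arange(n_gam), ks)
            bps = _sample_breakpoints(rng, k_tot, edges, cum_w, sort=False)
            # number of breakpoints left of each marker, per gamete
            slot = np.searchsorted(mpos, bps, side="left")
            hist = np.bincount(gidx * (m_c + 1) + slot, minlength=n_gam * (m_c + 1))
            cnt = hist.reshape(n_gam, m_c + 1).cumsum(axis=1, dtype=np.int32)[:, :m_c]
            which = ((starts[:, None] + cnt) & 1).reshape(n, 2, m_c)
            H = np.where(which == 0, H[:, 0:1, :], H[:, 1:2, :])
        origins[:, :, cidx] = H

    # allele calls from founder haplotypes
    hi = founders.haplotypes[founders.parents.index(cross.parent_i)]
    hj = founders.haplotypes[founders.parents.index(cross.parent_j)]
    allele = np.where(origins == 0, hi[None, None, :], hj[None, None, :])
    calls = ((allele[:, 0, :] + allele[:, 1, :]) // 2).astype(np.int8)  # dose 0/1/2

    individuals = [f"{cross.pop_id}_R{i + 1:03d}" for i in range(n)]
    table = GenotypeTable(
        individuals=individuals,
        populations=[cross.pop_id] * n,
        panel=panel.copy(),
        calls=calls,
        quality=np.ones(n_markers),
        coding="allele",
    )

    truth_rec = None
    if record_truth:
        informative = hi != hj
        origin_geno = (origins[:, 0, :] + origins[:, 1, :]).astype(np.int8)  # 0/1/2
        per_chrom = {}
        for chrom in founders.chromosomes:
            cidx = np.flatnonzero((chrom_arr == chrom.name) & informative)
            per_chrom[chrom.name] = transition_counts_matrix(origin_geno[:, cidx])
        totals = np.sum(np.column_stack(list(per_chrom.values())), axis=1)
        recs = []
        for line in range(n):
            for chrom in founders.chromosomes:
                recs.append((individuals[line], chrom.name, int(per_chrom[chrom.name][line])))
            recs.append((individuals[line], "genome", int(totals[line])))
        truth_rec = TrueCrossovers(
            pop_id=cross.pop_id,
            counts=pd.DataFrame(recs, columns=["ril", "chrom", "count"]),
            origins=origins,
        )
    return table, truth_rec


def inject_assay_noise(
    geno: GenotypeTable,
    missing_rate: float = 0.02,
    frac_low_quality: float = 0.0,
    seed: int = 0,
) -> GenotypeTable:
    """Return a copy with random missing calls and per-marker quality scores.

    Quality scores mimic an array clustering score: a ``frac_low_quality``
    share of markers draws from Uniform(0.2, 0.7) (failing a 0.7 threshold),
    the rest from Uniform(0.7, 1.0).  The input table is left unmodified.
    """
    for name, rate in (("missing_rate", missing_rate), ("frac_low_quality", frac_low_quality)):
        if not 0.0 <= rate <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1]")
    out = geno.copy()
    rng = np.random.default_rng(_child_seed(seed, "noise"))
    if missing_rate > 0:
        mask = rng.random(out.calls.shape) < missing_rate
        out.calls[mask] = -1
    m = out.n_markers
    low = rng.random(m) < frac_low_quality
    quality = rng.uniform(0.7, 1.0, size=m)
    quality[low] = rng.uniform(0.2, 0.7, size=int(low.sum()))
    out.quality = quality
    return out


@dataclass
class SimulatedExperiment:
    """A full synthetic DRR dataset with its generating truth."""

    founders: FounderSet
    design: CrossDesign
    truth: TrueRecombinationModel
    genotypes: dict[str, GenotypeTable] = field(default_factory=dict)
    true_crossovers: dict[str, TrueCrossovers] = field(default_factory=dict)


def simulate_experiment(
    n_parents: int = 23,
    chrom_spec: list[Chromosome] | None = None,
    marker_spacing: int = 1_000_000,
    n_rils_range: tuple[int, int] = (35, 146),
    layout: str = "paper",
    generations: int = 5,
    missing_rate: float = 0.0,
    frac_low_quality: float = 0.0,
    seed: int = 0,
    gre_mode: str = "marker",
    tau2_g: float = TAU2_G,
    tau2_s: float = TAU2_S,
    keep_origins: bool = False,
) -> SimulatedExperiment:
    """Generate founders, design, truth and all RIL populations in one call.

    Defaults reproduce the study conditions the package targets: 23 parents,
    45 crosses ('paper' layout), 35-146 RILs selfed to S4, a U-shaped
    landscape with genome mean 0.45 cM/Mbp and an 8:1 GRE:SRE variance ratio.
    """
    founders = generate_founders(
        n_parents, chrom_spec, marker_spacing, seed=_child_seed(seed, "founders")
    )
    design = simulate_drr_design(founders, n_rils_range, seed=seed, layout=layout)
    truth = make_truth(founders, design, seed=seed, tau2_g=tau2_g, tau2_s=tau2_s,
                       gre_mode=gre_mode)
    exp = SimulatedExperiment(founders=founders, design=design, truth=truth)
    for cross in design.crosses:
        table, rec = simulate_population(
            cross, founders, truth, generations=generations, seed=seed
        )
        if missing_rate > 0 or frac_low_quality > 0:
            table = inject_assay_noise(
                table, missing_rate, frac_low_quality, seed=_child_seed(seed, "noise", cross.pop_id)
            )
        if rec is not None and not keep_origins:
            rec.origins = None
        exp.genotypes[cross.pop_id] = table
        exp.true_crossovers[cross.pop_id] = rec
    return exp
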