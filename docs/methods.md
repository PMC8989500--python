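# Methods

This note documents the models, algorithms and design choices behind
`recombkit`, in the order the pipeline runs them.

## The experimental design being modelled

The package targets a double round-robin (DRR) crossing experiment: a set
of homozygous parental inbreds is arranged on a ring and each parent is
mated with its neighbours at ring distance 1 and 2, so every parent
contributes to several biparental families. Each family is carried from the
F2 by single-seed descent to S4 and genotyped with a dense SNP array. The
reference configuration is 23 spring-barley-like parents, 45 crosses
(the double ring gives 46 nominal pairs; the preset drops the last
distance-2 cross to mirror the realized experiment), 35–146 RILs per
family, and seven chromosomes of 558–768 Mbp with strongly suppressed
pericentromeric recombination.

Because every parent appears in several crosses, the cross-level
recombination rate c_ij can be decomposed as

    c_ij = mu + GRE_i + GRE_j + SRE_ij + e,

where GRE (general recombination effect) captures what a parent
contributes on average over its crosses and SRE (specific recombination
effect) the deviation of one particular combination.

## Synthetic data generator (`simkit`)

**Landscape.** Each chromosome's baseline rate on the 10 Mbp window grid is
`floor + s^3` with `s` the distance from the centromere normalized by the
longer arm, rescaled so the unweighted genome mean is 0.45 cM/Mbp. With
`floor = 0.008` the windows around the centromere sit >20-fold below the
genome mean, giving a contiguous pericentromeric interval per chromosome;
distal rates rise to ~1.7 cM/Mbp.

**Effects.** A cross's landscape is the baseline times
`exp(g_i + g_j + s_ij)`. Effects act multiplicatively (log-additively) so
rates stay non-negative; the analysis-side model stays additive on the rate
scale, which is an adequate linearization because the effects are small
(tau_g ≈ 0.106). Variances default to tau_g^2 : tau_s^2 = 8 : 1, with
tau_g chosen so that var(GRE) on the rate scale ≈ 0.45^2 · tau_g^2 ≈
2.3·10^-3, the magnitude such an experiment exhibits. By default each
parent's g_i is a centred, rescaled sum of random marker effects over its
genotype (an infinitesimal architecture), so genomic prediction has a
signal to find; `gre_mode="iid"` removes the marker linkage.

**Meiosis.** No crossover interference: per chromosome the crossover count
of a meiosis is Poisson with mean equal to the cross's genetic length in
Morgans (sum of window rate × width / 100), with an optional obligate-CO
floor, and breakpoint positions are drawn proportionally to the windowed
intensity. Gametes alternate parental phase at the breakpoints. S4 means
five meiosis rounds after the F1 (F2 plus four selfings, one plant per line
per generation), leaving 0.5^5 ≈ 3.1% residual heterozygosity per locus.
All randomness flows from one master seed through per-population hashed
streams, so populations are reproducible independently of execution order.

**Recorded truth.** For every RIL the generator records, per chromosome,
the number of opposite-homozygote transitions of the true parental-origin
sequence over the population's informative markers (markers where the two
parents carry different alleles). This is exactly the quantity an observer
of the allele calls can recover, so it serves as an exact oracle for the
crossover-counting chain; crossovers that land between informative markers
and back again are invisible to both and are intentionally not counted.

What the generator does not emulate: crossover interference, gene
conversion, structural variants, segregation distortion (the scan's
positives on simulated data are type-I errors by construction), array
chemistry artefacts beyond missingness and a clustering-quality score, and
environment-dependent recombination plasticity. Passing tests therefore
validate the estimation machinery, not these biological complications.

## Cleaning and linkage maps (`qcmap`)

Markers failing the clustering quality score (< 0.7) or with > 10% missing
calls are removed first, then RILs with > 10% missing or > 10% residual
heterozygosity (strict inequalities at the boundary). Allele calls are
recoded population-locally to parental origin; markers where either parent
is heterozygous, missing, or where both parents share the allele are
dropped for that population.

Maps are anchored to the physical order — the package does not re-order
markers, because the target analyses assume near-perfect collinearity with
the reference and the estimation chain, not map ordering, is the point.
The observed recombinant fraction R between adjacent markers is computed
on doubly homozygous RILs and inverted to the per-meiosis r.

**Finite-selfing correction.** The familiar Haldane–Waddington limit
R = 2r/(1+2r) holds for fully inbred lines. At S4 it is materially wrong
for tight linkage: the exact two-locus selfing recursion (implemented in
`selfing_observed_fraction`) shows R_S4/R_inf → 0.844 as r → 0, i.e. the
asymptotic inversion underestimates r — and hence every map length and
window rate — by ~16%. The package therefore inverts the exact
finite-generation relation (a cached 512-point grid of the recursion,
inverted monotonically) whenever the generation number is known; the
asymptotic formula remains available as the `generations=None` default of
`invert_ril_fraction`. With the correction, simulated S4 map lengths agree
with the generating genetic lengths to ~1%.

Cosegregating adjacent markers (r = 0) collapse into bins anchored at
their mean physical position; cumulative distances use Haldane's map
function by default (consistent with the interference-free meiosis model),
Kosambi optionally. NA adjacent fractions are chained through the nearest
informative flanking pair; an unbridgeable gap raises an error naming it.

## Marey maps and window rates (`marey`)

Bin coordinates (anchor bp, cumulative cM) form the Marey map. Points
falling more than 2 cM below the running maximum of retained points are
removed; smaller diversions are kept untouched.

A cubic smoothing spline of cM on Mbp is fitted per
chromosome–population. scipy's `UnivariateSpline` controls smoothness
through a residual budget `s`; the initial budget comes from a
second-difference noise estimate (`s = n·sigma_hat^2`) and is escalated
(×4) until the fitted derivative is ≥ −10^-6 cM/Mbp everywhere, with
negative derivatives clipped to zero on evaluation. For steep-flat-steep
chromosomes no single cubic-spline budget may be monotone; after 25
escalations the fitter falls back to a guaranteed-monotone construction —
pool-adjacent-violators isotonic regression followed by a PCHIP
interpolant — and flags the fit. PAVA is implemented in-package (a dozen
lines) since no pre-installed dependency exposes isotonic regression for
this use.

Window rates on the half-open 0-based 10 Mbp grid are mean slopes:
(spline at window end − spline at window start) / width, evaluated within
the spline support, which makes rate × width exactly additive to the
fitted map span (the conservation property tested to 2%). The last partial
window is normalized by its true width. An extreme window containing no
markers instead takes the derivative at the mean position of the five
nearest markers. Chromosome rates are unweighted means of their window
rates, and the genome-wide rate is the unweighted mean of the chromosome
means. The consensus map integrates the cross-population mean window rate
as a piecewise-constant intensity over physical position; the
pericentromeric interval is the maximal contiguous window run containing
the centromere at ≤ genome mean / 20.

## GRE/SRE decomposition (`remodel`)

The mixed model c = Xb + Z_GRE u_GRE + Z_SRE u_SRE + e with
u_GRE ~ N(0, A·sigma2_a), u_SRE ~ N(0, D·sigma2_d) is fitted by REML:
two EM warm-up steps, then average-information updates with step-halving
accepted only when the restricted likelihood does not decrease, EM
fallback otherwise, components kept non-negative by projection (the
residual keeps a 10^-8·var(y) floor so V stays invertible) and a
Nelder-Mead polish if the iteration budget is exhausted on a likelihood
ridge. Convergence: relative component change < 10^-8, gradient norm
< 10^-6, or a flat likelihood (three consecutive relative changes
< 10^-7). BLUPs come from V^-1 at the converged components and are
verified in tests against a direct Henderson mixed-model-equation solve
and against brute-force likelihood maximization.

**Identifiability.** With identity A/D and each cross phenotyped once,
Z_SRE D Z_SRE' = I and sigma2_d is confounded with sigma2_e. The fitter
detects this, folds SRE into the residual (reports sigma2_d = 0 with a
`confounded` flag). The genome-level decomposition therefore fits the
seven chromosome-wise rates per population as replicate observations with
a chromosome fixed effect (`fit_genomewide`), which restores
identifiability of all three components; this is also how the
parameter-recovery benchmark estimates the GRE:SRE ratio. Broad-sense
heritability is H² = (sigma2_a + sigma2_d)/(sigma2_a + sigma2_d +
sigma2_e). Note that on synthetic data the residual contains only
estimation noise, so H² comes out higher (~0.8) than a field experiment
with biological residual variation would show.

## Genomic prediction (`gpred`)

The additive GRM follows VanRaden's first method with training-set allele
frequencies: G = WW'/(2·Σp(1−p)), W the 2p-centred dose matrix, with a
10^-8 diagonal ridge. For fully homozygous inbreds the mean diagonal is
≈ 2 (1 + f at f = 1). The cross-level dominance matrix is built from the
parental GRM as D[(i,j),(k,l)] = (A_ik·A_jl + A_il·A_jk)/4, rescaled to
unit mean diagonal — a standard parent-pair identity construction adopted
here as the package's interpretation, validated by its identity-reduction
and simulation behaviour rather than by an external reference.

GBLUP is the same REML machinery with genomic A/D. RR-BLUP solves the
equivalent ridge system in the individual dimension (W W' + λI) with
λ = sigma2_e/(sigma2_g/k); the GBLUP/RR-BLUP predictions agree to
< 10^-6, checked numerically rather than assumed. GRE BLUPs extend to
unphenotyped individuals by u_new = A_cross A_train^+ u_train, and the
GEBV of a potential cross is mu + GRE_G(i) + GRE_G(j), with an optional
relationship-predicted SRE term (off by default; with one phenotype per
cross the SRE of an unobserved cross is essentially prior mean anyway).

Cross-validation: (1) fivefold over populations — five disjoint near-equal
subsets per repeat, each once the validation set, with 4/3/2 of the
remaining subsets (subsampled at random when fewer than 4) as training
set; (2) leave-parents-out — all populations touching 3 (or 5) randomly
chosen parents form the validation set, so training and validation share
no parents (asserted every run). Reported statistics are the medians of
Pearson correlations across runs: r_PG between observed rates and GEBVs of
validation populations, and r(GRE_P, GRE_G) between full-data phenotypic
GRE BLUPs and training-set genomic GRE BLUPs over the validation parents.
Zou's modified-asymptotic interval (Fisher-z per-correlation limits,
recombined; independent and overlapping-dependent variants) compares two
prediction abilities. Marker thinning samples one marker uniformly per
1/5/10 Mbp bin per run.

## Crossover counting and QTL scan (`coqtl`)

A RIL's crossover count per chromosome is the number of transitions
between opposite homozygous origin states scanning markers in physical
order; heterozygous and missing calls are skipped, because at S4 a
residual heterozygote is ambiguous between 0 and 1 extra crossover and the
minimal-transition convention is the conservative reading. Outliers are
RILs whose count exceeds by more than 2 the last bin of the first
contiguous occupied run of the population's integer count histogram
(counted from the minimum); the run-based reading of "last consecutive
bin" is a configurable interpretation (`margin` parameter).

The multi-population scan fits, at each grid position (one marker per
10 Mbp by default), CO ~ population + population:marker-dose and tests the
cross-specific slopes with an F statistic. After within-population
centring this reduces to independent within-population simple regressions,
so the sum-of-squares reduction has the closed form Σ_p Sxy²/Sxx and the
scan vectorizes over positions. The genome-wide threshold is the 0.95
quantile of the maximal −log10 p over within-population phenotype
permutations (1,000 by default, reduced in tests). This is a deliberately
simplified cross-specific scan, not a re-implementation of any multi-parent
QTL package; with missing genotype calls the residual sum of squares is
approximated on the pooled non-missing subsets.

## Problem sizes used by the benchmarks

`scripts/acceptance.py` and the acceptance tests run the preset at 23
parents / 45 crosses / 100 RILs per cross / 7 chromosomes with 0.4 Mbp
marker spacing (~1,500 markers per chromosome): 20 pipeline replicates for
parameter recovery, fivefold CV at 10 repeats and leave-parents-out at 50
repeats per scenario. One replicate of the full chain takes ~12 s on one
CPU; the whole script about 6 minutes. The package-level defaults keep the
full published repeat counts (100 and 1,000).

## Known limitations

- The additive GRE/SRE analysis of a multiplicative generator is a
  linearization; at the simulated effect sizes the induced bias is far
  below replicate noise, but the SRE variance estimate absorbs part of the
  curvature, which widens the recovered-ratio distribution.
- The smoothing-spline boundary bias flattens steep distal ends slightly;
  the monotone fallback removes the bias at the cost of noisier window
  rates near chromosome ends.
- Per-window GRE/SRE fits with a single observation per cross remain
  confounded (sigma2_d reported 0, flagged); only replicated observations
  separate SRE from residual.
- Simulated per-RIL genome-wide crossover counts centre near ~34 at the
  preset scale: selfing to S4 roughly doubles the per-meiosis map
  (junction accumulation), and with ~55% informative markers most
  junctions are visible. Real array data, with sparser informative
  coverage and stricter counting, yields lower counts; the count scale is
  a generator property, while the count-vs-rate correlation is the tested
  behaviour.
- The SD scan uses per-marker α = 0.05 with no multiplicity correction,
  matching how such regions are conventionally reported; region counts on
  clean data are type-I errors by design.
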