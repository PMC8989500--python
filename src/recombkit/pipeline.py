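"""End-to-end chains: genotypes -> linkage maps -> window rates -> effects.

These helpers wire the per-module operations together in the order the
analysis runs: clean each RIL population, convert to parental-origin codes,
estimate adjacent recombination fractions, build the anchored linkage map,
fit Marey splines and read off 10 Mbp window rates, then decompose the
population rates into GRE/SRE.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import marey, qcmap, remodel
from .containers import CrossDesign, FounderSet, GenotypeTable, WindowRates
from .simkit import SimulatedExperiment


def population_linkage_map(
    geno: GenotypeTable,
    founders: FounderSet,
    cross,
    clean: bool = True,
    map_function: str = "haldane",
    generations: int | None = 5,
) -> tuple[qcmap.LinkageMap, GenotypeTable, qcmap.CleanReport | None]:
    """Clean one population and build its anchored linkage map.

    Returns the map, the cleaned origin-coded genotypes and the cleaning
    report (None when ``clean`` is off).
    """
    report = None
    if clean:
        geno, report = qcmap.clean_population(geno)
    pi = founders.haplotypes[founders.parents.index(cross.parent_i)]
    pj = founders.haplotypes[founders.parents.index(cross.parent_j)]
    # align parent calls to the possibly marker-filtered table
    keep = geno.panel["marker"].to_numpy()
    full = founders.panel["marker"].to_numpy()
    sel = pd.Index(full).get_indexer(keep)
    origin = qcmap.to_parental_origin(geno, pi[sel], pj[sel])
    rf = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for chrom in dict.fromkeys(origin.panel["chrom"]):
            rf[chrom] = qcmap.pairwise_recombination_fraction(
                origin, chrom, generations=generations
            )
        linkmap = qcmap.build_linkage_map(
            rf, origin.panel, map_function, geno=origin, generations=generations
        )
    return linkmap, origin, report


def experiment_window_rates(
    exp: SimulatedExperiment,
    clean: bool = True,
    tolerance_cm: float = 2.0,
    window_bp: int = marey.WINDOW_BP,
) -> tuple[WindowRates, dict[str, GenotypeTable]]:
    """Window rates for every population of a (simulated) experiment.

    Also returns the cleaned origin-coded genotypes per population for
    downstream crossover counting.
    """
    per_pop: dict[str, pd.DataFrame] = {}
    origins: dict[str, GenotypeTable] = {}
    for cross in exp.design.crosses:
        geno = exp.genotypes[cross.pop_id]
        linkmap, origin, _ = population_linkage_map(geno, exp.founders, cross, clean=clean)
        per_pop[cross.pop_id] = marey.population_window_rates(
            linkmap, exp.founders.chromosomes, tolerance_cm, window_bp
        )
        origins[cross.pop_id] = origin
    return marey.collect_window_rates(per_pop), origins


def decompose_rates(
    wr: WindowRates,
    design: CrossDesign,
    A: np.ndarray | None = None,
    D: np.ndarray | None = None,
    level: str = "chromosome",
) -> remodel.GREFit:
    """GRE/SRE fit of the experiment's rates.

    ``level='chromosome'`` (default) fits the per-chromosome rates with a
    chromosome fixed effect, which keeps all three variance components
    identifiable; ``'genome'`` fits the 45 genome-wide rates directly (the
    SRE then folds into the residual under identity matrices).
    """
    if level == "chromosome":
        return remodel.fit_genomewide(wr.chromosome_means(), design, A=A, D=D)
    if level != "genome":
        raise ValueError(f"unknown level {level!r}")
    gm = wr.genome_means()
    pops = [p for p in design.pop_ids if p in gm.index]
    inc = remodel.build_incidence(design, obs_pop=pops)
    return remodel.fit_gre_sre(gm.loc[pops].to_numpy(), inc, A=A, D=D)
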