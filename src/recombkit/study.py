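"""Preset study runs: the full pipeline at the conditions it was built for.

These helpers wire the generator, rate-estimation chain, GRE/SRE
decomposition and cross-validation together at the design's reference
scale — 23 parents, 45 crosses, 7 barley-like chromosomes — so parameter
recovery and prediction benchmarks can be reproduced with one call each.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import gpred, pipeline, remodel, simkit
from .simkit import SimulatedExperiment


def drr_preset_experiment(
    seed: int,
    n_rils: int = 100,
    marker_spacing: int = 400_000,
) -> SimulatedExperiment:
    """The reference synthetic experiment: 23 parents, 45 crosses, 7
    chromosomes, ~1,500 markers per chromosome, S4 RILs, 8:1 GRE:SRE."""
    return simkit.simulate_experiment(
        n_parents=23,
        marker_spacing=marker_spacing,
        n_rils_range=(n_rils, n_rils),
        layout="paper",
        seed=seed,
    )


def recovery_replicate(seed: int, n_rils: int = 100,
                       marker_spacing: int = 400_000,
                       keep_experiment: bool = False) -> dict:
    """Simulate one preset experiment and push it through the whole chain.

    Returns the estimated variance components, their GRE/SRE ratio, H2 and
    the genome-wide rate summary; optionally also the experiment and window
    rates for reuse.
    """
    exp = drr_preset_experiment(seed, n_rils, marker_spacing)
    wr, origins = pipeline.experiment_window_rates(exp)
    fit = pipeline.decompose_rates(wr, exp.design)
    gm = wr.genome_means()
    out = {
        "seed": seed,
        "sigma2_a": fit.vc.sigma2_a,
        "sigma2_d": fit.vc.sigma2_d,
        "sigma2_e": fit.vc.sigma2_e,
        "ratio": fit.vc.sigma2_a / fit.vc.sigma2_d if fit.vc.sigma2_d > 0 else np.inf,
        "h2": fit.h2,
        "genome_median": float(gm.median()),
        "genome_min": float(gm.min()),
        "genome_max": float(gm.max()),
    }
    if keep_experiment:
        out["experiment"] = exp
        out["window_rates"] = wr
        out["origins"] = origins
        out["fit"] = fit
    return out


def run_recovery(n_replicates: int = 20, seed: int = 1, n_rils: int = 100,
                 marker_spacing: int = 400_000) -> pd.DataFrame:
    """Replicate the parameter-recovery experiment.

    The key check: the replicate distribution of the estimated
    sigma2_GRE/sigma2_SRE ratio should cover the generating 8:1 truth.
    """
    rows = []
    for rep in range(n_replicates):
        rows.append(recovery_replicate(seed * 10_000 + rep, n_rils, marker_spacing))
    return pd.DataFrame(rows)


def cv_benchmark(
    exp: SimulatedExperiment,
    wr,
    seed: int = 1,
    fivefold_repeats: int = 10,
    lpo_repeats: int = 50,
) -> dict[str, gpred.CVResult]:
    """All cross-validation scenarios on one experiment.

    Fivefold CV with 4/3/2 training subsets (training sets of 36/27/18
    populations for the 45-cross preset) plus leave-3- and leave-5-parents-out.
    """
    A = gpred.additive_grm(exp.founders.haplotypes, exp.founders.parents)
    D = gpred.dominance_grm(exp.design, A)
    gm = wr.genome_means()
    gre_p = pipeline.decompose_rates(wr, exp.design).u_gre
    out: dict[str, gpred.CVResult] = {}
    for n_ts in (4, 3, 2):
        out[f"fivefold_ts{n_ts}"] = gpred.cv_fivefold(
            gm, exp.design, A, D, gre_p,
            n_subsets_in_ts=n_ts, repeats=fivefold_repeats, seed=seed,
        )
    for n_par in (3, 5):
        out[f"leave{n_par}parents"] = gpred.cv_leave_parents_out(
            gm, exp.design, A, D, gre_p,
            n_par=n_par, repeats=lpo_repeats, seed=seed,
        )
    return out


def oracle_checks(seed: int = 1) -> dict[str, float]:
    """Numerical-identity checks between dual formulations.

    Returns the maximal |difference| between GBLUP and RR-BLUP predictions
    and between REML BLUPs and a direct mixed-model-equation solve, plus the
    fraction of RILs whose counted crossovers equal the simulator's recorded
    ground truth in a small noise-free experiment.
    """
    from . import coqtl
    from .containers import Cross, CrossDesign

    rng = np.random.default_rng(seed)

    # GBLUP vs RR-BLUP duality on simulated inbreds
    f = simkit.generate_founders(23, simkit.BARLEY_CHROMOSOMES[:2], 2_000_000, seed=seed)
    calls = f.haplotypes.astype(float)
    p = calls.mean(axis=0) / 2.0
    k = 2.0 * np.sum(p * (1.0 - p))
    beta = rng.normal(0, 0.02, calls.shape[1])
    y = (calls - 2 * p) @ beta + rng.normal(0, 0.3, calls.shape[0])
    G = gpred.additive_grm(calls, f.parents, ridge=0.0)
    s2g, s2e = 0.2, 0.1
    lam = s2e / (s2g / k)
    me = gpred.rrblup_marker_effects(y, calls, ridge=lam)
    pred_rr = me.predict(calls, p)
    V = s2g * G.values + s2e * np.eye(len(y))
    Vi = np.linalg.inv(V)
    ones = np.ones(len(y))
    mu = float((ones @ Vi @ y) / (ones @ Vi @ ones))
    gebv = mu + s2g * G.values @ Vi @ (y - mu)
    gblup_rrblup_delta = float(np.max(np.abs(pred_rr - gebv)))

    # REML BLUPs vs direct Henderson solve
    par = [f"P{i:02d}" for i in range(8)]
    crosses = [Cross(par[i], par[(i + 1) % 8], f"C{i}", 10) for i in range(8)]
    design = CrossDesign(crosses)
    obs = [c.pop_id for c in crosses for _ in range(3)]
    inc = remodel.build_incidence(design, obs_pop=obs)
    g = rng.normal(0, 0.028, 8)
    s = rng.normal(0, 0.01, 8)
    yy = 0.45 + inc.Z_gre @ g + inc.Z_sre @ s + rng.normal(0, 0.02, len(obs))
    fit = remodel.fit_gre_sre(yy, inc)
    s2a, s2d, s2e2 = (max(v, 1e-12) for v in fit.vc.as_tuple())
    X = np.ones((len(yy), 1))
    W = np.hstack([X, inc.Z_gre, inc.Z_sre])
    C = W.T @ W / s2e2
    C[1:9, 1:9] += np.eye(8) / s2a
    C[9:, 9:] += np.eye(8) / s2d
    sol = np.linalg.solve(C, W.T @ yy / s2e2)
    mme_delta = float(max(
        np.max(np.abs(sol[1:9] - fit.u_gre.to_numpy())),
        np.max(np.abs(sol[9:] - fit.u_sre.to_numpy())),
    ))

    # counted crossovers vs recorded truth, noise off
    exp = simkit.simulate_experiment(
        n_parents=4, chrom_spec=simkit.BARLEY_CHROMOSOMES[:1],
        marker_spacing=1_000_000, n_rils_range=(40, 40), layout="single",
        seed=seed,
    )
    wr, origins = pipeline.experiment_window_rates(exp)
    matches = total = 0
    for pop, origin in origins.items():
        counted = coqtl.count_crossovers(origin)["genome"].astype(int)
        truth = exp.true_crossovers[pop].counts
        truth_g = truth[truth["chrom"] == "genome"].set_index("ril")["count"]
        shared = counted.index.intersection(truth_g.index)
        matches += int((counted.loc[shared].to_numpy() == truth_g.loc[shared].to_numpy()).sum())
        total += len(shared)
    co_match_fraction = matches / total if total else float("nan")

    return {
        "gblup_rrblup_max_abs_delta": gblup_rrblup_delta,
        "reml_blup_vs_mme_max_abs_delta": mme_delta,
        "co_count_truth_match_fraction": co_match_fraction,
    }


def analytic_limits() -> dict[str, float]:
    """Closed-form sanity quantities the pipeline must reproduce.

    A linear Marey map with slope 0.5 cM/Mbp must give window rates of 0.5;
    the window rates must telescope to the fitted map's total span; and the
    heritability of components (2, 1, 1) is 0.75.
    """
    from . import marey
    from .qcmap import LinkageMap

    bp = np.linspace(0, 95e6, 60)
    df = pd.DataFrame({
        "bin": np.arange(60), "cm": 0.5 * bp / 1e6, "anchor_bp": bp,
        "members": [[f"m{i}"] for i in range(60)],
    })
    lm = LinkageMap(bins={"c1": df})
    fit = marey.fit_marey_spline(marey.assemble_marey(lm))["c1"]
    wtab = marey.window_recombination_rates(fit, 95_000_000)
    linear_rate = float(wtab["rate"].mean())

    rng = np.random.default_rng(0)
    bp2 = np.sort(rng.uniform(0, 300e6, 200))
    bp2[0], bp2[-1] = 0.0, 300e6
    cm2 = np.cumsum(rng.exponential(0.5, 200))
    df2 = pd.DataFrame({
        "bin": np.arange(200), "cm": cm2, "anchor_bp": bp2,
        "members": [[f"m{i}"] for i in range(200)],
    })
    fit2 = marey.fit_marey_spline(marey.assemble_marey(LinkageMap(bins={"c1": df2})))["c1"]
    w2 = marey.window_recombination_rates(fit2, 300_000_000)
    total = float(np.sum(w2["rate"] * w2["eff_width_bp"] / 1e6))
    conservation_rel_error = abs(total - fit2.total_span_cm()) / fit2.total_span_cm()

    return {
        "linear_marey_window_rate": linear_rate,
        "window_sum_conservation_rel_error": float(conservation_rel_error),
        "h2_of_2_1_1": remodel.heritability((2.0, 1.0, 1.0)),
    }
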