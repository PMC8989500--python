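"""Shared fixtures: small synthetic experiments reused across test modules."""

import numpy as np
import pytest

from recombkit import pipeline, simkit
from recombkit.containers import Chromosome


@pytest.fixture(scope="session")
def mini_exp():
    """A small but realistic DRR experiment: 10 parents, 20 crosses, 2
    barley-like chromosomes, 100 RILs per population, no assay noise."""
    return simkit.simulate_experiment(
        n_parents=10,
        chrom_spec=simkit.BARLEY_CHROMOSOMES[:2],
        marker_spacing=1_000_000,
        n_rils_range=(100, 100),
        layout="double",
        seed=20240915,
    )


@pytest.fixture(scope="session")
def mini_rates(mini_exp):
    """Window rates and origin-coded genotypes for the mini experiment."""
    wr, origins = pipeline.experiment_window_rates(mini_exp)
    return wr, origins


@pytest.fixture(scope="session")
def flat_truth_factory():
    """Builds a constant-landscape truth for arbitrary chromosomes."""

    def make(chromosomes, rate, pop_ids=("X",), parents=("P01", "P02")):
        from recombkit.containers import TrueRecombinationModel

        baseline = {}
        for c in chromosomes:
            n_win = int(np.ceil(c.length_bp / 10_000_000))
            baseline[c.name] = np.full(n_win, float(rate))
        return TrueRecombinationModel(
            chromosomes=list(chromosomes),
            window_bp=10_000_000,
            baseline=baseline,
            gre={p: 0.0 for p in parents},
            sre={p: 0.0 for p in pop_ids},
            tau2_g=0.0,
            tau2_s=0.0,
        )

    return make


@pytest.fixture()
def chrom100():
    return Chromosome("c1", 100_000_000, 50_000_000)
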