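"""Cleaning, segregation distortion and linkage-map construction tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest

from recombkit import qcmap
from recombkit.containers import Chromosome, GenotypeTable


def _table(calls, quality=None, pos=None, coding="origin", pop="POP"):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    pos = np.arange(m) * 1_000_000 if pos is None else np.asarray(pos)
    panel = pd.DataFrame({"marker": [f"m{i}" for i in range(m)], "chrom": "c1", "pos": pos})
    return GenotypeTable(
        individuals=[f"R{i}" for i in range(n)],
        populations=[pop] * n,
        panel=panel,
        calls=calls,
        quality=np.ones(m) if quality is None else np.asarray(quality, dtype=float),
        coding=coding,
    )


class TestCleanPopulation:
    def test_quality_threshold_is_strict_less_than(self):
        g = _table(np.zeros((12, 3)), quality=[0.69, 0.70, 0.95], coding="allele")
        out, rep = qcmap.clean_population(g)
        assert out.panel["marker"].tolist() == ["m1", "m2"]
        assert rep.markers_removed["quality"] == 1

    def test_ril_missing_boundary(self):
        calls = np.zeros((50, 100), dtype=np.int8)
        calls[0, :11] = -1  # 11% missing -> removed
        calls[1, :10] = -1  # exactly 10% -> retained (strict >)
        g = _table(calls, coding="allele")
        out, rep = qcmap.clean_population(g)
        assert "R0" not in out.individuals and "R1" in out.individuals
        assert rep.rils_removed["missingness"] == 1

    def test_het_ril_removed(self):
        calls = np.zeros((3, 100), dtype=np.int8)
        calls[2, :15] = 1
        g = _table(calls, coding="allele")
        out, rep = qcmap.clean_population(g)
        assert "R2" not in out.individuals
        assert rep.rils_removed["heterozygosity"] == 1

    def test_idempotent_and_conserving(self):
        rng = np.random.default_rng(0)
        calls = rng.choice([0, 2], size=(40, 60)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.03] = -1
        g = _table(calls, quality=rng.uniform(0.5, 1.0, 60), coding="allele")
        out1, rep1 = qcmap.clean_population(g)
        assert rep1.n_markers_removed + rep1.n_markers_retained == g.n_markers
        assert rep1.n_rils_removed + rep1.n_rils_retained == g.n_individuals
        out2, rep2 = qcmap.clean_population(out1)
        assert rep2.n_markers_removed == 0 and rep2.n_rils_removed == 0

    def test_all_markers_removed_raises_with_report(self):
        g = _table(np.zeros((5, 3)), quality=[0.1, 0.2, 0.3], coding="allele")
        with pytest.raises(qcmap.EmptyPopulationError) as exc:
            qcmap.clean_population(g)
        assert exc.value.report.markers_removed["quality"] == 3


class TestParentalOrigin:
    def test_conversion_and_uninformative_drop(self):
        # parent_i = [0,2,0,0], parent_j = [2,0,0,2]; marker 2 uninformative
        calls = np.array([[0, 2, 0, 2], [2, 0, 2, 1], [1, -1, 0, 0]], dtype=np.int8)
        g = _table(calls, coding="allele")
        out = qcmap.to_parental_origin(g, np.array([0, 2, 0, 0]), np.array([2, 0, 0, 2]))
        assert out.n_markers == 3
        expect = np.array([[0, 0, 2], [2, 2, 1], [1, -1, 0]], dtype=np.int8)
        assert np.array_equal(out.calls, expect)
        assert out.coding == "origin"


class TestSegregationDistortion:
    def test_balanced_not_flagged(self):
        calls = np.array([[0] * 50 + [2] * 50]).T.repeat(3, axis=1).astype(np.int8)
        g = _table(calls)
        assert qcmap.segregation_distortion_scan(g) == []

    def test_extreme_flagged(self):
        g = _table(np.zeros((100, 4), dtype=np.int8))
        regions = qcmap.segregation_distortion_scan(g, parent_i="A", parent_j="B")
        assert len(regions) == 1
        assert regions[0].favoured_parent == "A"
        assert regions[0].min_p < 1e-6
        assert regions[0].n_markers == 4

    def test_65_of_100_matches_exact_binomial(self):
        calls = np.array([[0] * 65 + [2] * 35]).T.astype(np.int8)
        g = _table(calls)
        regions = qcmap.segregation_distortion_scan(g)
        assert len(regions) == 1
        expect_p = binomtest(65, 100, 0.5).pvalue
        assert regions[0].min_p == pytest.approx(expect_p)
        assert expect_p == pytest.approx(0.0035, abs=2e-4)

    def test_type_i_error_controlled_on_balanced_population(self):
        rng = np.random.default_rng(5)
        calls = rng.choice([0, 2], size=(200, 400)).astype(np.int8)
        g = _table(calls, pos=np.arange(400) * 500_000)
        regions = qcmap.segregation_distortion_scan(g, alpha=0.05)
        n_flagged = sum(r.n_markers for r in regions)
        # exact test is conservative; allow up to alpha + 3 binomial SD
        assert n_flagged / 400 <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 400)


class TestRecombinationFractions:
    def test_zero_and_limit(self):
        assert qcmap.invert_ril_fraction(0.0) == 0.0
        assert qcmap.invert_ril_fraction(0.5) < 0.5
        assert qcmap.invert_ril_fraction(2 * 0.2 / 1.4) == pytest.approx(0.2, abs=1e-6)

    def test_selfing_recursion_against_independent_oracle(self):
        # independent dict-based recursion over two-locus diplotypes
        def oracle(r, gens):
            def gametes(diplo):
                (a1, b1), (a2, b2) = diplo
                g = {}
                for hap, p in (((a1, b1), (1 - r) / 2), ((a2, b2), (1 - r) / 2),
                               ((a1, b2), r / 2), ((a2, b1), r / 2)):
                    g[hap] = g.get(hap, 0) + p
                return g

            dist = {tuple(sorted((("A", "B"), ("a", "b")))): 1.0}
            for _ in range(gens):
                new = {}
                for diplo, p in dist.items():
                    gs = gametes(diplo)
                    for g1, p1 in gs.items():
                        for g2, p2 in gs.items():
                            key = tuple(sorted((g1, g2)))
                            new[key] = new.get(key, 0) + p * p1 * p2
                dist = new
            num = den = 0.0
            for (h1, h2), p in dist.items():
                if h1[0] == h2[0] and h1[1] == h2[1]:
                    den += p
                    if (h1[0], h1[1]) in (("A", "b"), ("a", "B")):
                        num += p
            return num / den

        for r in (0.01, 0.1, 0.3):
            for gens in (2, 5):
                got = float(qcmap.selfing_observed_fraction(r, gens))
                assert got == pytest.approx(oracle(r, gens), abs=1e-12)

    def test_finite_generation_inversion_round_trip(self):
        r = np.array([0.005, 0.05, 0.2])
        R = qcmap.selfing_observed_fraction(r, 5)
        back = qcmap.invert_ril_fraction(R, generations=5)
        assert np.allclose(back, r, atol=1e-4)

    def test_adjacent_fraction_recovers_simulated_r(self):
        # two loci, selfed lines simulated from the exact recursion at r=0.2:
        # sampling many RILs and inverting should recover r within 3 SE
        rng = np.random.default_rng(8)
        R_true = float(qcmap.selfing_observed_fraction(0.2, 5))
        n = 4000
        rec = rng.random(n) < R_true
        calls = np.zeros((n, 2), dtype=np.int8)
        calls[rec, 1] = 2
        g = _table(calls)
        r_hat = qcmap.pairwise_recombination_fraction(g, "c1", generations=5)
        se = np.sqrt(R_true * (1 - R_true) / n)  # SE on R scale
        dR_dr = (qcmap.selfing_observed_fraction(0.21, 5)
                 - qcmap.selfing_observed_fraction(0.19, 5)) / 0.02
        assert abs(float(r_hat[0]) - 0.2) < 3 * se / dR_dr

    def test_few_informative_pairs_na(self):
        calls = np.full((5, 3), 1, dtype=np.int8)
        calls[:, 0] = 0
        g = _table(calls)
        with pytest.warns(UserWarning):
            r = qcmap.pairwise_recombination_fraction(g, "c1")
        assert np.isnan(r).all()


class TestMapFunctions:
    def test_haldane_closed_form(self):
        assert float(qcmap.haldane_cm(0.2)) == pytest.approx(-50 * np.log(0.6))
        assert float(qcmap.haldane_cm(0.2)) == pytest.approx(25.54, abs=0.01)
        assert float(qcmap.haldane_cm(0.0)) == 0.0

    def test_kosambi_below_haldane(self):
        r = np.linspace(0.01, 0.4, 10)
        assert (np.asarray(qcmap.kosambi_cm(r)) < np.asarray(qcmap.haldane_cm(r))).all()


class TestLinkageMap:
    def test_cosegregating_markers_collapse_to_one_bin(self):
        panel = _table(np.zeros((2, 5)), coding="origin").panel
        rf = np.zeros(4)
        lm = qcmap.build_linkage_map(rf, panel)
        assert len(lm.bins["c1"]) == 1
        assert lm.total_length_cm("c1") == 0.0

    def test_haldane_distance_between_bins(self):
        panel = _table(np.zeros((2, 2)), coding="origin").panel
        lm = qcmap.build_linkage_map(np.array([0.2]), panel)
        assert lm.total_length_cm("c1") == pytest.approx(25.5413, abs=1e-3)
        assert lm.bins["c1"]["cm"].iloc[0] == 0.0

    def test_na_gap_chained_through_genotypes(self):
        rng = np.random.default_rng(3)
        n = 200
        calls = np.zeros((n, 3), dtype=np.int8)
        rec = rng.random(n) < 0.1
        calls[rec, 2] = 2
        calls[:, 1] = 1  # middle marker all het -> uninformative pair
        calls[rec, 1] = 1
        g = _table(calls)
        with pytest.warns(UserWarning):
            rf = qcmap.pairwise_recombination_fraction(g, "c1")
        assert np.isnan(rf).all()
        lm = qcmap.build_linkage_map(rf, g.panel, geno=g)
        # both gaps bridged through the informative outer pair
        assert lm.total_length_cm("c1") > 0

    def test_unbridgeable_gap_raises(self):
        calls = np.full((20, 3), 1, dtype=np.int8)
        g = _table(calls)
        with pytest.warns(UserWarning):
            rf = qcmap.pairwise_recombination_fraction(g, "c1")
        with pytest.raises(qcmap.DisconnectedMapError):
            qcmap.build_linkage_map(rf, g.panel, geno=g)

    def test_map_order_follows_physical_anchoring(self):
        rng = np.random.default_rng(9)
        n, m = 300, 30
        calls = np.zeros((n, m), dtype=np.int8)
        state = np.zeros(n, dtype=np.int8)
        for j in range(m):
            flip = rng.random(n) < 0.05
            state = np.where(flip, 2 - state, state)
            calls[:, j] = state
        g = _table(calls)
        rf = qcmap.pairwise_recombination_fraction(g, "c1")
        lm = qcmap.build_linkage_map(rf, g.panel)
        cm = lm.bins["c1"]["cm"].to_numpy()
        bp = lm.bins["c1"]["anchor_bp"].to_numpy()
        assert (np.diff(bp) > 0).all()
        assert (np.diff(cm) >= 0).all()
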