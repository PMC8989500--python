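"""GRM construction, GBLUP/RR-BLUP duality, prediction metrics and CV."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from recombkit import gpred, remodel, simkit
from recombkit.containers import Cross, CrossDesign, DesignError, ValidationError


@pytest.fixture(scope="module")
def founders23():
    return simkit.generate_founders(23, simkit.BARLEY_CHROMOSOMES[:2], 2_000_000, seed=9)


class TestAdditiveGrm:
    def test_duplicate_inbreds_share_row(self):
        calls = np.array([[0, 2, 2, 0], [0, 2, 2, 0], [2, 0, 0, 2]], dtype=np.int8)
        g = gpred.additive_grm(calls, ["a", "b", "c"])
        assert g.values[0, 1] == pytest.approx(g.values[0, 0], abs=1e-7)

    def test_marker_permutation_invariance(self, founders23):
        calls = founders23.haplotypes
        rng = np.random.default_rng(0)
        perm = rng.permutation(calls.shape[1])
        g1 = gpred.additive_grm(calls, founders23.parents)
        g2 = gpred.additive_grm(calls[:, perm], founders23.parents)
        assert np.allclose(g1.values, g2.values)

    def test_matches_bruteforce_summation(self, founders23):
        calls = founders23.haplotypes[:, :500].astype(float)
        g = gpred.additive_grm(calls, founders23.parents, ridge=0.0)
        p = calls.mean(axis=0) / 2
        denom = 2 * np.sum(p * (1 - p))
        n = calls.shape[0]
        expect = np.zeros((n, n))
        for i in range(n):  # independent summation order
            for j in range(n):
                expect[i, j] = np.sum((calls[i] - 2 * p) * (calls[j] - 2 * p)) / denom
        assert np.allclose(g.values, expect, atol=1e-9)

    def test_inbred_diagonal_near_two(self, founders23):
        g = gpred.additive_grm(founders23.haplotypes, founders23.parents)
        # fully homozygous lines under 2p-centring: mean diagonal ~ 1 + f = 2
        assert np.mean(np.diag(g.values)) == pytest.approx(2.0, rel=0.15)

    def test_monomorphic_panel_rejected(self):
        calls = np.zeros((3, 10), dtype=np.int8)
        with pytest.raises(ValidationError):
            gpred.additive_grm(calls, ["a", "b", "c"])


class TestDominanceGrm:
    def _design(self):
        return CrossDesign([
            Cross("P1", "P2", "X", 10),
            Cross("P3", "P4", "Y", 10),
            Cross("P1", "P3", "Z", 10),
        ])

    def test_identity_parents_give_identity_crosses(self):
        A = gpred.GRM(ids=["P1", "P2", "P3", "P4"], values=np.eye(4), kind="additive", n_markers=0)
        D = gpred.dominance_grm(self._design(), A)
        assert np.allclose(D.values, np.eye(3))

    def test_disjoint_crosses_of_unrelated_parents_unrelated(self):
        A = gpred.GRM(ids=["P1", "P2", "P3", "P4"], values=np.eye(4), kind="additive", n_markers=0)
        D = gpred.dominance_grm(self._design(), A)
        assert D.values[0, 1] == 0.0  # X and Y share no parents

    def test_missing_parent_rejected(self):
        A = gpred.GRM(ids=["P1", "P2"], values=np.eye(2), kind="additive", n_markers=0)
        with pytest.raises(DesignError):
            gpred.dominance_grm(self._design(), A)


class TestGblupIdentityReduction:
    def test_identity_matrices_reproduce_identity_fit(self):
        rng = np.random.default_rng(21)
        par = [f"P{i}" for i in range(6)]
        crosses = [Cross(par[i], par[(i + 1) % 6], f"C{i}", 10) for i in range(6)]
        design = CrossDesign(crosses)
        obs = [c.pop_id for c in crosses for _ in range(2)]
        inc = remodel.build_incidence(design, obs_pop=obs)
        y = 0.45 + rng.normal(0, 0.03, len(obs))
        A = gpred.GRM(ids=par, values=np.eye(6), kind="additive", n_markers=0)
        D = gpred.GRM(ids=design.pop_ids, values=np.eye(6), kind="dominance", n_markers=0)
        f_ident = remodel.fit_gre_sre(y, inc)
        f_gen = gpred.fit_gblup(y, inc, A, D)
        assert np.allclose(f_gen.u_gre.to_numpy(), f_ident.u_gre.to_numpy(), atol=1e-8)
        assert f_gen.vc.sigma2_a == pytest.approx(f_ident.vc.sigma2_a, abs=1e-8)


class TestRrblup:
    def test_single_marker_ridge_closed_form(self):
        rng = np.random.default_rng(2)
        x = rng.choice([0.0, 2.0], size=50)
        y = 0.3 * x + rng.normal(0, 0.01, 50)
        lam = 5.0
        me = gpred.rrblup_marker_effects(y, x[:, None], ridge=lam)
        w = x - x.mean()
        beta_expect = (w @ (y - y.mean())) / (w @ w + lam)
        # centring via the mixed-model intercept matches simple centring here
        assert me.effects[0] == pytest.approx(beta_expect, rel=1e-6)

    def test_zero_targets_zero_effects(self):
        rng = np.random.default_rng(3)
        M = rng.choice([0.0, 2.0], size=(30, 40))
        me = gpred.rrblup_marker_effects(np.zeros(30), M, ridge=1.0)
        assert np.allclose(me.effects, 0.0)

    def test_gblup_rrblup_duality(self, founders23):
        # GBLUP breeding values and RR-BLUP marker-effect predictions are the
        # same ridge estimator in different coordinates
        rng = np.random.default_rng(4)
        calls = founders23.haplotypes.astype(float)
        p = calls.mean(axis=0) / 2
        k = 2 * np.sum(p * (1 - p))
        beta = rng.normal(0, 0.02, calls.shape[1])
        y = (calls - 2 * p) @ beta + rng.normal(0, 0.5, calls.shape[0])

        G = gpred.additive_grm(calls, founders23.parents, ridge=0.0)
        s2g, s2e = 0.2, 0.1  # any positive pair; duality is an identity
        lam = s2e / (s2g / k)
        me = gpred.rrblup_marker_effects(y, calls, ridge=lam)
        pred_rr = me.predict(calls, p)

        V = s2g * G.values + s2e * np.eye(len(y))
        Vi = np.linalg.inv(V)
        ones = np.ones(len(y))
        mu = float((ones @ Vi @ y) / (ones @ Vi @ ones))
        gebv = mu + s2g * G.values @ Vi @ (y - mu)
        assert np.max(np.abs(pred_rr - gebv)) < 1e-6


class TestPredictNew:
    def test_duplicate_of_training_parent(self):
        u = pd.Series([0.1, -0.2, 0.05], index=["a", "b", "c"])
        A_train = np.eye(3)
        fit = _fake_fit(u)
        pred = gpred.predict_gre_new(fit, A_train[[1]], A_train)
        assert pred[0] == pytest.approx(-0.2)

    def test_orthogonal_individual_prior_mean(self):
        u = pd.Series([0.1, -0.2, 0.05], index=["a", "b", "c"])
        fit = _fake_fit(u)
        pred = gpred.predict_gre_new(fit, np.zeros((1, 3)), np.eye(3))
        assert pred[0] == 0.0

    def test_ril_midway_between_parents(self, founders23):
        # a RIL mixing two parents' genomes relates halfway to each, so its
        # predicted GRE approximates the parental mean
        rng = np.random.default_rng(8)
        calls = founders23.haplotypes
        A = gpred.additive_grm(calls, founders23.parents)
        g_true = rng.normal(0, 0.1, 23)
        u = pd.Series(A.values @ g_true * 0.05, index=founders23.parents)
        fit = _fake_fit(u)
        mask = rng.random(calls.shape[1]) < 0.5
        ril = np.where(mask, calls[0], calls[1])[None, :]
        A_cross = gpred.cross_relationship(ril, calls)
        pred = float(gpred.predict_gre_new(fit, A_cross, A.values)[0])
        expect = 0.5 * (u["P01"] + u["P02"])
        spread = np.abs(u.to_numpy()).mean()
        assert abs(pred - expect) < 0.35 * spread


def _fake_fit(u_gre):
    from recombkit.remodel import GREFit, VarianceComponents

    return GREFit(
        mu=np.array([0.0]), u_gre=u_gre, u_sre=pd.Series(dtype=float),
        vc=VarianceComponents(1.0, 0.0, 1.0), h2=0.5, mode="genomic",
    )


class TestGebv:
    def test_pair_count_formula_matches_enumeration(self):
        g = pd.Series(np.zeros(5), index=list("abcde"))
        table = gpred.predict_cross_gebv(g, mu=0.45)
        assert len(table) == gpred.n_hybrid_combinations(5) == 15
        assert (table["gebv"] == 0.45).all()

    def test_published_scale_count(self):
        assert gpred.n_hybrid_combinations(3959) == 7_838_820

    def test_ranking_invariant_to_constant_shift(self):
        rng = np.random.default_rng(5)
        g = pd.Series(rng.normal(size=6), index=list("abcdef"))
        t1 = gpred.predict_cross_gebv(g, mu=0.0)
        t2 = gpred.predict_cross_gebv(g + 3.0, mu=0.0)
        assert (t1["gebv"].rank() == t2["gebv"].rank()).all()


class TestPredictionAbility:
    def test_perfect_and_inverted(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert gpred.prediction_ability(x, x) == pytest.approx(1.0)
        assert gpred.prediction_ability(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_five_points(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        sx, sy = x - x.mean(), y - y.mean()
        expect = np.sum(sx * sy) / np.sqrt(np.sum(sx**2) * np.sum(sy**2))
        assert gpred.prediction_ability(x, y) == pytest.approx(expect)

    def test_affine_invariance_positive_slope(self):
        rng = np.random.default_rng(10)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r1 = gpred.prediction_ability(x, y)
        r2 = gpred.prediction_ability(x, 3.0 * y + 7.0)
        assert r1 == pytest.approx(r2)

    def test_zero_variance_warns_nan(self):
        with pytest.warns(UserWarning):
            out = gpred.prediction_ability(np.ones(5), np.arange(5.0))
        assert np.isnan(out)


class TestZouIntervals:
    def test_equal_correlations_contain_zero(self):
        lo, hi = gpred.zou_correlation_diff(0.5, 0.5, 50, 50)
        assert lo < 0 < hi

    def test_large_gap_excludes_zero(self):
        lo, hi = gpred.zou_correlation_diff(0.9, 0.1, 100, 100)
        assert lo > 0

    def test_endpoints_bounded(self):
        for r1, r2 in [(-0.95, 0.95), (0.99, -0.99), (0.0, 0.0)]:
            lo, hi = gpred.zou_correlation_diff(r1, r2, 10, 10)
            assert -2 < lo <= hi < 2

    def test_coverage_against_simulation(self):
        # simulated bivariate normals: the 95% interval for rho1 - rho2
        # should cover the true difference in most replicates
        rng = np.random.default_rng(14)
        rho1, rho2, n = 0.8, 0.3, 80
        cov1 = np.array([[1, rho1], [rho1, 1]])
        cov2 = np.array([[1, rho2], [rho2, 1]])
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            a = rng.multivariate_normal([0, 0], cov1, size=n)
            b = rng.multivariate_normal([0, 0], cov2, size=n)
            r1 = stats.pearsonr(a[:, 0], a[:, 1])[0]
            r2 = stats.pearsonr(b[:, 0], b[:, 1])[0]
            lo, hi = gpred.zou_correlation_diff(r1, r2, n, n)
            hits += lo <= (rho1 - rho2) <= hi
        assert 0.90 <= hits / n_rep <= 0.99

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            gpred.zou_correlation_diff(1.0, 0.5, 10, 10)
        with pytest.raises(ValidationError):
            gpred.zou_correlation_diff(0.5, 0.2, 3, 10)


class TestThinning:
    def test_bin_count_on_dense_panel(self):
        panel = pd.DataFrame({
            "marker": [f"m{i}" for i in range(7000)],
            "chrom": "c1",
            "pos": np.arange(7000) * 100_000,  # 700 Mbp dense
        })
        idx = gpred.thin_markers(panel, 10, np.random.default_rng(0))
        assert len(idx) == 70

    def test_same_bins_different_members_across_seeds(self):
        panel = pd.DataFrame({
            "marker": [f"m{i}" for i in range(300)],
            "chrom": "c1",
            "pos": np.arange(300) * 1_000_000,
        })
        i1 = gpred.thin_markers(panel, 5, np.random.default_rng(1))
        i2 = gpred.thin_markers(panel, 5, np.random.default_rng(2))
        assert len(i1) == len(i2) == 60
        assert not np.array_equal(i1, i2)
        bins1 = panel["pos"].to_numpy()[i1] // 5_000_000
        bins2 = panel["pos"].to_numpy()[i2] // 5_000_000
        assert np.array_equal(bins1, bins2)

    def test_empty_bins_skipped(self):
        panel = pd.DataFrame({
            "marker": ["a", "b"], "chrom": "c1", "pos": [0, 50_000_000],
        })
        idx = gpred.thin_markers(panel, 10, np.random.default_rng(0))
        assert len(idx) == 2


@pytest.fixture(scope="module")
def cv_inputs():
    rng = np.random.default_rng(30)
    f = simkit.generate_founders(12, simkit.BARLEY_CHROMOSOMES[:1], 2_000_000, seed=3)
    design = simkit.simulate_drr_design(f, (50, 50), seed=3, layout="double")
    A = gpred.additive_grm(f.haplotypes, f.parents)
    D = gpred.dominance_grm(design, A)
    beta = rng.normal(0, 1.0, f.haplotypes.shape[1])
    g_raw = f.haplotypes @ beta
    g = (g_raw - g_raw.mean()) / g_raw.std() * 0.05
    gvals = pd.Series(g, index=f.parents)
    rates = pd.Series(index=design.pop_ids, dtype=float)
    for c in design.crosses:
        rates[c.pop_id] = 0.45 + gvals[c.parent_i] + gvals[c.parent_j] + \
            rng.normal(0, 0.02)
    return rates, design, A, D, gvals


class TestCvStructure:
    def test_fivefold_partitions_exhaust_populations(self, cv_inputs):
        rates, design, A, D, g = cv_inputs
        res = gpred.cv_fivefold(rates, design, A, D, g, repeats=2, seed=1)
        for rep in (0, 1):
            sub = res.runs[res.runs["repeat"] == rep]
            assert sub["n_vs"].sum() == len(design.crosses)

    def test_same_seed_same_partitions(self, cv_inputs):
        rates, design, A, D, g = cv_inputs
        r1 = gpred.cv_fivefold(rates, design, A, D, g, repeats=2, seed=5)
        r2 = gpred.cv_fivefold(rates, design, A, D, g, repeats=2, seed=5)
        pd.testing.assert_frame_equal(r1.runs, r2.runs)

    def test_prediction_signal_detected(self, cv_inputs):
        rates, design, A, D, g = cv_inputs
        res = gpred.cv_fivefold(rates, design, A, D, g, repeats=3, seed=2)
        assert res.median_r_pg > 0.4
        assert res.median_r_gre > 0.4

    def test_leave_parents_out_shares_no_parents(self, cv_inputs):
        rates, design, A, D, g = cv_inputs
        res = gpred.cv_leave_parents_out(rates, design, A, D, g, n_par=3,
                                         repeats=10, seed=4)
        assert len(res.runs) > 0  # internal assertion checks disjointness per run

    def test_all_parents_out_rejected(self, cv_inputs):
        rates, design, A, D, g = cv_inputs
        with pytest.raises(ValidationError):
            gpred.cv_leave_parents_out(rates, design, A, D, g,
                                       n_par=len(design.parents), repeats=1, seed=0)
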