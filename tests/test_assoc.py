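"""Logistic fitting, likelihood-ratio tests, axis selection and the three
trend tests."""

import numpy as np
import pytest
from scipy import optimize, stats

from gwexpand import (
    MDSResult,
    fit_logistic,
    likelihood_ratio_test,
    run_three_tests,
    select_axes,
    simulate_replicate,
    trend_test,
)
from gwexpand.assoc import AssocResult
from gwexpand.ibs_mds import classical_mds, ibs_matrix


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1.0] * 25 + [0.0] * 75)
        fit = fit_logistic(y, np.ones((100, 1)))
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(np.log(0.25 / 0.75), abs=1e-8)
        ll = 100 * (0.25 * np.log(0.25) + 0.75 * np.log(0.75))
        assert fit.log_likelihood == pytest.approx(ll, abs=1e-8)

    def test_two_by_two_table_slope(self):
        # exposure counts (case, non-case) = (30, 70); unexposed (50, 50)
        y = np.array([1.0] * 30 + [0.0] * 70 + [1.0] * 50 + [0.0] * 50)
        x = np.array([1.0] * 100 + [0.0] * 100)
        fit = fit_logistic(y, np.column_stack([np.ones(200), x]))
        assert fit.coefficients[1] == pytest.approx(
            np.log((30 * 50) / (70 * 50)), abs=1e-8)

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        X = np.column_stack([np.ones(300), rng.standard_normal((300, 3))])
        y = (rng.random(300) < 1 / (1 + np.exp(-(X @ [0.2, 0.5, -0.3, 0.0])))
             ).astype(float)
        fit = fit_logistic(y, X)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-6)
        assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-8)

    def test_null_covariate_coefficient_near_zero(self, rng):
        n = 400
        x = rng.standard_normal(n)
        y = (rng.random(n) < 0.3).astype(float)  # independent of x
        X = np.column_stack([np.ones(n), x])
        fit = fit_logistic(y, X)
        # 3 SE from the inverse Fisher information at the MLE
        p = 1 / (1 + np.exp(-(X @ fit.coefficients)))
        cov = np.linalg.inv((X.T * (p * (1 - p))) @ X)
        assert abs(fit.coefficients[1]) < 3 * np.sqrt(cov[1, 1])

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="single value"):
            fit_logistic(np.ones(10), np.ones((10, 1)))

    def test_rank_deficiency_errors(self):
        y = np.array([0.0, 1.0] * 10)
        X = np.column_stack([np.ones(20), np.arange(20.0), 2 * np.arange(20.0)])
        with pytest.raises(ValueError, match="rank deficient"):
            fit_logistic(y, X)


class TestLikelihoodRatioTest:
    def test_identical_fits(self):
        y = np.array([0.0, 1.0] * 20)
        fit = fit_logistic(y, np.ones((40, 1)))
        stat, p = likelihood_ratio_test(fit, fit, 1)
        assert stat == 0.0 and p == 1.0

    def test_chi2_quantile(self):
        from gwexpand.assoc import LogisticFit
        a = LogisticFit(np.zeros(1), -10.0, True, 1)
        b = LogisticFit(np.zeros(2), -10.0 + 3.841459 / 2, True, 1)
        stat, p = likelihood_ratio_test(a, b, 1)
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_detects_optimizer_failure(self):
        from gwexpand.assoc import LogisticFit
        a = LogisticFit(np.zeros(1), -10.0, True, 1)
        b = LogisticFit(np.zeros(2), -11.0, True, 1)
        with pytest.raises(RuntimeError, match="optimizer failure"):
            likelihood_ratio_test(a, b, 1)


class TestSelectAxes:
    def test_empty_selection_at_t_max_zero(self, rng):
        mds = MDSResult(rng.standard_normal((50, 3)) * [3, 2, 1],
                        np.array([3.0, 2.0, 1.0]))
        y = np.array([1.0] * 20 + [0.0] * 30)
        sel = select_axes(y, mds, 0)
        assert sel.indicators.size == 0

    def test_null_retention_frequency(self):
        # independent y and axes: each z_t = 1 at ~ the selection level
        n, reps = 400, 2000
        hits = np.zeros(3)
        master = np.random.default_rng(88)
        for _ in range(reps):
            rng = np.random.default_rng(master.integers(2 ** 63))
            scores = rng.standard_normal((n, 3)) * np.array([3.0, 2.0, 1.0])
            mds = MDSResult(scores - scores.mean(0), np.array([3.0, 2.0, 1.0]))
            y = np.zeros(n)
            y[rng.choice(n, 100, replace=False)] = 1.0
            hits += select_axes(y, mds, 3, 0.05).indicators
        se = np.sqrt(0.05 * 0.95 / reps)
        for t in range(3):
            assert hits[t] / reps == pytest.approx(0.05, abs=3 * se)

    def test_structured_axis_retained(self):
        # axis 1 mirrors a two-population split with case enrichment in pop 1
        master = np.random.default_rng(99)
        retained = 0
        reps = 150
        for _ in range(reps):
            rng = np.random.default_rng(master.integers(2 ** 63))
            pop = np.repeat([0, 1], 200)
            axis1 = (pop - pop.mean()) / pop.std() + 0.1 * rng.standard_normal(400)
            scores = np.column_stack([axis1, rng.standard_normal(400)])
            scores = scores - scores.mean(0)
            mds = MDSResult(scores, np.array([2.0, 1.0]))
            p_case = np.where(pop == 0, 0.5, 0.25)
            y = (rng.random(400) < p_case).astype(float)
            if y.min() == y.max():
                continue
            retained += select_axes(y, mds, 2, 0.05).indicators[0]
        assert retained / reps > 0.99

    def test_conditional_vs_marginal_modes(self, rng):
        scores = rng.standard_normal((200, 3))
        mds = MDSResult(scores - scores.mean(0), np.array([3.0, 2.0, 1.0]))
        y = np.array([1.0] * 60 + [0.0] * 140)
        for mode in ("conditional", "marginal"):
            sel = select_axes(y, mds, 3, 0.05, mode=mode)
            assert sel.indicators.size == 3
        with pytest.raises(ValueError):
            select_axes(y, mds, 3, 0.05, mode="backward")


class TestTrendTest:
    def test_monomorphic_is_degenerate(self):
        y = np.array([1.0, 0.0] * 20)
        res = trend_test(y, np.ones(40))
        assert res.status == "degenerate"
        assert res.p_value == 1.0
        assert np.isnan(res.odds_ratio)

    def test_null_rejection_rate(self):
        # no-effect simulation: rejections at ~ the nominal 5% level
        reps, n = 2000, 200
        master = np.random.default_rng(300)
        rej = 0
        for _ in range(reps):
            rng = np.random.default_rng(master.integers(2 ** 63))
            g = rng.binomial(2, 0.3, n).astype(float)
            y = np.zeros(n)
            y[rng.choice(n, 50, replace=False)] = 1.0
            rej += trend_test(y, g).p_value < 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert rej / reps == pytest.approx(0.05, abs=3 * se)

    def test_or_matches_independent_optimizer(self, rng):
        n = 300
        g = rng.binomial(2, 0.25, n).astype(float)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 * g - 1.0)))).astype(float)
        res = trend_test(y, g)

        def negll(beta):
            eta = beta[0] + beta[1] * g
            return -np.sum(y * eta - np.log1p(np.exp(eta)))

        opt = optimize.minimize(negll, [0.0, 0.0], method="BFGS",
                                options={"gtol": 1e-12})
        assert res.odds_ratio == pytest.approx(np.exp(opt.x[1]), abs=1e-6)

    def test_orthogonal_covariate_stability(self, rng):
        n = 400
        g = rng.binomial(2, 0.3, n).astype(float)
        y = (rng.random(n) < 0.25).astype(float)
        base = trend_test(y, g)
        # build a covariate orthogonal to both y and g
        c = rng.standard_normal(n)
        M = np.column_stack([np.ones(n), y, g])
        c -= M @ np.linalg.lstsq(M, c, rcond=None)[0]
        adj = trend_test(y, g, c)
        assert abs(adj.lrt - base.lrt) < 0.1


@pytest.fixture(scope="module")
def pipeline(small_config):
    data = simulate_replicate(small_config)
    sim = ibs_matrix(data.null_genotypes)
    mds = classical_mds(sim, 3)
    return data, mds


class TestRunThreeTests:
    def test_empty_selection_makes_tfmds_equal_tf(self, pipeline):
        data, mds = pipeline
        # alpha_select=0 retains nothing, so the models are identical
        t_cc, t_f, t_fmds = run_three_tests(data, mds, 3, alpha_select=1e-12)
        assert t_fmds.axes_used == ()
        assert t_fmds.lrt == t_f.lrt
        assert t_fmds.p_value == t_f.p_value
        assert t_fmds.beta == t_f.beta

    def test_deterministic(self, small_config):
        outs = []
        for _ in range(2):
            data = simulate_replicate(small_config)
            mds = classical_mds(ibs_matrix(data.null_genotypes), 3)
            outs.append(run_three_tests(data, mds, 3, 0.05))
        for a, b in zip(*outs):
            assert a.lrt == b.lrt and a.p_value == b.p_value

    def test_axis_rescaling_invariance(self, pipeline):
        data, mds = pipeline
        _, _, base = run_three_tests(data, mds, 3, 0.05)
        scaled = MDSResult(mds.scores * np.array([10.0, 1.0, 0.01]),
                           mds.eigenvalues)
        _, _, res = run_three_tests(data, scaled, 3, 0.05)
        assert res.axes_used == base.axes_used
        assert res.lrt == pytest.approx(base.lrt, abs=1e-8)

    def test_tcc_uses_source_samples_only(self, pipeline):
        data, mds = pipeline
        t_cc, t_f, _ = run_three_tests(data, mds, 3, 0.05)
        assert t_cc.test == "T_CC" and t_f.test == "T_F"
        # T_CC and T_F fit different data, so equality would be suspicious
        assert t_cc.lrt != t_f.lrt

    def test_selection_strategy_all(self, pipeline):
        data, mds = pipeline
        _, _, t_fmds = run_three_tests(data, mds, 3, 0.05, selection="all")
        assert t_fmds.axes_used == (0, 1, 2)
        with pytest.raises(ValueError):
            run_three_tests(data, mds, 3, 0.05, selection="best-subset")


class TestLrtNullUniformity:
    def test_pvalues_uniform_under_null(self):
        # trend-test P-values from pure-noise data follow Uniform(0,1)
        reps, n = 2000, 150
        master = np.random.default_rng(777)
        pvals = []
        for _ in range(reps):
            rng = np.random.default_rng(master.integers(2 ** 63))
            g = rng.binomial(2, 0.4, n).astype(float)
            y = np.zeros(n)
            y[rng.choice(n, 40, replace=False)] = 1.0
            if g.min() == g.max():
                continue
            pvals.append(trend_test(y, g).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
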