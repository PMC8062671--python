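import math

import numpy as np
import pytest

from firestats.sizedist import (
    DegeneracyError,
    DistributionFit,
    FitError,
    MeanExcessCurve,
    _truncated_pareto_alpha,
    compare_families,
    fit_distribution,
    goodness_of_fit,
    mean_excess_curve,
    select_threshold,
)
from firestats.synthetic import sample_sizes


class TestFitting:
    def test_pareto_matches_hill_closed_form(self):
        x = np.array([1.0, 2.0, 4.0, 8.0] * 3)
        fit = fit_distribution(x, "pareto")
        beta = x.min()
        alpha = x.size / np.sum(np.log(x / beta))  # closed-form Hill estimator
        assert fit.scale == beta
        assert fit.shape == pytest.approx(alpha, rel=1e-12)

    def test_lognormal_closed_form_on_logs(self):
        rng = np.random.default_rng(1)
        x = np.exp(rng.normal(3.0, 0.5, 200))
        fit = fit_distribution(x, "lognormal")
        assert fit.shape == pytest.approx(np.mean(np.log(x)), rel=1e-12)
        assert fit.scale == pytest.approx(np.std(np.log(x)), rel=1e-12)

    def test_degenerate_sample_raises(self):
        with pytest.raises(DegeneracyError):
            fit_distribution([math.e] * 12, "lognormal")

    def test_nonpositive_sizes_rejected(self):
        with pytest.raises(FitError):
            fit_distribution([1.0] * 11 + [-2.0], "pareto")

    @pytest.mark.parametrize(
        "family,params",
        [
            ("pareto", {"alpha": 0.728, "beta": 61.935}),
            ("truncated_pareto", {"alpha": 0.482, "beta": 52.627, "h": 459000.0}),
            ("lognormal", {"alpha": 4.79, "beta": 1.83}),
            ("gamma", {"alpha": 0.8, "beta": 0.002}),
            ("weibull", {"alpha": 0.497, "beta": 319.241}),
        ],
    )
    def test_parameter_recovery_at_n5000(self, family, params):
        """Fitting data simulated from each family recovers its shape."""
        rng = np.random.default_rng(42)
        x = sample_sizes(family, params, 5000, rng)
        fit = fit_distribution(x, family)
        # generous factor-level check; tight 3-SE checks live in acceptance
        assert fit.shape == pytest.approx(params["alpha"], rel=0.10)

    def test_truncated_pareto_tends_to_pareto_as_h_grows(self):
        rng = np.random.default_rng(3)
        x = sample_sizes("pareto", {"alpha": 1.2, "beta": 10.0}, 2000, rng)
        hill = fit_distribution(x, "pareto").shape
        far_h = 1e12 * x.max()
        alpha = _truncated_pareto_alpha(x, float(x.min()), far_h)
        assert alpha == pytest.approx(hill, rel=1e-6)

    def test_log_transform_restricted_families(self):
        rng = np.random.default_rng(4)
        x = np.exp(rng.normal(4.0, 1.0, 100)) + 10
        fit = fit_distribution(x, "weibull", log_transform=True)
        assert fit.log_transformed
        with pytest.raises(ValueError):
            fit_distribution(x, "pareto", log_transform=True)


def _median_fit(value):
    """A lognormal fit whose CDF is exactly 0.5 at ``value``."""
    return DistributionFit(
        family="lognormal", shape=math.log(value), scale=1.0, loglik=-10.0, n=1, support_min=value
    )


class TestGoodnessOfFit:
    def test_single_point_ks_closed_form(self):
        gof = goodness_of_fit(_median_fit(2.0), [2.0])
        assert gof.ks == pytest.approx(0.5)

    def test_single_point_cvm_closed_form(self):
        gof = goodness_of_fit(_median_fit(2.0), [2.0])
        assert gof.cvm == pytest.approx(1.0 / 12.0)

    def test_aic_arithmetic(self):
        gof = goodness_of_fit(_median_fit(2.0), [2.0])
        assert gof.aic == pytest.approx(2 * 2 - 2 * (-10.0))  # = 24

    def test_ks_cvm_invariant_under_monotone_reparameterization(self):
        # squaring lognormal data doubles both log-parameters and leaves
        # every F(x_(i)) unchanged, hence identical statistics
        rng = np.random.default_rng(5)
        x = np.exp(rng.normal(2.0, 0.7, 300))
        fit = fit_distribution(x, "lognormal")
        fit_sq = DistributionFit(
            family="lognormal", shape=2 * fit.shape, scale=2 * fit.scale,
            loglik=fit.loglik, n=fit.n, support_min=float((x**2).min()),
        )
        g1, g2 = goodness_of_fit(fit, x), goodness_of_fit(fit_sq, x**2)
        assert g1.ks == pytest.approx(g2.ks, rel=1e-10)
        assert g1.cvm == pytest.approx(g2.cvm, rel=1e-10)


class TestMeanExcess:
    def test_exponential_mean_excess_is_flat_at_the_mean(self):
        rng = np.random.default_rng(6)
        scale = 3.0
        x = rng.exponential(scale, 20000)
        curve = mean_excess_curve(x, min_exceedances=500)
        # memorylessness: e(u) = scale for every u
        assert np.all(np.abs(curve.mean_excess - scale) < 0.5)
        w = np.sqrt(curve.n_exceed.astype(float))
        slope = np.polyfit(curve.thresholds, curve.mean_excess, 1, w=w)[0]
        assert abs(slope) < 0.05

    def test_pareto_mean_excess_slope(self):
        # Pareto shape 2: e(u) linear with slope 1/(alpha-1) = 1
        slopes = []
        for seed in range(5):
            rng = np.random.default_rng(600 + seed)
            x = sample_sizes("pareto", {"alpha": 2.0, "beta": 1.0}, 20000, rng)
            curve = mean_excess_curve(x, min_exceedances=200)
            w = np.sqrt(curve.n_exceed.astype(float))
            slopes.append(np.polyfit(curve.thresholds, curve.mean_excess, 1, w=w)[0])
        se = np.std(slopes, ddof=1) / math.sqrt(len(slopes))
        assert np.mean(slopes) == pytest.approx(1.0, abs=3 * se + 0.02)

    def test_top_threshold_with_single_exceedance(self):
        x = np.arange(1.0, 21.0)
        curve = mean_excess_curve(x, min_exceedances=1)
        # at u = 19 (second largest) the only exceedance is 20
        assert curve.thresholds[-1] == 19.0
        assert curve.mean_excess[-1] == pytest.approx(1.0)
        assert curve.n_exceed[-1] == 1

    def test_mean_excess_matches_brute_force(self):
        rng = np.random.default_rng(7)
        x = rng.lognormal(3, 1, 500)
        curve = mean_excess_curve(x, min_exceedances=20)
        for u, e, m in list(zip(curve.thresholds, curve.mean_excess, curve.n_exceed))[::50]:
            exc = x[x > u] - u
            assert m == exc.size
            assert e == pytest.approx(exc.mean())


class TestThresholdSelection:
    def test_exactly_linear_curve_returns_smallest_candidate(self):
        u = np.linspace(10, 1000, 60)
        curve = MeanExcessCurve(u, 2.0 * u + 5.0, np.full(60, 100))
        sel = select_threshold(curve, [100.0, 300.0, 500.0])
        assert sel.threshold == 100.0

    def test_constructed_change_point_recovered(self):
        u = np.linspace(0, 1000, 201)
        e = np.where(u < 500, 100.0, 100.0 + (u - 500))  # flat, then slope 1
        curve = MeanExcessCurve(u, e, np.full(u.size, 50))
        sel = select_threshold(curve, [float(c) for c in range(100, 1001, 50)])
        assert abs(sel.threshold - 500.0) <= 50.0
        assert sel.slope == pytest.approx(1.0, abs=0.05)

    def test_spliced_tail_scenario_recovers_graft_point(self):
        from firestats.sizedist import SELECTION_MIN_EXCEEDANCES
        rng = np.random.default_rng(8)
        x = sample_sizes(
            "spliced_lognormal_pareto",
            {"min_size": 10.0, "threshold": 500.0, "body_logmean": 5.0,
             "body_logsd": 0.8, "tail_alpha": 2.0, "p_tail": 0.1968},
            6000,
            rng,
        )
        curve = mean_excess_curve(x, min_exceedances=SELECTION_MIN_EXCEEDANCES)
        sel = select_threshold(curve, [float(c) for c in range(100, 2001, 50)])
        assert abs(sel.threshold - 500.0) <= 50.0

    def test_too_few_tail_points_raises(self):
        curve = MeanExcessCurve(np.array([1.0, 2.0]), np.array([1.0, 1.0]), np.array([5, 5]))
        with pytest.raises(FitError):
            select_threshold(curve, [10.0])


class TestCompareFamilies:
    def test_single_family_rejected(self):
        with pytest.raises(ValueError):
            compare_families(np.arange(1.0, 30.0), families=["pareto"])

    def test_ranking_invariant_to_data_order(self):
        rng = np.random.default_rng(9)
        x = rng.lognormal(4, 1.5, 400)
        a = compare_families(x)
        b = compare_families(rng.permutation(x))
        assert a.ranking == b.ranking

    def test_lognormal_data_ranks_lognormal_first_usually(self):
        wins = 0
        for rep in range(10):
            rng = np.random.default_rng(90 + rep)
            x = sample_sizes("lognormal", {"alpha": 4.79, "beta": 1.83}, 1000, rng)
            wins += compare_families(x).best("aic") == "lognormal"
        assert wins >= 8

    def test_failures_do_not_abort_other_families(self):
        x = np.full(20, 7.0)  # degenerate for everyone except nothing useful
        x[:10] = np.linspace(5, 9, 10)
        cmp = compare_families(x, families=["pareto", "lognormal"])
        assert set(f.family for f, _ in cmp.results) | set(cmp.failures) >= {"pareto", "lognormal"}
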