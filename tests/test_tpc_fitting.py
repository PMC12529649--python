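"""Fitting, AIC selection, bootstrap bands and critical thermal limits."""

import numpy as np
import pytest

from thermoniche.models import RR_PARAMS, model_family, pawar_rate
from thermoniche.tpc import (
    TPCFit,
    TPCFitError,
    aic,
    bootstrap_bands,
    fit_model,
    limits_sensitivity,
    select_best,
    thermal_limits,
)

PAWAR = model_family(["pawar"])[0]
GAUSSIAN = model_family(["gaussian"])[0]
TEMPS_15 = np.arange(12.0, 41.0, 2.0)


def _fit_like(n_params=3, aic_score=0.0):
    model = GAUSSIAN if n_params == 3 else PAWAR
    return TPCFit(model=model, theta=np.ones(model.n_params), rss=1.0,
                  n_points=10, aic=aic_score)


class TestAIC:
    def test_closed_form_value(self):
        assert aic(1.5, 15, 4) == pytest.approx(15 * np.log(0.1) + 10)

    def test_monotone_in_rss(self):
        assert aic(0.5, 15, 4) < aic(1.5, 15, 4)

    def test_extra_parameter_costs_two(self):
        assert aic(1.5, 15, 5) - aic(1.5, 15, 4) == pytest.approx(2.0)

    def test_perfect_fit_ranks_best(self):
        assert aic(0.0, 15, 4) == -np.inf

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            aic(-1.0, 15, 4)
        with pytest.raises(ValueError):
            aic(1.0, 0, 4)


class TestSelection:
    def test_single_fit_returned(self):
        fit = _fit_like(aic_score=3.0)
        assert select_best([fit]) is fit

    def test_lowest_aic_wins(self):
        a = _fit_like(aic_score=10.0)
        b = _fit_like(aic_score=12.0)
        assert select_best([b, a]) is a

    def test_tie_broken_by_fewer_parameters(self):
        p3 = TPCFit(model=GAUSSIAN, theta=np.ones(3), rss=1.0, n_points=10, aic=5.0)
        p4 = TPCFit(model=PAWAR, theta=np.ones(4), rss=1.0, n_points=10, aic=5.0)
        assert select_best([p4, p3]) is p3

    def test_empty_rejected(self):
        with pytest.raises(TPCFitError):
            select_best([])


class TestFitModel:
    def test_noiseless_self_consistency(self):
        """Fitting the generator's own noise-free rates recovers the
        parameters to < 0.1 % and rss to machine level."""
        rate = pawar_rate(TEMPS_15, RR_PARAMS)
        fit = fit_model(TEMPS_15, rate, PAWAR, n_starts=20, seed=5)
        assert fit.rss < 1e-10
        for got, true in zip(fit.theta, RR_PARAMS.as_array()):
            assert got == pytest.approx(true, rel=1e-3)

    def test_noisy_recovery_of_optimum(self, rng):
        true_rate = pawar_rate(TEMPS_15, RR_PARAMS)
        noisy = np.clip(true_rate + rng.normal(0.0, 0.05, TEMPS_15.size), 0.0, None)
        fit = fit_model(TEMPS_15, noisy, PAWAR, n_starts=20, seed=5)
        assert fit.parameters["t_opt"] == pytest.approx(RR_PARAMS.t_opt, abs=1.0)

    def test_underdetermined_data_rejected(self):
        t = np.array([10.0, 20.0, 30.0])
        with pytest.raises(TPCFitError, match="parameters"):
            fit_model(t, pawar_rate(t, RR_PARAMS), PAWAR)

    def test_negative_rates_rejected(self):
        t = np.linspace(12, 40, 10)
        with pytest.raises(TPCFitError):
            fit_model(t, np.full(10, -0.1), PAWAR)

    def test_shuffle_and_reseed_invariance(self, rng):
        t = np.repeat(TEMPS_15, 3)
        rate = np.clip(
            pawar_rate(t, RR_PARAMS) + rng.normal(0, 0.03, t.size), 0, None
        )
        order = rng.permutation(t.size)
        a = fit_model(t, rate, PAWAR, seed=17)
        b = fit_model(t[order], rate[order], PAWAR, seed=17)
        assert np.array_equal(a.theta, b.theta)
        assert a.rss == b.rss

    def test_multistart_matches_exhaustive_grid_search(self):
        """Oracle equivalence on a 3-parameter Gaussian TPC with 5 points:
        NLS lands within one 0.01 grid step of a brute-force search."""
        t = np.array([15.0, 22.0, 29.0, 33.0, 38.0])
        truth = np.array([1.0, 30.0, 5.0])
        rate = GAUSSIAN(t, truth) + np.array([0.02, -0.01, 0.015, -0.02, 0.01])
        step = 0.01
        rmax_g = np.arange(0.9, 1.1 + step / 2, step)
        topt_g = np.arange(29.0, 31.0 + step / 2, step)
        sig_g = np.arange(4.0, 6.0 + step / 2, step)
        R, O, S = np.meshgrid(rmax_g, topt_g, sig_g, indexing="ij")
        pred = R[..., None] * np.exp(
            -0.5 * ((t[None, None, None, :] - O[..., None]) / S[..., None]) ** 2
        )
        rss = np.sum((pred - rate) ** 2, axis=-1)
        i, j, l = np.unravel_index(np.argmin(rss), rss.shape)
        grid_best = np.array([rmax_g[i], topt_g[j], sig_g[l]])

        # bound the NLS search to the same box the grid covers
        box_model = model_family(["gaussian"])[0]
        fit = fit_model(t, rate, box_model, n_starts=30, seed=3)
        assert np.all(np.abs(fit.theta - grid_best) <= step + 1e-9)


@pytest.fixture(scope="module")
def noisy_fit():
    rng = np.random.default_rng(8)
    t = np.repeat(TEMPS_15, 3)
    rate = np.clip(
        pawar_rate(t, RR_PARAMS) + rng.normal(0, 0.04, t.size), 0, None
    )
    return t, rate, fit_model(t, rate, PAWAR, seed=8)


class TestBootstrap:
    def test_bands_bracket_point_prediction(self, noisy_fit):
        t, rate, fit = noisy_fit
        bands = bootstrap_bands(fit, t, rate, n_boot=60, seed=8)
        assert np.all(bands["lower"] <= bands["rate"] + 1e-12)
        assert np.all(bands["upper"] >= bands["rate"] - 1e-12)

    def test_zero_replicates_rejected(self, noisy_fit):
        t, rate, fit = noisy_fit
        with pytest.raises(ValueError):
            bootstrap_bands(fit, t, rate, n_boot=0)

    def test_determinism_given_seed(self, noisy_fit):
        t, rate, fit = noisy_fit
        a = bootstrap_bands(fit, t, rate, n_boot=30, seed=5)
        b = bootstrap_bands(fit, t, rate, n_boot=30, seed=5)
        assert np.array_equal(a["lower"], b["lower"])
        assert np.array_equal(a["upper"], b["upper"])

    def test_nominal_coverage_at_optimum(self):
        """Over repeated synthetic datasets the 95 % band should contain
        the true curve value at the optimum in roughly 95 % of runs."""
        truth = np.array([1.0, 30.0, 5.0])
        t = np.repeat(np.linspace(15.0, 40.0, 9), 3)
        true_at_opt = float(GAUSSIAN(np.array([30.0]), truth)[0])
        rng = np.random.default_rng(0)
        hits = 0
        n_runs = 40
        for _ in range(n_runs):
            rate = np.clip(GAUSSIAN(t, truth) + rng.normal(0, 0.08, t.size), 0, None)
            fit = fit_model(t, rate, GAUSSIAN, n_starts=5,
                            seed=int(rng.integers(2**31 - 1)))
            bands = bootstrap_bands(
                fit, t, rate, n_boot=120,
                seed=int(rng.integers(2**31 - 1)),
                grid=np.array([30.0]), n_starts=1,
            )
            if bands["lower"].iloc[0] <= true_at_opt <= bands["upper"].iloc[0]:
                hits += 1
        coverage = hits / n_runs
        assert 0.85 <= coverage <= 0.99


class TestThermalLimits:
    def test_printed_parameters_reproduce_printed_limits(self, rr_curve):
        lim = thermal_limits(rr_curve, threshold=0.098)
        assert round(lim.ctmax, 1) == 39.0
        assert round(lim.ctmin, 1) == 6.4

    def test_rate_ratio_at_limits_equals_threshold(self, rr_curve):
        lim = thermal_limits(rr_curve, threshold=0.098)
        peak = rr_curve.peak_rate()
        for t in (lim.ctmin, lim.ctmax):
            assert float(rr_curve.predict(t)) / peak == pytest.approx(
                0.098, abs=1e-6
            )

    def test_threshold_one_collapses_to_optimum(self, rr_curve):
        lim = thermal_limits(rr_curve, threshold=1.0)
        assert lim.ctmin == lim.ctmax == pytest.approx(RR_PARAMS.t_opt, abs=1e-3)

    @pytest.mark.parametrize("lo, hi", [(0.05, 0.098), (0.098, 0.15), (0.15, 0.5)])
    def test_monotone_in_threshold(self, rr_curve, lo, hi):
        a = thermal_limits(rr_curve, threshold=lo)
        b = thermal_limits(rr_curve, threshold=hi)
        assert b.ctmin > a.ctmin
        assert b.ctmax < a.ctmax

    def test_limits_bracket_optimum(self, rr_curve):
        lim = thermal_limits(rr_curve, threshold=0.098)
        assert lim.ctmin < RR_PARAMS.t_opt < lim.ctmax

    def test_no_sign_change_raises(self):
        # a very broad Gaussian never falls to half its peak on the interval
        fit = TPCFit(model=GAUSSIAN, theta=np.array([1.0, 20.0, 200.0]),
                     rss=0.1, n_points=10, aic=0.0)
        with pytest.raises(TPCFitError, match="sign change"):
            thermal_limits(fit, threshold=0.9)

    def test_invalid_threshold(self, rr_curve):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                thermal_limits(rr_curve, threshold=bad)

    def test_sensitivity_table(self, rr_curve):
        table = limits_sensitivity(rr_curve, (0.05, 0.098, 0.15))
        assert list(table["threshold"]) == [0.05, 0.098, 0.15]
        assert table["ctmin_C"].is_monotonic_increasing
        assert table["ctmax_C"].is_monotonic_decreasing
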