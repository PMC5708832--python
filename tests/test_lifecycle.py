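"""Smolting/survival curves, smolt-equivalents and transition-rate fits."""

import numpy as np
import pytest

from condsmolt import lifecycle as lc


class TestSmoltProbability:
    def test_half_at_threshold(self):
        assert float(lc.smolt_probability(120.0)) == pytest.approx(0.5)

    def test_direct_evaluation(self):
        assert float(lc.smolt_probability(130.0)) == pytest.approx(
            1 / (1 + np.exp(-1)), abs=1e-9
        )

    def test_logistic_limits_and_monotone(self):
        L = np.linspace(1.0, 1000.0, 2000)
        p = lc.smolt_probability(L)
        assert float(lc.smolt_probability(1.0)) < 1e-4
        assert float(lc.smolt_probability(1000.0)) > 1 - 1e-9
        assert np.all(np.diff(p) >= 0)
        assert np.all((p >= 0) & (p <= 1))


class TestMarineSurvival:
    def test_ceiling_applied(self):
        assert float(lc.marine_survival(300.0)) == pytest.approx(0.35)

    def test_direct_evaluation(self):
        expected = 0.84 / (1 + np.exp(8.657 - 0.0369 * 150))
        assert float(lc.marine_survival(150.0)) == pytest.approx(expected)
        assert expected == pytest.approx(0.0355, abs=2e-4)

    def test_lower_tail_near_zero(self):
        assert float(lc.marine_survival(1e-9)) == pytest.approx(
            0.84 / (1 + np.exp(8.657)), rel=1e-6
        )

    def test_monotone_bounded(self):
        L = np.linspace(1.0, 1000.0, 2000)
        s = lc.marine_survival(L)
        assert np.all(np.diff(s) >= 0)
        assert np.all((s >= 0) & (s <= 0.35 + 1e-12))


class TestCapBindingLength:
    def test_default_is_226(self):
        assert lc.cap_binding_length() == 226

    def test_half_asymptote_at_zero(self):
        p = lc.SurvivalParams(ceiling=0.42, asymptote=0.84, intercept=0.0, slope=1.0)
        assert lc.cap_binding_length(p) == 0

    def test_never_binding_rejected(self):
        with pytest.raises(ValueError):
            lc.cap_binding_length(
                lc.SurvivalParams(ceiling=0.9, asymptote=0.84, intercept=8.657, slope=0.0369)
            )

    def test_against_grid_scan_oracle(self, rng):
        # brute-force scan over integer lengths for random parameter sets
        for _ in range(100):
            asym = rng.uniform(0.3, 0.95)
            ceil_ = rng.uniform(0.05, asym * 0.95)
            icpt = rng.uniform(2.0, 12.0)
            slope = rng.uniform(0.01, 0.08)
            p = lc.SurvivalParams(ceiling=ceil_, asymptote=asym, intercept=icpt, slope=slope)
            grid = np.arange(0, 1001)
            logistic = asym / (1 + np.exp(icpt - slope * grid))
            hits = np.nonzero(logistic >= ceil_)[0]
            if hits.size == 0:
                continue
            assert lc.cap_binding_length(p) == int(hits[0])


class TestSmoltEquivalents:
    def test_per_fish_product_oracle(self):
        lengths = np.full(50, 120.0)
        expected = 0.5 * float(lc.marine_survival(120.0)) * 10_000
        assert lc.smolt_equivalents(lengths, 10_000) == pytest.approx(expected)

    def test_zero_abundance(self):
        assert lc.smolt_equivalents([100.0], 0.0) == 0.0

    def test_empty_lengths_with_abundance_rejected(self):
        with pytest.raises(ValueError):
            lc.smolt_equivalents([], 100.0)

    def test_length_shift_monotonicity(self, rng):
        lengths = rng.normal(110, 15, 200).clip(30)
        assert lc.smolt_equivalents(lengths + 20, 1000) > lc.smolt_equivalents(
            lengths, 1000
        )


def _inputs(n=10, seed=0, **kwargs):
    rng = np.random.default_rng(seed)
    years = np.arange(2000, 2000 + n)
    J = rng.uniform(1e4, 1e5, n)
    C = rng.uniform(500, 5000, n)
    return lc.CohortInputs(
        years=years,
        adults=np.zeros(n),
        wild=J,
        captive=C,
        wild_star=J * 0.01,
        captive_star=C * 0.1,
        **kwargs,
    )


class TestPredictAdults:
    def test_all_zero_predictors(self):
        inp = _inputs()
        inp.wild[:] = 0
        inp.captive[:] = 0
        _, pred = lc.predict_adults(inp, (0.5, 0.5), lc.FIXED_RATE)
        assert np.all(pred == 0)

    def test_hand_arithmetic(self):
        inp = lc.CohortInputs(
            years=np.array([1, 2, 3]),
            adults=np.zeros(3),
            wild=np.array([5_000.0, 10_000.0, 0.0]),
            captive=np.zeros(3),
        )
        years, pred = lc.predict_adults(inp, (0.01, 0.0), lc.FIXED_RATE)
        assert list(years) == [3]
        assert pred[0] == pytest.approx(0.01 * (0.53 * 10_000 + 0.47 * 5_000))
        assert pred[0] == pytest.approx(76.5)

    def test_linear_superposition_in_q(self, rng):
        inp = _inputs(seed=3)
        _, p1 = lc.predict_adults(inp, (0.3, 0.0), lc.FIXED_RATE)
        _, p2 = lc.predict_adults(inp, (0.0, 0.7), lc.FIXED_RATE)
        _, p12 = lc.predict_adults(inp, (0.3, 0.7), lc.FIXED_RATE)
        np.testing.assert_allclose(p1 + p2, p12, rtol=1e-12)

    def test_apparent_rate_ratio_printed_value(self):
        # magnitude of a negative captive coefficient relative to wild
        assert abs(-0.0433) / 0.0076 == pytest.approx(5.7, abs=0.05)


class TestFitTransitionRates:
    def test_exact_recovery_noise_free(self):
        inp = _inputs(n=12, seed=1)
        q_true = (1.178, 0.594)
        yrs, pred = lc.predict_adults(inp, q_true, lc.SIZE_CONDITIONAL)
        inp.adults[np.isin(inp.years, yrs)] = pred
        inp.adults[:2] = np.nan  # seed years unusable
        fit = lc.fit_transition_rates(inp, lc.SIZE_CONDITIONAL)
        np.testing.assert_allclose(fit.q, q_true, rtol=1e-9)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_unbiased_under_noise(self):
        inp = _inputs(n=18, seed=2)
        q_true = np.array([1.178, 0.594])
        yrs, pred = lc.predict_adults(inp, q_true, lc.SIZE_CONDITIONAL)
        mask = np.isin(inp.years, yrs)
        qs = []
        for rep in range(300):
            rng = np.random.default_rng(1000 + rep)
            inp.adults[mask] = pred + rng.normal(0, 30, pred.size)
            fit = lc.fit_transition_rates(inp, lc.SIZE_CONDITIONAL)
            qs.append(fit.q)
        bias = np.mean(qs, axis=0) - q_true
        mc_se = np.std(qs, axis=0) / np.sqrt(300)
        assert np.all(np.abs(bias) < 4 * mc_se)

    def test_negative_coefficient_allowed(self):
        inp = _inputs(n=12, seed=4)
        yrs, pred = lc.predict_adults(inp, (0.9, -0.4), lc.FIXED_RATE)
        inp.adults[np.isin(inp.years, yrs)] = pred
        fit = lc.fit_transition_rates(inp, lc.FIXED_RATE)
        assert fit.q[1] == pytest.approx(-0.4, rel=1e-6)

    def test_degenerate_captive_column_dropped(self):
        inp = _inputs(n=12, seed=5)
        inp.captive[:] = 0.0
        inp.captive_star[:] = 0.0
        yrs, pred = lc.predict_adults(inp, (1.0, 0.0), lc.SIZE_CONDITIONAL)
        inp.adults[np.isin(inp.years, yrs)] = pred
        with pytest.warns(UserWarning, match="degenerate captive"):
            fit = lc.fit_transition_rates(inp, lc.SIZE_CONDITIONAL)
        assert fit.dropped == ["captive"]
        assert np.isnan(fit.q[1])
        assert fit.q[0] == pytest.approx(1.0, rel=1e-9)

    def test_exclude_years(self):
        inp = _inputs(n=12, seed=6)
        yrs, pred = lc.predict_adults(inp, (1.0, 0.5), lc.SIZE_CONDITIONAL)
        inp.adults[np.isin(inp.years, yrs)] = pred
        fit = lc.fit_transition_rates(
            inp, lc.SIZE_CONDITIONAL, exclude_years=(int(yrs[0]),)
        )
        assert int(yrs[0]) not in fit.years


class TestDecomposeOrigin:
    def test_components_sum_to_prediction(self):
        inp = _inputs(n=14, seed=7)
        yrs, pred = lc.predict_adults(inp, (1.1, 0.6), lc.SIZE_CONDITIONAL)
        rng = np.random.default_rng(8)
        inp.adults[np.isin(inp.years, yrs)] = pred + rng.normal(0, 10, pred.size)
        fit = lc.fit_transition_rates(inp, lc.SIZE_CONDITIONAL)
        _, wild_pred, cap_pred = lc.decompose_origin(fit)
        np.testing.assert_allclose(wild_pred + cap_pred, fit.predictions, atol=1e-10)

    def test_no_captives_means_zero_captive_share(self):
        inp = _inputs(n=12, seed=9)
        inp.captive_star[:] = 0.0
        yrs, pred = lc.predict_adults(inp, (1.0, 0.0), lc.SIZE_CONDITIONAL)
        inp.adults[np.isin(inp.years, yrs)] = pred
        fit = lc.fit_transition_rates(inp, lc.SIZE_CONDITIONAL)
        _, _, cap_pred = lc.decompose_origin(fit)
        np.testing.assert_allclose(cap_pred, 0.0, atol=1e-12)
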