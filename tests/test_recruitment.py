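"""Density-regulation models, bias-correction arithmetic and length regressions."""

import warnings

import numpy as np
import pandas as pd
import pytest

from condsmolt import recruitment as rec
from condsmolt.synthetic_data import generate_recruitment_series


class TestPredictRecruitment:
    def test_proportional_product(self):
        spec = rec.model_spec("proportional")
        pred = rec.predict_recruitment(spec, {"r": 270.0}, [100.0])
        assert pred[0] == pytest.approx(27_000)

    def test_logistic_vertex(self):
        spec = rec.model_spec("logistic_capacity")
        K = 282_676.0
        # choose A so that r*A = K/2; prediction is K/4
        r = 272.5
        A = K / (2 * r)
        pred = rec.predict_recruitment(spec, {"r": r, "K": K}, [A])
        assert pred[0] == pytest.approx(K / 4)

    def test_logistic_approximates_proportional_at_low_abundance(self):
        spec = rec.model_spec("logistic_capacity")
        params = {"r": 272.5, "K": 282_676.0}
        A = np.array([1.0, 5.0, 10.0])
        pred = rec.predict_recruitment(spec, params, A)
        np.testing.assert_allclose(pred, params["r"] * A, rtol=0.01)

    def test_negative_prediction_floored_with_warning(self):
        spec = rec.model_spec("logistic_capacity")
        with pytest.warns(UserWarning, match="floored"):
            pred = rec.predict_recruitment(spec, {"r": 10.0, "K": 100.0}, [100.0])
        assert pred[0] == 0.0

    def test_translocation_term_added(self):
        spec = rec.model_spec("fixed_production_translocations")
        pred = rec.predict_recruitment(spec, {"K": 1000.0, "s": 0.5}, [7.0], [200.0])
        assert pred[0] == pytest.approx(1100.0)

    def test_parameter_counts_match_table_layout(self):
        assert rec.model_spec("fixed_production").k == 2
        assert rec.model_spec("proportional").k == 2
        assert rec.model_spec("logistic_capacity").k == 3
        assert rec.model_spec("fixed_production_translocations").k == 3
        assert rec.model_spec("logistic_capacity_translocations").k == 4


class TestFitRecruitment:
    def test_fixed_production_is_mean(self):
        J = np.array([100.0, 120.0, 80.0, 95.0, 105.0, 110.0])
        params, score = rec.fit_recruitment("fixed_production", J, np.ones(6))
        assert params["K"] == pytest.approx(J.mean(), rel=1e-6)
        assert score.k == 2

    def test_recovery_single_replicate(self):
        truth = {"r": 272.5, "K": 282_676.0, "s": 1.9}
        J, A, R = generate_recruitment_series(
            truth, "logistic_capacity_translocations", 18, seed=1, noise_cv=0.05
        )
        params, _ = rec.fit_recruitment(
            "logistic_capacity_translocations", J, A, R, seed=0
        )
        assert params["r"] == pytest.approx(truth["r"], rel=0.3)
        assert params["K"] == pytest.approx(truth["K"], rel=0.2)
        assert params["s"] == pytest.approx(truth["s"], rel=0.5)

    def test_local_optimality_against_random_vectors(self):
        truth = {"r": 200.0, "K": 150_000.0, "s": 1.0}
        J, A, R = generate_recruitment_series(
            truth, "logistic_capacity_translocations", 18, seed=3, noise_cv=0.1
        )
        spec = rec.model_spec("logistic_capacity_translocations")
        params, score = rec.fit_recruitment(
            "logistic_capacity_translocations", J, A, R, seed=0
        )
        rng = np.random.default_rng(0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(1000):
                trial = {
                    "r": rng.uniform(1, 1000),
                    "K": rng.uniform(1e4, 1e6),
                    "s": rng.uniform(0, 10),
                }
                rss = float(
                    np.sum((rec.predict_recruitment(spec, trial, A, R) - J) ** 2)
                )
                assert rss >= score.rss - 1e-6

    def test_logistic_degenerates_to_proportional_as_K_grows(self):
        spec_l = rec.model_spec("logistic_capacity")
        spec_p = rec.model_spec("proportional")
        A = np.linspace(10, 500, 20)
        pl = rec.predict_recruitment(spec_l, {"r": 272.5, "K": 1e12}, A)
        pp = rec.predict_recruitment(spec_p, {"r": 272.5}, A)
        np.testing.assert_allclose(pl, pp, rtol=1e-6)

    def test_ranking_covers_all_models(self):
        rng = np.random.default_rng(4)
        A = rng.uniform(50, 800, 18)
        R = rng.uniform(1e3, 2e4, 18)
        J = 5000.0 + rng.normal(0, 400, 18)  # flat production, no adult signal
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ranked, fitted = rec.fit_all_recruitment(J, A, R, seed=0)
        assert len(ranked) == 6
        assert ranked[0].delta == 0.0
        assert ranked[0].name.startswith("fixed_production")


class TestBiasCorrection:
    def test_printed_corrections(self):
        out = rec.bias_correct({"r": 272.5, "K": 282_676.0, "s": 1.9})
        assert round(out["r"]) == 193
        assert out["K"] == pytest.approx(734_000, abs=1000)
        assert out["s"] == pytest.approx(0.73, abs=0.005)

    def test_expected_wild_transition(self):
        assert rec.expected_wild_transition() == pytest.approx(1.43, abs=0.005)

    def test_shortfall_of_printed_estimate(self):
        assert rec.transition_shortfall(1.178) == pytest.approx(0.18, abs=0.005)

    def test_round_trip_identity(self):
        params = {"r": 123.4, "K": 9_999.0, "s": 0.42}
        corrected = rec.bias_correct(params)
        back = rec.bias_restore(corrected)
        for k, v in params.items():
            assert back[k] == pytest.approx(v, rel=1e-12)

    def test_invalid_constants_rejected(self):
        with pytest.raises(ValueError):
            rec.BiasConstants(adult_bias=0.2)


class TestLengthModels:
    def _data(self, seed, flow_effect=1.15, noise=3.0, n=18):
        rng = np.random.default_rng(seed)
        flow = rng.uniform(1, 15, n)
        adults = rng.uniform(50, 800, n)
        transloc = rng.uniform(2_000, 20_000, n)
        y = 67.82 + flow_effect * flow + rng.normal(0, noise, n)
        return pd.DataFrame(
            {
                "mean_length": y,
                "adults": adults,
                "translocations": transloc,
                "flow": flow,
            }
        )

    def test_flow_signal_recovered(self):
        ranked, fits = rec.fit_length_models(self._data(0))
        assert ranked[0].name in ("flow", "adults_flow", "translocations_flow")
        assert "flow" in ranked[0].extra["terms"]
        slope = fits["flow"].params[1]
        assert slope == pytest.approx(1.15, abs=0.6)

    def test_translocation_scaling_arithmetic(self):
        # a -0.0006 mm-per-fish coefficient is 0.6 mm lost per 1000 fish
        assert -(-0.0006) * 1000 == pytest.approx(0.6)

    def test_null_response_favors_intercept_only(self):
        wins = 0
        for seed in range(10):
            data = self._data(seed, flow_effect=0.0, noise=5.0)
            ranked, _ = rec.fit_length_models(data)
            by_name = {s.name: s for s in ranked}
            if by_name["intercept_only"].delta < 2.0:
                wins += 1
        assert wins >= 6

    def test_all_seven_models_fitted_with_intercepts(self):
        ranked, fits = rec.fit_length_models(self._data(1))
        assert {s.name for s in ranked} == set(rec.LENGTH_MODEL_TERMS)
        for name, terms in rec.LENGTH_MODEL_TERMS.items():
            assert fits[name].params.size == len(terms) + 1
        ks = {s.name: s.k for s in ranked}
        assert ks["intercept_only"] == 2 and ks["flow"] == 3 and ks["adults_flow"] == 4

    def test_condition_number_reported(self):
        ranked, _ = rec.fit_length_models(self._data(2))
        assert all(np.isfinite(s.extra["condition_number"]) for s in ranked)

    def test_too_few_years_rejected(self):
        with pytest.raises(ValueError):
            rec.fit_length_models(self._data(0, n=5))
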