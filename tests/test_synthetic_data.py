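"""Generator determinism, calibration targets and truth round-trips."""

import numpy as np
import pandas as pd
import pytest

from condsmolt import lifecycle as lc
from condsmolt import synthetic_data as sd


class TestScenarioConfig:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            sd.ScenarioConfig(yoy_fraction=0.0)
        with pytest.raises(ValueError):
            sd.ScenarioConfig(capture_prob=1.5)
        with pytest.raises(ValueError):
            sd.ScenarioConfig(channel_length_m=-1)
        with pytest.raises(ValueError):
            sd.ScenarioConfig(ocean_age_split=(0.6, 0.6))

    def test_round_trips_through_dict(self):
        cfg = sd.ScenarioConfig(seed=42, sites=("a", "b"))
        assert sd.ScenarioConfig.from_dict(cfg.to_dict()) == cfg


class TestLengthGeneration:
    def test_single_component_mean(self, rng):
        lengths, labels = sd.mixture_lengths([1.0], [75.0], [8.0], 100, rng)
        assert lengths.mean() == pytest.approx(75, abs=3 * 8 / 10)
        assert set(labels) == {0}

    def test_yoy_fraction_binomial_oracle(self):
        rng = np.random.default_rng(7)
        lengths, labels = sd.mixture_lengths(
            [0.77, 0.23], [75.0, 130.0], [9.0, 14.0], 300, rng
        )
        assert (labels == 0).mean() == pytest.approx(0.77, abs=0.06)

    def test_site_year_lengths_track_growth_truth(self):
        cfg = sd.ScenarioConfig(sites=("site_1",), cohort_n=80, seed=3)
        sample, truth = sd.generate_site_year_lengths(
            cfg, "site_1", 1998, density_per_m=2.0
        )
        assert sample.n == truth["n_total"]
        assert truth["component_weights"][0] == pytest.approx(0.77)
        # YOY component is centred on the simulated October outcome
        assert truth["component_means"][0] == pytest.approx(truth["oct_mean"])

    def test_zero_density_empty_sample_with_warning(self):
        cfg = sd.ScenarioConfig(sites=("site_1",), cohort_n=50, seed=3)
        with pytest.warns(UserWarning, match="zero target density"):
            sample, truth = sd.generate_site_year_lengths(
                cfg, "site_1", 1998, density_per_m=0.0
            )
        assert sample is None
        assert truth["n_total"] == 0


class TestDepletion:
    def test_empty_site(self):
        assert sd.generate_depletion_passes(0, 0.5, 3, 0) == (0, 0, 0)

    def test_certain_capture(self):
        assert sd.generate_depletion_passes(120, 1.0, 3, 0) == (120, 0, 0)

    def test_zero_capture_prob_rejected(self):
        with pytest.raises(ValueError):
            sd.generate_depletion_passes(100, 0.0, 3, 0)

    def test_binomial_expectation_oracle(self):
        counts = np.array(
            [sd.generate_depletion_passes(120, 0.5, 3, seed) for seed in range(500)]
        )
        np.testing.assert_allclose(counts.mean(axis=0), [60, 30, 15], atol=1.5)
        assert counts.sum(axis=1).max() <= 120


class TestTemperature:
    def test_constant_when_no_amplitude_no_noise(self):
        cfg = sd.ScenarioConfig(temp_amplitude=0.0, temp_noise_sd=0.0)
        t = sd.generate_temperature(cfg, cfg.sites[0], 2000)
        assert t["temp_C"].nunique() == 1
        assert t["temp_C"].iloc[0] == pytest.approx(cfg.temp_mean)

    def test_closed_form_extremes(self):
        cfg = sd.ScenarioConfig(temp_mean=14.0, temp_amplitude=6.0, temp_noise_sd=0.0)
        t = sd.generate_temperature(cfg, cfg.sites[0], 2000)["temp_C"]
        assert t.max() == pytest.approx(20.0, abs=0.01)
        assert t.min() == pytest.approx(8.0, abs=0.01)

    def test_default_summer_mostly_below_stress_band(self):
        cfg = sd.ScenarioConfig()
        t = sd.generate_temperature(cfg, cfg.sites[0], 2000)
        summer = t[t["date"].dt.month.isin([6, 7, 8, 9])]["temp_C"]
        assert (summer < 21.0).mean() > 0.9

    def test_spans_emergence_to_april(self):
        cfg = sd.ScenarioConfig()
        t = sd.generate_temperature(cfg, cfg.sites[0], 2001)
        assert t["date"].iloc[0] == pd.Timestamp(2001, 5, 1)
        assert t["date"].iloc[-1] == pd.Timestamp(2002, 4, 1)


class TestDensityField:
    def test_annual_cv_converges(self):
        # 200 replicate years, 9 sites: annual CV of the cross-site mean
        cfg = sd.ScenarioConfig(start_year=1800, end_year=1999, seed=5)
        dens = sd.generate_density_field(cfg)
        annual_mean = dens.mean(axis=1)
        cv = annual_mean.std() / annual_mean.mean()
        assert cv == pytest.approx(cfg.annual_cv, rel=0.2)

    def test_spatial_cv_converges(self):
        cfg = sd.ScenarioConfig(start_year=1800, end_year=1999, seed=5)
        dens = sd.generate_density_field(cfg)
        within = dens / dens.mean(axis=1, keepdims=True)
        cv = within.std(axis=1).mean()
        assert cv == pytest.approx(cfg.spatial_cv, rel=0.2)

    def test_mean_density_near_target(self):
        cfg = sd.ScenarioConfig(start_year=1700, end_year=1999, seed=2)
        dens = sd.generate_density_field(cfg)
        assert dens.mean() == pytest.approx(cfg.yoy_density_mean, rel=0.1)


class TestAnnualSeries:
    def test_zero_transitions_leave_noise_only(self):
        cfg = sd.ScenarioConfig(true_transitions=(0.0, 0.0), adult_noise_sd=10.0)
        n = len(cfg.years)
        adults = sd.generate_annual_series(
            cfg, np.full(n, 1e4), np.full(n, 1e3), rng=np.random.default_rng(0)
        )
        assert np.all(adults[2:] >= 0)
        assert adults[2:].max() < 100  # pure truncated noise

    def test_deterministic_linear_form_without_noise(self):
        cfg = sd.ScenarioConfig(adult_noise_sd=0.0)
        n = len(cfg.years)
        rng = np.random.default_rng(1)
        j_star = rng.uniform(100, 1000, n)
        c_star = rng.uniform(10, 300, n)
        adults = sd.generate_annual_series(cfg, j_star, c_star)
        q3, q4 = cfg.true_transitions
        for t in range(2, n):
            expected = q3 * (0.53 * j_star[t - 1] + 0.47 * j_star[t - 2]) + q4 * (
                0.53 * c_star[t - 1] + 0.47 * c_star[t - 2]
            )
            assert adults[t] == pytest.approx(expected)

    def test_declining_food_produces_lagged_adult_decline(self):
        cfg = sd.ScenarioConfig(
            sites=("site_1", "site_2"),
            cohort_n=60,
            seed=21,
            adult_noise_sd=0.0,
            annual_cv=0.0,
            spatial_cv=0.0,
            n_decline_sites=2,
        )
        ds = sd.generate_scenario(cfg)
        adults = ds.annual["adults"].to_numpy()[2:]
        third = len(adults) // 3
        assert adults[:third].mean() > 3 * adults[-third:].mean()


class TestScenarioDataset:
    def test_bit_identical_regeneration(self, small_config, small_dataset):
        again = sd.generate_scenario(small_config)
        pd.testing.assert_frame_equal(small_dataset.survey, again.survey)
        pd.testing.assert_frame_equal(small_dataset.annual, again.annual)
        pd.testing.assert_frame_equal(small_dataset.temperature, again.temperature)

    def test_every_site_year_has_passes(self, small_config, small_dataset):
        counts = small_dataset.survey.groupby(["site", "year"])["pass"].nunique()
        assert (counts >= 1).all()
        assert small_dataset.survey["pass"].between(1, 3).all()

    def test_truth_supports_recomputation(self, small_config, small_dataset):
        truth = small_dataset.truth
        assert sd.ScenarioConfig.from_dict(truth["config"]) == small_config
        ann = truth["annual"]
        # adult series reproduces the forward model applied to the truth series
        adults = sd.generate_annual_series(
            small_config,
            np.array(ann["J_star_true"]),
            np.array(ann["C_star_true"]),
            rng=None,
        )
        # noise stream differs, but the lag structure must match in expectation:
        # regenerate the whole scenario instead for the exact check
        again = sd.generate_scenario(small_config)
        np.testing.assert_allclose(
            again.truth["annual"]["adults"], ann["adults"], rtol=1e-12
        )
        assert adults.shape == np.asarray(ann["adults"]).shape

    def test_write_and_reload_round_trip(self, small_dataset, tmp_path):
        from condsmolt.io import load_dataset

        small_dataset.write(tmp_path)
        back = load_dataset(tmp_path)
        pd.testing.assert_frame_equal(small_dataset.survey, back.survey)
        pd.testing.assert_frame_equal(small_dataset.annual, back.annual)
        assert back.truth["config"]["seed"] == small_dataset.truth["config"]["seed"]

    def test_smolt_equivalents_consistent_with_lifecycle(self, small_dataset):
        truth = small_dataset.truth
        ann = truth["annual"]
        years = ann["years"]
        caps = small_dataset.captive_lengths
        releases = dict(zip(small_dataset.annual["year"], small_dataset.annual["captives_released"]))
        for i, y in enumerate(years[:3]):
            lens = caps.loc[caps["year"] == y, "length_mm"].to_numpy()
            expected = lc.smolt_equivalents(lens, releases[y])
            assert ann["C_star_true"][i] == pytest.approx(expected, rel=1e-9)
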