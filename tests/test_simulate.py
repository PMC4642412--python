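"""Tests for the synthetic cohort generator and its ground truth."""
import datetime as dt

import numpy as np
import pandas as pd
import pytest

from tailorpa.accel import detect_nonwear, pal_per_minute
from tailorpa.baecke import score_baecke
from tailorpa.energy import daily_pal
from tailorpa.simulate import (
    ConfigError,
    SimulationConfig,
    generate_profiles,
    simulate_baecke,
    simulate_minute_counts,
    true_pal_at,
)

WINDOW_START = dt.date(2013, 3, 4)


class TestConfig:
    def test_invalid_value_names_field(self):
        with pytest.raises(ConfigError, match="true_pal_sd"):
            SimulationConfig(true_pal_sd=-0.1).validate()
        with pytest.raises(ConfigError, match="n_participants"):
            SimulationConfig(n_participants=2).validate()
        with pytest.raises(ConfigError, match="nonwear_gap_rate"):
            SimulationConfig(nonwear_gap_rate=-1).validate()


class TestProfiles:
    def test_block_randomization_n4(self):
        prof = generate_profiles(SimulationConfig(n_participants=4, seed=1))
        assert sorted(prof["group"]) == ["L0", "L1", "L2", "L3"]

    def test_groups_balanced_in_blocks(self):
        prof = generate_profiles(SimulationConfig(n_participants=100, seed=2))
        assert prof["group"].value_counts().nunique() == 1

    def test_carrier_fraction_near_cohort_value(self):
        prof = generate_profiles(SimulationConfig(n_participants=1000, seed=7))
        carriers = prof["fto_genotype"].isin(["AA", "AT"]).mean()
        se = np.sqrt(0.693 * 0.307 / 1000)
        assert abs(carriers - 0.693) <= 3 * se

    def test_determinism(self):
        cfg = SimulationConfig(n_participants=50, seed=9)
        pd.testing.assert_frame_equal(generate_profiles(cfg), generate_profiles(cfg))

    def test_composition_targets(self):
        cfg = SimulationConfig(n_participants=2000, seed=3)
        prof = generate_profiles(cfg)
        assert (prof["age"] >= 18).all()
        assert (prof["weight"] > 0).all()
        assert abs((prof["sex"] == "female").mean() - cfg.female_fraction) < 0.04
        assert abs(prof["age"].mean() - cfg.age_mean) < 1.5
        bmi = prof["weight"] / (prof["height"] / 100) ** 2
        assert abs(bmi.mean() - cfg.bmi_mean) < 0.4
        assert abs(prof["true_pal"].mean() - 1.73) < 0.02
        assert abs(prof["true_pal"].std() - 0.18) < 0.02


class TestMinuteCounts:
    def profile(self):
        return {"id": "P1", "wearing_position": "belt", "sex": "male"}

    def test_eq1_round_trip_recovers_true_pal(self, rng, position_table):
        cfg = SimulationConfig(seed=4)
        sim = simulate_minute_counts(
            self.profile(), WINDOW_START, 14, cfg, 1.73, rng=rng
        )
        counts = sim.series.frame["counts"].to_numpy().reshape(14, 1440)
        daily = np.array([daily_pal(c.sum()) for c in counts])
        assert abs(daily.mean() - 1.73) <= 0.02

    def test_counts_shape_and_nonnegative(self, rng):
        cfg = SimulationConfig(seed=4)
        sim = simulate_minute_counts(self.profile(), WINDOW_START, 3, cfg, 1.7, rng=rng)
        assert sim.series.n_epochs == 3 * 1440
        assert (sim.series.frame["counts"] >= 0).all()

    def test_zero_gap_rate_gives_all_wear_truth(self, rng):
        cfg = SimulationConfig(seed=4, nonwear_gap_rate=0.0)
        sim = simulate_minute_counts(self.profile(), WINDOW_START, 7, cfg, 1.7, rng=rng)
        assert sim.wear_truth.all()

    def test_gap_minutes_are_subthreshold_pal(self, rng, position_table):
        cfg = SimulationConfig(seed=6)
        sim = simulate_minute_counts(self.profile(), WINDOW_START, 7, cfg, 1.7, rng=rng)
        gaps = ~sim.wear_truth
        if gaps.any():
            pal = pal_per_minute(
                sim.series.frame["counts"].to_numpy()[gaps], "belt", position_table
            )
            assert (pal < 1.3889).all()

    def test_detection_agrees_with_truth_mask(self, rng, position_table):
        cfg = SimulationConfig(seed=11)
        sim = simulate_minute_counts(self.profile(), WINDOW_START, 14, cfg, 1.73, rng=rng)
        pal = pal_per_minute(
            sim.series.frame["counts"].to_numpy(), "belt", position_table
        )
        detected = detect_nonwear(pal)
        agreement = (detected == sim.wear_truth).mean()
        assert agreement >= 0.95

    def test_weekend_ratio_one_is_symmetric(self):
        cfg = SimulationConfig(seed=5, weekend_activity_ratio=1.0, nonwear_gap_rate=0.0)
        weekday_means, weekend_means = [], []
        for s in range(12):
            sim = simulate_minute_counts(
                self.profile(), WINDOW_START, 14, cfg, 1.73,
                rng=np.random.default_rng(s),
            )
            counts = sim.series.frame["counts"].to_numpy().reshape(14, 1440)
            dates = [WINDOW_START + dt.timedelta(d) for d in range(14)]
            for d, c in zip(dates, counts):
                (weekend_means if d.isoweekday() >= 6 else weekday_means).append(c.mean())
        ratio = np.mean(weekend_means) / np.mean(weekday_means)
        assert abs(ratio - 1.0) < 0.08

    def test_weekend_ratio_below_one_lowers_weekend_counts(self):
        cfg = SimulationConfig(seed=5, weekend_activity_ratio=0.6, nonwear_gap_rate=0.0)
        sim = simulate_minute_counts(
            self.profile(), WINDOW_START, 14, cfg, 1.73,
            rng=np.random.default_rng(0),
        )
        counts = sim.series.frame["counts"].to_numpy().reshape(14, 1440)
        dates = [WINDOW_START + dt.timedelta(d) for d in range(14)]
        we = np.mean([c.mean() for d, c in zip(dates, counts) if d.isoweekday() >= 6])
        wd = np.mean([c.mean() for d, c in zip(dates, counts) if d.isoweekday() < 6])
        assert we < wd


class TestBaeckeGeneration:
    def test_calibrated_total_index_near_cohort_mean(self):
        cfg = SimulationConfig(seed=8, reporting_bias=0.0)
        totals = []
        for s in range(400):
            resp = simulate_baecke(
                {"employment_status": "employed"}, 1.73, cfg,
                rng=np.random.default_rng(s),
            )
            totals.append(score_baecke(resp).total_index)
        assert abs(np.mean(totals) - 7.8) < 0.5

    def test_reporting_bias_shifts_total_additively(self):
        cfg0 = SimulationConfig(seed=8, reporting_bias=0.0)
        cfg5 = SimulationConfig(seed=8, reporting_bias=0.5)
        def mean_total(cfg):
            vals = []
            for s in range(400):
                resp = simulate_baecke(
                    {"employment_status": "employed"}, 1.73, cfg,
                    rng=np.random.default_rng(s),
                )
                vals.append(score_baecke(resp).total_index)
            return np.mean(vals)
        diff = mean_total(cfg5) - mean_total(cfg0)
        assert 0.3 <= diff <= 0.7

    def test_total_index_monotone_in_true_pal(self):
        cfg = SimulationConfig(seed=8)
        def mean_total(pal):
            vals = []
            for s in range(300):
                resp = simulate_baecke(
                    {"employment_status": "employed"}, pal, cfg,
                    rng=np.random.default_rng(s),
                )
                vals.append(score_baecke(resp).total_index)
            return np.mean(vals)
        totals = [mean_total(p) for p in (1.5, 1.7, 1.9, 2.1)]
        assert all(a < b for a, b in zip(totals, totals[1:]))

    def test_unemployed_has_no_work_index(self):
        cfg = SimulationConfig(seed=8)
        resp = simulate_baecke(
            {"employment_status": "retired_or_unemployed"}, 1.73, cfg,
            rng=np.random.default_rng(0),
        )
        assert resp.employment_status == "retired_or_unemployed"
        assert score_baecke(resp).work_index is None

    def test_true_pal_domain_enforced(self):
        with pytest.raises(ConfigError):
            simulate_baecke({"employment_status": "employed"}, 2.6,
                            SimulationConfig(seed=1))


class TestInterventionEffects:
    def test_effects_shift_follow_up_truth(self):
        cfg = SimulationConfig(
            n_participants=400,
            seed=10,
            response_sd=0.0,
            effect_size_by_level={
                "L0": (0.0, 0.0),
                "L1": (0.05, 0.05),
                "L2": (0.05, 0.05),
                "L3": (0.05, 0.05),
            },
        )
        prof = generate_profiles(cfg)
        t0 = true_pal_at(prof, cfg, "baseline")
        t3 = true_pal_at(prof, cfg, "month3")
        personalized = prof["group"] != "L0"
        shift = (t3 - t0)[personalized]
        assert np.allclose(shift, 0.05)
        assert np.allclose((t3 - t0)[~personalized], 0.0)
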