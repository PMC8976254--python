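import numpy as np
import pandas as pd
import pytest

from sleepverse.errors import ConfigurationError
from sleepverse import synthetic as syn
from sleepverse.preprocess import SensorConfig, classify_events, clean_events
from sleepverse.windows import build_grids
from sleepverse.features import detect_bed_time

from oracles import brute_night_grid, brute_first_sleep_run


class TestParams:
    def test_bad_probability_names_field(self):
        with pytest.raises(ConfigurationError, match="sensor_flip_prob"):
            syn.SimulationParams(sensor_flip_prob=1.5)

    def test_negative_sd_rejected(self):
        with pytest.raises(ConfigurationError, match="accel_offset_sd"):
            syn.SimulationParams(accel_offset_sd=-1.0)

    def test_single_day_rejected(self):
        with pytest.raises(ConfigurationError, match="n_days"):
            syn.SimulationParams(n_days=1)

    def test_unknown_effect_feature_rejected(self):
        with pytest.raises(ConfigurationError, match="bogus"):
            syn.SimulationParams(effect_sizes={"ssq": {"bogus": 1.0}})

    def test_unknown_effect_outcome_rejected(self):
        with pytest.raises(ConfigurationError, match="happiness"):
            syn.SimulationParams(effect_sizes={"happiness": {"sleep_time": 1.0}})


class TestSchedules:
    def test_zero_interruption_rate(self):
        params = syn.SimulationParams(n_participants=3, n_days=3, interruption_rate=0.0)
        for s in syn.simulate_schedules(params):
            assert s.interruptions == ()

    def test_same_seed_identical(self):
        params = syn.SimulationParams(n_participants=3, n_days=3, seed=42)
        assert syn.simulate_schedules(params) == syn.simulate_schedules(params)

    def test_different_seed_differs(self):
        a = syn.simulate_schedules(syn.SimulationParams(n_participants=3, n_days=3, seed=1))
        b = syn.simulate_schedules(syn.SimulationParams(n_participants=3, n_days=3, seed=2))
        assert a != b

    def test_degenerate_bed_time(self):
        params = syn.SimulationParams(
            n_participants=3, n_days=3, bed_time_sd_hours=0.0, bed_time_mean_hour=23.0)
        for s in syn.simulate_schedules(params):
            assert s.bed_hours == 1.0
            assert s.true_bed_time.hour == 23

    def test_one_schedule_per_participant_night(self):
        params = syn.SimulationParams(n_participants=4, n_days=5)
        schedules = syn.simulate_schedules(params)
        keys = {(s.participant_id, s.night_date) for s in schedules}
        assert len(schedules) == len(keys) == 20

    def test_schedule_invariants(self):
        params = syn.SimulationParams(n_participants=5, n_days=10, seed=9,
                                      interruption_rate=3.0)
        for s in syn.simulate_schedules(params):
            assert 0 <= s.bed_hours < s.wake_hours <= 12.0
            last_end = s.bed_hours
            for start, dur in s.interruptions:
                assert start > last_end
                assert start + dur / 60 < s.wake_hours
                last_end = start + dur / 60


class TestSensorStreams:
    def test_noise_free_charging_true_during_sleep(self, noise_free_dataset):
        params, (schedules, events, _) = noise_free_dataset
        by_key = {(s.participant_id, s.night_date): s for s in schedules}
        charging = events[events["sensor"] == "charging"]
        for (pid, night), sched in by_key.items():
            start = pd.Timestamp(night) + pd.Timedelta(hours=22)
            sub = charging[(charging["participant_id"] == pid)
                           & (charging["timestamp"] >= start)
                           & (charging["timestamp"] < start + pd.Timedelta(hours=12))]
            hours = (sub["timestamp"] - start).dt.total_seconds().to_numpy() / 3600.0
            asleep = sched.asleep(hours)
            assert (sub["value"].to_numpy(dtype=bool) == asleep).all()

    def test_no_flash_means_no_short_screen_runs(self, noise_free_dataset):
        params, (schedules, events, _) = noise_free_dataset
        screen = events[events["sensor"] == "screen"]
        for pid, grp in screen.groupby("participant_id"):
            ts = grp["timestamp"].to_numpy()
            vals = grp["value"].to_numpy()
            for i in range(len(vals) - 1):
                if vals[i] == "on" and vals[i + 1] == "off":
                    assert (ts[i + 1] - ts[i]) / np.timedelta64(1, "s") >= 12

    def test_table_rules_recover_sleep_state_when_noise_free(self, noise_free_dataset):
        params, (schedules, events, _) = noise_free_dataset
        by_key = {(s.participant_id, s.night_date): s for s in schedules}
        cleaned, _ = clean_events(events)  # centering needed for accelerometer
        for config in [SensorConfig("accelerometer", 0.25), SensorConfig("light", 8.0),
                       SensorConfig("charging"), SensorConfig("activity"),
                       SensorConfig("wifi")]:
            classified = classify_events(cleaned, config)
            wrong = 0
            total = 0
            for (pid, night), sched in by_key.items():
                start = pd.Timestamp(night) + pd.Timedelta(hours=22)
                sub = classified[(classified["participant_id"] == pid)
                                 & (classified["timestamp"] >= start)
                                 & (classified["timestamp"] < start + pd.Timedelta(hours=12))]
                hours = (sub["timestamp"] - start).dt.total_seconds().to_numpy() / 3600.0
                asleep = sched.asleep(hours)
                sleeping = sub["sleeping"].to_numpy(dtype=bool)
                total += int(asleep.sum())
                wrong += int((asleep & ~sleeping).sum())
            # every in-sleep sampled instant classifies as sleeping
            assert total > 0
            assert wrong == 0, config.label

    def test_gaps_within_night_never_exceed_15_minutes(self, noise_free_dataset):
        params, (schedules, events, _) = noise_free_dataset
        sampled = events[events["sensor"].isin(["charging", "light", "wifi"])]
        for (pid, sensor), grp in sampled.groupby(["participant_id", "sensor"]):
            night = grp["timestamp"].dt.hour.isin(list(range(22, 24)) + list(range(0, 10)))
            ts = grp[night]["timestamp"]
            shifted = ts - pd.Timedelta(hours=22)
            for _, night_grp in ts.groupby(shifted.dt.date):
                gaps = night_grp.diff().dt.total_seconds().dropna() / 60.0
                assert (gaps <= 15.0 + 1 / 30).all()

    def test_requires_schedules(self):
        with pytest.raises(ValueError):
            syn.simulate_sensor_streams([], syn.SimulationParams())

    def test_deterministic(self):
        params = syn.SimulationParams(n_participants=2, n_days=2, seed=3)
        schedules = syn.simulate_schedules(params)
        a = syn.simulate_sensor_streams(schedules, params)
        b = syn.simulate_sensor_streams(schedules, params)
        pd.testing.assert_frame_equal(a, b)

    def test_noise_free_bed_time_matches_event_oracle(self, noise_free_dataset):
        """Pipeline BedTime (k=3) equals the value from a brute-force
        scan of the generated charging events."""
        params, (schedules, events, _) = noise_free_dataset
        cleaned, _ = clean_events(events)
        grids = build_grids(cleaned, SensorConfig("charging"))
        charging = cleaned[cleaned["sensor"] == "charging"]
        assert grids
        for g in grids:
            sub = charging[charging["participant_id"] == g.participant_id]
            t0 = pd.Timestamp("2024-01-01")
            times = (sub["timestamp"] - t0).dt.total_seconds().tolist()
            start = (pd.Timestamp(g.night_date) + pd.Timedelta(hours=22) - t0).total_seconds()
            oracle_states = brute_night_grid(
                times, [int(v) for v in sub["value"]], start, state_machine=True)
            expected_bed = brute_first_sleep_run(oracle_states, 3)
            assert detect_bed_time(g, 3) == expected_bed


class TestOutcomes:
    def test_constant_model(self):
        params = syn.SimulationParams(
            n_participants=3, n_days=3, noise_sd={o: 0.0 for o in syn.OUTCOMES},
            participant_intercept_sd=0.0, missing_ssq_prob=0.0)
        schedules = syn.simulate_schedules(params)
        outcomes = syn.simulate_outcomes(schedules, params)
        assert (outcomes.daily["ssq"] == 50.0).all()
        assert (outcomes.daily["na"] == 50.0).all()
        assert (outcomes.person["depression"] == 50.0).all()

    def test_noiseless_linear_determinism(self):
        params = syn.SimulationParams(
            n_participants=4, n_days=6, seed=2,
            effect_sizes={"ssq": {"sleep_time": 3.0}},
            noise_sd={o: 0.0 for o in syn.OUTCOMES},
            participant_intercept_sd=0.0, missing_ssq_prob=0.0)
        schedules = syn.simulate_schedules(params)
        outcomes = syn.simulate_outcomes(schedules, params)
        truth = syn.true_feature_table(schedules)
        truth["date"] = truth["night_date"].map(lambda d: d + pd.Timedelta(days=1).to_pytimedelta())
        merged = truth.merge(outcomes.daily, on=["participant_id", "date"])
        clipped = (merged["ssq"] <= 0) | (merged["ssq"] >= 100)
        sub = merged[~clipped]
        assert len(sub) >= 10
        assert sub["ssq"].corr(sub["sleep_time"]) == pytest.approx(1.0)

    def test_night_pairs_with_next_day(self):
        params = syn.SimulationParams(n_participants=2, n_days=3, missing_ssq_prob=0.0)
        schedules = syn.simulate_schedules(params)
        outcomes = syn.simulate_outcomes(schedules, params)
        nights = {s.night_date for s in schedules}
        days = set(outcomes.daily["date"])
        assert days == {n + pd.Timedelta(days=1).to_pytimedelta() for n in nights}

    def test_missing_ssq_fraction(self):
        params = syn.SimulationParams(n_participants=20, n_days=14, seed=4,
                                      missing_ssq_prob=0.3)
        schedules = syn.simulate_schedules(params)
        outcomes = syn.simulate_outcomes(schedules, params)
        frac = outcomes.daily["ssq"].isna().mean()
        assert 0.2 < frac < 0.4
        assert outcomes.daily["na"].notna().all()

    def test_one_depression_per_participant_with_gender(self):
        params = syn.SimulationParams(n_participants=10, n_days=3, seed=6)
        schedules = syn.simulate_schedules(params)
        outcomes = syn.simulate_outcomes(schedules, params)
        assert len(outcomes.person) == 10
        assert set(outcomes.person["gender"]) <= {"M", "F"}


class TestSlopeRecovery:
    def test_mixed_model_recovers_effect_in_most_replicates(self):
        """Known slope, moderate noise: the mixed-model estimate on the
        true features lands within 2 SE of truth in most replicates
        (small-n version of the full recovery experiment)."""
        import statsmodels.api as sm
        from statsmodels.regression.mixed_linear_model import MixedLM
        import warnings

        b = 4.0
        hits = 0
        n_rep = 10
        for seed in range(n_rep):
            params = syn.SimulationParams(
                n_participants=30, n_days=14, seed=seed,
                effect_sizes={"ssq": {"sleep_time": b}},
                noise_sd={"ssq": 8.0, "na": 8.0, "depression": 8.0},
                missing_ssq_prob=0.0)
            schedules = syn.simulate_schedules(params)
            outcomes = syn.simulate_outcomes(schedules, params)
            truth = syn.true_feature_table(schedules)
            truth["date"] = truth["night_date"].map(
                lambda d: d + pd.Timedelta(days=1).to_pytimedelta())
            df = truth.merge(outcomes.daily, on=["participant_id", "date"]).dropna(
                subset=["ssq"])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = MixedLM(df["ssq"].to_numpy(),
                              sm.add_constant(df["sleep_time"].to_numpy()),
                              groups=df["participant_id"].to_numpy()).fit()
            se = fit.bse[1]
            if abs(fit.params[1] - b) <= 2 * se:
                hits += 1
        assert hits >= 8
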