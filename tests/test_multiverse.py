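import numpy as np
import pandas as pd
import pytest

from sleepverse import multiverse as mv


class TestEnumerateGrid:
    def test_default_grid_is_12600(self):
        assert len(mv.enumerate_grid()) == 12600

    def test_one_outcome_is_4200(self):
        assert len(mv.enumerate_grid(outcomes=("ssq",))) == 4200

    def test_feature_outcome_pairs_21(self):
        assert len(mv.feature_outcome_pairs(mv.enumerate_grid())) == 21

    def test_deterministic_order_and_unique(self):
        grid1 = mv.enumerate_grid()
        grid2 = mv.enumerate_grid()
        assert grid1 == grid2
        assert len(set(grid1)) == len(grid1)


class TestSplitLongitudinal:
    def _rows(self, n_days=14, pid="p1", start="2024-03-05"):
        dates = pd.date_range(start, periods=n_days).date
        return pd.DataFrame({"participant_id": pid, "date": dates,
                             "sleep_time": np.arange(n_days, dtype=float)})

    def test_partition_exhaustive_disjoint(self):
        rows = self._rows()
        train, val, test = mv.split_longitudinal(rows)
        assert len(train) + len(val) + len(test) == len(rows)
        all_dates = set(train["date"]) | set(val["date"]) | set(test["date"])
        assert all_dates == set(rows["date"])
        assert set(train["date"]).isdisjoint(val["date"])
        assert set(val["date"]).isdisjoint(test["date"])

    def test_day8_validation_day12_test(self):
        rows = self._rows()
        train, val, test = mv.split_longitudinal(rows)
        day8 = rows.iloc[7]["date"]
        day12 = rows.iloc[11]["date"]
        assert day8 in set(val["date"])
        assert day12 in set(test["date"])
        assert len(train) == 7 and len(val) == 4 and len(test) == 3

    def test_per_participant_clock(self):
        rows = pd.concat([
            self._rows(pid="p1", start="2024-03-05"),
            self._rows(pid="p2", start="2024-03-08"),
        ]).reset_index(drop=True)
        train, val, test = mv.split_longitudinal(rows)
        p2_train = train[train["participant_id"] == "p2"]
        assert len(p2_train) == 7
        assert min(p2_train["date"]) == pd.Timestamp("2024-03-08").date()

    def test_short_span_errors(self):
        with pytest.raises(ValueError, match="14-day"):
            mv.split_longitudinal(self._rows(n_days=10))
        train, val, test = mv.split_longitudinal(self._rows(n_days=10), allow_short=True)
        assert len(test) == 0


class TestSplitDepression:
    def _participants(self, n_m=14, n_f=36):
        pids = [f"p{i:03d}" for i in range(n_m + n_f)]
        genders = ["M"] * n_m + ["F"] * n_f
        return pd.DataFrame({"participant_id": pids, "gender": genders,
                             "depression": 50.0})

    def test_stratified_counts_50_participants(self):
        rows = self._participants()
        train, val, test = mv.split_depression(rows, seed=0)
        assert (len(train), len(val), len(test)) == (30, 10, 10)
        assert (train["gender"] == "M").sum() == 8
        assert (val["gender"] == "M").sum() == 3
        assert (test["gender"] == "M").sum() == 3

    def test_same_seed_identical(self):
        rows = self._participants()
        a = mv.split_depression(rows, seed=5)
        b = mv.split_depression(rows, seed=5)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_single_gender_plain_split(self):
        rows = self._participants(n_m=0, n_f=10)
        train, val, test = mv.split_depression(rows, seed=1)
        assert (len(train), len(val), len(test)) == (6, 2, 2)

    def test_partition(self):
        rows = self._participants()
        train, val, test = mv.split_depression(rows, seed=2)
        combined = set(train["participant_id"]) | set(val["participant_id"]) | \
            set(test["participant_id"])
        assert combined == set(rows["participant_id"])


class TestBootstrapSE:
    def test_zero_residuals_zero_se(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        assert mv.bootstrap_r2_se(obs, obs, seed=0) == 0.0

    def test_deterministic(self, rng):
        obs = rng.normal(size=30)
        pred = obs + rng.normal(scale=0.5, size=30)
        assert mv.bootstrap_r2_se(obs, pred, seed=3) == \
            mv.bootstrap_r2_se(obs, pred, seed=3)

    def test_noisier_predictions_have_larger_se(self, rng):
        obs = rng.normal(size=200)
        tight = obs + rng.normal(scale=0.05, size=200)
        loose = obs + rng.normal(scale=1.0, size=200)
        assert mv.bootstrap_r2_se(obs, tight, seed=1) < \
            mv.bootstrap_r2_se(obs, loose, seed=1)


def _fake_result(r2_val, model="mixed_effects", feature="sleep_time",
                 sensor="charging", residual_scale=0.3, seed=0):
    rng = np.random.default_rng(seed)
    obs = rng.normal(size=40)
    pred = obs * np.sqrt(max(r2_val, 0)) if r2_val >= 0 else rng.normal(size=40)
    pred = obs - rng.normal(scale=residual_scale, size=40)
    config = mv.MultiverseConfig(sensor, feature, "ssq", model, "none", 3)
    r = mv.EvalResult(config=config, r2_validation=r2_val, r2_train=r2_val)
    r._val_obs, r._val_pred = obs, pred
    return r


class TestSelectOneSE:
    def test_single_result_selected(self):
        r = _fake_result(0.5)
        assert mv.select_one_se([r]) == [r]

    def test_cap_at_five(self):
        results = [_fake_result(0.5 - 0.001 * i, sensor=f"s{i}", residual_scale=2.0)
                   for i in range(10)]
        selected = mv.select_one_se(results, seed=0)
        assert len(selected) == 5
        assert selected[0].r2_validation == max(r.r2_validation for r in results)

    def test_zero_se_selects_exact_ties_only(self):
        best = _fake_result(0.9)
        best._val_pred = best._val_obs  # perfect fit -> SE 0
        tied = _fake_result(0.9, sensor="other")
        worse = _fake_result(0.899999, sensor="worse")
        selected = mv.select_one_se([best, tied, worse], seed=0)
        assert worse not in selected
        assert best in selected and tied in selected

    def test_all_inoperable_empty(self):
        r = _fake_result(0.5)
        r.status = "inoperable"
        assert mv.select_one_se([r]) == []

    def test_mixed_outcomes_rejected(self):
        a = _fake_result(0.5)
        b = _fake_result(0.4)
        b.config = mv.MultiverseConfig("charging", "sleep_time", "na",
                                       "mixed_effects", "none", 3)
        with pytest.raises(ValueError):
            mv.select_one_se([a, b])


@pytest.fixture(scope="module")
def small_sweep(tiny_dataset):
    _, events, outcomes = tiny_dataset
    data = mv.prepare_data(events, outcomes)
    configs = mv.enumerate_grid(
        sensors=["charging", "accelerometer_0.5"],
        features=("sleep_time", "total_sleep"),
        outcomes=("ssq",),
        model_kinds=("mixed_effects", "knn"),
        outlier_kinds=("none", "median_3mad"),
        ks=(3,),
    )
    results = mv.run_multiverse(configs, data, seed=0)
    return data, configs, results


class TestRunMultiverse:
    def test_one_result_per_config(self, small_sweep):
        _, configs, results = small_sweep
        assert len(results) == len(configs) == 16

    def test_missing_feature_table_inoperable(self, small_sweep):
        data, _, _ = small_sweep
        config = mv.MultiverseConfig("nonexistent", "sleep_time", "ssq",
                                     "mixed_effects", "none", 3)
        r = mv.run_config(config, data)
        assert r.status == "inoperable"

    def test_deterministic(self, small_sweep):
        data, configs, results = small_sweep
        again = mv.run_multiverse(configs, data, seed=0)
        pd.testing.assert_frame_equal(mv.results_frame(results),
                                      mv.results_frame(again))

    def test_order_independent(self, small_sweep):
        data, configs, results = small_sweep
        reversed_results = mv.run_multiverse(list(reversed(configs)), data, seed=0)
        a = mv.results_frame(results).sort_values(
            ["sensor", "feature", "model", "outlier"]).reset_index(drop=True)
        b = mv.results_frame(reversed_results).sort_values(
            ["sensor", "feature", "model", "outlier"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_no_leakage_between_splits(self, small_sweep):
        _, _, results = small_sweep
        for r in results:
            if r.status != "ok":
                continue
            fp = r._split_fingerprints
            assert fp["train"].isdisjoint(fp["validation"])
            assert fp["train"].isdisjoint(fp["test"])
            assert fp["validation"].isdisjoint(fp["test"])

    def test_workflow_selection_and_test_eval(self, small_sweep):
        data, configs, results = small_sweep
        selected = mv.select_one_se(
            [r for r in results if r.config.outcome == "ssq"], seed=0)
        assert 1 <= len(selected) <= 5
        final = mv.evaluate_selected(selected)
        assert len(final) == len(selected)
        assert final["r2_test"].notna().all()
        # test R2 appears only on selected configs
        frame = mv.results_frame(results)
        assert frame["r2_test"].notna().sum() == sum(
            1 for r in results if r.r2_test is not None)
        for r in results:
            if r not in selected:
                assert r.r2_test is None
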