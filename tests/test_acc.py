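"""Burst validation, feature extraction, SVM classification, budgets."""

import numpy as np
import pandas as pd
import pytest

from hogwatch import acc, synthetic


def sine_burst(freq_hz, n=250, rate=100.0, axis=0, amplitude=1.0):
    t = np.arange(n) / rate
    burst = np.zeros((n, 3))
    burst[:, axis] = amplitude * np.sin(2 * np.pi * freq_hz * t)
    burst[:, 2] += 1.0
    return burst


class TestValidateBursts:
    def test_complete_bursts_retained_truncated_removed(self, rng):
        samples = rng.normal(size=(10, 250, 3)).astype(np.float32)
        n_valid = np.full(10, 250)
        samples[3, 200:] = np.nan
        n_valid[3] = 200
        samples[7, 249:] = np.nan   # a single missing sample is enough
        n_valid[7] = 249
        meta = pd.DataFrame({"individual_id": "a",
                             "start_timestamp": pd.date_range(
                                 "2016-08-20", periods=10, freq="1min"),
                             "n_valid": n_valid})
        table = synthetic.BurstTable(meta=meta, samples=samples)
        kept, n_removed = acc.validate_bursts(table, 250)
        assert n_removed == 2 and len(kept) == 8
        assert (kept.meta["n_valid"] == 250).all()

    def test_generator_truncation_count_recovered(self):
        cfg = synthetic.small_config(seed=13)
        sched = synthetic.make_schedule(cfg, individuals=["ctrl_f1"], n_days=1)
        bursts = synthetic.simulate_acc(sched[sched["treatment"] == "pre"],
                                        cfg, truncation_rate=0.05)
        k = int((bursts.meta["n_valid"] < 250).sum())
        _, n_removed = acc.validate_bursts(bursts, 250)
        assert n_removed == k


class TestCompleteDays:
    @pytest.mark.parametrize("n_minutes,kept", [(1440, True), (1430, True),
                                                (1429, False)])
    def test_day_completeness_threshold(self, n_minutes, kept):
        ts = pd.date_range("2016-08-20 00:00", periods=n_minutes, freq="1min")
        frame = pd.DataFrame({"individual_id": "a", "start_timestamp": ts})
        retained, dropped = acc.filter_complete_days(frame)
        assert (len(retained) == n_minutes) is kept
        assert (len(dropped) == 0) is kept


class TestFeatures:
    def test_all_zero_burst(self):
        vec, flags = acc.extract_features(np.zeros((250, 3)))
        assert np.allclose(vec, 0.0)
        assert "constant_axis" in flags

    def test_exactly_25_named_features(self):
        assert len(acc.FEATURE_NAMES) == 25
        vec, _ = acc.extract_features(sine_burst(2.0))
        assert vec.shape == (25,) and np.isfinite(vec).all()

    def test_dominant_frequency_of_pure_sine(self):
        vec, _ = acc.extract_features(sine_burst(2.0, n=250))
        names = list(acc.FEATURE_NAMES)
        assert vec[names.index("x_domfreq_hz")] == pytest.approx(2.0, abs=0.4)
        # frequency resolution is the only burst-length dependence
        vec264, _ = acc.extract_features(sine_burst(2.0, n=264))
        assert vec264[names.index("x_domfreq_hz")] == pytest.approx(2.0, abs=0.4)

    def test_amplitude_scaling_doubles_sd_and_odba_not_correlations(self, rng):
        burst = rng.normal(0, 0.3, size=(250, 3)) + [0, 0, 1.0]
        v1, _ = acc.extract_features(burst)
        v2, _ = acc.extract_features(burst * 2)
        names = list(acc.FEATURE_NAMES)
        for nm in ("x_sd", "y_sd", "z_sd", "odba_mean"):
            assert v2[names.index(nm)] == pytest.approx(2 * v1[names.index(nm)])
        for nm in ("corr_xy", "corr_xz", "corr_yz"):
            assert v2[names.index(nm)] == pytest.approx(v1[names.index(nm)])

    def test_extraction_is_pure(self, rng):
        burst = rng.normal(size=(250, 3))
        v1, _ = acc.extract_features(burst)
        v2, _ = acc.extract_features(burst)
        assert np.array_equal(v1, v2)


class TestClassifier:
    def test_well_separated_clusters_learned(self, rng):
        X = np.vstack([rng.normal(c, 0.05, size=(60, 25))
                       for c in (0.0, 1.0, 2.0)])
        y = np.repeat(["resting", "balling", "walking"], 60)
        model = acc.train_classifier(X, y, seed=0)
        labels = acc.classify(model, X)
        assert (labels["label"] == y).mean() >= 0.99

    def test_label_permutation_gives_chance_accuracy(self, rng):
        X = np.vstack([rng.normal(c, 0.05, size=(60, 25))
                       for c in (0.0, 1.0, 2.0)])
        y = rng.permutation(np.repeat(["resting", "balling", "walking"], 60))
        model = acc.train_classifier(X, y, seed=0)
        labels = acc.classify(model, X, threshold=0.0)
        assert (labels["label"] == y).mean() == pytest.approx(1 / 3, abs=0.12)

    def test_single_class_input_is_an_error(self, rng):
        X = rng.normal(size=(30, 25))
        with pytest.raises(ValueError, match="two behaviour classes"):
            acc.train_classifier(X, ["resting"] * 30, seed=0)

    def test_serialised_model_predicts_identically(self, tmp_path,
                                                   trained_behaviour_model):
        model, _train, test = trained_behaviour_model
        X = test[list(acc.FEATURE_NAMES)].to_numpy()[:100]
        model.save(tmp_path / "m.joblib")
        reloaded = acc.BehaviourModel.load(tmp_path / "m.joblib")
        assert np.array_equal(model.predict_proba(X), reloaded.predict_proba(X))


class DummyModel:
    """Fixed-probability stub for the threshold rule."""

    classes = np.array(["balling", "resting", "walking"])

    def __init__(self, proba):
        self._proba = np.asarray(proba)

    def predict_proba(self, X):
        return np.tile(self._proba, (len(X), 1))


class TestThresholdRule:
    def test_confident_maximum_keeps_its_class(self):
        labels = acc.classify(DummyModel([0.8, 0.1, 0.1]), np.zeros((3, 25)))
        assert (labels["label"] == "balling").all()

    def test_sub_threshold_maximum_becomes_other(self):
        labels = acc.classify(DummyModel([0.5, 0.3, 0.2]), np.zeros((3, 25)))
        assert (labels["label"] == acc.OTHER_LABEL).all()

    def test_exactly_at_threshold_is_kept(self):
        labels = acc.classify(DummyModel([0.7, 0.2, 0.1]), np.zeros((2, 25)))
        assert (labels["label"] == "balling").all()

    def test_threshold_zero_never_other(self):
        labels = acc.classify(DummyModel([0.4, 0.35, 0.25]),
                              np.zeros((5, 25)), threshold=0.0)
        assert (labels["label"] != acc.OTHER_LABEL).all()


class TestBudgets:
    def _labels(self, counts):
        rows = []
        t0 = pd.Timestamp("2016-08-20 00:00")
        i = 0
        for label, n in counts.items():
            for _ in range(n):
                rows.append({"individual_id": "a",
                             "timestamp": t0 + pd.Timedelta(minutes=i),
                             "label": label})
                i += 1
        return pd.DataFrame(rows)

    def test_all_resting_day(self):
        b = acc.behaviour_budget(self._labels({"resting": 1440}))
        assert b.loc[0, "resting"] == 1.0 and b.loc[0, "n_bursts"] == 1440

    def test_even_split(self):
        b = acc.behaviour_budget(self._labels({"resting": 720, "walking": 720}))
        assert b.loc[0, "resting"] == 0.5 and b.loc[0, "walking"] == 0.5

    def test_budgets_sum_to_one(self, trained_behaviour_model):
        model, _train, test = trained_behaviour_model
        labels = acc.classify(model, test[list(acc.FEATURE_NAMES)].to_numpy(),
                              timestamps=test["start_timestamp"],
                              individual_ids=test["individual_id"])
        budgets = acc.behaviour_budget(labels)
        props = budgets.drop(columns=["individual_id", "day", "n_bursts"])
        assert np.allclose(props.sum(axis=1), 1.0, atol=1e-9)

    def test_minute_level_state_recovery(self, trained_behaviour_model):
        model, _train, test = trained_behaviour_model
        labels = acc.classify(model, test[list(acc.FEATURE_NAMES)].to_numpy())
        assert (labels["label"].to_numpy()
                == test["true_state"].to_numpy()).mean() >= 0.90
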