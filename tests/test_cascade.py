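import numpy as np
import pandas as pd
import pytest

from ahcascade import (
    AH,
    N,
    UNKNOWN,
    FEATURE_NAMES,
    REDUCED_FEATURES,
    LabelSequence,
    crossvalidate,
    load_model,
    predict_60,
    predict_cascade,
    save_model,
    train_cascade,
)
from ahcascade.cascade import SchemaError, gate_mask, _inverse_ratio_weights


def make_table(n, window_s, rng, separation=4.0, ah_frac=0.3, recording="r0"):
    """Linearly separable synthetic feature table: AH rows shifted up."""
    labels = np.where(rng.random(n) < ah_frac, AH, N)
    data = rng.normal(0, 1, (n, len(FEATURE_NAMES)))
    data[labels == AH] += separation
    df = pd.DataFrame(data, columns=FEATURE_NAMES)
    df.insert(0, "recording", recording)
    df.insert(1, "start_s", np.arange(n))
    df.insert(2, "window_s", window_s)
    df.insert(3, "label", labels)
    return df


@pytest.fixture(scope="module")
def tables():
    rng = np.random.default_rng(0)
    return make_table(400, 60, rng), make_table(450, 10, rng)


@pytest.fixture(scope="module")
def model(tables):
    return train_cascade(*tables, seed=0)


class TestTraining:
    def test_inverse_ratio_class_weights(self):
        labels = pd.Series([AH] * 10 + [N] * 90)
        w = _inverse_ratio_weights(labels)
        assert w[AH] / w[N] == pytest.approx(9.0)

    def test_tree_counts(self, model):
        assert model.detector60.n_estimators == 10
        assert model.detector10.n_estimators == 20
        assert model.features_60 == REDUCED_FEATURES

    def test_single_class_labels_rejected(self, tables):
        t60, t10 = tables
        bad = t60.copy()
        bad["label"] = N
        with pytest.raises(ValueError, match="single class"):
            train_cascade(bad, t10, seed=0)

    def test_same_seed_same_predictions(self, tables):
        t60, t10 = tables
        rng = np.random.default_rng(99)
        held = make_table(100, 10, rng)
        p1 = train_cascade(t60, t10, seed=5).detector10.predict(held[FEATURE_NAMES])
        p2 = train_cascade(t60, t10, seed=5).detector10.predict(held[FEATURE_NAMES])
        np.testing.assert_array_equal(p1, p2)

    def test_separable_data_high_heldout_accuracy(self, tables, model):
        held = make_table(300, 10, np.random.default_rng(123))
        pred = model.detector10.predict(held[FEATURE_NAMES])
        assert np.mean(pred == held["label"]) > 0.95

    def test_model_round_trip(self, model, tables, tmp_path):
        save_model(model, tmp_path / "m.joblib")
        back = load_model(tmp_path / "m.joblib")
        _, t10 = tables
        np.testing.assert_array_equal(
            back.detector10.predict(t10[FEATURE_NAMES]),
            model.detector10.predict(t10[FEATURE_NAMES]),
        )


class TestPredict60:
    def test_missing_column_schema_error(self, model, tables):
        t60, _ = tables
        with pytest.raises(SchemaError, match="Spdum"):
            predict_60(model, t60.drop(columns=["Spdum"]))

    def test_prediction_deterministic(self, model, tables):
        t60, _ = tables
        np.testing.assert_array_equal(predict_60(model, t60), predict_60(model, t60))

    def test_event_free_night_mostly_n(self, model):
        rng = np.random.default_rng(42)
        quiet = make_table(400, 60, rng, ah_frac=0.0)
        pred = predict_60(model, quiet)
        assert np.mean(pred == AH) < 0.05


class TestGating:
    def test_contain_rule_geometry(self):
        gate = gate_mask(np.array([100]), 200, "contain")
        assert gate[100:151].all()
        assert not gate[99] and not gate[151]

    def test_overlap_rule_geometry(self):
        gate = gate_mask(np.array([100]), 200, "overlap")
        assert gate[91:160].all()
        assert not gate[90] and not gate[160]

    def test_all_n_screen_closes_gate(self, tables, model):
        t60, t10 = tables
        quiet60 = t60.copy()
        quiet60[FEATURE_NAMES] = -10.0  # far into the N side
        seq = predict_cascade(model, quiet60, t10)
        assert not np.any(seq.labels == AH)

    def test_open_gate_equals_raw_detector10(self, tables, model):
        t60, t10 = tables
        loud60 = t60.copy()
        loud60[FEATURE_NAMES] = 10.0  # every 60-s window screened in
        seq = predict_cascade(model, loud60, t10)
        raw = model.detector10.predict(t10[FEATURE_NAMES])
        starts = t10["start_s"].to_numpy(int)
        gate = gate_mask(np.arange(len(loud60)), len(seq.labels), "contain")
        covered = gate[starts]
        np.testing.assert_array_equal(seq.labels[starts[covered]], raw[covered])

    def test_cascade_ah_subset_of_raw_detector10(self, tables, model):
        t60, t10 = tables
        seq = predict_cascade(model, t60, t10)
        raw = model.detector10.predict(t10[FEATURE_NAMES])
        starts = t10["start_s"].to_numpy(int)
        cascade_ah = set(starts[seq.labels[starts] == AH])
        raw_ah = set(starts[raw == AH])
        assert cascade_ah <= raw_ah

    def test_mixed_recordings_rejected(self, tables, model):
        t60, t10 = tables
        other = t10.copy()
        other["recording"] = "r1"
        with pytest.raises(ValueError, match="mix"):
            predict_cascade(model, t60, other)

    def test_unusable_starts_marked_unknown(self, tables, model):
        t60, t10 = tables
        sparse = t10[t10["start_s"] % 7 != 0]
        seq = predict_cascade(model, t60, sparse, n_starts_10=450)
        missing = np.arange(0, 450, 7)
        assert all(seq.labels[missing] == UNKNOWN)


class TestCrossvalidate:
    def make_cohort_tables(self, n_rec=4, seed=0):
        rng = np.random.default_rng(seed)
        t60 = pd.concat(
            [make_table(120, 60, rng, recording=f"r{i}") for i in range(n_rec)],
            ignore_index=True,
        )
        t10 = pd.concat(
            [make_table(170, 10, rng, recording=f"r{i}") for i in range(n_rec)],
            ignore_index=True,
        )
        return t60, t10

    def test_each_segment_predicted_exactly_once(self):
        t60, t10 = self.make_cohort_tables()
        cv = crossvalidate(t60, t10, seed=3)
        assert sorted(np.unique(cv["folds_10"])) == [0, 1]
        total = sum(len(s.labels) - np.sum(s.labels == UNKNOWN) for s in
                    cv["raw10_sequences"].values())
        assert total == len(t10)

    def test_subject_split_separates_recordings(self):
        t60, t10 = self.make_cohort_tables()
        cv = crossvalidate(t60, t10, seed=3, split="subject")
        for fold in (0, 1):
            recs_in_fold = set(t10.loc[cv["folds_10"] == fold, "recording"])
            recs_out = set(t10.loc[cv["folds_10"] != fold, "recording"])
            assert recs_in_fold.isdisjoint(recs_out)

    def test_same_seed_identical_assignment(self):
        t60, t10 = self.make_cohort_tables()
        cv1 = crossvalidate(t60, t10, seed=7)
        cv2 = crossvalidate(t60, t10, seed=7)
        np.testing.assert_array_equal(cv1["folds_10"], cv2["folds_10"])
        for r in cv1["sequences"]:
            assert cv1["sequences"][r] == cv2["sequences"][r]

    def test_too_few_segments_rejected(self):
        t60, t10 = self.make_cohort_tables()
        with pytest.raises(ValueError, match="at least 2"):
            crossvalidate(t60.iloc[:1], t10, seed=0)


class TestThresholdRuleEquivalence:
    def test_single_tree_forest_learns_hand_set_threshold(self):
        """A one-feature table split at a hand-set threshold is reproduced
        exactly by the fitted trees away from the decision boundary."""
        rng = np.random.default_rng(5)

        def one_feature_table(n, window_s):
            x = rng.uniform(0, 1, n)
            x = x[np.abs(x - 0.5) > 0.05]  # margin around the threshold
            df = pd.DataFrame(0.0, index=range(len(x)), columns=FEATURE_NAMES)
            df["Fhap"] = x
            df.insert(0, "recording", "r0")
            df.insert(1, "start_s", np.arange(len(x)))
            df.insert(2, "window_s", window_s)
            df.insert(3, "label", np.where(x > 0.5, AH, N))
            return df

        t60, t10 = one_feature_table(300, 60), one_feature_table(300, 10)
        model = train_cascade(t60, t10, seed=0)
        test = one_feature_table(200, 10)
        pred = model.detector10.predict(test[FEATURE_NAMES])
        np.testing.assert_array_equal(pred, test["label"].to_numpy())
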