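"""Classifier training/prediction contracts and the fixed-slot baseline."""

import numpy as np
import pandas as pd
import pytest

import pir_adl as pa
from pir_adl.classification import (
    AWAY_DEGREE_MAX,
    ClassifierSpec,
    merge_predictions,
    predict_adl,
    predict_visitor,
    slice_fixed_windows,
    train_adl,
    train_visitor,
)
from pir_adl.home import ConfigurationError
from conftest import build_grid


def make_segments(x, labels, degree=0.9, extra=None):
    n = len(x)
    df = pd.DataFrame({
        "start_s": np.arange(n) * 100.0,
        "end_s": np.arange(1, n + 1) * 100.0,
        "duration_s": 100.0,
        "activity_degree": degree,
        "x_mean": np.asarray(x, dtype=float),
        "truth_label": labels,
    })
    for col, val in (extra or {}).items():
        df[col] = val
    df.index.name = "segment_id"
    return df


class TestTrainAdl:
    def test_separable_classes_fit_perfectly_with_rf(self):
        segs = make_segments([0, 0.1, 0.2, 5.0, 5.1, 5.2],
                             ["Cooking"] * 3 + ["Sleeping"] * 3)
        model = train_adl(segs, ClassifierSpec("rf", random_seed=0))
        pred = predict_adl(model, segs)
        assert list(pred["label"]) == list(segs["truth_label"])

    @pytest.mark.parametrize("algo", ["nb", "svm", "rf"])
    def test_same_seed_reproduces_predictions(self, algo):
        rng = np.random.default_rng(1)
        x = rng.normal(size=60)
        segs = make_segments(x, np.where(x + rng.normal(scale=2, size=60) > 0,
                                         "Cooking", "Sleeping"))
        held = make_segments(rng.normal(size=20), ["Cooking"] * 20)
        p1 = predict_adl(train_adl(segs, ClassifierSpec(algo, random_seed=7)), held)
        p2 = predict_adl(train_adl(segs, ClassifierSpec(algo, random_seed=7)), held)
        pd.testing.assert_frame_equal(p1, p2)

    def test_gaussian_nb_boundary_sits_between_symmetric_classes(self):
        """Two classes with means 0 and 1, equal spread and priors: the
        posterior decision boundary is at 0.5."""
        segs = make_segments([-0.2, 0.2, -0.2, 0.2, 0.8, 1.2, 0.8, 1.2],
                             ["Cooking"] * 4 + ["Sleeping"] * 4)
        segs = segs.drop(columns=["duration_s", "activity_degree"])
        model = train_adl(segs, ClassifierSpec("nb"))
        probe = make_segments([0.49, 0.51], ["Cooking", "Sleeping"]).drop(
            columns=["duration_s", "activity_degree"])
        pred = predict_adl(model, probe)
        assert list(pred["label"]) == ["Cooking", "Sleeping"]

    def test_single_class_rejected(self):
        segs = make_segments([0, 1, 2], ["Cooking"] * 3)
        with pytest.raises(ValueError, match="2 ADL classes"):
            train_adl(segs, ClassifierSpec("rf"))

    def test_nan_feature_rejected_by_name(self):
        segs = make_segments([0, 1, np.nan, 3], ["Cooking", "Cooking",
                                                 "Sleeping", "Sleeping"])
        with pytest.raises(ValueError, match="x_mean"):
            train_adl(segs, ClassifierSpec("rf"))

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ConfigurationError):
            ClassifierSpec("gradient_boost")


class TestPredictAdl:
    def test_empty_segment_table_gives_empty_predictions(self):
        segs = make_segments([0, 5], ["Cooking", "Sleeping"])
        model = train_adl(segs, ClassifierSpec("rf"))
        pred = predict_adl(model, segs.iloc[:0])
        assert len(pred) == 0
        assert list(pred.columns) == ["start_s", "end_s", "label", "visitor"]

    def test_labels_stay_inside_training_set_plus_away(self):
        segs = make_segments(np.linspace(0, 5, 30),
                             ["Cooking"] * 15 + ["Sleeping"] * 15)
        model = train_adl(segs, ClassifierSpec("rf"))
        probe = make_segments(np.linspace(-10, 20, 50), ["Cooking"] * 50,
                              degree=np.linspace(0, 1, 50))
        pred = predict_adl(model, probe)
        assert set(pred["label"]) <= {"Cooking", "Sleeping", pa.AWAY}

    def test_low_activity_degree_ruled_away(self):
        segs = make_segments([0, 5], ["Cooking", "Sleeping"])
        model = train_adl(segs, ClassifierSpec("rf"))
        probe = make_segments([1.0], ["Cooking"], degree=AWAY_DEGREE_MAX / 2)
        assert predict_adl(model, probe)["label"].iloc[0] == pa.AWAY

    def test_room_none_ruled_away(self):
        segs = make_segments([0, 5], ["Cooking", "Sleeping"],
                             extra={"room": ["KITCHEN", "BEDROOM"]})
        model = train_adl(segs, ClassifierSpec("rf"))
        probe = make_segments([1.0], ["Cooking"], extra={"room": ["NONE"]})
        assert predict_adl(model, probe)["label"].iloc[0] == pa.AWAY

    def test_unseen_room_level_maps_to_unknown_not_error(self):
        segs = make_segments([0, 0.1, 5, 5.1], ["Cooking"] * 2 + ["Sleeping"] * 2,
                             extra={"room": ["KITCHEN"] * 2 + ["BEDROOM"] * 2})
        model = train_adl(segs, ClassifierSpec("rf"))
        probe = make_segments([0.0], ["Cooking"], extra={"room": ["GARAGE"]})
        assert predict_adl(model, probe)["label"].iloc[0] in {"Cooking", "Sleeping"}

    def test_missing_feature_column_rejected(self):
        segs = make_segments([0, 5], ["Cooking", "Sleeping"])
        model = train_adl(segs, ClassifierSpec("rf"))
        with pytest.raises(ValueError, match="x_mean"):
            predict_adl(model, segs.drop(columns=["x_mean"]))


class TestVisitor:
    def _segments(self):
        rng = np.random.default_rng(5)
        n = 80
        visitor = (rng.random(n) < 0.3).astype(int)
        df = make_segments(rng.normal(size=n), ["Cooking"] * n)
        df["truth_visitor"] = visitor
        df["BATHROOM_pir_mean"] = rng.random(n)
        df["TV_ROOM_pir_mean"] = 0.1 + 0.8 * visitor + 0.05 * rng.random(n)
        df["KITCHEN_pir_mean"] = rng.random(n)
        df["weekday"] = 0
        return df

    def test_room_subset_restricts_feature_columns(self):
        segs = self._segments()
        model = train_visitor(segs, ClassifierSpec("rf"),
                              room_subset={"BATHROOM", "TV_ROOM"})
        assert "KITCHEN_pir_mean" not in model.encoder.numeric_columns
        assert "TV_ROOM_pir_mean" in model.encoder.numeric_columns
        # token context is never part of the visitor model
        assert not any(c.endswith("token") for c in model.encoder.categorical_columns)

    def test_no_subset_keeps_all_room_columns(self):
        segs = self._segments()
        model = train_visitor(segs, ClassifierSpec("rf"))
        assert {"KITCHEN_pir_mean", "TV_ROOM_pir_mean",
                "BATHROOM_pir_mean"} <= set(model.encoder.numeric_columns)

    def test_learns_concurrent_second_room_signature(self):
        segs = self._segments()
        model = train_visitor(segs, ClassifierSpec("rf"),
                              room_subset={"BATHROOM", "TV_ROOM"})
        pred = predict_visitor(model, segs)
        assert (pred["visitor"] == segs["truth_visitor"]).mean() > 0.9

    def test_single_class_visitor_labels_rejected(self):
        segs = self._segments()
        segs["truth_visitor"] = 0
        with pytest.raises(ValueError, match="single class"):
            train_visitor(segs, ClassifierSpec("rf"))

    def test_non_rf_algorithm_rejected(self):
        with pytest.raises(ConfigurationError, match="rf"):
            train_visitor(self._segments(), ClassifierSpec("svm"))


class TestMergePredictions:
    def _tables(self):
        adl = pd.DataFrame({"start_s": [0.0], "end_s": [100.0],
                            "label": ["Cooking"], "visitor": [0]})
        vis = pd.DataFrame({"start_s": [0.0], "end_s": [100.0], "visitor": [1]})
        return adl, vis

    def test_label_and_flag_come_from_their_own_classifier(self):
        adl, vis = self._tables()
        merged = merge_predictions(adl, vis)
        assert merged["label"].iloc[0] == "Cooking"
        assert merged["visitor"].iloc[0] == 1

    def test_merge_is_idempotent_and_empty_safe(self):
        adl, vis = self._tables()
        merged = merge_predictions(adl, vis)
        pd.testing.assert_frame_equal(merge_predictions(merged, merged), merged)
        assert len(merge_predictions(adl.iloc[:0], vis.iloc[:0])) == 0

    def test_mismatched_segment_ids_rejected(self):
        adl, vis = self._tables()
        with pytest.raises(ValueError, match="segment ids"):
            merge_predictions(adl, vis.rename(index={0: 5}))


class TestFixedWindows:
    def test_600s_grid_cuts_into_ten_slots(self):
        grid = build_grid({"KITCHEN": np.ones(120)})
        segs = slice_fixed_windows(grid, 60)
        assert len(segs) == 10
        assert (segs["duration_s"] == 60).all()

    def test_trailing_partial_window_kept(self):
        grid = build_grid({"KITCHEN": np.ones(130)})
        segs = slice_fixed_windows(grid, 60)
        assert len(segs) == 11
        assert segs["duration_s"].iloc[-1] == 50.0
        assert segs["duration_s"].sum() == 650.0

    def test_slot_must_be_grid_multiple(self):
        grid = build_grid({"KITCHEN": np.ones(10)})
        with pytest.raises(ConfigurationError):
            slice_fixed_windows(grid, 42)


class TestEndToEnd:
    def test_sleeping_recognised_on_easy_synthetic_data(self, layout, specs):
        """RF on room segments finds >= 90% of bedroom night segments."""
        noise = pa.easy_noise()
        train_ds = pa.simulate_home(layout, specs, noise, 2, seed=41, home_id="a")
        test_ds = pa.simulate_home(layout, specs, noise, 2, seed=43, home_id="b")
        seg_train = pa.segment_rooms(pa.preprocess_home(train_ds))
        seg_test = pa.segment_rooms(pa.preprocess_home(test_ds))
        model = train_adl(seg_train, ClassifierSpec("rf", random_seed=0))
        pred = predict_adl(model, seg_test)
        sleeping = seg_test["truth_label"] == "Sleeping"
        assert sleeping.sum() >= 2
        assert (pred.loc[sleeping.to_numpy(), "label"] == "Sleeping").mean() >= 0.9
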