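"""Filtered PIR scores, activity periods, room change points, short filter."""

import numpy as np
import pandas as pd
import pytest

import pir_adl as pa
from pir_adl.home import ConfigurationError
from pir_adl.preprocess import room_pir_matrix
from pir_adl.room_segmentation import (
    NO_ROOM,
    RoomFilterConfig,
    activity_boundaries,
    build_room_segments,
    detect_activity_periods,
    detect_room_changepoints,
    exclude_short_segments,
    filter_pir,
    merge_changepoints,
    segment_rooms,
)
from conftest import build_grid


def cfg(**kw):
    return RoomFilterConfig(**kw)


class TestFilter:
    def test_zero_pir_gives_zero_scores(self):
        grid = build_grid({"KITCHEN": np.zeros(50)})
        assert (filter_pir(grid, cfg())["KITCHEN_pir"] == 0).all()

    def test_constant_pir_saturates_at_summed_weights(self):
        grid = build_grid({"KITCHEN": np.ones(200)})
        scores = filter_pir(grid, cfg())["KITCHEN_pir"]
        assert scores.max() == pytest.approx(2.0)  # weights (1, 1)
        assert (scores <= 2.0 + 1e-12).all()

    def test_single_firing_short_window_score(self):
        pir = np.zeros(101)
        pir[50] = 1
        grid = build_grid({"HALL": pir})
        c = cfg(short_window_s=15, long_window_s=300, default_weights=(1.0, 0.0))
        scores = filter_pir(grid, c)["HALL_pir"]
        assert scores.iloc[50] == pytest.approx(1 / 3)

    def test_bathroom_short_term_upweighted_by_default(self):
        pir = np.zeros(101)
        pir[50] = 1
        grid = build_grid({"BATHROOM": pir, "HALL": pir})
        scores = filter_pir(grid, cfg())
        assert scores["BATHROOM_pir"].iloc[50] > scores["HALL_pir"].iloc[50]

    def test_bad_windows_rejected(self):
        with pytest.raises(ConfigurationError):
            cfg(short_window_s=300, long_window_s=15)
        with pytest.raises(ConfigurationError):
            filter_pir(build_grid({"HALL": np.zeros(10)}), cfg(short_window_s=7.0))


class TestActivityPeriods:
    def test_all_quiet_day_is_one_inactive_period(self):
        grid = build_grid({"KITCHEN": np.zeros(500)})
        scores = filter_pir(grid, cfg())
        periods = detect_activity_periods(scores, cfg(), np.zeros(500))
        assert periods == [(0, 500, False)]

    def test_short_gap_absorbed_into_activity(self):
        # 1 h on / 10 min off / 1 h on with a 900-s minimum gap
        pir = np.concatenate([np.ones(720), np.zeros(120), np.ones(720)])
        grid = build_grid({"KITCHEN": pir})
        c = cfg(min_gap_s=900)
        periods = detect_activity_periods(filter_pir(grid, c), c, pir)
        active = [p for p in periods if p[2]]
        assert len(active) == 1
        assert active[0][0] == 0 and active[0][1] == 1560

    def test_edge_burst_recovered_by_raw_refinement(self):
        # smoothing clips a 2-row burst just past the filtered boundary;
        # the raw-PIR edge rule must pull it back in
        pir = np.zeros(700)
        pir[:599] = 1
        pir[600:602] = 1
        grid = build_grid({"KITCHEN": pir})
        c = cfg(short_window_s=15, long_window_s=30, default_weights=(1.0, 0.0),
                activity_threshold=0.9, min_gap_s=0, edge_keep_s=20)
        periods = detect_activity_periods(filter_pir(grid, c), c, pir)
        active = [p for p in periods if p[2]]

        # independent brute-force restatement of the boundary rule
        ma = np.array([pir[max(0, i - 1):i + 2].mean() for i in range(700)])
        mask = ma >= 0.9
        end = int(np.flatnonzero(mask).max()) + 1
        window = pir[end:end + 4]
        expect_end = end + int(np.flatnonzero(window).max()) + 1
        assert expect_end == 602
        assert active[0][1] == expect_end

    def test_partition_covers_grid(self):
        rng = np.random.default_rng(3)
        pir = (rng.random(2000) < 0.3).astype(float)
        grid = build_grid({"KITCHEN": pir})
        periods = detect_activity_periods(filter_pir(grid, cfg()), cfg(), pir)
        assert periods[0][0] == 0 and periods[-1][1] == 2000
        for (s1, e1, a1), (s2, e2, a2) in zip(periods, periods[1:]):
            assert e1 == s2 and a1 != a2

    def test_raising_threshold_never_extends_activity(self):
        rng = np.random.default_rng(7)
        pir = (rng.random(3000) < 0.15).astype(float)
        grid = build_grid({"KITCHEN": pir})
        totals = []
        for thr in (0.1, 0.3, 0.5, 0.8, 1.2):
            c = cfg(activity_threshold=thr)
            periods = detect_activity_periods(filter_pir(grid, c), c, pir)
            totals.append(sum(e - s for s, e, a in periods if a))
        assert all(a >= b for a, b in zip(totals, totals[1:]))


class TestRoomChangepoints:
    def test_constant_winner_yields_no_changepoints(self):
        grid = build_grid({"KITCHEN": np.ones(100), "LIVING": np.zeros(100)})
        scores = filter_pir(grid, cfg())
        cps = detect_room_changepoints(scores, [(0, 100, True)])
        assert len(cps) == 0

    def test_exact_tie_goes_to_canonical_order(self):
        grid = build_grid({"KITCHEN": np.ones(100), "LIVING": np.ones(100)})
        scores = filter_pir(grid, cfg())
        cps = detect_room_changepoints(scores, [(0, 100, True)])
        assert len(cps) == 0  # KITCHEN wins every row

    def test_clean_transition_detected_within_long_window(self):
        pir_k = np.concatenate([np.ones(200), np.zeros(200)])
        pir_l = np.concatenate([np.zeros(200), np.ones(200)])
        grid = build_grid({"KITCHEN": pir_k, "LIVING": pir_l})
        scores = filter_pir(grid, cfg())
        cps = detect_room_changepoints(scores, [(0, 400, True)])
        assert len(cps) == 1
        assert abs(int(cps[0]) - 200) * 5 <= cfg().long_window_s


class TestMergeAndBuild:
    def test_merge_examples(self):
        assert list(merge_changepoints([10, 50], [50, 80])) == [10, 50, 80]
        assert list(merge_changepoints([], [])) == []
        merged = merge_changepoints([40, 10], [25, 10])
        assert (np.diff(merged) > 0).all()

    def test_room_and_degree_assignment(self):
        pir_b = np.concatenate([np.ones(40), np.zeros(200)])
        grid = build_grid({"KITCHEN": np.zeros(240), "BATHROOM": pir_b})
        segs = segment_rooms(grid, cfg())
        assert segs["room"].iloc[0] == "BATHROOM"
        assert segs["activity_degree"].iloc[0] == pytest.approx(1.0, abs=0.05)
        assert segs["room"].iloc[-1] == NO_ROOM
        assert segs["activity_degree"].iloc[-1] == pytest.approx(0.0, abs=0.02)

    def test_mixed_segment_degree_is_firing_fraction(self):
        pir = np.zeros(40)
        pir[:12] = 1
        grid = build_grid({"KITCHEN": pir})
        segs = build_room_segments(grid, np.array([], dtype=int), cfg())
        assert segs["activity_degree"].iloc[0] == pytest.approx(12 / 40)


class TestShortActivityExclusion:
    def _segments(self):
        # active 15 s / active 20 s / active 25 s / inactive 40 s
        pir = np.concatenate([np.ones(3), np.ones(4), np.ones(5), np.zeros(8)])
        grid = build_grid(
            {"KITCHEN": pir},
            truth=["Cooking"] * 3 + ["Eating"] * 4 + ["Toileting"] * 5 + ["NONE"] * 8,
        )
        c = cfg(activity_threshold=0.01, min_gap_s=0, edge_keep_s=0)
        segs = build_room_segments(grid, np.array([3, 7, 12]), c)
        segs["room"] = ["KITCHEN", "KITCHEN", "KITCHEN", NO_ROOM]
        return segs

    def test_strictly_shorter_segments_dropped_span_conserved(self):
        segs = self._segments()
        out = exclude_short_segments(segs, 20.0)
        assert len(out) == len(segs) - 1
        assert out["duration_s"].sum() == segs["duration_s"].sum()
        # the 15-s head is annexed by the following 20-s segment
        assert out["duration_s"].iloc[0] == 35.0
        assert out["truth_label"].iloc[0] == "Eating"
        assert set(out["truth_label"]) == {"Eating", "Toileting", "NONE"}
        assert (out["start_s"].to_numpy()[1:] == out["end_s"].to_numpy()[:-1]).all()

    def test_zero_threshold_is_identity(self):
        segs = self._segments()
        pd.testing.assert_frame_equal(exclude_short_segments(segs, 0.0), segs)

    def test_inactive_segments_never_removed(self):
        segs = self._segments()
        out = exclude_short_segments(segs, 1000.0)
        assert NO_ROOM in set(out["room"])
        assert out["duration_s"].sum() == segs["duration_s"].sum()

    def test_merged_means_are_duration_weighted(self):
        segs = self._segments()
        out = exclude_short_segments(segs, 20.0)
        a, b = segs.iloc[0], segs.iloc[1]
        expect = (3 * a["KITCHEN_pir_mean"] + 4 * b["KITCHEN_pir_mean"]) / 7
        assert out["KITCHEN_pir_mean"].iloc[0] == pytest.approx(expect)


class TestRecovery:
    def test_most_room_transitions_matched_by_changepoints(self, layout, specs):
        """On easy-noise data >= 90% of true room-transition times have a
        merged change point within one long filter window."""
        noise = pa.easy_noise()
        ds = pa.simulate_home(layout, specs, noise, n_days=2, seed=31)
        grid = pa.preprocess_home(ds)
        c = cfg()
        scores = filter_pir(grid, c)
        raw = room_pir_matrix(grid)[0].max(axis=1)
        periods = detect_activity_periods(scores, c, raw)
        merged = merge_changepoints(
            activity_boundaries(periods), detect_room_changepoints(scores, periods)
        )
        cp_times = merged * 5.0

        room_of = {s.label: s.room for s in specs}
        iv = ds.log.intervals.sort_values("start_s")
        rooms = [room_of.get(lab) for lab in iv["label"]]
        transitions = [
            t for (t, r1, r2) in zip(iv["start_s"].to_numpy()[1:], rooms[:-1], rooms[1:])
            if r1 != r2
        ]
        assert len(transitions) > 20
        matched = sum(
            1 for t in transitions if np.abs(cp_times - t).min() <= c.long_window_s
        )
        assert matched / len(transitions) >= 0.9
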