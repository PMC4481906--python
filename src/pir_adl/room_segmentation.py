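"""Room-based segmentation: filtered PIR scores, activity periods, room
change points, merged change-point lists and the short-activity filter.

Each room's binary PIR train is smoothed with two centred moving averages
(a short and a long window, shrinking at the grid boundaries) and combined
with per-room weights; the bathroom's short-term movements are up-weighted
by default because its dominant activity (toileting) is brief.  A row is
*active* when any room's score reaches the activity threshold; short
no-activity gaps are absorbed, and activity-period boundaries are extended
to nearby raw PIR firings so that short information peaks at the edges of a
period (e.g. leaving the flat) are preserved rather than smoothed away.
Within active periods the occupant's room is the score argmax, and a change
point is set wherever that room changes.  Both change-point lists are merged
and the periods in between are compressed exactly as in the token pipeline,
additionally recording the room and the activity degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .home import GRID_STEP_S, ConfigurationError
from .preprocess import pir_columns, room_of_column, room_pir_matrix
from .token_segmentation import compress_segments

NO_ROOM = "NONE"


@dataclass(frozen=True)
class RoomFilterConfig:
    """Tunables of the room-based clustering (all seconds unless noted).

    ``room_weights`` maps a room code to its (short-window, long-window)
    filter weights; rooms not listed use ``default_weights``.
    """

    short_window_s: float = 15.0
    long_window_s: float = 300.0
    room_weights: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"BATHROOM": (2.0, 1.0)}
    )
    default_weights: tuple[float, float] = (1.0, 1.0)
    activity_threshold: float = 0.5
    min_gap_s: float = 300.0
    edge_keep_s: float = 10.0
    min_activity_s: float = 20.0

    def __post_init__(self) -> None:
        if not self.short_window_s < self.long_window_s:
            raise ConfigurationError("short_window_s must be smaller than long_window_s")
        for w in (self.short_window_s, self.long_window_s):
            if w < GRID_STEP_S:
                raise ConfigurationError("filter window shorter than one grid step")
        for room, (sw, lw) in self.room_weights.items():
            if sw <= 0 or lw < 0:
                raise ConfigurationError(f"non-positive weight for room {room}")
        if self.activity_threshold < 0 or self.min_gap_s < 0 or self.min_activity_s < 0:
            raise ConfigurationError("thresholds must be non-negative")

    def weights_for(self, room: str) -> tuple[float, float]:
        return self.room_weights.get(room, self.default_weights)

    @classmethod
    def from_dict(cls, d: dict) -> "RoomFilterConfig":
        d = dict(d)
        if "room_weights" in d:
            d["room_weights"] = {r: tuple(w) for r, w in d["room_weights"].items()}
        if "default_weights" in d:
            d["default_weights"] = tuple(d["default_weights"])
        return cls(**d)


def _window_rows(window_s: float) -> int:
    w = window_s / GRID_STEP_S
    if abs(w - round(w)) > 1e-9 or round(w) < 1:
        raise ConfigurationError(f"window {window_s}s is not a whole number of 5-s rows")
    return int(round(w))


def filter_pir(grid: pd.DataFrame, cfg: RoomFilterConfig) -> pd.DataFrame:
    """Weighted short+long centred moving averages of each PIR train.

    One score per sensor location: rooms overseen by several boxes (the
    living-room table/sofa case) keep one score per box, so that moves
    between zones of one room are visible to the location argmax.  Weights
    are looked up by the column's room.  Scores lie in
    ``[0, short_weight + long_weight]``; the averaging windows shrink
    symmetrically at the grid boundaries.
    """
    cols = pir_columns(grid)
    if not cols:
        raise ValueError("grid has no PIR columns")
    w_short = _window_rows(cfg.short_window_s)
    w_long = _window_rows(cfg.long_window_s)
    pir = grid[cols].astype(float)
    ma_s = pir.rolling(w_short, center=True, min_periods=1).mean()
    ma_l = pir.rolling(w_long, center=True, min_periods=1).mean()
    out = pd.DataFrame(index=grid.index)
    for col in cols:
        sw, lw = cfg.weights_for(room_of_column(col))
        out[col] = sw * ma_s[col] + lw * ma_l[col]
    return out


def detect_activity_periods(
    scores: pd.DataFrame,
    cfg: RoomFilterConfig,
    raw_any_pir: np.ndarray,
) -> list[tuple[int, int, bool]]:
    """Partition the grid into half-open (start_row, end_row, is_active) runs.

    A row is active iff the maximum room score reaches the activity
    threshold.  Interior no-activity gaps shorter than ``min_gap_s`` are
    absorbed into the surrounding activity period.  Active boundaries are
    then extended outward to raw PIR firings within ``edge_keep_s``, so that
    brief firing bursts clipped by the smoothing stay inside the period.
    """
    n = len(scores)
    if n == 0:
        raise ValueError("empty score table")
    raw = np.asarray(raw_any_pir).astype(bool)
    if len(raw) != n:
        raise ValueError("raw PIR length does not match scores")
    active = scores.to_numpy().max(axis=1) >= cfg.activity_threshold

    # runs of constant state
    runs: list[tuple[int, int, bool]] = []
    edges = np.flatnonzero(np.diff(active.astype(np.int8))) + 1
    bounds = np.concatenate([[0], edges, [n]])
    for s, e in zip(bounds[:-1], bounds[1:]):
        runs.append((int(s), int(e), bool(active[s])))

    # absorb short interior inactive gaps
    min_gap = int(round(cfg.min_gap_s / GRID_STEP_S))
    absorbed: list[tuple[int, int, bool]] = []
    for i, (s, e, act) in enumerate(runs):
        interior = 0 < i < len(runs) - 1
        if not act and interior and (e - s) < min_gap:
            act = True
        if absorbed and absorbed[-1][2] == act:
            absorbed[-1] = (absorbed[-1][0], e, act)
        else:
            absorbed.append((s, e, act))

    # extend active boundaries to nearby raw firings
    edge = int(round(cfg.edge_keep_s / GRID_STEP_S))
    starts = [s for s, _e, a in absorbed if a]
    ends = [e for _s, e, a in absorbed if a]
    new_active: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        lo = max(0, s - edge)
        fir = np.flatnonzero(raw[lo:s])
        if fir.size:
            s = lo + int(fir[0])
        hi = min(n, e + edge)
        fir = np.flatnonzero(raw[e:hi])
        if fir.size:
            e = e + int(fir[-1]) + 1
        if new_active and s <= new_active[-1][1]:
            new_active[-1] = (new_active[-1][0], max(e, new_active[-1][1]))
        else:
            new_active.append((s, e))

    # rebuild the full partition
    out: list[tuple[int, int, bool]] = []
    cursor = 0
    for s, e in new_active:
        if s > cursor:
            out.append((cursor, s, False))
        out.append((s, e, True))
        cursor = e
    if cursor < n:
        out.append((cursor, n, False))
    if not out:
        out = [(0, n, False)]
    return out


def detect_room_changepoints(
    scores: pd.DataFrame,
    periods: list[tuple[int, int, bool]],
) -> np.ndarray:
    """Rows (within active periods) at which the score-argmax location changes.

    Ties go to the location earliest in canonical order (argmax convention).
    """
    vals = scores.to_numpy()
    cps: list[int] = []
    for s, e, act in periods:
        if not act or e - s < 2:
            continue
        current = vals[s:e].argmax(axis=1)
        change = np.flatnonzero(current[1:] != current[:-1]) + 1
        cps.extend((s + change).tolist())
    return np.asarray(sorted(cps), dtype=np.int64)


def activity_boundaries(periods: list[tuple[int, int, bool]]) -> np.ndarray:
    """Interior period boundaries (each period's start row except row 0)."""
    return np.asarray([s for s, _e, _a in periods if s > 0], dtype=np.int64)


def merge_changepoints(
    boundaries: np.ndarray,
    room_changepoints: np.ndarray,
) -> np.ndarray:
    """Sorted, de-duplicated union of the two change-point lists."""
    merged = np.union1d(
        np.asarray(boundaries, dtype=np.int64),
        np.asarray(room_changepoints, dtype=np.int64),
    )
    return merged.astype(np.int64)


def build_room_segments(
    grid: pd.DataFrame,
    merged_changepoints: np.ndarray,
    cfg: RoomFilterConfig,
    scores: pd.DataFrame | None = None,
    periods: list[tuple[int, int, bool]] | None = None,
) -> pd.DataFrame:
    """Compress merged periods and attach room and activity degree.

    The room of an active segment is the argmax over rooms of the summed
    weighted score within the segment; no-activity segments get room NONE.
    """
    if scores is None:
        scores = filter_pir(grid, cfg)
    if periods is None:
        raw_any = room_pir_matrix(grid)[0].max(axis=1)
        periods = detect_activity_periods(scores, cfg, raw_any)
    segments = compress_segments(grid, merged_changepoints)

    active_row = np.zeros(len(grid), dtype=bool)
    for s, e, act in periods:
        if act:
            active_row[s:e] = True

    times = grid.index.to_numpy()
    vals = scores.to_numpy()
    rooms = [room_of_column(c) for c in scores.columns]
    seg_rooms: list[str] = []
    for _, seg in segments.iterrows():
        s = int(np.searchsorted(times, seg["start_s"]))
        e = int(np.searchsorted(times, seg["end_s"]))
        if active_row[s:e].mean() > 0.5:
            seg_rooms.append(rooms[int(vals[s:e].sum(axis=0).argmax())])
        else:
            seg_rooms.append(NO_ROOM)
    segments.insert(3, "room", seg_rooms)
    return segments


def _pooled_merge(a: pd.Series, b: pd.Series, keep: str) -> pd.Series:
    """Merge two adjacent segment rows, keeping the identity of `keep` ('a'|'b')."""
    na = max(a["duration_s"] / GRID_STEP_S, 1.0)
    nb = max(b["duration_s"] / GRID_STEP_S, 1.0)
    out = (a if keep == "a" else b).copy()
    out["start_s"] = a["start_s"]
    out["end_s"] = b["end_s"]
    out["duration_s"] = a["duration_s"] + b["duration_s"]
    out["activity_degree"] = (na * a["activity_degree"] + nb * b["activity_degree"]) / (na + nb)
    out["truth_visitor"] = int(
        (na * a["truth_visitor"] + nb * b["truth_visitor"]) / (na + nb) >= 0.5
    )
    for col in a.index:
        if col.endswith("_mean"):
            stem = col[: -len("_mean")]
            m = (na * a[col] + nb * b[col]) / (na + nb)
            if f"{stem}_var" in a.index:
                va = a[f"{stem}_var"] + (a[col] - m) ** 2
                vb = b[f"{stem}_var"] + (b[col] - m) ** 2
                out[f"{stem}_var"] = (na * va + nb * vb) / (na + nb)
            out[col] = m
        elif col.endswith("_min"):
            out[col] = min(a[col], b[col])
        elif col.endswith("_max"):
            out[col] = max(a[col], b[col])
        elif col.endswith("_first"):
            out[col] = a[col]
        elif col.endswith("_last"):
            out[col] = b[col]
    return out


def exclude_short_segments(segments: pd.DataFrame, min_activity_s: float) -> pd.DataFrame:
    """Drop active segments strictly shorter than ``min_activity_s``.

    A 20-s segment survives a 20-s threshold.  The span of a removed segment
    is annexed to the preceding segment (or the following one, if it is
    first), so total coverage is conserved.  No-activity segments are never
    removed.
    """
    if min_activity_s < 0:
        raise ValueError("min_activity_s must be >= 0")
    if min_activity_s == 0 or segments.empty:
        return segments.copy()
    has_room = "room" in segments.columns

    kept: list[pd.Series] = []
    pending: pd.Series | None = None  # short first segment(s) waiting for a host
    for _, row in segments.iterrows():
        active = (row["room"] != NO_ROOM) if has_room else True
        short = active and row["duration_s"] < min_activity_s
        if short:
            if kept:
                kept[-1] = _pooled_merge(kept[-1], row, keep="a")
            elif pending is not None:
                pending = _pooled_merge(pending, row, keep="a")
            else:
                pending = row.copy()
            continue
        if pending is not None:
            row = _pooled_merge(pending, row, keep="b")
            pending = None
        kept.append(row.copy())
    if pending is not None:  # everything was short: keep the merged remnant
        kept.append(pending)

    out = pd.DataFrame(kept).reset_index(drop=True)
    out["prev_token"] = np.concatenate([[-1], out["token"].to_numpy()[:-1]])
    out["next_token"] = np.concatenate([out["token"].to_numpy()[1:], [-1]])
    out.index.name = "segment_id"
    return out


def segment_rooms(grid: pd.DataFrame, cfg: RoomFilterConfig | None = None) -> pd.DataFrame:
    """Full room-based pipeline: filter, periods, change points, compress,
    short-activity exclusion."""
    cfg = cfg or RoomFilterConfig()
    scores = filter_pir(grid, cfg)
    raw_any = room_pir_matrix(grid)[0].max(axis=1)
    periods = detect_activity_periods(scores, cfg, raw_any)
    room_cps = detect_room_changepoints(scores, periods)
    merged = merge_changepoints(activity_boundaries(periods), room_cps)
    segments = build_room_segments(grid, merged, cfg, scores=scores, periods=periods)
    return exclude_short_segments(segments, cfg.min_activity_s)
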