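"""From raw sensor events to the wide 5-s feature grid.

The pipeline is: associate each sensor box with its room code
(:func:`map_boxes_to_rooms`), snap every reading onto a 5-s grid
(:func:`resample_to_grid`), and assemble the labelled wide table
(:func:`build_feature_grid`) with one row per 5 s and one column per
room x channel, plus the weekday and the aligned ground truth.

Column naming is ``{ROOM}_{channel}`` (e.g. ``KITCHEN_pir``); when two boxes
of one room provide the same channel — the living-room table/sofa case —
their columns are suffixed ``_a``/``_b`` in mapping order
(``LIVING_a_pir``, ``LIVING_b_pir``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .home import (
    AWAY,
    CHANNEL_ORDER,
    DAY_S,
    GRID_STEP_S,
    NO_ACTIVITY,
    ConfigurationError,
    GroundTruthLog,
    HomeDataset,
    HomeLayout,
)

TRUTH_COLUMNS = ("truth_label", "truth_visitor")
_SUFFIXES = "abcdefgh"


def _column_plan(mapping: dict[str, str], channels_by_box: dict[str, tuple[str, ...]]):
    """(box_id, channel) -> column name, plus ordered column and room lists."""
    by_room: dict[str, list[str]] = {}
    for box_id, room in mapping.items():
        by_room.setdefault(room, []).append(box_id)

    suffix: dict[str, str] = {}
    for room, box_ids in by_room.items():
        clash = [
            b for b in box_ids
            if any(set(channels_by_box.get(b, ())) & set(channels_by_box.get(o, ()))
                   for o in box_ids if o != b)
        ]
        for i, b in enumerate(clash):
            suffix[b] = _SUFFIXES[i]

    names: dict[tuple[str, str], str] = {}
    column_order: list[str] = []
    room_order: list[str] = []
    for box_id, room in mapping.items():
        if room not in room_order:
            room_order.append(room)
        stem = f"{room}_{suffix[box_id]}" if box_id in suffix else room
        for ch in sorted(channels_by_box.get(box_id, ()), key=CHANNEL_ORDER.index):
            name = f"{stem}_{ch}"
            names[(box_id, ch)] = name
            column_order.append(name)
    return names, column_order, room_order


def map_boxes_to_rooms(readings: pd.DataFrame, mapping: dict[str, str]) -> pd.DataFrame:
    """Annotate raw readings with room codes and feature-column names.

    ``mapping`` is box_id -> canonical room code; its insertion order defines
    the canonical room (and hence token-bit) order downstream.
    """
    seen = set(str(b) for b in readings["box_id"].unique())
    unmapped = seen - set(mapping)
    if unmapped:
        raise ConfigurationError(f"box id(s) without room mapping: {sorted(unmapped)}")

    channels_by_box = (
        readings.groupby("box_id", observed=True)["channel"]
        .agg(lambda s: tuple(sorted(set(str(c) for c in s), key=CHANNEL_ORDER.index)))
        .to_dict()
    )
    channels_by_box = {str(k): v for k, v in channels_by_box.items()}
    names, column_order, room_order = _column_plan(mapping, channels_by_box)

    out = readings.copy()
    key = pd.MultiIndex.from_arrays(
        [out["box_id"].astype(str), out["channel"].astype(str)]
    )
    out["room"] = pd.Categorical(out["box_id"].astype(str).map(mapping))
    out["column"] = pd.Categorical(key.map(names))
    out.attrs["column_order"] = column_order
    out.attrs["room_order"] = room_order
    return out


def resample_to_grid(mapped: pd.DataFrame) -> pd.DataFrame:
    """Assign each reading to the nearest 5-s grid point (half-up at ties).

    Collisions on one grid point take the maximum for PIR and the mean for
    continuous channels.  Missing continuous values are forward-filled
    (leading gaps backward-filled); missing PIR samples count as 0.
    """
    if mapped.empty:
        raise ValueError("cannot resample an empty reading stream")
    df = mapped.copy()
    df["grid"] = (np.floor(df["time_s"].to_numpy() / GRID_STEP_S + 0.5)
                  * GRID_STEP_S).astype(np.int64)

    is_pir = df["channel"].astype(str) == "pir"
    parts = []
    for sub, agg in ((df[is_pir], "max"), (df[~is_pir], "mean")):
        if len(sub):
            parts.append(
                sub.pivot_table(index="grid", columns="column", values="value",
                                aggfunc=agg, observed=True)
            )
    wide = pd.concat(parts, axis=1)

    full = np.arange(0, wide.index.max() + GRID_STEP_S, GRID_STEP_S, dtype=np.int64)
    wide = wide.reindex(full)
    order = [c for c in mapped.attrs.get("column_order", wide.columns) if c in wide.columns]
    wide = wide[order]

    pir_cols = [c for c in wide.columns if c.endswith("_pir")]
    wide[pir_cols] = wide[pir_cols].fillna(0.0)
    cont = [c for c in wide.columns if c not in pir_cols]
    wide[cont] = wide[cont].ffill().bfill()
    wide.index.name = "time_s"
    wide.attrs["room_order"] = list(mapped.attrs.get("room_order", []))
    return wide


def build_feature_grid(
    grid: pd.DataFrame,
    layout: HomeLayout,
    log: GroundTruthLog,
) -> pd.DataFrame:
    """Finish the feature table: acceleration magnitude, weekday, ground truth.

    Truth labels follow the half-open ``[start_s, end_s)`` convention; when
    intervals overlap, the shorter (interrupting) interval wins.  Rows with no
    covering interval are NONE; away periods are AWAY.
    """
    out = grid.copy()
    out.attrs["room_order"] = list(grid.attrs.get("room_order", []))

    for col in [c for c in out.columns if c.endswith("_accel_x")]:
        stem = col[: -len("_accel_x")]
        if f"{stem}_accel_y" in out.columns and f"{stem}_accel_z" in out.columns:
            mag = np.sqrt(out[col] ** 2 + out[f"{stem}_accel_y"] ** 2
                          + out[f"{stem}_accel_z"] ** 2)
            out.insert(out.columns.get_loc(f"{stem}_accel_z") + 1, f"{stem}_accel_mag", mag)

    times = out.index.to_numpy()
    span = float(times[-1]) + GRID_STEP_S if len(times) else 0.0
    out["weekday"] = ((times // DAY_S) % 7).astype(np.int64)

    labels = np.full(len(out), NO_ACTIVITY, dtype=object)
    visitor = np.zeros(len(out), dtype=np.int64)
    iv = log.intervals
    if len(iv):
        if float(iv["end_s"].max()) > span + GRID_STEP_S:
            raise ValueError(
                f"log interval ends at {iv['end_s'].max()} s, beyond grid span {span} s"
            )
        dur = (iv["end_s"] - iv["start_s"]).to_numpy()
        for k in np.argsort(-dur, kind="stable"):  # longest first; shortest wins
            i0 = int(np.searchsorted(times, iv["start_s"].iloc[k], side="left"))
            i1 = int(np.searchsorted(times, iv["end_s"].iloc[k], side="left"))
            labels[i0:i1] = iv["label"].iloc[k]
            visitor[i0:i1] = int(iv["visitor"].iloc[k])
    out["truth_label"] = labels
    out["truth_visitor"] = visitor
    return out


def preprocess_home(dataset: HomeDataset) -> pd.DataFrame:
    """Full preprocessing of one home: map, resample, label."""
    mapped = map_boxes_to_rooms(dataset.readings, dataset.layout.box_room_mapping())
    grid = resample_to_grid(mapped)
    return build_feature_grid(grid, dataset.layout, dataset.log)


def feature_columns(grid: pd.DataFrame) -> list[str]:
    """Sensor + weekday columns (everything except the ground truth)."""
    return [c for c in grid.columns if c not in TRUTH_COLUMNS]


def pir_columns(grid: pd.DataFrame) -> list[str]:
    return [c for c in grid.columns if c.endswith("_pir")]


def room_of_column(column: str) -> str:
    """Strip the channel (and any _a/_b box suffix) from a column name."""
    for ch in sorted(CHANNEL_ORDER + ("accel_mag",), key=len, reverse=True):
        suffix = f"_{ch}"
        if column.endswith(suffix):
            stem = column[: -len(suffix)]
            parts = stem.rsplit("_", 1)
            if len(parts) == 2 and len(parts[1]) == 1 and parts[1] in _SUFFIXES:
                return parts[0]
            return stem
    return column


def room_pir_matrix(grid: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Per-room binary PIR matrix (rows x rooms), ORing multi-box rooms.

    Room order is the canonical order of first appearance among the grid's
    PIR columns, which preprocessing keeps aligned with the layout order.
    """
    cols = pir_columns(grid)
    if not cols:
        raise ValueError("grid has no PIR columns")
    rooms: list[str] = []
    for c in cols:
        r = room_of_column(c)
        if r not in rooms:
            rooms.append(r)
    mat = np.zeros((len(grid), len(rooms)), dtype=np.int8)
    for c in cols:
        j = rooms.index(room_of_column(c))
        mat[:, j] |= (grid[c].to_numpy() > 0.5).astype(np.int8)
    return mat, rooms
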