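"""Reading and writing the on-disk dataset layout.

A home dataset directory holds three plain-text files:

* ``readings.csv`` — time_s, box_id, channel, value (PIR values in {0, 1})
* ``logbook.csv`` — start_s, end_s, label, visitor (0/1)
* ``rooms.csv``   — box_id, room_code (row order fixes the canonical room order)
"""

from __future__ import annotations

import math
import os
from pathlib import Path

import pandas as pd

from .home import (
    CHANNEL_ORDER,
    DAY_S,
    GroundTruthLog,
    HomeDataset,
    HomeLayout,
    SensorBox,
)

READINGS_FILE = "readings.csv"
LOGBOOK_FILE = "logbook.csv"
ROOMS_FILE = "rooms.csv"


def write_dataset(dataset: HomeDataset, directory: str | os.PathLike) -> dict[str, Path]:
    """Write readings.csv / logbook.csv / rooms.csv; returns the file paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "readings": directory / READINGS_FILE,
        "logbook": directory / LOGBOOK_FILE,
        "rooms": directory / ROOMS_FILE,
    }
    dataset.readings.to_csv(paths["readings"], index=False)
    dataset.log.intervals.to_csv(paths["logbook"], index=False)
    rooms = pd.DataFrame(
        {"box_id": [b.box_id for b in dataset.layout.boxes],
         "room_code": [b.room for b in dataset.layout.boxes]}
    )
    rooms.to_csv(paths["rooms"], index=False)
    return paths


def read_readings(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"box_id": str, "channel": str})
    df["box_id"] = pd.Categorical(df["box_id"])
    df["channel"] = pd.Categorical(df["channel"])
    return df


def read_logbook(path: str | os.PathLike, home_id: str = "") -> GroundTruthLog:
    df = pd.read_csv(path, dtype={"label": str})
    if df.empty:
        df = pd.DataFrame(columns=["start_s", "end_s", "label", "visitor"])
    return GroundTruthLog(df, home_id=home_id)


def read_rooms(path: str | os.PathLike) -> dict[str, str]:
    """box_id -> room_code, preserving file row order."""
    df = pd.read_csv(path, dtype=str)
    return dict(zip(df["box_id"], df["room_code"]))


def _layout_from_parts(mapping: dict[str, str], readings: pd.DataFrame) -> HomeLayout:
    """Reconstruct a layout from the room mapping plus the observed channels."""
    chan_by_box = (
        readings.groupby("box_id", observed=True)["channel"]
        .agg(lambda s: tuple(sorted(set(s), key=CHANNEL_ORDER.index)))
        .to_dict()
    )
    rooms: list[str] = []
    for room in mapping.values():
        if room not in rooms:
            rooms.append(room)
    boxes = tuple(
        SensorBox(box_id, room, chan_by_box.get(box_id, ("pir",)))
        for box_id, room in mapping.items()
    )
    return HomeLayout(rooms=tuple(rooms), boxes=boxes)


def read_dataset(directory: str | os.PathLike, home_id: str | None = None) -> HomeDataset:
    """Read a dataset directory back into a :class:`HomeDataset`."""
    directory = Path(directory)
    readings = read_readings(directory / READINGS_FILE)
    mapping = read_rooms(directory / ROOMS_FILE)
    home_id = home_id if home_id is not None else directory.name
    log = read_logbook(directory / LOGBOOK_FILE, home_id=home_id)
    t_max = float(readings["time_s"].max()) if len(readings) else 0.0
    n_days = max(1, math.ceil((t_max + 1e-9) / DAY_S))
    layout = _layout_from_parts(mapping, readings)
    return HomeDataset(home_id=home_id, layout=layout, readings=readings, log=log, n_days=n_days)


def write_feature_grid(grid: pd.DataFrame, path: str | os.PathLike) -> Path:
    path = Path(path)
    grid.to_csv(path, index_label="time_s")
    return path


def read_feature_grid(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="time_s")
    df.index = df.index.astype(int)
    return df


def write_segments(segments: pd.DataFrame, path: str | os.PathLike) -> Path:
    path = Path(path)
    segments.to_csv(path, index_label="segment_id")
    return path


def read_segments(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="segment_id")
    if "room" in df.columns:
        df["room"] = df["room"].astype(str)
    return df
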