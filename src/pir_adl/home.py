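"""Domain types for a sensed smart home.

A home is described by a :class:`HomeLayout` (rooms and wireless sensor
boxes), a set of :class:`ActivitySpec` entries describing the resident's
activities of daily living (ADLs), and a :class:`SensorNoiseModel` giving
the stochastic behaviour of every sensor channel.  The ground truth of a
recording is a :class:`GroundTruthLog` of labelled activity intervals; a
complete recording bundle is a :class:`HomeDataset`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

#: Canonical ADL labels, in report order.
ADL_LABELS: tuple[str, ...] = (
    "Cooking",
    "Eating",
    "Get ready for bed",
    "Grooming",
    "Seated activity",
    "Sleeping",
    "Toileting",
    "Watching TV",
)

#: Pseudo-label for periods in which the resident is out of the flat.
AWAY: str = "AWAY"

#: Label for grid rows covered by no logged interval (at home, nothing logged).
NO_ACTIVITY: str = "NONE"

#: Sensor channels, in canonical column order.
CHANNEL_ORDER: tuple[str, ...] = (
    "temp",
    "lux",
    "pir",
    "humidity",
    "accel_x",
    "accel_y",
    "accel_z",
)

#: Grid step of the resampled feature table and of the sensor sampling (0.2 Hz).
GRID_STEP_S: int = 5

#: Length of a simulated day in seconds.
DAY_S: int = 86_400


class ConfigurationError(ValueError):
    """A layout/spec/mapping inconsistency detected before any computation."""


@dataclass(frozen=True)
class SensorBox:
    """One wireless sensor box placed in a room."""

    box_id: str
    room: str
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        unknown = set(self.channels) - set(CHANNEL_ORDER)
        if unknown:
            raise ConfigurationError(f"box {self.box_id}: unknown channels {sorted(unknown)}")
        if not self.channels:
            raise ConfigurationError(f"box {self.box_id}: empty channel set")


@dataclass(frozen=True)
class HomeLayout:
    """Rooms of a flat and the sensor boxes installed in them."""

    rooms: tuple[str, ...]
    boxes: tuple[SensorBox, ...]

    def __post_init__(self) -> None:
        if not self.rooms:
            raise ConfigurationError("room list is empty")
        if len(set(self.rooms)) != len(self.rooms):
            raise ConfigurationError("room codes are not unique")
        for box in self.boxes:
            if box.room not in self.rooms:
                raise ConfigurationError(f"box {box.box_id} placed in unknown room {box.room}")
        ids = [b.box_id for b in self.boxes]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("box ids are not unique")
        if sum("humidity" in b.channels for b in self.boxes) > 1:
            raise ConfigurationError("at most one humidity box allowed")
        if sum("accel_x" in b.channels for b in self.boxes) > 1:
            raise ConfigurationError("at most one acceleration box allowed")

    @property
    def bathroom_has_humidity(self) -> bool:
        return any("humidity" in b.channels and b.room == "BATHROOM" for b in self.boxes)

    @property
    def fridge_box_has_acceleration(self) -> bool:
        return any("accel_x" in b.channels for b in self.boxes)

    def box(self, box_id: str) -> SensorBox:
        for b in self.boxes:
            if b.box_id == box_id:
                return b
        raise ConfigurationError(f"unknown box id {box_id!r}")

    def box_room_mapping(self) -> dict[str, str]:
        """box_id -> room code, in layout order (order fixes column naming)."""
        return {b.box_id: b.room for b in self.boxes}


@dataclass(frozen=True)
class ActivitySpec:
    """Statistical description of one ADL for the simulator.

    Durations are log-normal: ``duration_median_s * exp(duration_sigma * N(0,1))``
    seconds.  ``daily_windows`` are clock-time windows (hours, half-open) in
    which the activity may start; ``mean_occurrences_per_day`` acts as the
    relative selection weight of the activity among the eligible ones.
    """

    label: str
    room: str | None
    duration_median_s: float
    duration_sigma: float
    daily_windows: tuple[tuple[float, float], ...]
    mean_occurrences_per_day: float
    lights_on: bool = True
    preferred_box: str | None = None

    def __post_init__(self) -> None:
        if self.duration_median_s <= 0 or self.duration_sigma <= 0:
            raise ConfigurationError(f"{self.label}: duration parameters must be positive")
        if self.mean_occurrences_per_day < 0:
            raise ConfigurationError(f"{self.label}: negative occurrence rate")
        for lo, hi in self.daily_windows:
            if not (0.0 <= lo < hi <= 24.0):
                raise ConfigurationError(f"{self.label}: window ({lo}, {hi}) outside [0, 24]")

    def starts_in_window(self, clock_s: float) -> bool:
        h = (clock_s % DAY_S) / 3600.0
        return any(lo <= h < hi for lo, hi in self.daily_windows)


@dataclass(frozen=True)
class SensorNoiseModel:
    """Stochastic behaviour of every sensor channel.

    PIR: a sample fires with ``pir_hit_prob`` while the box's room is occupied
    by a moving person, with ``pir_false_prob`` otherwise, and with
    ``pir_cross_zone_prob`` when the room is occupied but the activity is
    covered by a different box of the same room (table vs. sofa sensor).
    Continuous channels are simple parametric signals plus Gaussian jitter.
    """

    pir_hit_prob: float = 0.85
    pir_false_prob: float = 0.005
    pir_cross_zone_prob: float = 0.15
    temp_base: float = 21.0
    temp_amplitude: float = 2.0
    temp_noise_sd: float = 0.1
    lux_day: float = 300.0
    lux_night: float = 5.0
    lamp_lux_bonus: float = 150.0
    lux_noise_sd: float = 2.0
    humidity_base: float = 9.0
    humidity_shower_spike: float = 6.0
    humidity_noise_sd: float = 0.2
    accel_idle: float = 0.2
    accel_event_magnitude: float = 8.0
    accel_noise_sd: float = 0.05
    fridge_event_prob: float = 0.1

    def __post_init__(self) -> None:
        for name in ("pir_hit_prob", "pir_false_prob", "pir_cross_zone_prob", "fridge_event_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        if self.pir_hit_prob <= self.pir_false_prob:
            raise ConfigurationError("pir_hit_prob must exceed pir_false_prob")


@dataclass
class GroundTruthLog:
    """Labelled activity intervals (the resident's logbook).

    ``intervals`` columns: start_s, end_s, label, visitor (0/1).  Intervals are
    half-open ``[start_s, end_s)``; away periods carry the pseudo-label AWAY.
    """

    intervals: pd.DataFrame
    home_id: str = ""

    def __post_init__(self) -> None:
        df = self.intervals
        required = ["start_s", "end_s", "label", "visitor"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"logbook missing columns {missing}")
        self.intervals = df = df[required].reset_index(drop=True)
        if len(df) and not (df.start_s < df.end_s).all():
            raise ValueError("logbook has intervals with start >= end")

    def __len__(self) -> int:
        return len(self.intervals)

    def same_label_overlaps(self) -> int:
        """Count of overlapping interval pairs sharing a label (should be 0)."""
        n = 0
        for _, grp in self.intervals.groupby("label"):
            g = grp.sort_values("start_s")
            n += int((g.start_s.values[1:] < g.end_s.values[:-1]).sum())
        return n


@dataclass
class HomeDataset:
    """One home's recording: layout, raw readings, logbook and its length."""

    home_id: str
    layout: HomeLayout
    readings: pd.DataFrame  # columns: time_s, box_id, channel, value
    log: GroundTruthLog
    n_days: int

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        t = self.readings["time_s"]
        if len(t) and (t.min() < 0 or t.max() >= self.n_days * DAY_S):
            raise ValueError("reading timestamps outside [0, n_days * 86400)")
        known = {b.box_id for b in self.layout.boxes}
        seen = set(self.readings["box_id"].unique())
        if seen - known:
            raise ValueError(f"readings reference unknown boxes {sorted(seen - known)}")


def default_layout() -> HomeLayout:
    """Reference 6-room flat with 8 boxes.

    Two boxes share the living room (one oversees the dining table, one the
    sofa); the bathroom box carries the humidity channel and a dedicated box
    on the fridge door carries the three acceleration channels.
    """
    rooms = ("KITCHEN", "BATHROOM", "BEDROOM", "LIVING", "TV_ROOM", "HALL")
    amb = ("temp", "lux", "pir")
    boxes = (
        SensorBox("b01", "KITCHEN", amb),
        SensorBox("b02", "BATHROOM", ("temp", "lux", "pir", "humidity")),
        SensorBox("b03", "BEDROOM", amb),
        SensorBox("b04", "LIVING", amb),   # dining table
        SensorBox("b05", "LIVING", amb),   # sofa
        SensorBox("b06", "TV_ROOM", amb),
        SensorBox("b07", "HALL", amb),
        SensorBox("b08", "KITCHEN", ("accel_x", "accel_y", "accel_z")),  # fridge door
    )
    return HomeLayout(rooms=rooms, boxes=boxes)


def default_activity_specs() -> tuple[ActivitySpec, ...]:
    """Eight ADLs with realistic rooms, durations and times of day."""
    return (
        ActivitySpec("Cooking", "KITCHEN", 2100, 0.35,
                     ((7, 9), (11.5, 13.5), (17.5, 19.5)), 2.5),
        ActivitySpec("Eating", "LIVING", 1800, 0.30,
                     ((7.5, 9.5), (12, 14), (18, 20.5)), 2.5, preferred_box="b04"),
        ActivitySpec("Get ready for bed", "BEDROOM", 900, 0.30, ((20.5, 23.5),), 1.0),
        ActivitySpec("Grooming", "BATHROOM", 1200, 0.40, ((6.5, 9.5), (20.5, 23)), 1.5),
        ActivitySpec("Seated activity", "LIVING", 4200, 0.50,
                     ((5.5, 20.5),), 2.0, preferred_box="b05"),
        ActivitySpec("Sleeping", "BEDROOM", 25200, 0.15,
                     ((0, 4.5), (21, 24)), 1.0, lights_on=False),
        ActivitySpec("Toileting", "BATHROOM", 240, 0.50, ((0, 24),), 5.0),
        ActivitySpec("Watching TV", "TV_ROOM", 5400, 0.40, ((16.5, 22.5),), 1.5),
    )


def default_away_spec() -> ActivitySpec:
    """Out-of-home periods, modelled as a room-less pseudo-activity."""
    return ActivitySpec(AWAY, None, 7200, 0.50, ((8.5, 18),), 1.5, lights_on=False)


def default_noise() -> SensorNoiseModel:
    return SensorNoiseModel()


def easy_noise() -> SensorNoiseModel:
    """The easy-noise regime used for pipeline recovery checks."""
    return replace(SensorNoiseModel(), pir_hit_prob=0.85, pir_false_prob=0.005)


def validate_specs(specs: tuple[ActivitySpec, ...], layout: HomeLayout) -> None:
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ConfigurationError("duplicate activity labels")
    for s in specs:
        if s.room is not None and s.room not in layout.rooms:
            raise ConfigurationError(f"activity {s.label!r} references unknown room {s.room!r}")
        if s.preferred_box is not None:
            box = layout.box(s.preferred_box)
            if box.room != s.room:
                raise ConfigurationError(
                    f"activity {s.label!r}: preferred box {s.preferred_box} not in room {s.room}"
                )
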