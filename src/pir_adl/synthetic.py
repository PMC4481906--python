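"""Synthetic multi-room ambient sensor data generator.

The resident is modelled as a single occupant following a semi-Markov
schedule: at every transition an activity is drawn among the specs whose
clock-time windows cover the current time (weighted by their daily rates),
and its dwell time is drawn from the activity's log-normal duration
distribution.  Away-from-home periods are a room-less pseudo-activity.
Every sensor box then samples its channels at 0.2 Hz with the stochastic
model of :class:`~pir_adl.home.SensorNoiseModel`.

Seeding: a master seed is combined with the day index through
``numpy.random.SeedSequence([seed, day_index])``, which is then split into
independent streams for the schedule, the overlap draws, the visitor draws
and the sensor rendering, so each day is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .home import (
    AWAY,
    DAY_S,
    GRID_STEP_S,
    ActivitySpec,
    ConfigurationError,
    GroundTruthLog,
    HomeDataset,
    HomeLayout,
    SensorNoiseModel,
    validate_specs,
)

SAMPLES_PER_DAY = DAY_S // GRID_STEP_S

#: Rooms a visitor prefers, in order of priority.
VISITOR_ROOMS = ("TV_ROOM", "LIVING")

#: Hard floor on drawn dwell times (seconds).
MIN_DWELL_S = 30.0


@dataclass(frozen=True)
class _Interval:
    label: str
    room: str | None
    start: float
    end: float


def _day_streams(seed: int, day_index: int):
    ss = np.random.SeedSequence([int(seed), int(day_index)])
    return [np.random.default_rng(c) for c in ss.spawn(4)]


def _draw_duration(spec: ActivitySpec, rng: np.random.Generator) -> float:
    d = spec.duration_median_s * float(np.exp(spec.duration_sigma * rng.standard_normal()))
    return max(d, MIN_DWELL_S)


def _day_schedule(
    specs: tuple[ActivitySpec, ...],
    away: ActivitySpec,
    day_index: int,
    rng: np.random.Generator,
) -> list[_Interval]:
    """Semi-Markov activity schedule covering [day_start, day_end) exactly."""
    day_start = float(day_index * DAY_S)
    day_end = day_start + DAY_S
    pool = list(specs) + [away]
    out: list[_Interval] = []
    t = day_start
    prev: str | None = None
    while t < day_end:
        eligible = [s for s in pool if s.starts_in_window(t) and s.label != prev]
        if not eligible:
            eligible = [s for s in pool if s.starts_in_window(t)]
        if not eligible:  # no window covers this clock time: resident is out
            eligible = [away]
        w = np.array([s.mean_occurrences_per_day for s in eligible], dtype=float)
        if w.sum() <= 0:
            w[:] = 1.0
        spec = eligible[rng.choice(len(eligible), p=w / w.sum())]
        d = min(_draw_duration(spec, rng), day_end - t)
        out.append(_Interval(spec.label, spec.room, t, t + d))
        prev = spec.label
        t += d
    return out


def _apply_overlaps(
    schedule: list[_Interval],
    specs: tuple[ActivitySpec, ...],
    overlap_prob: float,
    rng: np.random.Generator,
) -> tuple[list[_Interval], list[_Interval]]:
    """Interrupt long activities by a nested second activity.

    Returns (trajectory, extra_log_intervals): the trajectory splits the
    interrupted interval into before/inside/after parts (the resident really
    moves), while the log keeps the outer interval whole and adds the nested
    one, producing overlapping logbook entries.
    """
    trajectory: list[_Interval] = []
    extra: list[_Interval] = []
    for iv in schedule:
        dur = iv.end - iv.start
        if iv.label == AWAY or dur < 1200 or rng.random() >= overlap_prob:
            trajectory.append(iv)
            continue
        t1 = iv.start + dur * rng.uniform(0.3, 0.5)
        candidates = [
            s for s in specs
            if s.label != iv.label and s.room != iv.room and s.starts_in_window(t1)
        ]
        if not candidates:
            trajectory.append(iv)
            continue
        spec = candidates[rng.choice(len(candidates))]
        d2 = min(_draw_duration(spec, rng), 0.4 * (iv.end - t1))
        if d2 < MIN_DWELL_S:
            trajectory.append(iv)
            continue
        trajectory.extend([
            _Interval(iv.label, iv.room, iv.start, t1),
            _Interval(spec.label, spec.room, t1, t1 + d2),
            _Interval(iv.label, iv.room, t1 + d2, iv.end),
        ])
        extra.append(_Interval(spec.label, spec.room, t1, t1 + d2))
    return trajectory, extra


def _draw_visitors(
    layout: HomeLayout,
    day_index: int,
    visitor_rate: float,
    rng: np.random.Generator,
) -> list[_Interval]:
    rooms = [r for r in VISITOR_ROOMS if r in layout.rooms]
    if not rooms:
        rooms = [r for r in layout.rooms if r != "BEDROOM"]
    day_start = day_index * DAY_S
    episodes: list[_Interval] = []
    for _ in range(rng.poisson(visitor_rate)):
        start = day_start + rng.uniform(10, 20) * 3600.0
        dur = 1800.0 * float(np.exp(0.5 * rng.standard_normal()))
        room = rooms[rng.choice(len(rooms))]
        episodes.append(_Interval("VISITOR", room, start, min(start + dur, day_start + DAY_S)))
    return episodes


def _interval_arrays(intervals: list[_Interval]):
    starts = np.array([iv.start for iv in intervals])
    ends = np.array([iv.end for iv in intervals])
    rooms = np.array([iv.room if iv.room is not None else "" for iv in intervals], dtype=object)
    labels = np.array([iv.label for iv in intervals], dtype=object)
    return starts, ends, rooms, labels


def _render_readings(
    layout: HomeLayout,
    specs: tuple[ActivitySpec, ...],
    noise: SensorNoiseModel,
    trajectory: list[_Interval],
    visitors: list[_Interval],
    day_index: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Sample every box's channels at 0.2 Hz over one day."""
    starts, _ends, rooms_at, labels_at = _interval_arrays(trajectory)
    lights = {s.label: s.lights_on for s in specs}
    preferred = {s.label: s.preferred_box for s in specs if s.preferred_box is not None}
    day_start = day_index * DAY_S

    times_parts, box_parts, chan_parts, value_parts = [], [], [], []
    base = day_start + GRID_STEP_S * np.arange(SAMPLES_PER_DAY, dtype=float)
    for box in layout.boxes:
        phase = round(float(rng.uniform(0.0, 2.4)), 3)
        ts = base + phase
        idx = np.searchsorted(starts, ts, side="right") - 1
        idx = np.clip(idx, 0, len(starts) - 1)
        room_at = rooms_at[idx]
        label_at = labels_at[idx]
        clock = ts % DAY_S

        occupied = room_at == box.room
        vis_here = np.zeros(len(ts), dtype=bool)
        for ep in visitors:
            if ep.room == box.room:
                vis_here |= (ts >= ep.start) & (ts < ep.end)

        for channel in box.channels:
            if channel == "pir":
                p = np.where(occupied, noise.pir_hit_prob, noise.pir_false_prob)
                cross = [lab for lab, pb in preferred.items()
                         if pb != box.box_id and layout.box(pb).room == box.room]
                if cross:
                    mism = occupied & np.isin(label_at, cross)
                    p = np.where(mism, noise.pir_cross_zone_prob, p)
                p = np.maximum(p, np.where(vis_here, noise.pir_hit_prob, 0.0))
                values = (rng.random(len(ts)) < p).astype(float)
            elif channel == "temp":
                values = (noise.temp_base
                          + noise.temp_amplitude * np.sin(2 * np.pi * (clock - 32400.0) / DAY_S)
                          + noise.temp_noise_sd * rng.standard_normal(len(ts)))
            elif channel == "lux":
                daytime = (clock >= 7 * 3600) & (clock < 21 * 3600)
                lamp_on = np.array([lights.get(lab, False) for lab in label_at])
                values = np.where(daytime, noise.lux_day, noise.lux_night)
                values = values + np.where((occupied | vis_here) & lamp_on,
                                           noise.lamp_lux_bonus, 0.0)
                values = np.maximum(values + noise.lux_noise_sd * rng.standard_normal(len(ts)), 0.0)
            elif channel == "humidity":
                shower = label_at == "Grooming"
                values = (noise.humidity_base
                          + np.where(shower, noise.humidity_shower_spike, 0.0)
                          + noise.humidity_noise_sd * rng.standard_normal(len(ts)))
            elif channel in ("accel_x", "accel_y", "accel_z"):
                axis = ("accel_x", "accel_y", "accel_z").index(channel)
                cooking = label_at == "Cooking"
                # per-sample fridge-door events; axis chosen per event
                event = cooking & (rng.random(len(ts)) < noise.fridge_event_prob)
                event &= rng.integers(0, 3, len(ts)) == axis
                values = (noise.accel_idle
                          + np.where(event, noise.accel_event_magnitude, 0.0)
                          + noise.accel_noise_sd * rng.standard_normal(len(ts)))
            else:  # pragma: no cover - guarded by SensorBox validation
                raise ConfigurationError(f"unknown channel {channel}")
            times_parts.append(ts)
            box_parts.append(np.repeat(box.box_id, len(ts)))
            chan_parts.append(np.repeat(channel, len(ts)))
            value_parts.append(np.asarray(values, dtype=float))

    df = pd.DataFrame({
        "time_s": np.concatenate(times_parts),
        "box_id": pd.Categorical(np.concatenate(box_parts)),
        "channel": pd.Categorical(np.concatenate(chan_parts)),
        "value": np.concatenate(value_parts),
    })
    return df.sort_values("time_s", kind="stable").reset_index(drop=True)


def _log_frame(intervals: list[_Interval], visitors: list[_Interval]) -> pd.DataFrame:
    rows = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    visitor_flag = []
    for iv in rows:
        flag = any(ep.start < iv.end and iv.start < ep.end for ep in visitors)
        visitor_flag.append(int(flag))
    return pd.DataFrame({
        "start_s": [iv.start for iv in rows],
        "end_s": [iv.end for iv in rows],
        "label": [iv.label for iv in rows],
        "visitor": visitor_flag,
    })


def _simulate_one_day(
    layout: HomeLayout,
    specs: tuple[ActivitySpec, ...],
    away: ActivitySpec,
    noise: SensorNoiseModel,
    day_index: int,
    seed: int,
    overlap_prob: float,
    visitor_rate: float,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    rng_sched, rng_overlap, rng_visit, rng_render = _day_streams(seed, day_index)
    schedule = _day_schedule(specs, away, day_index, rng_sched)
    trajectory, extra = _apply_overlaps(schedule, specs, overlap_prob, rng_overlap)
    visitors = _draw_visitors(layout, day_index, visitor_rate, rng_visit) if visitor_rate > 0 else []
    readings = _render_readings(layout, specs, noise, trajectory, visitors, day_index, rng_render)
    log = _log_frame(schedule + extra, visitors)
    return readings, log


def simulate_day(
    layout: HomeLayout,
    specs: tuple[ActivitySpec, ...],
    noise: SensorNoiseModel,
    day_index: int,
    seed: int,
    away: ActivitySpec | None = None,
) -> tuple[pd.DataFrame, GroundTruthLog]:
    """Simulate a single day without overlaps or visitors.

    Returns the raw readings (time_s, box_id, channel, value) and the exact
    ground-truth log of the simulated intervals (including AWAY periods).
    Deterministic given all arguments.
    """
    if not specs:
        raise ConfigurationError("no activity specs given")
    validate_specs(specs, layout)
    from .home import default_away_spec

    away = away or default_away_spec()
    readings, log = _simulate_one_day(
        layout, specs, away, noise, day_index, seed, overlap_prob=0.0, visitor_rate=0.0
    )
    return readings, GroundTruthLog(log)


def simulate_home(
    layout: HomeLayout,
    specs: tuple[ActivitySpec, ...],
    noise: SensorNoiseModel,
    n_days: int,
    seed: int,
    overlap_prob: float = 0.0,
    visitor_rate: float = 0.0,
    home_id: str = "home",
    away: ActivitySpec | None = None,
) -> HomeDataset:
    """Simulate ``n_days`` consecutive days of one home.

    With probability ``overlap_prob`` a long activity is interrupted by a
    nested second activity (the logbook keeps both, overlapping); visitor
    episodes arrive at ``visitor_rate`` per day, fire the PIR of a second
    room concurrently and set the visitor flag on overlapping log intervals.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if not specs:
        raise ConfigurationError("no activity specs given")
    validate_specs(specs, layout)
    from .home import default_away_spec

    away = away or default_away_spec()
    readings_parts, log_parts = [], []
    for day in range(n_days):
        r, g = _simulate_one_day(layout, specs, away, noise, day, seed, overlap_prob, visitor_rate)
        readings_parts.append(r)
        log_parts.append(g)
    readings = pd.concat(readings_parts, ignore_index=True)
    log = GroundTruthLog(pd.concat(log_parts, ignore_index=True), home_id=home_id)
    return HomeDataset(home_id=home_id, layout=layout, readings=readings, log=log, n_days=n_days)


def simulate_cohort(
    n_homes: int,
    n_days: int,
    seed: int,
    layout: HomeLayout | None = None,
    specs: tuple[ActivitySpec, ...] | None = None,
    noise: SensorNoiseModel | None = None,
    overlap_prob: float = 0.0,
    visitor_rate: float = 0.0,
) -> list[HomeDataset]:
    """Simulate a cohort of homes with per-home derived seeds."""
    from .home import default_activity_specs, default_layout, default_noise

    layout = layout or default_layout()
    specs = specs or default_activity_specs()
    noise = noise or default_noise()
    seeds = np.random.SeedSequence(int(seed)).generate_state(n_homes) % (2**31)
    return [
        simulate_home(layout, specs, noise, n_days, int(seeds[h]),
                      overlap_prob=overlap_prob, visitor_rate=visitor_rate,
                      home_id=f"home_{h:02d}")
        for h in range(n_homes)
    ]
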