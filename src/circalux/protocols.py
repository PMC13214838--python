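"""Light-schedule construction.

Every simulation in this package is driven by a :class:`LightSchedule`, a
piecewise-linear lux-vs-time forcing covering a whole multi-day protocol.
Three families of schedules are provided:

* the two-week eBook / paper-book laboratory protocol (90 or 500 lux
  daytime, a 18:00-22:00 reading window at 30 lux (eBook) or 3 lux (book),
  sleep opportunity 22:00-06:00 in darkness, dim constant-posture
  assessment days closing each condition),
* a regular entrainment schedule (1000 lux for 16 h from a configurable
  lights-on clock time) used to equilibrate every parameter set, and
* baseline-plus-pulse days (ramped baseline 0-1000 lux, a 1 h bright pulse
  placed a given number of hours after the 06:00 waking reference, 50 lux
  at night except in the full-darkness case).

Schedules are the sole model input: there is no external data anywhere in
the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "LightSchedule",
    "ProtocolSpec",
    "ConditionOrder",
    "build_chang_schedule",
    "build_equilibration_schedule",
    "build_pulse_schedule",
    "lux_for_circadian_input",
]

HOURS_PER_DAY = 24.0


class ConditionOrder(str, Enum):
    """Which reading condition occupies the first study week."""

    EBOOK_FIRST = "ebook-first"
    BOOK_FIRST = "book-first"


@dataclass(frozen=True)
class LightSchedule:
    """Piecewise-linear illuminance forcing over ``total_days`` days.

    ``segments`` is an ``(n, 4)`` float array of rows
    ``(t_start_h, t_end_h, lux_start, lux_end)`` tiling
    ``[0, 24 * total_days]`` with no gaps or overlaps; lux is linearly
    interpolated inside a segment.
    """

    segments: np.ndarray
    total_days: int
    label: str = ""

    def __post_init__(self) -> None:
        seg = np.asarray(self.segments, dtype=float)
        if seg.ndim != 2 or seg.shape[1] != 4:
            raise ValueError("segments must be an (n, 4) array")
        if seg.shape[0] == 0:
            raise ValueError("schedule must contain at least one segment")
        object.__setattr__(self, "segments", seg)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        seg = self.segments
        t0, t1 = seg[:, 0], seg[:, 1]
        if np.any(t1 <= t0):
            raise ValueError("segments must have positive duration")
        if not np.all(np.diff(t0) > 0):
            raise ValueError("segments must be sorted by start time")
        if abs(t0[0]) > 1e-9:
            raise ValueError("schedule must start at t = 0")
        if len(seg) > 1 and np.max(np.abs(t0[1:] - t1[:-1])) > 1e-9:
            raise ValueError("segments must tile time with no gaps/overlaps")
        if abs(t1[-1] - HOURS_PER_DAY * self.total_days) > 1e-9:
            raise ValueError("segments must cover exactly total_days")
        if np.any(seg[:, 2:] < 0):
            raise ValueError("lux values must be non-negative")

    @property
    def t_end(self) -> float:
        return float(self.segments[-1, 1])

    # -- evaluation -------------------------------------------------------
    def lux(self, t):
        """Interpolated lux at time(s) ``t`` (hours since start).

        At a segment boundary the *right-hand* segment wins, so step
        changes take effect exactly at their scheduled instant.
        """
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < -1e-9) or np.any(t_arr > self.t_end + 1e-9):
            raise ValueError(f"time out of schedule range [0, {self.t_end}]")
        seg = self.segments
        idx = np.clip(np.searchsorted(seg[:, 0], t_arr, side="right") - 1, 0, len(seg) - 1)
        s = seg[idx]
        w = np.clip((t_arr - s[..., 0]) / (s[..., 1] - s[..., 0]), 0.0, 1.0)
        out = s[..., 2] + w * (s[..., 3] - s[..., 2])
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out

    def breakpoints(self) -> np.ndarray:
        """All segment boundary times, including 0 and the end."""
        return np.append(self.segments[:, 0], self.t_end)

    # -- serialization ----------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        header = "t_start_h,t_end_h,lux_start,lux_end"
        np.savetxt(path, self.segments, delimiter=",", header=header, comments="", fmt="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path, total_days: int | None = None, label: str = "") -> "LightSchedule":
        seg = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        if total_days is None:
            total_days = int(round(seg[-1, 1] / HOURS_PER_DAY))
        return cls(seg, total_days, label)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "label": self.label,
            "total_days": self.total_days,
            "segments": self.segments.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "LightSchedule":
        payload = json.loads(Path(path).read_text())
        return cls(np.asarray(payload["segments"]), payload["total_days"], payload["label"])


@dataclass(frozen=True)
class ProtocolSpec:
    """Parameters of the two-week eBook / paper-book laboratory protocol.

    Defaults reproduce the digitized laboratory conditions: 90 lux ambient
    daytime light, reading 18:00-22:00 at 30 lux (eBook) or 3 lux (book),
    darkness during the 22:00-06:00 sleep opportunity, five reading days
    per condition followed by two dim constant-posture (CP) assessment
    days.  The CP illuminance is not printed in the source protocol; 3 lux
    (dim-light melatonin assessment convention) is used and configurable.
    """

    baseline_lux: float = 90.0
    order: ConditionOrder = ConditionOrder.EBOOK_FIRST
    days_per_condition: int = 5
    cp_days_per_condition: int = 2
    reading_window: tuple[float, float] = (18.0, 22.0)
    ebook_lux: float = 30.0
    book_lux: float = 3.0
    sleep_window: tuple[float, float] = (22.0, 6.0)
    cp_lux: float = 3.0
    wake_window: tuple[float, float] = (6.0, 22.0)

    def __post_init__(self) -> None:
        if self.days_per_condition < 1:
            raise ValueError("days_per_condition must be >= 1")
        if self.ebook_lux <= self.book_lux:
            raise ValueError("ebook_lux must exceed book_lux")
        r0, r1 = self.reading_window
        w0, w1 = self.wake_window
        if not (w0 <= r0 < r1 <= w1):
            raise ValueError("reading window must lie inside the wake period")
        if min(self.baseline_lux, self.cp_lux, self.book_lux) < 0:
            raise ValueError("lux values must be non-negative")

    @property
    def total_days(self) -> int:
        return 2 * (self.days_per_condition + self.cp_days_per_condition)


def _segments_from_day_profiles(day_profiles: Sequence[Sequence[tuple[float, float, float, float]]]) -> np.ndarray:
    """Concatenate per-day clock-time profiles into absolute segments,
    merging adjacent segments with identical constant lux."""
    rows: list[list[float]] = []
    for d, profile in enumerate(day_profiles):
        off = HOURS_PER_DAY * d
        for (a, b, l0, l1) in profile:
            if b <= a:
                continue
            rows.append([off + a, off + b, l0, l1])
    merged: list[list[float]] = []
    for row in rows:
        if (
            merged
            and abs(merged[-1][1] - row[0]) < 1e-9
            and merged[-1][2] == merged[-1][3] == row[2] == row[3]
        ):
            merged[-1][1] = row[1]
        else:
            merged.append(list(row))
    return np.asarray(merged)


def _chang_day(spec: ProtocolSpec, reading_lux: float | None) -> list[tuple[float, float, float, float]]:
    """One protocol day as clock-time segments. ``reading_lux=None`` marks a
    constant-posture day (dim cp_lux across the whole wake period)."""
    w0, w1 = spec.wake_window
    prof: list[tuple[float, float, float, float]] = [(0.0, w0, 0.0, 0.0)]
    if reading_lux is None:
        prof.append((w0, w1, spec.cp_lux, spec.cp_lux))
    else:
        r0, r1 = spec.reading_window
        prof.append((w0, r0, spec.baseline_lux, spec.baseline_lux))
        prof.append((r0, r1, reading_lux, reading_lux))
        if r1 < w1:
            prof.append((r1, w1, spec.baseline_lux, spec.baseline_lux))
    prof.append((w1, HOURS_PER_DAY, 0.0, 0.0))
    return prof


def build_chang_schedule(spec: ProtocolSpec) -> LightSchedule:
    """Build the full two-condition laboratory schedule.

    The schedule covers ``days_per_condition`` reading days plus
    ``cp_days_per_condition`` constant-posture days for each condition, in
    the order given by ``spec.order`` (14 days with the defaults).  Daytime
    lux equals ``baseline_lux`` outside the reading window, the reading
    window carries the condition's lux, the sleep window is dark, and CP
    days are uniformly dim at ``cp_lux``.
    """
    first, second = (
        (spec.ebook_lux, spec.book_lux)
        if spec.order is ConditionOrder.EBOOK_FIRST
        else (spec.book_lux, spec.ebook_lux)
    )
    days: list[list[tuple[float, float, float, float]]] = []
    for lux in (first, second):
        days += [_chang_day(spec, lux)] * spec.days_per_condition
        days += [_chang_day(spec, None)] * spec.cp_days_per_condition
    label = f"chang-{spec.baseline_lux:g}lux-{spec.order.value}"
    return LightSchedule(_segments_from_day_profiles(days), spec.total_days, label)


def build_equilibration_schedule(lights_on_clock_time: float = 6.0, n_days: int = 30, lux: float = 1000.0) -> LightSchedule:
    """Regular 16 h light / 8 h dark entrainment schedule.

    ``lux`` (default 1000) from ``lights_on_clock_time`` for 16 h, darkness
    otherwise, repeated ``n_days`` times.  Lights-on times later than 08:00
    wrap the lit period across midnight.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if not 0.0 <= lights_on_clock_time < 24.0:
        raise ValueError("lights_on_clock_time must be a clock hour in [0, 24)")
    on, dur = float(lights_on_clock_time), 16.0
    days = []
    for _ in range(n_days):
        if on + dur <= HOURS_PER_DAY:
            prof = [(0.0, on, 0.0, 0.0), (on, on + dur, lux, lux), (on + dur, HOURS_PER_DAY, 0.0, 0.0)]
        else:
            spill = on + dur - HOURS_PER_DAY
            prof = [(0.0, spill, lux, lux), (spill, on, 0.0, 0.0), (on, HOURS_PER_DAY, lux, lux)]
        days.append(prof)
    label = f"equilibration-{lux:g}lux-on{lights_on_clock_time:g}h"
    return LightSchedule(_segments_from_day_profiles(days), n_days, label)


def build_pulse_schedule(
    baseline_lux: float,
    pulse_offset_h: float,
    pulse_lux: float = 5000.0,
    pulse_duration_h: float = 1.0,
    n_days: int = 20,
    nighttime_lux: float = 50.0,
    caption_ramps: bool = False,
) -> LightSchedule:
    """Baseline-plus-pulse day, repeated ``n_days`` times (default 20).

    The default dialect follows the normative description: nighttime lux
    before 06:00 and after 22:00, a linear ramp up to ``baseline_lux``
    06:00-08:00 and back down to the nighttime value 20:00-22:00.  The
    nighttime value is 50 lux unless ``baseline_lux`` is 0 (full-darkness
    case, nighttime 0).  A rectangular ``pulse_lux`` pulse of
    ``pulse_duration_h`` starts ``pulse_offset_h`` after the 06:00 waking
    reference.  ``caption_ramps=True`` selects the alternative dialect in
    which light ramps down to zero between 18:00 and 20:00.
    """
    if baseline_lux < 0:
        raise ValueError("baseline_lux must be non-negative")
    if not 0.0 <= pulse_offset_h <= 14.0:
        raise ValueError("pulse_offset_h must be in [0, 14]")
    if pulse_lux < baseline_lux:
        raise ValueError("pulse_lux must be at least baseline_lux")
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    night = 0.0 if baseline_lux == 0 else float(nighttime_lux)
    wake_ref = 6.0
    p0 = wake_ref + pulse_offset_h
    p1 = p0 + pulse_duration_h
    if p1 > HOURS_PER_DAY:
        raise ValueError("pulse extends past the end of the day; wrapping is not supported")
    if caption_ramps:
        base = [
            (0.0, 6.0, night, night),
            (6.0, 8.0, night, baseline_lux),
            (8.0, 18.0, baseline_lux, baseline_lux),
            (18.0, 20.0, baseline_lux, 0.0),
            (20.0, HOURS_PER_DAY, 0.0, 0.0),
        ]
    else:
        base = [
            (0.0, 6.0, night, night),
            (6.0, 8.0, night, baseline_lux),
            (8.0, 20.0, baseline_lux, baseline_lux),
            (20.0, 22.0, baseline_lux, night),
            (22.0, HOURS_PER_DAY, night, night),
        ]
    # overlay the rectangular pulse, splitting base segments at its edges
    prof: list[tuple[float, float, float, float]] = []
    for (a, b, l0, l1) in base:
        def interp(t: float) -> float:
            return l0 + (t - a) / (b - a) * (l1 - l0)

        lo, hi = max(a, p0), min(b, p1)
        if lo >= hi:  # no overlap
            prof.append((a, b, l0, l1))
            continue
        if a < p0:
            prof.append((a, p0, l0, interp(p0)))
        prof.append((lo, hi, pulse_lux, pulse_lux))
        if p1 < b:
            prof.append((p1, b, interp(p1), l1))
    label = f"pulse-{baseline_lux:g}base-{pulse_lux:g}lux-at{pulse_offset_h:g}h"
    return LightSchedule(_segments_from_day_profiles([prof] * n_days), n_days, label)


def lux_for_circadian_input(schedule: LightSchedule, t: float, asleep: bool) -> float:
    """Light input seen by the circadian model: 0 lux during sleep (eyes
    closed), the schedule's interpolated value otherwise."""
    val = schedule.lux(t)  # raises if t is out of range, even when asleep
    return 0.0 if asleep else val
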