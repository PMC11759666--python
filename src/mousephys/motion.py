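"""Spontaneous-motion-artifact screening from triaxial accelerometry.

A head-mounted accelerometer on an awake mouse reads ~9.81 m/s^2 at rest
(gravity) plus posture drift; movement shows up as broadband transients.
After baseline removal, a motion artifact is any interval during which the
acceleration magnitude exceeds 0.2 m/s^2 for 200 ms or longer; recordings are
additionally summarized on a 0.5 s screening grid.  Imaging trials that
overlap an artifact are flagged as corrupted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "TriaxialTrace",
    "AccelMagnitudeTrace",
    "ArtifactEvent",
    "MotionConfig",
    "accel_magnitude",
    "remove_baseline",
    "detect_artifacts",
    "screen_intervals",
    "screen_trials",
]


@dataclass(frozen=True)
class TriaxialTrace:
    """Uniformly sampled triaxial accelerometer samples in m/s^2."""

    time: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        n = len(self.time)
        if not (len(self.ax) == len(self.ay) == len(self.az) == n):
            raise ValueError("time and axis channels must have equal lengths")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")


@dataclass(frozen=True)
class AccelMagnitudeTrace:
    time: np.ndarray
    magnitude: np.ndarray
    sampling_rate: float


@dataclass(frozen=True)
class ArtifactEvent:
    """A detected motion bout: half-open interval [start, end) in seconds."""

    start: float
    end: float
    peak_magnitude: float

    @property
    def duration(self) -> float:
        return self.end - self.start

    def overlaps(self, start: float, end: float) -> bool:
        return self.start < end and self.end > start


@dataclass
class MotionConfig:
    """Detection rule parameters.

    threshold
        Magnitude bound in m/s^2 (applied after baseline removal by default).
    min_duration
        Minimum sustained supra-threshold duration in seconds.
    screen_interval
        Grid spacing of the boolean screening summary.
    baseline_window
        Sliding-median window (s) used to remove gravity and posture drift.
    """

    threshold: float = 0.2
    min_duration: float = 0.2
    screen_interval: float = 0.5
    baseline_window: float = 1.0

    def validate(self) -> None:
        for name in ("threshold", "min_duration", "screen_interval", "baseline_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"MotionConfig.{name} must be positive")


def accel_magnitude(trace: TriaxialTrace) -> AccelMagnitudeTrace:
    """Euclidean magnitude sqrt(ax^2 + ay^2 + az^2) per sample."""
    mag = np.sqrt(
        np.asarray(trace.ax) ** 2
        + np.asarray(trace.ay) ** 2
        + np.asarray(trace.az) ** 2
    )
    return AccelMagnitudeTrace(np.asarray(trace.time), mag, trace.sampling_rate)


def remove_baseline(trace: TriaxialTrace, config: MotionConfig) -> TriaxialTrace:
    """Subtract a per-axis sliding median, removing gravity and slow drift.

    The window (``config.baseline_window`` seconds) must be much longer than a
    movement bout so the median tracks posture, not motion.
    """
    config.validate()
    win = int(round(config.baseline_window * trace.sampling_rate))
    if win > len(trace.time):
        raise ValueError("baseline_window longer than the trace")
    win = max(win, 1)
    if win % 2 == 0:
        win += 1
    out = {}
    for name in ("ax", "ay", "az"):
        x = np.asarray(getattr(trace, name), dtype=float)
        out[name] = x - ndimage.median_filter(x, size=win, mode="nearest")
    return TriaxialTrace(trace.time, out["ax"], out["ay"], out["az"], trace.sampling_rate)


def detect_artifacts(
    mag: AccelMagnitudeTrace, config: MotionConfig
) -> list[ArtifactEvent]:
    """Sustained-threshold rule: supra-threshold runs lasting >= min_duration.

    Runs separated by a single sub-threshold sample are merged (one movement,
    not two).  Event intervals are half-open in time; duration is the number
    of supra-threshold samples over the sampling rate.
    """
    config.validate()
    m = np.asarray(mag.magnitude, dtype=float)
    above = m > config.threshold
    if not above.any():
        return []
    # merge runs separated by exactly one sub-threshold sample
    merged = above.copy()
    interior = np.flatnonzero(~above[1:-1] & above[:-2] & above[2:]) + 1
    merged[interior] = True

    dt = 1.0 / mag.sampling_rate
    events: list[ArtifactEvent] = []
    labeled, nlab = ndimage.label(merged)
    for sl in ndimage.find_objects(labeled):
        i0, i1 = sl[0].start, sl[0].stop
        duration = (i1 - i0) * dt
        if duration >= config.min_duration - 1e-12:
            events.append(
                ArtifactEvent(
                    start=float(mag.time[i0]),
                    end=float(mag.time[i1 - 1]) + dt,
                    peak_magnitude=float(m[i0:i1].max()),
                )
            )
    return events


def screen_intervals(
    mag: AccelMagnitudeTrace,
    config: MotionConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean artifact summary on the screening grid.

    Returns ``(interval_starts, flags)`` where ``flags[k]`` is True iff a
    detected artifact overlaps ``[interval_starts[k], interval_starts[k] +
    screen_interval)``.
    """
    events = detect_artifacts(mag, config)
    t0 = float(mag.time[0])
    t1 = float(mag.time[-1]) + 1.0 / mag.sampling_rate
    starts = np.arange(t0, t1, config.screen_interval)
    flags = np.array(
        [
            any(e.overlaps(s, s + config.screen_interval) for e in events)
            for s in starts
        ],
        dtype=bool,
    )
    return starts, flags


def screen_trials(
    events: list[ArtifactEvent], trials: list[tuple[float, float]]
) -> np.ndarray:
    """Per-trial viability: a trial [start, end) is corrupted iff any artifact
    event overlaps it.  Returns a boolean array, True = viable."""
    ordered = sorted(trials)
    for (s0, e0), (s1, _) in zip(ordered, ordered[1:]):
        if s1 < e0:
            warnings.warn("trial intervals overlap", stacklevel=2)
            break
    viable = np.array(
        [not any(e.overlaps(s, t) for e in events) for (s, t) in trials],
        dtype=bool,
    )
    return viable
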