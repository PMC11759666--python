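"""Trigger parsing, trial segmentation, normalization, and block averaging.

Stimulation trials are initiated by a 5 V TTL trigger; each trial is a
pre-stimulation baseline, a stimulus train, and a post-stimulation window
(e.g. 5/3/22 s for reflectance imaging at 5 fps, 3/3/6.5 s for calcium
imaging at 20 fps).  Optical signals are expressed as fractional change
relative to the pre-stimulus baseline (dR/R0 or dF/F0); reflectance traces
are sign-inverted so that an increase represents an increase in blood volume.
Pupil diameter is kept in pixels with baseline subtraction only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "AnalogTrace",
    "StimProtocol",
    "Trial",
    "NormalizedTrace",
    "BlockAverage",
    "detect_triggers",
    "segment_trials",
    "normalize_trial",
    "block_average",
    "detrend_trace",
]


@dataclass(frozen=True)
class AnalogTrace:
    """A uniformly sampled scalar channel (trigger volts, ROI signal, px)."""

    time: np.ndarray
    values: np.ndarray
    sampling_rate: float
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("time and values must be equal-length 1-D arrays")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class StimProtocol:
    """Trial timing: pre/stim/post windows and the pulse train inside stim.

    Defaults follow a 3 Hz pneumatic whisker-deflection train: five 300 ms
    pulses separated by 300 ms gaps.
    """

    pre: float
    stim: float
    post: float
    pulse_duration: float = 0.3
    pulse_interval: float = 0.3
    n_pulses: int = 5

    def __post_init__(self) -> None:
        if min(self.pre, self.stim, self.post) < 0:
            raise ValueError("pre/stim/post must be non-negative")
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        train = (
            self.n_pulses * self.pulse_duration
            + (self.n_pulses - 1) * self.pulse_interval
        )
        if train > self.stim + 1e-9:
            raise ValueError("pulse train does not fit inside the stim window")

    @property
    def trial_duration(self) -> float:
        return self.pre + self.stim + self.post

    @property
    def pulse_onsets(self) -> np.ndarray:
        """Pulse onset times relative to stimulus onset (s)."""
        return np.arange(self.n_pulses) * (self.pulse_duration + self.pulse_interval)

    def n_samples(self, sampling_rate: float) -> int:
        return int(round(self.trial_duration * sampling_rate))


@dataclass(frozen=True)
class Trial:
    """One stimulus-locked segment; time is trial-relative (0 = trial start)."""

    time: np.ndarray
    values: np.ndarray
    stim_onset: float
    sampling_rate: float
    modality: str = ""
    index: int = -1
    start_time: float = 0.0
    viable: bool = True


@dataclass(frozen=True)
class NormalizedTrace:
    """Baseline-normalized trial signal.

    ``values`` are dimensionless fractional change (dR/R0, dF/F0) or pixels
    (pupil, baseline-subtracted).  The baseline-window mean of ``values`` is
    zero by construction.
    """

    time: np.ndarray
    values: np.ndarray
    stim_onset: float
    sampling_rate: float
    baseline_value: float
    sign_convention: str = "raw"  # "raw" | "inverted"
    modality: str = ""
    viable: bool = True


@dataclass(frozen=True)
class BlockAverage:
    """Pointwise mean over viable trials with per-timepoint SD and n."""

    time: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: int
    stim_onset: float
    sampling_rate: float
    modality: str = ""


def detect_triggers(trace: AnalogTrace, high_threshold: float = 2.5) -> np.ndarray:
    """Rising-edge times: transitions from below to at-or-above the threshold.

    Edges closer than two samples collapse to the first (contact debounce).
    """
    v = trace.values
    if not np.all(np.isfinite(v)):
        raise ValueError("trigger trace contains non-finite samples")
    above = v >= high_threshold
    edges = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if len(edges) == 0:
        return np.array([], dtype=float)
    keep = [edges[0]]
    for e in edges[1:]:
        if e - keep[-1] >= 2:
            keep.append(e)
    return trace.time[np.array(keep)]


def segment_trials(
    trace: AnalogTrace,
    trial_starts: Sequence[float],
    protocol: StimProtocol,
    modality: str = "",
) -> list[Trial]:
    """Cut ``[start, start + pre + stim + post)`` segments out of a trace.

    Trial-relative time starts at 0; the first stimulus pulse is at
    ``protocol.pre``.  A trial extending past the trace end raises, naming
    the trial index.
    """
    fs = trace.sampling_rate
    n = protocol.n_samples(fs)
    t0 = float(trace.time[0])
    trials: list[Trial] = []
    for k, start in enumerate(trial_starts):
        i0 = int(round((start - t0) * fs))
        if i0 < 0 or i0 + n > len(trace.values):
            raise ValueError(
                f"trial {k} (start {start:.3f} s) extends outside the trace"
            )
        trials.append(
            Trial(
                time=np.arange(n) / fs,
                values=trace.values[i0 : i0 + n].copy(),
                stim_onset=protocol.pre,
                sampling_rate=fs,
                modality=modality,
                index=k,
                start_time=float(start),
            )
        )
    return trials


def normalize_trial(
    trial: Trial, invert: bool = False, mode: str = "fractional"
) -> NormalizedTrace:
    """Express a trial relative to its pre-stimulus baseline.

    ``mode="fractional"`` gives (x - x0)/x0 with x0 the baseline-window mean
    (dR/R0, dF/F0); ``invert`` flips the sign, the blood-volume convention
    for reflectance.  ``mode="subtract"`` only subtracts the baseline (pupil
    diameter stays in px).
    """
    baseline = trial.values[trial.time < trial.stim_onset]
    if baseline.size == 0:
        raise ValueError("empty baseline window: stim_onset must be > 0")
    x0 = float(baseline.mean())
    if mode == "fractional":
        scale = max(1.0, float(np.abs(trial.values).max()))
        if abs(x0) < 1e-12 * scale:
            raise ValueError("baseline mean is zero: fractional change undefined")
        out = (trial.values - x0) / x0
    elif mode == "subtract":
        out = trial.values - x0
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if invert:
        out = -out
    return NormalizedTrace(
        time=trial.time,
        values=out,
        stim_onset=trial.stim_onset,
        sampling_rate=trial.sampling_rate,
        baseline_value=x0,
        sign_convention="inverted" if invert else "raw",
        modality=trial.modality,
        viable=trial.viable,
    )


def block_average(traces: Sequence[NormalizedTrace]) -> BlockAverage:
    """Pointwise mean over viable trials; SD uses ddof=1 when n > 1."""
    viable = [t for t in traces if t.viable]
    if not viable:
        raise ValueError("no viable trials to average")
    n = len(viable)
    lengths = {len(t.values) for t in viable}
    if len(lengths) != 1:
        raise ValueError("trials have unequal lengths")
    stack = np.vstack([t.values for t in viable])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if n > 1 else np.zeros_like(mean)
    ref = viable[0]
    return BlockAverage(
        time=ref.time,
        mean=mean,
        sd=sd,
        n=n,
        stim_onset=ref.stim_onset,
        sampling_rate=ref.sampling_rate,
        modality=ref.modality,
    )


def detrend_trace(
    trace: NormalizedTrace, window: Optional[tuple[float, float]] = None
) -> NormalizedTrace:
    """Subtract the least-squares line fitted over ``window`` (whole trace by
    default).  The line is evaluated over the full trace."""
    t = trace.time
    if window is None:
        sel = np.ones_like(t, dtype=bool)
    else:
        sel = (t >= window[0]) & (t < window[1])
    if sel.sum() < 3:
        raise ValueError("detrend window must contain at least 3 samples")
    coeffs = np.polyfit(t[sel], trace.values[sel], 1)
    return replace(trace, values=trace.values - np.polyval(coeffs, t))
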