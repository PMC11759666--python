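"""Stimulus-evoked response kinetics and cross-modal timing analysis.

Onset time is the interval from the first stimulus pulse to the response's
first crossing of 10% of its peak height; rise time is the interval between
the first crossings of 10% and 90% of peak height.  Crossings are linearly
interpolated between samples, which is what makes sub-sample timing possible
at 5 fps.  Temporal relationships between modalities (pupil vs hemodynamics,
pupil vs calcium) are quantified by windowed, coefficient-normalized
cross-correlation; group timing differences by a two-tailed pooled-variance
t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .trials import NormalizedTrace

__all__ = [
    "KineticsEstimate",
    "XCorrResult",
    "GroupComparison",
    "onset_time",
    "rise_time",
    "response_kinetics",
    "cross_correlate",
    "compare_groups",
]


@dataclass(frozen=True)
class KineticsEstimate:
    """Onset/rise summary of one evoked response.

    Times are in seconds.  ``onset_time`` and ``rise_time`` are relative to
    the first stimulus; ``t10``/``t90``/``peak_time`` are in trial time.
    ``defined`` is False when the response has no positive peak or the
    threshold crossings do not occur.
    """

    onset_time: float
    rise_time: float
    peak_value: float
    peak_time: float
    t10: float
    t90: float
    defined: bool = True


@dataclass(frozen=True)
class XCorrResult:
    lags: np.ndarray          # seconds; positive lag means `a` leads `b`
    coefficients: np.ndarray  # dimensionless, in [-1, 1]
    peak_lag: float
    peak_value: float
    window: tuple[float, float]


@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    p: float
    degenerate: bool = False


def _first_upward_crossing(
    t: np.ndarray, y: np.ndarray, level: float
) -> Optional[float]:
    """Time of the first transition from below `level` to at-or-above it,
    linearly interpolated between the bracketing samples."""
    if y[0] >= level:
        return float(t[0])
    hits = np.flatnonzero((y[1:] >= level) & (y[:-1] < level))
    if len(hits) == 0:
        return None
    i = int(hits[0])
    frac = (level - y[i]) / (y[i + 1] - y[i])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def response_kinetics(
    trace: NormalizedTrace,
    stim_onset: Optional[float] = None,
    search_window: Optional[tuple[float, float]] = None,
) -> KineticsEstimate:
    """Peak, onset (to 10% of peak), and 10-90% rise time of a response.

    The peak is the global maximum inside ``search_window`` (default: first
    stimulus to end of trial — robust to pulse-locked ripple in calcium
    traces).  The trace must already be baseline-normalized so the
    pre-stimulus level is zero.
    """
    t = trace.time
    y = trace.values
    s0 = trace.stim_onset if stim_onset is None else stim_onset
    if search_window is None:
        search_window = (s0, float(t[-1]) + 1.0 / trace.sampling_rate)
    sel = (t >= search_window[0]) & (t < search_window[1])
    if not sel.any():
        raise ValueError("search window contains no samples")
    peak_idx_local = int(np.argmax(y[sel]))
    peak_idx = np.flatnonzero(sel)[peak_idx_local]
    peak = float(y[peak_idx])
    undefined = KineticsEstimate(np.nan, np.nan, peak, float(t[peak_idx]),
                                 np.nan, np.nan, defined=False)
    if peak <= 0:
        return undefined
    after = t >= s0
    t10 = _first_upward_crossing(t[after], y[after], 0.1 * peak)
    t90 = _first_upward_crossing(t[after], y[after], 0.9 * peak)
    if t10 is None or t90 is None:
        return undefined
    return KineticsEstimate(
        onset_time=t10 - s0,
        rise_time=t90 - t10,
        peak_value=peak,
        peak_time=float(t[peak_idx]),
        t10=t10,
        t90=t90,
    )


def onset_time(
    trace: NormalizedTrace,
    stim_onset: Optional[float] = None,
    search_window: Optional[tuple[float, float]] = None,
) -> float:
    """First-stimulus-to-10%-of-peak latency in seconds (NaN if undefined)."""
    return response_kinetics(trace, stim_onset, search_window).onset_time


def rise_time(
    trace: NormalizedTrace,
    stim_onset: Optional[float] = None,
    search_window: Optional[tuple[float, float]] = None,
) -> float:
    """10%-to-90%-of-peak rise time in seconds (NaN if undefined)."""
    return response_kinetics(trace, stim_onset, search_window).rise_time


def cross_correlate(
    a: NormalizedTrace,
    b: NormalizedTrace,
    window: Optional[tuple[float, float]] = None,
    max_lag: Optional[float] = None,
) -> XCorrResult:
    """Coefficient-normalized cross-correlation over a time window.

    Both signals are mean-subtracted over the window; normalization is by the
    product of their window-wide root energies, so the autocorrelation equals
    1 at zero lag.  ``peak_lag`` is the lag of the maximum coefficient;
    positive lag means ``a`` leads ``b``.  Detrending of a drifting channel
    (typically the pupil) is the caller's responsibility.
    """
    if a.sampling_rate != b.sampling_rate:
        raise ValueError("traces must share a sampling rate")
    fs = a.sampling_rate
    if window is None:
        window = (float(a.time[0]), float(a.time[-1]) + 1.0 / fs)
    sel_a = (a.time >= window[0]) & (a.time < window[1])
    sel_b = (b.time >= window[0]) & (b.time < window[1])
    xa = a.values[sel_a] - a.values[sel_a].mean()
    xb = b.values[sel_b] - b.values[sel_b].mean()
    n = min(len(xa), len(xb))
    xa, xb = xa[:n], xb[:n]
    if n < 2:
        raise ValueError("correlation window too short")
    denom = np.sqrt(np.dot(xa, xa) * np.dot(xb, xb))
    if denom == 0:
        raise ValueError("zero-variance input in the correlation window")
    # full[k] corresponds to lag (k - (n-1)); at positive lag, a is shifted
    # earlier relative to b, i.e. a leads b.
    full = np.correlate(xb, xa, mode="full") / denom
    lags = (np.arange(-(n - 1), n)) / fs
    if max_lag is None:
        max_lag = (window[1] - window[0]) / 2.0
    keep = np.abs(lags) <= max_lag + 1e-12
    lags, coef = lags[keep], full[keep]
    i = int(np.argmax(coef))
    return XCorrResult(
        lags=lags,
        coefficients=coef,
        peak_lag=float(lags[i]),
        peak_value=float(coef[i]),
        window=window,
    )


def compare_groups(a: Sequence[float], b: Sequence[float]) -> GroupComparison:
    """Two-tailed independent t-test with pooled variance (mean +/- SD)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    sd_a = float(a.std(ddof=1))
    sd_b = float(b.std(ddof=1))
    if sd_a == 0 and sd_b == 0:
        # zero pooled variance: identical-mean groups are indistinguishable
        equal = float(a.mean()) == float(b.mean())
        t = 0.0 if equal else float(np.sign(a.mean() - b.mean()) * np.inf)
        p = 1.0 if equal else 0.0
        return GroupComparison(
            float(a.mean()), sd_a, len(a), float(b.mean()), sd_b, len(b),
            t, p, degenerate=True,
        )
    res = stats.ttest_ind(a, b, equal_var=True)
    return GroupComparison(
        float(a.mean()), sd_a, len(a),
        float(b.mean()), sd_b, len(b),
        float(res.statistic), float(res.pvalue),
    )
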