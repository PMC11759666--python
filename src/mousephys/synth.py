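"""Synthetic fixtures with exact ground truth.

Three generators make every other module testable without recorded data:

* :func:`render_eye_frame` draws an anti-aliased eye image — dark elliptical
  pupil on a brighter iris disk, optional specular highlight and a whisker-like
  occluder bar that can split the pupil in two — and returns the true ellipse.
* :func:`gen_accel_trace` synthesizes gravity + noise + half-sine movement
  bouts and returns the bouts that satisfy the artifact rule analytically.
* :func:`gen_evoked_session` builds a full stimulation session: per-modality
  evoked responses from parametric kernels (fast adapting per-pulse calcium,
  slow hemodynamic, train-integrating pupil), a TTL trigger channel, an
  accelerometer channel, and artifact-corrupted trials — with onset and rise
  times of each noiseless response computed on a dense grid as ground truth.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .motion import ArtifactEvent, TriaxialTrace
from .pupil import EllipseFit, GrayFrame
from .trials import AnalogTrace, StimProtocol

__all__ = [
    "EyeSceneParams",
    "Occluder",
    "MotionBout",
    "EvokedModelParams",
    "SyntheticSession",
    "render_eye_frame",
    "gen_accel_trace",
    "gen_evoked_session",
    "default_models",
    "write_session",
]

DENSE_DT = 1e-4  # grid step (s) for analytic onset/rise ground truth


@dataclass(frozen=True)
class Occluder:
    """A straight bar (whisker) crossing the frame.

    ``orientation`` is the bar direction in radians (0 = horizontal);
    ``offset`` displaces the bar from the pupil center along the bar normal;
    ``width`` is in px.  Intensity defaults to the iris intensity.
    """

    orientation: float = 0.0
    width: float = 3.0
    offset: float = 0.0
    intensity: Optional[float] = None


@dataclass(frozen=True)
class EyeSceneParams:
    """Geometry and photometry of a rendered eye frame (8-bit counts)."""

    shape: tuple[int, int] = (240, 320)  # (rows, cols)
    center: tuple[float, float] = (160.0, 120.0)  # (x, y) px
    axes: tuple[float, float] = (40.0, 24.0)  # full (major, minor) px
    orientation: float = 0.0
    pupil_intensity: float = 30.0
    iris_intensity: float = 150.0
    background_intensity: float = 200.0
    iris_radius: float = 90.0
    specular: Optional[tuple[tuple[float, float], float, float]] = None
    occluder: Optional[Occluder] = None
    noise_sigma: float = 0.0
    seed: int = 0
    supersample: int = 4

    def __post_init__(self) -> None:
        if self.pupil_intensity >= self.iris_intensity:
            raise ValueError("dark-pupil convention: pupil_intensity < iris_intensity")
        a, b = self.axes[0] / 2.0, self.axes[1] / 2.0
        if not a >= b > 0:
            raise ValueError("axes must satisfy major >= minor > 0")
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        half_w = np.hypot(a * c, b * s)
        half_h = np.hypot(a * s, b * c)
        x, y = self.center
        rows, cols = self.shape
        if not (half_w <= x <= cols - 1 - half_w and half_h <= y <= rows - 1 - half_h):
            raise ValueError("pupil ellipse does not fit inside the frame")


def render_eye_frame(params: EyeSceneParams) -> tuple[GrayFrame, EllipseFit]:
    """Render one frame by supersampled averaging (anti-aliased edges)."""
    s = params.supersample
    rows, cols = params.shape
    yy = (np.arange(rows * s) + 0.5) / s - 0.5
    xx = (np.arange(cols * s) + 0.5) / s - 0.5
    X, Y = np.meshgrid(xx, yy)

    img = np.full((rows * s, cols * s), params.background_intensity, dtype=float)

    cx, cy = params.center
    dx, dy = X - cx, Y - cy
    iris = dx**2 + dy**2 <= params.iris_radius**2
    img[iris] = params.iris_intensity

    a, b = params.axes[0] / 2.0, params.axes[1] / 2.0
    c, sn = np.cos(params.orientation), np.sin(params.orientation)
    u = dx * c + dy * sn
    v = -dx * sn + dy * c
    pupil = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    img[pupil] = params.pupil_intensity

    if params.specular is not None:
        (sx, sy), srad, sval = params.specular
        spec = (X - sx) ** 2 + (Y - sy) ** 2 <= srad**2
        img[spec] = sval

    occ = params.occluder
    if occ is not None and occ.width > 0:
        phi = occ.orientation
        # signed distance from the bar's center line along its normal
        dist = -(X - cx) * np.sin(phi) + (Y - cy) * np.cos(phi) - occ.offset
        bar = np.abs(dist) <= occ.width / 2.0
        img[bar] = occ.intensity if occ.intensity is not None else params.iris_intensity

    # average the supersampled grid down to the target resolution
    img = img.reshape(rows, s, cols, s).mean(axis=(1, 3))

    if params.noise_sigma > 0:
        rng = np.random.default_rng(params.seed)
        img = img + rng.normal(0.0, params.noise_sigma, img.shape)

    frame = GrayFrame(np.clip(np.round(img), 0, 255).astype(np.uint8))
    truth = EllipseFit(
        center=params.center,
        major_axis_length=params.axes[0],
        minor_axis_length=params.axes[1],
        orientation=params.orientation % np.pi,
    )
    return frame, truth


@dataclass(frozen=True)
class MotionBout:
    """A half-sine movement transient injected into the accelerometer."""

    start: float
    duration: float
    amplitude: float
    axis_mix: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("bout duration must be positive")
        if self.amplitude < 0:
            raise ValueError("bout amplitude must be non-negative")

    def supra_threshold_interval(
        self, threshold: float
    ) -> Optional[tuple[float, float]]:
        """Analytic interval where the half-sine envelope exceeds threshold."""
        if self.amplitude <= threshold:
            return None
        frac = np.arcsin(threshold / self.amplitude) / np.pi  # of duration
        return (
            self.start + frac * self.duration,
            self.start + (1 - frac) * self.duration,
        )


def gen_accel_trace(
    duration: float,
    fs: float = 50.0,
    gravity: tuple[float, float, float] = (0.0, 0.0, 9.81),
    noise_sigma: float = 0.0,
    bouts: Sequence[MotionBout] = (),
    seed: int = 0,
    threshold: float = 0.2,
    min_duration: float = 0.2,
) -> tuple[TriaxialTrace, list[ArtifactEvent]]:
    """Gravity + white noise + half-sine bouts; returns the trace and the
    ground-truth artifact events (bouts whose supra-threshold envelope lasts
    at least ``min_duration``)."""
    ordered = sorted(bouts, key=lambda b: b.start)
    for b0, b1 in zip(ordered, ordered[1:]):
        if b1.start < b0.start + b0.duration:
            raise ValueError("bouts overlap")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)
    data = np.tile(np.asarray(gravity, dtype=float), (n, 1))
    if noise_sigma > 0:
        data += rng.normal(0.0, noise_sigma, (n, 3))
    truth: list[ArtifactEvent] = []
    for bout in ordered:
        mix = np.asarray(bout.axis_mix, dtype=float)
        mix = mix / np.linalg.norm(mix)
        sel = (t >= bout.start) & (t < bout.start + bout.duration)
        wave = bout.amplitude * np.sin(np.pi * (t[sel] - bout.start) / bout.duration)
        data[sel] += wave[:, None] * mix[None, :]
        supra = bout.supra_threshold_interval(threshold)
        if supra is not None and supra[1] - supra[0] >= min_duration:
            truth.append(
                ArtifactEvent(start=supra[0], end=supra[1], peak_magnitude=bout.amplitude)
            )
    trace = TriaxialTrace(t, data[:, 0], data[:, 1], data[:, 2], fs)
    return trace, truth


@dataclass
class EvokedModelParams:
    """Parametric evoked-response model for one modality.

    The noiseless response is the stimulus train passed through a kernel and
    normalized to unit peak; ``amplitude`` then scales it into signal units
    (fractional change for optical channels, px for pupil).  ``latency``
    shifts the whole response (neural/neurovascular delay).  Per-pulse models
    place one kernel per stimulus pulse with multiplicative ``pulse_gain``
    adaptation; the integrating model convolves the kernel with a boxcar
    drive spanning the whole stimulus window (the pupil dilates gradually as
    the train persists).  ``noise_sigma`` is relative to the response peak.
    """

    modality: str
    kernel: str = "double_exp"  # "double_exp" | "gamma"
    latency: float = 0.0
    tau_rise: float = 0.1
    tau_decay: float = 0.4
    gamma_shape: float = 6.0
    gamma_scale: float = 0.25
    per_pulse: bool = True
    pulse_gain: float = 1.0
    amplitude: float = 0.05
    baseline: float = 100.0
    noise_sigma: float = 0.0
    sampling_rate: float = 20.0
    negate: bool = False


def default_models(noise_sigma: float = 0.0) -> dict[str, EvokedModelParams]:
    """Study-condition defaults for the three modalities.

    Time constants were chosen so the noiseless kinetics reproduce the
    physiological ordering: calcium onsets first and rises fastest, the pupil
    onsets before the hemodynamic response but takes longest to peak.
    """
    return {
        "GCaMP": EvokedModelParams(
            modality="GCaMP", kernel="double_exp", latency=0.05,
            tau_rise=0.1, tau_decay=0.35, per_pulse=True, pulse_gain=0.5,
            amplitude=0.05, baseline=100.0, noise_sigma=noise_sigma,
            sampling_rate=20.0,
        ),
        "OIS": EvokedModelParams(
            modality="OIS", kernel="gamma", latency=0.35,
            gamma_shape=6.0, gamma_scale=0.25, per_pulse=True,
            amplitude=0.02, baseline=100.0, noise_sigma=noise_sigma,
            sampling_rate=5.0, negate=True,
        ),
        "pupil": EvokedModelParams(
            modality="pupil", kernel="double_exp", latency=0.15,
            tau_rise=0.3, tau_decay=4.0, per_pulse=False,
            amplitude=5.0, baseline=30.0, noise_sigma=noise_sigma,
            sampling_rate=20.0,
        ),
    }


def _kernel(t: np.ndarray, model: EvokedModelParams) -> np.ndarray:
    tt = np.maximum(t, 0.0)
    if model.kernel == "double_exp":
        k = np.exp(-tt / model.tau_decay) - np.exp(-tt / model.tau_rise)
    elif model.kernel == "gamma":
        k = tt ** (model.gamma_shape - 1) * np.exp(-tt / model.gamma_scale)
    else:
        raise ValueError(f"unknown kernel {model.kernel!r}")
    k = np.where(t >= 0, k, 0.0)
    peak = k.max()
    return k / peak if peak > 0 else k


def evoked_response_dense(
    model: EvokedModelParams, protocol: StimProtocol, dt: float = DENSE_DT
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless unit-peak response on a dense grid.

    Time is relative to the first stimulus pulse and extends to the end of
    the post-stimulation window.
    """
    horizon = protocol.stim + protocol.post
    t = np.arange(0.0, horizon, dt)
    if model.per_pulse:
        r = np.zeros_like(t)
        for k, onset in enumerate(protocol.pulse_onsets):
            r += model.pulse_gain**k * _kernel(t - onset - model.latency, model)
    else:
        from scipy.signal import fftconvolve

        drive = ((t >= 0) & (t < protocol.stim)).astype(float)
        r = fftconvolve(drive, _kernel(t, model))[: len(t)] * dt
        r = np.interp(t - model.latency, t, r, left=0.0)
    peak = r.max()
    if peak <= 0:
        raise ValueError("degenerate evoked model: non-positive response")
    return t, r / peak


def _dense_crossing_kinetics(t: np.ndarray, r: np.ndarray) -> tuple[float, float]:
    """Brute-force onset (t10) and rise (t90 - t10) on a dense grid."""
    peak = r.max()

    def first_cross(level: float) -> float:
        idx = np.flatnonzero((r[1:] >= level) & (r[:-1] < level))
        i = int(idx[0])
        frac = (level - r[i]) / (r[i + 1] - r[i])
        return float(t[i] + frac * (t[i + 1] - t[i]))

    t10 = first_cross(0.1 * peak)
    t90 = first_cross(0.9 * peak)
    return t10, t90 - t10


@dataclass
class SessionGroundTruth:
    """Oracle record emitted next to every synthetic session."""

    analytic_onset: dict[str, float]
    analytic_rise: dict[str, float]
    artifact_trials: list[int]
    accel_events: list[ArtifactEvent]
    trial_starts: np.ndarray


@dataclass
class SyntheticSession:
    traces: dict[str, AnalogTrace]
    trigger: AnalogTrace
    accel: TriaxialTrace
    protocol: StimProtocol
    models: dict[str, EvokedModelParams]
    ground_truth: SessionGroundTruth


def gen_evoked_session(
    protocol: Optional[StimProtocol] = None,
    models: Optional[dict[str, EvokedModelParams]] = None,
    n_trials: int = 20,
    artifact_rate: float = 0.0,
    seed: int = 0,
    lead_in: float = 5.0,
    inter_trial_gap: float = 2.0,
    trigger_fs: float = 100.0,
    accel_fs: float = 50.0,
    accel_noise_sigma: float = 0.02,
    bout_amplitude: float = 0.6,
    bout_duration: float = 0.3,
) -> SyntheticSession:
    """Simulate a full stimulation session with known kinetics and artifacts.

    Trials are back-to-back with ``inter_trial_gap`` between them; each trial
    start is marked by a 5 V TTL pulse.  Trials drawn (Bernoulli,
    ``artifact_rate``) to contain a motion artifact receive a half-sine
    accelerometer bout plus a coincident broadband glitch in every signal
    channel, emulating movement-corrupted recordings.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    protocol = protocol or StimProtocol(pre=5.0, stim=3.0, post=22.0)
    models = models if models is not None else default_models()
    rng = np.random.default_rng(seed)

    period = protocol.trial_duration + inter_trial_gap
    trial_starts = lead_in + np.arange(n_trials) * period
    total = lead_in + n_trials * period
    stim_times = trial_starts + protocol.pre

    artifact_flags = rng.random(n_trials) < artifact_rate
    artifact_trials = [int(k) for k in np.flatnonzero(artifact_flags)]
    glitch_dur = 0.4
    glitch_times = {
        k: float(
            stim_times[k]
            + rng.uniform(0.2, protocol.stim + protocol.post - glitch_dur - 0.2)
        )
        for k in artifact_trials
    }

    # trigger channel: 100 ms 5 V pulse at each trial start
    nt = int(round(total * trigger_fs))
    t_trig = np.arange(nt) / trigger_fs
    trig = np.zeros(nt)
    for s in trial_starts:
        trig[(t_trig >= s) & (t_trig < s + 0.1)] = 5.0
    trigger = AnalogTrace(t_trig, trig, trigger_fs, label="trigger")

    # accelerometer channel with bouts in artifact trials
    bouts = [
        MotionBout(start=glitch_times[k], duration=bout_duration,
                   amplitude=bout_amplitude, axis_mix=(0.6, 0.6, 0.5))
        for k in artifact_trials
    ]
    accel, accel_events = gen_accel_trace(
        total, fs=accel_fs, noise_sigma=accel_noise_sigma, bouts=bouts,
        seed=int(rng.integers(2**31)),
    )

    traces: dict[str, AnalogTrace] = {}
    analytic_onset: dict[str, float] = {}
    analytic_rise: dict[str, float] = {}
    for name, model in models.items():
        dense_t, dense_r = evoked_response_dense(model, protocol)
        onset, rise = _dense_crossing_kinetics(dense_t, dense_r)
        analytic_onset[name] = onset
        analytic_rise[name] = rise

        fs = model.sampling_rate
        nmod = int(round(total * fs))
        tmod = np.arange(nmod) / fs
        resp = np.zeros(nmod)
        for s in stim_times:
            resp += np.interp(tmod - s, dense_t, dense_r, left=0.0, right=0.0)
        if model.negate:
            resp = -resp
        for k in artifact_trials:
            g0 = glitch_times[k]
            sel = (tmod >= g0) & (tmod < g0 + glitch_dur)
            resp[sel] += 2.5 * np.sin(np.pi * (tmod[sel] - g0) / glitch_dur)
        if model.noise_sigma > 0:
            resp = resp + rng.normal(0.0, model.noise_sigma, nmod)
        if model.modality == "pupil":
            values = model.baseline + model.amplitude * resp
        else:
            values = model.baseline * (1.0 + model.amplitude * resp)
        traces[name] = AnalogTrace(tmod, values, fs, label=name)

    truth = SessionGroundTruth(
        analytic_onset=analytic_onset,
        analytic_rise=analytic_rise,
        artifact_trials=artifact_trials,
        accel_events=accel_events,
        trial_starts=trial_starts,
    )
    return SyntheticSession(traces, trigger, accel, protocol, models, truth)


def write_session(session: SyntheticSession, out_dir: str | Path) -> dict[str, Path]:
    """Write a synthetic session as CSV traces plus a ground-truth JSON."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, tr in session.traces.items():
        p = out / f"{name.lower()}.csv"
        pd.DataFrame({"time_s": tr.time, "value": tr.values}).to_csv(p, index=False)
        paths[name] = p
    p = out / "trigger.csv"
    pd.DataFrame(
        {"time_s": session.trigger.time, "volts": session.trigger.values}
    ).to_csv(p, index=False)
    paths["trigger"] = p
    p = out / "accel.csv"
    pd.DataFrame(
        {
            "time_s": session.accel.time,
            "ax": session.accel.ax,
            "ay": session.accel.ay,
            "az": session.accel.az,
        }
    ).to_csv(p, index=False)
    paths["accel"] = p
    gt = session.ground_truth
    p = out / "ground_truth.json"
    p.write_text(
        json.dumps(
            {
                "analytic_onset": gt.analytic_onset,
                "analytic_rise": gt.analytic_rise,
                "artifact_trials": [int(k) for k in gt.artifact_trials],
                "accel_events": [
                    {"start": e.start, "end": e.end, "peak_magnitude": e.peak_magnitude}
                    for e in gt.accel_events
                ],
                "trial_starts": [float(s) for s in gt.trial_starts],
                "protocol": asdict(session.protocol),
                "sampling_rates": {
                    name: m.sampling_rate for name, m in session.models.items()
                },
            },
            indent=2,
        )
    )
    paths["ground_truth"] = p
    return paths
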