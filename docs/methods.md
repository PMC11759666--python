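# Methods

`mousephys` analyzes behavioral and physiological recordings from awake,
head-fixed mice during stimulus-evoked widefield optical imaging: an
infrared eye camera (pupillometry), a head-mounted triaxial accelerometer
(motion screening), a TTL trigger channel (trial timing), and per-ROI
optical traces (intrinsic-signal reflectance and GCaMP fluorescence).  This
note documents the models, the defaults, and the choices made where the
procedure was genuinely open.

## Pupillometry

Each grayscale frame is processed as: intensity inversion (the dark pupil
becomes the brightest object), binarization, connected-component filtering,
reconnection of split components, and a single ellipse fit.  The reported
diameter is the ellipse's minor-axis length in pixels — the minor axis is
used because it is insensitive to the foreshortening of an eye viewed
off-axis, which elongates only the apparent major axis.

**Thresholding.** The threshold method is configurable.  `auto` (default)
applies a three-class multi-Otsu split to the inverted frame and keeps the
brightest class.  Three classes rather than two: an eye-camera frame
typically contains background/fur, iris, and pupil; a binary Otsu split
lands between background and eye and segments the whole eye.  `fixed` mode
(`fixed_threshold`, counts, `>=` convention) is exposed for reproducibility
across sessions.

**Region filtering.** Components with area < 50 px² or circularity
4πA/P² < 0.3 are discarded (both configurable).  The perimeter comes from
the component's outer contour; discretization can push the shape factor of
a small disk slightly above 1, so circularity is clipped to 1.  The
defaults are permissive: at the working distance of a mouse eye camera the
pupil is hundreds of px², and even a half-moon pupil fragment has
circularity well above 0.3, while eyelash shadows and glint streaks fall
below it.

**Reconnection and ellipse fitting.** A whisker crossing the eye can split
the thresholded pupil into two components.  Up to `max_regions_to_merge`
(default 2) largest surviving components are pooled (area ties broken by
centroid distance to the frame center).  Sub-pixel boundary points of each
component (0.5-level contours, holes filled) are pooled, and points lying
more than 0.75 px below the joint convex hull are discarded.  Because the
pupil is convex, the genuine limbus arcs lie on the hull while the
occluder's cut-edges are interior chords; the depth filter removes the
latter without the ~0.5 px/side dilation that rasterized convex-hull
filling would introduce.  A direct algebraic least-squares conic is fitted
to the surviving points (the Halir–Flusser stable direct method), with a
second-moment (inertia-tensor) ellipse of the pooled pixels as a fallback
for degenerate conics.  On rendered ground truth this pipeline recovers the
minor axis within ~0.4 px without occlusion and within ~0.5 px with
splitting bars up to 5 px wide.

**Filtering and gaps.** Frames with no plausible pupil (blinks, full
occlusion) yield `valid=False`; interior gaps up to 0.5 s are linearly
interpolated and flagged, longer dropouts are left missing rather than
fabricated.  The diameter trace is low-pass filtered below 1 Hz with a
fourth-order Butterworth filter.  The default application is zero-phase
(forward–backward), which doubles the effective order and introduces zero
group delay — onset and rise times downstream must not be shifted by filter
delay.  A causal single-pass mode is exposed for parity with streaming
processing.  Filtering is skipped (with a warning) when the sampling rate
cannot support the cutoff or the trace is shorter than the filter's edge
padding.

## Motion-artifact screening

The acceleration magnitude is √(ax²+ay²+az²) per sample.  A resting
head-mounted sensor reads ≈ 9.81 m/s² (gravity) plus slow posture drift, so
each axis first has a sliding median (window 1 s, configurable) subtracted;
the 0.2 m/s² rule below is applied to the magnitude of the residual.  An
artifact is any interval in which the magnitude exceeds 0.2 m/s² for
at least 200 ms; supra-threshold runs separated by a single sub-threshold
sample are merged so one movement is not double-counted.  A 0.5 s boolean
screening grid summarizes the same events for quick inspection.  A trial
[start, end) is corrupted iff any artifact event overlaps it.

The threshold is applied after baseline removal because the rule's
magnitude scale (0.2 m/s²) is far below gravity; applying it to the raw
magnitude would never fire.  The raw-magnitude option remains available by
skipping `remove_baseline`.

## Trials and normalization

Trials are initiated by a 5 V TTL trigger; rising edges are detected at a
configurable threshold (default 2.5 V, mid-rail for noise robustness) with
a two-sample debounce.  Each trial covers [start, start+pre+stim+post) with
trial-relative time and the first stimulus pulse at `pre`.  The default
protocol is a 3 Hz pneumatic whisker-deflection train: five 300 ms pulses
with 300 ms gaps; trial structures 5/3/22 s (reflectance, 5 fps → 150
samples) and 3/3/6.5 s (fluorescence, 20 fps → 250 samples).

Optical signals are normalized per trial to fractional change over the full
pre-stimulus window, (x − x̄₀)/x̄₀ (ΔR/R₀, ΔF/F₀).  Reflectance traces are
sign-inverted so an upward deflection represents an increase in total
hemoglobin (blood volume): functional hyperemia absorbs more 568 nm light,
so raw reflectance goes down.  Pupil diameter stays in pixels with baseline
subtraction only (fractional mode is available).  Block averages are
pointwise means over viable trials with per-timepoint SD (ddof 1) and n.
Baseline subtraction is per trial, not per block, so slow drift between
trials does not leak into the average.

## Kinetics

Onset time is the interval from the first stimulus pulse to the response's
first upward crossing of 10% of peak height; rise time is between the first
crossings of 10% and 90%.  The peak is the global maximum within the search
window (default: first stimulus to end of trial), which is robust to
pulse-locked ripple in calcium traces.  Crossings are linearly interpolated
between bracketing samples — at 5 fps, sample-aligned crossings would
quantize timing to 200 ms.  A response with no positive peak or no crossing
is flagged undefined rather than returning a silent number.

Cross-correlation is windowed (default: first stimulus onset plus a stated
duration, e.g. 5 s for reflectance vs pupil, 4 s for fluorescence vs
pupil), mean-subtracted, and coefficient-normalized so an autocorrelation
peaks at exactly 1 at zero lag; positive peak lag means the first signal
leads.  The pupil trace is detrended (least-squares line over the window)
before correlation, because slow arousal drift otherwise dominates the
coefficient.  Timing distributions are compared with a classic two-tailed
pooled-variance t-test reported as mean ± SD; only the two planned
comparisons per modality pair (onset, rise) are made and no multiplicity
correction is applied, which the report states explicitly.

## Synthetic data

The generators define the study conditions for every test.

**Eye frames** are rendered by 4× supersampled averaging: background
(200 counts), iris disk (150), anti-aliased elliptical pupil (30), optional
specular highlight, and an optional straight occluder bar drawn at iris
intensity across the frame — the whisker-shadow failure mode.  Gaussian
noise is added after downsampling, seeded.  The true ellipse is returned
with every frame.

**Accelerometer traces** are a constant gravity vector plus white noise
plus half-sine bouts distributed over axes.  Ground-truth events apply the
artifact rule analytically to the half-sine envelope: a bout of amplitude A
and duration T exceeds a threshold θ < A for T·(1 − (2/π)·arcsin(θ/A)),
and qualifies iff that interval is ≥ 200 ms.

**Evoked sessions** build per-modality responses from parametric kernels,
normalized to unit peak and scaled into signal units:

| modality | kernel | latency | defaults | noiseless onset / rise |
|---|---|---|---|---|
| GCaMP | per-pulse double-exponential, gain 0.5/pulse | 0.05 s | τ_rise 0.1 s, τ_decay 0.35 s | 0.056 s / 0.098 s |
| OIS | per-pulse gamma | 0.35 s | shape 6, scale 0.25 s | 0.875 s / 1.444 s |
| pupil | 3 s boxcar drive ∗ double-exponential | 0.15 s | τ_rise 0.3 s, τ_decay 4 s | 0.589 s / 2.270 s |

These constants are modelling choices, not measured values.  They were
fixed once so the noiseless kinetics reproduce the physiological ordering —
calcium onsets first and rises fastest; the pupil onsets before the
hemodynamic response but takes longest to reach peak — with magnitudes in
the range reported for whisker-evoked responses in barrel cortex.  The
per-pulse gain < 1 models sensory adaptation and gives the calcium trace
five discrete pulse-locked peaks whose first is the global maximum.
Reflectance responses are emitted negative-going so the inversion
convention is exercised end to end.  Ground-truth onset/rise values are
computed on a 0.1 ms grid by brute-force crossing search, independent of
the kinetics module's code path.

Trials drawn Bernoulli(artifact_rate) receive a half-sine accelerometer
bout (0.6 m/s², 300 ms) and a coincident 0.4 s transient glitch in every
signal channel.  Signal noise is white Gaussian, specified relative to the
response peak (0.1 = 10% of peak, the default study condition along with 20
trials per session).

What the generator does **not** emulate: eye-lid/blink dynamics and gaze
shifts, pupil light reflex, heartbeat and respiration oscillations in the
optical signals, 1/f hemodynamic noise, heavy-tailed movement statistics,
or slow photobleaching.  Passing tests therefore demonstrate correctness of
the computations under known kinetics and controlled corruption — not
robustness to every property of in-vivo recordings.

## Numerical choices and limitations

- Coordinates are 0-based, origin top-left, x = column, y = row; diameters
  in px (a px-per-mm scalar converts if supplied).
- Intervals are half-open [start, end); trial time 0 is trial start.
- The fractional-change normalization errors out on a near-zero baseline
  mean instead of emitting infinities.
- Unequal trial lengths raise in strict mode; segmentation rounds trial
  starts to the nearest sample of each channel's grid.
- Problem sizes in the validation scripts (6-point diameter sweep, 100
  accelerometer traces, 20-trial sessions) were chosen as the smallest
  sets that exercise every code path with stable statistics.
- The block-average pupil channel is low-pass filtered at 1 Hz before
  kinetics, consistent with the pupillometry pipeline; the optical channels
  are not filtered beyond block averaging.
- Group comparisons with zero pooled variance are flagged degenerate
  (t = 0, p = 1 when means agree) rather than raising.
- The ellipse fit assumes the pupil boundary is at least half visible;
  occlusions that leave less than half the limbus produce unstable fits
  and are better treated as invalid frames.
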