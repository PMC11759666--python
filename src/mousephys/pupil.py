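"""Occlusion-robust pupillometry from infrared eye-camera frames.

The pipeline mirrors the stepwise segmentation used on awake head-fixed mice:
the grayscale frame is intensity-inverted (the dark pupil becomes the
brightest object), binarized, small and non-circular connected components are
discarded, the surviving region(s) are reconnected — a whisker crossing the
eye can split the pupil into two components — and a single ellipse is fitted.
The pupil diameter is the minor-axis length of that ellipse in pixels, and the
per-frame diameter trace is low-pass filtered below 1 Hz with a fourth-order
Butterworth filter (zero-phase by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, signal
from scipy.spatial import ConvexHull, QhullError
from skimage import measure
from skimage.filters import threshold_multiotsu, threshold_otsu

__all__ = [
    "GrayFrame",
    "PupilConfig",
    "RegionCandidate",
    "EllipseFit",
    "PupilFit",
    "PupilTrace",
    "invert_image",
    "binarize",
    "extract_regions",
    "reconnect_and_fit",
    "measure_pupil_frame",
    "pupil_timeseries",
    "lowpass_filter",
    "load_frames",
]


@dataclass(frozen=True)
class GrayFrame:
    """A single grayscale eye image.

    ``pixels`` is a 2-D integer array (8- or 16-bit counts); ``timestamp`` is
    seconds from session start.  Coordinates are 0-based with origin at the
    top-left corner, x = column, y = row.
    """

    pixels: np.ndarray
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("GrayFrame requires a non-empty 2-D pixel array")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError("GrayFrame pixels must be an integer dtype (counts)")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def max_value(self) -> int:
        """Largest representable intensity for this frame's bit depth."""
        return int(np.iinfo(self.pixels.dtype).max)


@dataclass
class PupilConfig:
    """Parameters of the pupil segmentation and filtering pipeline.

    threshold_mode
        ``"auto"`` picks an Otsu histogram split on the inverted frame;
        ``"fixed"`` uses ``fixed_threshold`` (counts) for reproducibility.
    min_area, min_circularity
        Connected components below either bound are discarded before fitting.
        Circularity is the shape factor 4*pi*A/P^2 (1 for a disk).
    max_regions_to_merge
        Upper bound on the number of components pooled when the pupil is
        split by an occluder.
    lowpass_cutoff, lowpass_order, sampling_rate
        Butterworth low-pass applied to the diameter trace. ``filter_mode``
        selects zero-phase (forward-backward) or causal one-pass application.
    max_gap_s
        Invalid-frame gaps up to this length are linearly interpolated;
        longer dropouts are left as missing values.
    """

    threshold_mode: str = "auto"
    fixed_threshold: Optional[float] = None
    min_area: float = 50.0
    min_circularity: float = 0.3
    max_regions_to_merge: int = 2
    lowpass_cutoff: float = 1.0
    lowpass_order: int = 4
    sampling_rate: float = 20.0
    filter_mode: str = "zero_phase"
    max_gap_s: float = 0.5
    px_per_mm: Optional[float] = None

    def validate(self) -> None:
        if not 0.0 <= self.min_circularity <= 1.0:
            raise ValueError("min_circularity must lie in [0, 1]")
        if self.threshold_mode not in ("auto", "fixed"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.threshold_mode == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed threshold_mode requires fixed_threshold")
        if self.max_regions_to_merge < 1:
            raise ValueError("max_regions_to_merge must be >= 1")
        if self.filter_mode not in ("zero_phase", "causal"):
            raise ValueError(f"unknown filter_mode {self.filter_mode!r}")
        if self.lowpass_cutoff <= 0 or self.sampling_rate <= 0:
            raise ValueError("lowpass_cutoff and sampling_rate must be positive")


@dataclass(frozen=True)
class RegionCandidate:
    """A connected component surviving the area/circularity filters."""

    coords: np.ndarray  # (n, 2) array of (row, col) pixel indices
    area: float
    perimeter: float
    circularity: float
    centroid: tuple[float, float]  # (row, col)


@dataclass(frozen=True)
class EllipseFit:
    """Fitted pupil ellipse; axis lengths are full lengths in pixels."""

    center: tuple[float, float]  # (x, y) px
    major_axis_length: float
    minor_axis_length: float
    orientation: float  # radians

    def __post_init__(self) -> None:
        if not self.major_axis_length >= self.minor_axis_length > 0:
            raise ValueError("require major_axis_length >= minor_axis_length > 0")


@dataclass(frozen=True)
class PupilFit:
    """Per-frame measurement result; ``valid`` iff an ellipse was fitted."""

    frame_index: int
    ellipse: Optional[EllipseFit]
    diameter: Optional[float]
    valid: bool
    n_regions_merged: int


@dataclass
class PupilTrace:
    """Diameter time series with validity/interpolation bookkeeping."""

    time: np.ndarray
    diameter_px: np.ndarray          # raw (gap-filled where interpolated)
    diameter_filtered_px: np.ndarray
    valid: np.ndarray                # frame yielded a fit
    interpolated: np.ndarray         # gap-filled by interpolation
    n_regions_merged: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.time,
                "diameter_px": self.diameter_px,
                "diameter_filtered_px": self.diameter_filtered_px,
                "valid": self.valid.astype(int),
                "n_regions_merged": self.n_regions_merged,
            }
        )


def invert_image(frame: GrayFrame) -> GrayFrame:
    """Invert intensities so the dark pupil becomes the brightest region."""
    inv = frame.max_value - frame.pixels
    return GrayFrame(inv.astype(frame.pixels.dtype), timestamp=frame.timestamp)


def binarize(frame: GrayFrame, config: PupilConfig) -> np.ndarray:
    """Threshold an (inverted) frame into a boolean pupil-candidate mask.

    Fixed mode keeps pixels ``>= fixed_threshold``. Auto mode derives the
    threshold from the frame histogram: a 3-class multi-Otsu split whose top
    threshold isolates the brightest class (the inverted pupil) even when the
    scene also contains a background/iris boundary; frames with too little
    contrast fall back to a plain Otsu split, and a frame with no contrast
    yields an all-background mask.
    """
    config.validate()
    px = frame.pixels
    if config.threshold_mode == "fixed":
        thr = float(config.fixed_threshold)
        if not 0 <= thr <= frame.max_value:
            raise ValueError(
                f"fixed_threshold {thr} outside the frame bit depth [0, {frame.max_value}]"
            )
        return px >= thr
    if px.min() == px.max():  # no contrast: nothing to segment
        return np.zeros_like(px, dtype=bool)
    try:
        thr = threshold_multiotsu(px, classes=3)[-1]
    except ValueError:  # fewer than 3 distinguishable classes
        thr = threshold_otsu(px)
    return px > thr


def _circularity(area: float, perimeter: float) -> float:
    if perimeter <= 0:
        return 1.0
    return min(1.0, 4.0 * np.pi * area / perimeter**2)


def extract_regions(mask: np.ndarray, config: PupilConfig) -> list[RegionCandidate]:
    """Connected components (8-connectivity) passing area and circularity cuts.

    Returned sorted by decreasing area.
    """
    labels = measure.label(np.asarray(mask, dtype=bool), connectivity=2)
    out: list[RegionCandidate] = []
    for region in measure.regionprops(labels):
        area = float(region.area)
        perim = float(region.perimeter)
        circ = _circularity(area, perim)
        if area >= config.min_area and circ >= config.min_circularity:
            out.append(
                RegionCandidate(
                    coords=region.coords,
                    area=area,
                    perimeter=perim,
                    circularity=circ,
                    centroid=tuple(region.centroid),
                )
            )
    out.sort(key=lambda r: -r.area)
    return out


def _select_regions(
    regions: Sequence[RegionCandidate],
    config: PupilConfig,
    frame_shape: Optional[tuple[int, int]],
) -> list[RegionCandidate]:
    # Largest first; area ties broken by centroid distance to frame center.
    if frame_shape is not None:
        cy, cx = (frame_shape[0] - 1) / 2.0, (frame_shape[1] - 1) / 2.0
        key = lambda r: (-r.area, (r.centroid[0] - cy) ** 2 + (r.centroid[1] - cx) ** 2)
    else:
        key = lambda r: -r.area
    ranked = sorted(regions, key=key)
    return ranked[: config.max_regions_to_merge]


_HULL_DEPTH_TOL = 0.75  # px; cut-edge rejection depth below the convex hull


def _region_contour_points(region: RegionCandidate) -> np.ndarray:
    """Sub-pixel (x, y) outer-boundary points of one region (holes filled)."""
    coords = region.coords
    rmin, cmin = coords.min(axis=0)
    rmax, cmax = coords.max(axis=0)
    patch = np.zeros((rmax - rmin + 3, cmax - cmin + 3), dtype=bool)
    patch[coords[:, 0] - rmin + 1, coords[:, 1] - cmin + 1] = True
    patch = ndimage.binary_fill_holes(patch)
    pts = []
    for contour in measure.find_contours(patch.astype(float), 0.5):
        pts.append(
            np.column_stack([contour[:, 1] + cmin - 1, contour[:, 0] + rmin - 1])
        )
    return np.vstack(pts) if pts else np.empty((0, 2))


def reconnect_and_fit(
    regions: Sequence[RegionCandidate],
    config: PupilConfig,
    frame_shape: Optional[tuple[int, int]] = None,
) -> tuple[Optional[EllipseFit], int]:
    """Pool up to ``max_regions_to_merge`` regions and fit one ellipse.

    Sub-pixel boundary points of the selected regions are pooled, and points
    lying more than ~0.75 px below their joint convex hull are discarded: the
    pupil is convex, so an occluder bar that splits it only contributes
    interior cut-edges, which this depth filter removes while keeping the
    genuine limbus arcs.  A direct algebraic least-squares conic is then
    fitted to the surviving points; the second-moment (inertia-tensor)
    ellipse of the pooled pixels is the fallback when the conic fit is
    degenerate.  Returns ``(fit_or_None, n_regions_merged)``.
    """
    if len(regions) == 0:
        return None, 0
    chosen = _select_regions(regions, config, frame_shape)
    if sum(len(r.coords) for r in chosen) < 5:  # fit underdetermined
        return None, len(chosen)

    pts = np.vstack([_region_contour_points(r) for r in chosen])
    if np.unique(np.round(pts, 6), axis=0).shape[0] < 5:
        return None, len(chosen)
    try:
        hull = ConvexHull(pts)
        depth = -(pts @ hull.equations[:, :2].T + hull.equations[:, 2]).max(axis=1)
        keep = pts[depth <= _HULL_DEPTH_TOL]
    except QhullError:
        keep = pts
    if np.unique(np.round(keep, 6), axis=0).shape[0] < 5:
        return None, len(chosen)

    model = measure.EllipseModel.from_estimate(keep)
    if model and np.all(np.isfinite(model.axis_lengths)) and min(model.axis_lengths) > 0:
        xc, yc = model.center
        a, b = model.axis_lengths
        theta = model.theta
        if a >= b:
            major, minor, orient = 2 * a, 2 * b, theta
        else:
            major, minor, orient = 2 * b, 2 * a, theta + np.pi / 2
        return EllipseFit((xc, yc), major, minor, orient % np.pi), len(chosen)

    # moments fallback on the pooled pixels
    coords = np.vstack([r.coords for r in chosen])
    rmin, cmin = coords.min(axis=0)
    rmax, cmax = coords.max(axis=0)
    patch = np.zeros((rmax - rmin + 3, cmax - cmin + 3), dtype=int)
    patch[coords[:, 0] - rmin + 1, coords[:, 1] - cmin + 1] = 1
    props = measure.regionprops(ndimage.binary_fill_holes(patch).astype(int))[0]
    cy, cx = props.centroid
    major = props.axis_major_length
    minor = props.axis_minor_length
    if minor <= 0:
        return None, len(chosen)
    fit = EllipseFit(
        (cx + cmin - 1, cy + rmin - 1), major, minor, (-props.orientation) % np.pi
    )
    return fit, len(chosen)


def measure_pupil_frame(
    frame: GrayFrame, config: PupilConfig, frame_index: int = -1
) -> PupilFit:
    """Full per-frame pipeline: invert, binarize, filter regions, fit ellipse.

    Never raises on image content — a frame with no plausible pupil yields
    ``valid=False``.  Configuration errors do propagate.
    """
    inv = invert_image(frame)
    mask = binarize(inv, config)
    regions = extract_regions(mask, config)
    fit, n_merged = reconnect_and_fit(regions, config, frame_shape=frame.pixels.shape)
    if fit is None:
        return PupilFit(frame_index, None, None, False, n_merged)
    return PupilFit(frame_index, fit, fit.minor_axis_length, True, n_merged)


def lowpass_filter(
    x: np.ndarray,
    sampling_rate: float,
    cutoff: float = 1.0,
    order: int = 4,
    zero_phase: bool = True,
) -> np.ndarray:
    """Butterworth low-pass; zero-phase (forward-backward) by default.

    Zero-phase application squares the one-pass magnitude response and
    introduces no group delay, which matters for onset/rise-time analysis.
    """
    if sampling_rate <= 2 * cutoff:
        raise ValueError("sampling_rate must exceed twice the cutoff")
    sos = signal.butter(order, cutoff, btype="low", fs=sampling_rate, output="sos")
    if zero_phase:
        return signal.sosfiltfilt(sos, x)
    return signal.sosfilt(sos, x)


def _fill_gaps(diam: np.ndarray, valid: np.ndarray, max_gap: int) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation across invalid runs of length <= max_gap samples."""
    filled = diam.copy()
    interpolated = np.zeros_like(valid)
    idx = np.arange(len(diam))
    good = np.flatnonzero(valid)
    bad_runs = []
    i = 0
    while i < len(diam):
        if not valid[i]:
            j = i
            while j < len(diam) and not valid[j]:
                j += 1
            bad_runs.append((i, j))
            i = j
        else:
            i += 1
    for start, stop in bad_runs:
        run = stop - start
        interior = start > 0 and stop < len(diam)
        if interior and run <= max_gap:
            filled[start:stop] = np.interp(idx[start:stop], good, diam[good])
            interpolated[start:stop] = True
        else:
            filled[start:stop] = np.nan
    return filled, interpolated


def pupil_timeseries(
    frames: Sequence[GrayFrame], config: PupilConfig
) -> PupilTrace:
    """Measure every frame, gap-fill brief dropouts, and low-pass filter.

    Frames are assumed uniformly sampled at ``config.sampling_rate``.  Raises
    if no frame yields a valid fit.  When the sampling rate cannot support the
    configured cutoff the filtering step is skipped with a warning.
    """
    config.validate()
    fits = [measure_pupil_frame(f, config, i) for i, f in enumerate(frames)]
    n = len(fits)
    if n == 0:
        raise ValueError("no frames provided")
    valid = np.array([f.valid for f in fits], dtype=bool)
    if not valid.any():
        raise ValueError("all frames invalid: no pupil found in any frame")
    diam = np.array([f.diameter if f.valid else np.nan for f in fits], dtype=float)
    merged = np.array([f.n_regions_merged for f in fits], dtype=int)
    fs = config.sampling_rate
    time = np.arange(n) / fs

    max_gap = int(round(config.max_gap_s * fs))
    filled, interpolated = _fill_gaps(diam, valid, max_gap)

    # zero-phase filtering needs enough samples for its edge padding
    min_len = 3 * (2 * (config.lowpass_order // 2 + config.lowpass_order % 2) + 1) + 1
    if fs <= 2 * config.lowpass_cutoff or n < min_len:
        warnings.warn(
            "trace too short or sampling rate too low for the configured "
            "low-pass; filtering skipped",
            stacklevel=2,
        )
        filtered = filled.copy()
    else:
        # remaining NaN (long dropouts) are bridged for filtering only
        nanmask = np.isnan(filled)
        work = filled.copy()
        if nanmask.any():
            ok = np.flatnonzero(~nanmask)
            work[nanmask] = np.interp(np.flatnonzero(nanmask), ok, work[ok])
        filtered = lowpass_filter(
            work,
            fs,
            cutoff=config.lowpass_cutoff,
            order=config.lowpass_order,
            zero_phase=config.filter_mode == "zero_phase",
        )
        filtered[nanmask] = np.nan

    return PupilTrace(time, filled, filtered, valid, interpolated, merged)


def load_frames(path: str | Path, sampling_rate: float = 20.0) -> list[GrayFrame]:
    """Load eye frames from a directory of PNGs (lexicographic order) or a
    multi-page TIFF; timestamps from the sampling rate."""
    import imageio.v3 as iio
    import tifffile

    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.png")) + sorted(path.glob("*.tif*"))
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF frames in {path}")
        stacks = [np.atleast_2d(iio.imread(f)) for f in files]
    else:
        arr = tifffile.imread(path)
        stacks = list(arr) if arr.ndim == 3 else [arr]
    return [
        GrayFrame(np.asarray(a), timestamp=i / sampling_rate)
        for i, a in enumerate(stacks)
    ]
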