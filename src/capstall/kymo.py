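"""Line-scan kymograph velocimetry: RBC passage detection, flux and speed
traces, motion-artifact rejection, and flux-speed correlation.

A kymograph is a space-time image built by scanning a short line along a
capillary axis (rows = time, one per scanned line; columns = position).
With the plasma fluorescently labelled, each red blood cell transit casts
a dark slanted streak whose slope encodes its speed (time per distance =
1/speed) and whose count per unit time is the cell flux.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from skimage.transform import radon

__all__ = [
    "Kymograph",
    "PassageEvent",
    "HemoTrace",
    "FluxSpeedCorrelation",
    "detect_passages",
    "compute_hemo_trace",
    "correlate_flux_speed",
]


@dataclass(frozen=True)
class Kymograph:
    """Space-time line-scan image with its acquisition geometry.

    ``image`` rows are consecutive scanned lines (time, spacing
    1/``line_rate`` s); columns are position along the vessel axis
    (spacing ``pixel_pitch`` µm).
    """

    image: np.ndarray
    line_rate: float            # Hz
    pixel_pitch: float          # µm / pixel
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        img = np.asarray(self.image, dtype=float)
        if img.ndim != 2:
            raise ValueError("kymograph image must be 2-D (time x position)")
        if img.shape[1] < 16:
            raise ValueError("kymograph needs at least 16 position columns")
        if self.line_rate <= 0 or self.pixel_pitch <= 0:
            raise ValueError("line_rate and pixel_pitch must be positive")
        object.__setattr__(self, "image", img)

    @property
    def duration(self) -> float:
        return self.image.shape[0] / self.line_rate


@dataclass(frozen=True)
class PassageEvent:
    """One detected RBC transit."""

    entry_s: float              # time the streak centre crosses column 0
    slope_s_per_um: float       # streak slope (time per distance); inf if stationary
    speed_mm_s: float           # |1/slope|; 0 if stationary
    stationary: bool
    n_pixels: int


# streaks slower than this apparent speed are flagged stationary (a cell
# sitting in the scan line produces a vertical stripe, not a transit)
_STATIONARY_ANGLE_DEG = 1.0


def _shadow_threshold(residual: np.ndarray, contrast_threshold: float) -> float | None:
    """Depth below the static plasma profile that qualifies as shadow.

    Scaled from the MAD of the column-median-subtracted residual; on a
    noiseless image the MAD vanishes and the threshold is anchored at half
    the deepest shadow instead.  None means the image is featureless.
    """
    mad = np.median(np.abs(residual - np.median(residual)))
    robust_sd = 1.4826 * mad
    if robust_sd > 0:
        return contrast_threshold * robust_sd
    depth = -float(residual.min())
    if depth <= 0:
        return None
    return 0.5 * depth


def _streak_angle_deg(window: np.ndarray) -> float:
    """Orientation of the dominant streak in a (time x position) window.

    Radon-style estimate: project the window over a fan of angles and take
    the angle whose projection has maximal variance (projections along the
    streak direction concentrate its mass).  Returns the angle theta such
    that the streak advances tan(theta) columns per row, in (-90, 90].
    """
    win = window - window.mean()
    coarse = np.arange(0.0, 180.0, 1.0)
    sino = radon(win, theta=coarse, circle=False)
    best = coarse[int(np.argmax(sino.var(axis=0)))]
    fine = np.arange(best - 1.5, best + 1.5 + 1e-9, 0.1)
    sino = radon(win, theta=fine, circle=False)
    theta = float(fine[int(np.argmax(sino.var(axis=0)))])
    if theta > 90.0:
        theta -= 180.0
    return theta


def _column_runs(labels: np.ndarray, idx: int, sl, col: int,
                 max_gap: int = 2) -> list[tuple[int, int]]:
    """Maximal row runs of component ``idx`` in one absolute column.

    Gaps of up to ``max_gap`` rows (noise holes in the shadow) are bridged.
    Returns absolute (first_row, last_row) pairs; empty if the component
    does not touch the column.
    """
    if not (sl[1].start <= col < sl[1].stop):
        return []
    hit = np.nonzero(labels[sl][:, col - sl[1].start] == idx)[0]
    if hit.size == 0:
        return []
    runs = []
    start = prev = hit[0]
    for r in hit[1:]:
        if r - prev > max_gap + 1:
            runs.append((start + sl[0].start, prev + sl[0].start))
            start = r
        prev = r
    runs.append((start + sl[0].start, prev + sl[0].start))
    return runs


def detect_passages(
    kymo: Kymograph,
    contrast_threshold: float = 3.0,
    min_pixels: int = 8,
) -> list[PassageEvent]:
    """Detect dark RBC streaks and estimate each one's slope.

    The per-column median (the static plasma profile) is subtracted, pixels
    darker than ``contrast_threshold`` robust standard deviations below it
    are grouped into 8-connected components, and each component becomes one
    passage event.  The entry time comes from a least-squares line through
    the per-row shadow centroids extrapolated to column 0; the slope from a
    windowed Radon orientation estimate.  A constant image yields an empty
    list.
    """
    img = kymo.image
    residual = img - np.median(img, axis=0, keepdims=True)
    threshold = _shadow_threshold(residual, contrast_threshold)
    if threshold is None:
        return []
    mask = residual < -threshold
    labels, n_comp = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n_comp == 0:
        return []

    dt = 1.0 / kymo.line_rate
    events: list[PassageEvent] = []
    slices = ndimage.find_objects(labels)
    for idx, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        comp = labels[sl] == idx
        n_px = int(comp.sum())
        if n_px < min_pixels:
            continue
        depth = np.where(comp, -residual[sl], 0.0)

        # per-row weighted centroid -> line fit col = a + b*row; rows where
        # the shadow is truncated at the field edges bias the centroid and
        # are excluded when enough interior rows remain
        row_w = depth.sum(axis=1)
        rows = np.nonzero(row_w > 0)[0]
        cent = (depth[rows] * np.arange(depth.shape[1])).sum(axis=1) / row_w[rows]
        abs_rows = rows + sl[0].start
        abs_cent = cent + sl[1].start
        touches_edge = (comp[:, 0].astype(bool) if sl[1].start == 0 else
                        np.zeros(comp.shape[0], bool))
        if sl[1].stop == img.shape[1]:
            touches_edge |= comp[:, -1]
        interior = ~touches_edge[rows]
        if interior.sum() >= 2:
            abs_rows, abs_cent = abs_rows[interior], abs_cent[interior]

        theta = _streak_angle_deg(depth)
        stationary = abs(theta) < _STATIONARY_ANGLE_DEG
        if stationary:
            entry_s = float(abs_rows[0]) * dt
            events.append(PassageEvent(entry_s, math.inf, 0.0, True, n_px))
            continue

        m = math.tan(math.radians(theta))            # columns per row
        speed_um_s = abs(m) * kymo.pixel_pitch * kymo.line_rate
        slope_s_per_um = 1.0 / speed_um_s

        # cells co-occupying the segment merge into one component; the
        # number of distinct runs the component leaves in the reference
        # (central) column recovers the individual transits
        ref_col = img.shape[1] // 2
        runs = _column_runs(labels, idx, sl, ref_col)

        if len(abs_rows) >= 2:
            b, a = np.polyfit(abs_rows, abs_cent, 1)
        else:
            b, a = m, abs_cent[0] - m * abs_rows[0]
        if len(runs) > 1:
            # one event per reference-column crossing; entry extrapolated
            # back along the common slope to the entry edge of the field
            offset_um = (ref_col if b >= 0 else img.shape[1] - 1 - ref_col) \
                * kymo.pixel_pitch
            for r_lo, r_hi in runs:
                t_mid = (r_lo + r_hi) / 2.0 * dt
                entry_s = t_mid - offset_um * slope_s_per_um
                events.append(PassageEvent(float(entry_s), slope_s_per_um,
                                           speed_um_s / 1000.0, False,
                                           n_px // len(runs)))
            continue
        # single transit: extrapolate the centroid track to the entry edge
        if abs(b) > 0:
            col0 = 0.0 if b >= 0 else img.shape[1] - 1.0
            entry_row = (col0 - a) / b
        else:
            entry_row = float(abs_rows[0])
        events.append(PassageEvent(float(entry_row * dt), slope_s_per_um,
                                   speed_um_s / 1000.0, False, n_px))
    events.sort(key=lambda e: e.entry_s)
    return events


@dataclass(frozen=True)
class HemoTrace:
    """Windowed RBC flux (cells/s) and speed (mm/s) along a recording.

    ``valid`` marks windows free of motion artifacts; ``speed`` is NaN in
    windows with no measurable transit.  Windows tile the trace when
    ``step_s == window_s``.
    """

    window_centers: np.ndarray   # s
    flux: np.ndarray             # cells / s
    speed: np.ndarray            # mm / s, NaN where undefined
    valid: np.ndarray            # bool
    window_s: float
    step_s: float

    def __post_init__(self) -> None:
        n = len(self.window_centers)
        if not (len(self.flux) == len(self.speed) == len(self.valid) == n):
            raise ValueError("trace arrays must have equal length")
        if np.any(np.asarray(self.flux) < 0):
            raise ValueError("flux must be non-negative")

    @property
    def window_starts(self) -> np.ndarray:
        return np.asarray(self.window_centers) - self.window_s / 2.0

    @property
    def window_ends(self) -> np.ndarray:
        return np.asarray(self.window_centers) + self.window_s / 2.0


# whole-line median intensity jumping by more than this fraction between
# adjacent lines is treated as an axial-displacement (motion) artifact
ARTIFACT_JUMP_FRACTION = 0.25


def _artifact_rows(image: np.ndarray) -> np.ndarray:
    """Row indices r where the whole-line plasma level jumps > 25% to r+1.

    The plasma level is the line median over non-shadow pixels (shadow
    pixels found by the same residual threshold used for detection), so a
    line crowded by several RBC shadows is not mistaken for an axial jump.
    """
    residual = image - np.median(image, axis=0, keepdims=True)
    threshold = _shadow_threshold(residual, 3.0)
    masked = np.ma.masked_array(image, mask=(residual < -threshold)
                                if threshold is not None else False)
    level = np.ma.median(masked, axis=1).filled(np.nan)
    # fully-shadowed lines fall back to the plain line median
    fallback = np.median(image, axis=1)
    level = np.where(np.isfinite(level), level, fallback)
    prev = np.maximum(np.abs(level[:-1]), 1e-12)
    jump = np.abs(np.diff(level)) / prev
    return np.nonzero(jump > ARTIFACT_JUMP_FRACTION)[0]


def compute_hemo_trace(
    passages: list[PassageEvent],
    kymo: Kymograph,
    window_s: float = 1.0,
    step_s: float | None = None,
) -> HemoTrace:
    """Aggregate passage events into windowed flux and speed traces.

    Flux is events per window divided by the window length; speed is the
    per-window median of event speeds (robust to crossing streaks).  A
    window is flagged invalid when the whole-line median intensity jumps
    by more than 25% between adjacent lines inside it — the signature of
    an axial displacement of the preparation.
    """
    if kymo.image.size == 0:
        raise ValueError("empty kymograph")
    if window_s < 2.0 / kymo.line_rate:
        raise ValueError("window_s must cover at least two scan lines")
    if step_s is None:
        step_s = window_s
    if step_s <= 0:
        raise ValueError("step_s must be positive")

    duration = kymo.duration
    starts = np.arange(0.0, duration, step_s)
    # entry times extrapolated slightly outside the recording are clipped in
    # so that flux over all windows conserves the detected passage count
    entries = np.clip(np.array([p.entry_s for p in passages], dtype=float),
                      0.0, duration - 1e-9)
    speeds = np.array([p.speed_mm_s for p in passages], dtype=float)
    moving = np.array([not p.stationary for p in passages], dtype=bool)

    bad_rows = _artifact_rows(kymo.image)
    bad_times = (bad_rows + 0.5) / kymo.line_rate

    flux = np.zeros(starts.size)
    speed = np.full(starts.size, np.nan)
    valid = np.ones(starts.size, dtype=bool)
    for i, s0 in enumerate(starts):
        s1 = s0 + window_s
        in_win = (entries >= s0) & (entries < s1)
        flux[i] = in_win.sum() / window_s
        sel = in_win & moving
        if sel.any():
            speed[i] = float(np.median(speeds[sel]))
        if np.any((bad_times >= s0) & (bad_times < s1)):
            valid[i] = False
    return HemoTrace(
        window_centers=starts + window_s / 2.0,
        flux=flux, speed=speed, valid=valid,
        window_s=float(window_s), step_s=float(step_s),
    )


@dataclass(frozen=True)
class FluxSpeedCorrelation:
    r: float
    p_value: float
    slope: float            # mm/s per (cells/s)
    intercept: float        # mm/s
    n_windows: int


def correlate_flux_speed(trace: HemoTrace) -> FluxSpeedCorrelation:
    """Pearson correlation and OLS fit of speed on flux over valid windows.

    In healthy capillaries speed and flux stay linearly coupled even at
    low flow; a loss of this coupling is itself informative.  Only valid
    windows with a defined speed enter; fewer than 5 such windows is an
    error.
    """
    sel = np.asarray(trace.valid) & np.isfinite(np.asarray(trace.speed))
    if int(sel.sum()) < 5:
        raise ValueError("need at least 5 valid windows with defined speed")
    x = np.asarray(trace.flux)[sel]
    y = np.asarray(trace.speed)[sel]
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return FluxSpeedCorrelation(
        r=float(r), p_value=float(p),
        slope=float(fit.slope), intercept=float(fit.intercept),
        n_windows=int(sel.sum()),
    )
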