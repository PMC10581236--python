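"""Seeded synthetic-data generators standing in for the microscope.

Every input the analysis pipeline consumes can be generated here with the
ground-truth parameters retained, so that downstream estimators (passage
detection, stall calling, angiogram segmentation, trial statistics) can be
tested by parameter recovery rather than against deposited data.

Conventions
-----------
* Kymographs: rows = time (one row per scanned line), columns = position
  along the vessel axis.  This matches line-scan acquisition order.
* Volumes and frame stacks: 0-based, row-major, ``(time, y, x)`` or
  ``(time, z, y, x)`` axis order.
* Physical units in all interchange values: micrometres and seconds.
* All randomness flows through one ``numpy.random.Generator`` built from the
  spec's integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import erf

__all__ = [
    "KymoSpec",
    "AngioSpec",
    "TrialSpec",
    "RBCPassage",
    "generate_kymograph",
    "generate_angio_timeseries",
    "generate_trial_table",
    "replay_trial_table",
    "generate_power_sweep",
    "rasterize_segments",
]

# Outcome vocabulary shared with the stall-calling and statistics stages.
OUTCOME_BLOCKAGE = "BLOCKAGE"
OUTCOME_HEMORRHAGE = "HEMORRHAGE"
OUTCOME_NONE = "NONE"
OUTCOMES = (OUTCOME_BLOCKAGE, OUTCOME_HEMORRHAGE, OUTCOME_NONE)

# Shadow rendering: plasma is bright (1.0), an RBC occludes the labelled
# plasma and casts a dark streak.  Contrast and edge blur are free
# parameters of the generator (the imaging point-spread is not modelled).
PLASMA_LEVEL = 1.0
SHADOW_CONTRAST = 0.6
EDGE_BLUR_PX = 1.0


def _check_intervals(intervals: Sequence[tuple[float, float]], t_max: float, name: str) -> list[tuple[float, float]]:
    out = sorted((float(a), float(b)) for a, b in intervals)
    prev_end = -math.inf
    for a, b in out:
        if b <= a:
            raise ValueError(f"{name} interval ({a}, {b}) has non-positive length")
        if a < 0 or b > t_max + 1e-9:
            raise ValueError(f"{name} interval ({a}, {b}) outside [0, {t_max:.3f}]")
        if a < prev_end:
            raise ValueError(f"{name} intervals overlap at t={a}")
        prev_end = b
    return out


@dataclass(frozen=True)
class KymoSpec:
    """Parameters of a synthetic line-scan kymograph.

    A line is scanned repeatedly along ~``segment_length`` µm of a capillary
    axis at ``line_rate`` Hz.  RBC transits arrive as a homogeneous Poisson
    process of rate ``rbc_rate`` thinned to zero inside ``stall_intervals``;
    each cell crosses the segment at a log-normal speed with mean
    ``rbc_speed`` and coefficient of variation ``rbc_speed_cv``, leaving a
    slanted dark streak whose slope is 1/speed (time per distance).
    """

    line_rate: float = 800.0            # Hz
    n_lines: int = 8000
    segment_length: float = 15.0        # µm
    pixel_pitch: float = 0.25           # µm / pixel
    rbc_rate: float = 10.0              # cells / s
    rbc_speed: float = 0.5              # mm / s
    rbc_speed_cv: float = 0.2
    shadow_width: float = 4.0           # µm
    stall_intervals: tuple[tuple[float, float], ...] = ()
    artifact_intervals: tuple[tuple[float, float], ...] = ()
    artifact_gain: float = 1.6
    noise_sd: float = 0.05              # fraction of plasma intensity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.line_rate <= 0:
            raise ValueError("line_rate must be positive")
        if self.n_lines < 2:
            raise ValueError("n_lines must be at least 2")
        if self.segment_length <= 0 or self.pixel_pitch <= 0:
            raise ValueError("segment_length and pixel_pitch must be positive")
        if self.rbc_rate < 0:
            raise ValueError("rbc_rate must be non-negative")
        if self.rbc_speed <= 0:
            raise ValueError("rbc_speed must be positive")
        if self.rbc_speed_cv < 0:
            raise ValueError("rbc_speed_cv must be non-negative")
        if self.shadow_width <= 0:
            raise ValueError("shadow_width must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        _check_intervals(self.stall_intervals, self.duration, "stall")
        _check_intervals(self.artifact_intervals, self.duration, "artifact")

    @property
    def duration(self) -> float:
        """Total trace duration in seconds."""
        return self.n_lines / self.line_rate

    @property
    def n_columns(self) -> int:
        return max(16, int(round(self.segment_length / self.pixel_pitch)))


@dataclass(frozen=True)
class RBCPassage:
    """Ground truth for one RBC transit: entry time at column 0 and speed."""

    entry_s: float
    speed_mm_s: float

    @property
    def slope_s_per_um(self) -> float:
        """Streak slope, time per unit distance (1/speed)."""
        return 1.0 / (self.speed_mm_s * 1000.0)


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    # mean/CV parametrization of the log-normal
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - 0.5 * sigma2
    return mu, math.sqrt(sigma2)


def generate_kymograph(spec: KymoSpec, rng: np.random.Generator | None = None):
    """Render a synthetic kymograph and return it with its ground truth.

    Returns
    -------
    image : ndarray, shape (n_lines, n_columns), float32
        Bright plasma band with dark RBC shadows as slanted streaks.
    passages : list of RBCPassage
        One entry per simulated transit (none inside stall intervals).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    duration = spec.duration
    n_cols = spec.n_columns

    # Homogeneous Poisson arrivals thinned to zero inside stall intervals.
    passages: list[RBCPassage] = []
    if spec.rbc_rate > 0:
        n_events = rng.poisson(spec.rbc_rate * duration)
        times = np.sort(rng.uniform(0.0, duration, size=n_events))
        keep = np.ones(times.shape, dtype=bool)
        for a, b in spec.stall_intervals:
            keep &= ~((times > a) & (times < b))
        times = times[keep]
        if spec.rbc_speed_cv > 0:
            mu, s = _lognormal_params(spec.rbc_speed, spec.rbc_speed_cv)
            speeds = rng.lognormal(mu, s, size=times.size)
        else:
            speeds = np.full(times.size, spec.rbc_speed)
        passages = [RBCPassage(float(t), float(v)) for t, v in zip(times, speeds)]

    image = np.full((spec.n_lines, n_cols), PLASMA_LEVEL, dtype=np.float64)
    t_lines = np.arange(spec.n_lines) / spec.line_rate
    x_um = np.arange(n_cols) * spec.pixel_pitch
    half_w = spec.shadow_width / 2.0
    blur = EDGE_BLUR_PX * spec.pixel_pitch
    sqrt2b = math.sqrt(2.0) * blur

    for p in passages:
        v_um_s = p.speed_mm_s * 1000.0
        # rows during which the shadow centre is inside (padded) segment
        t0 = p.entry_s - (half_w + 3 * blur) / v_um_s
        t1 = p.entry_s + (spec.segment_length + half_w + 3 * blur) / v_um_s
        r0 = max(0, int(math.floor(t0 * spec.line_rate)))
        r1 = min(spec.n_lines, int(math.ceil(t1 * spec.line_rate)) + 1)
        if r1 <= r0:
            continue
        centers = (t_lines[r0:r1] - p.entry_s) * v_um_s  # µm along the axis
        d = x_um[None, :] - centers[:, None]
        # rectangle of width shadow_width with Gaussian edge blur
        profile = 0.5 * (erf((d + half_w) / sqrt2b) - erf((d - half_w) / sqrt2b))
        image[r0:r1] -= SHADOW_CONTRAST * profile

    # whole-line axial-jump artifacts: abrupt gain steps
    for a, b in spec.artifact_intervals:
        ra = int(round(a * spec.line_rate))
        rb = int(round(b * spec.line_rate))
        image[ra:rb] *= spec.artifact_gain

    if spec.noise_sd > 0:
        image += rng.normal(0.0, spec.noise_sd * PLASMA_LEVEL, size=image.shape)
    np.clip(image, 0.0, None, out=image)
    return image.astype(np.float32), passages


# ---------------------------------------------------------------------------
# Angiogram frame stacks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AngioSpec:
    """Synthetic angiographic frame-stack model.

    Vessel segments are drawn as capsules (cylinders with hemispherical
    caps) on the voxel grid.  Perfused segments show frame-to-frame
    intensity fluctuation of amplitude ``dynamic_contrast`` on top of a
    static base image; non-perfused segments and background are static up
    to additive noise of SD ``noise_sd``.
    """

    volume_shape: tuple[int, ...] = (64, 64)
    voxel_size: float = 2.0             # µm
    vessel_segments: tuple[tuple[tuple[float, ...], tuple[float, ...], float, bool], ...] = ()
    frames_per_timepoint: int = 16
    frame_interval: float = 0.5         # s
    dynamic_contrast: float = 0.5
    noise_sd: float = 0.05
    base_vessel_level: float = 0.5
    background_level: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.volume_shape) not in (2, 3):
            raise ValueError("volume_shape must be 2-D or 3-D")
        if any(s < 4 for s in self.volume_shape):
            raise ValueError("volume dimensions must be at least 4 voxels")
        if not self.vessel_segments:
            raise ValueError("vessel_segments must be non-empty")
        if self.frames_per_timepoint < 4:
            raise ValueError("frames_per_timepoint must be at least 4")
        if self.voxel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("voxel_size and frame_interval must be positive")
        if self.dynamic_contrast < 0 or self.noise_sd < 0:
            raise ValueError("dynamic_contrast and noise_sd must be non-negative")
        extent = np.asarray(self.volume_shape, float) * self.voxel_size
        for a, b, radius, _ in self.vessel_segments:
            if radius <= 0:
                raise ValueError("segment radius must be positive")
            for pt in (a, b):
                p = np.asarray(pt, float)
                if p.shape != (len(self.volume_shape),):
                    raise ValueError("segment endpoints must match volume dimensionality")
                if np.any(p < 0) or np.any(p > extent):
                    raise ValueError(f"segment endpoint {tuple(pt)} outside volume extent {tuple(extent)}")


def rasterize_segments(spec: AngioSpec) -> list[np.ndarray]:
    """Boolean capsule mask per segment (voxel centre within radius)."""
    grids = np.meshgrid(
        *[(np.arange(n) + 0.5) * spec.voxel_size for n in spec.volume_shape],
        indexing="ij",
    )
    pts = np.stack([g.ravel() for g in grids], axis=1)  # (N, ndim) in µm
    masks = []
    for a, b, radius, _ in spec.vessel_segments:
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            d2 = ((pts - a) ** 2).sum(axis=1)
        else:
            t = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
            proj = a + t[:, None] * ab
            d2 = ((pts - proj) ** 2).sum(axis=1)
        masks.append((d2 <= radius * radius).reshape(spec.volume_shape))
    return masks


def generate_angio_timeseries(
    spec: AngioSpec,
    timepoints: Sequence[str],
    perfusion_schedule: Sequence[Sequence[bool]] | None = None,
    rng: np.random.Generator | None = None,
):
    """Generate one frame stack per timepoint plus the ground truth.

    Parameters
    ----------
    timepoints : labels, e.g. ``["pre", "0h", "2h", "4h", "24h"]``.
    perfusion_schedule : per-timepoint list of perfused flags per segment.
        Defaults to each segment's own ``perfused`` flag at every timepoint.

    Returns
    -------
    stacks : dict label -> ndarray (frames, *volume_shape), float32
    truth : dict with ``segment_masks`` (list of boolean arrays),
        ``schedule`` (dict label -> tuple of perfused flags) and
        ``base`` (the static base image).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if not timepoints:
        raise ValueError("at least one timepoint label is required")
    if perfusion_schedule is None:
        flags = tuple(bool(s[3]) for s in spec.vessel_segments)
        perfusion_schedule = [flags] * len(timepoints)
    if len(perfusion_schedule) != len(timepoints):
        raise ValueError("perfusion_schedule length must match timepoints")
    for flags in perfusion_schedule:
        if len(flags) != len(spec.vessel_segments):
            raise ValueError("each schedule entry needs one flag per segment")

    masks = rasterize_segments(spec)
    base = np.full(spec.volume_shape, spec.background_level, dtype=np.float64)
    for m in masks:
        base[m] = spec.base_vessel_level

    stacks: dict[str, np.ndarray] = {}
    schedule: dict[str, tuple[bool, ...]] = {}
    for label, flags in zip(timepoints, perfusion_schedule):
        frames = np.broadcast_to(base, (spec.frames_per_timepoint,) + base.shape).copy()
        for m, perfused in zip(masks, flags):
            if perfused and spec.dynamic_contrast > 0:
                flicker = rng.normal(0.0, spec.dynamic_contrast,
                                     size=(spec.frames_per_timepoint, int(m.sum())))
                frames[:, m] += flicker
        if spec.noise_sd > 0:
            frames += rng.normal(0.0, spec.noise_sd, size=frames.shape)
        np.clip(frames, 0.0, None, out=frames)
        stacks[label] = frames.astype(np.float32)
        schedule[label] = tuple(bool(f) for f in flags)

    truth = {"segment_masks": masks, "schedule": schedule, "base": base}
    return stacks, truth


# ---------------------------------------------------------------------------
# Trial tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialSpec:
    """Bernoulli model of photo-excitation trials per injection group."""

    n_trials: dict[str, int] = field(default_factory=lambda: {"RoseBengal": 95, "FitC": 82})
    blockage_prob: dict[str, float] = field(default_factory=lambda: {"RoseBengal": 0.60, "FitC": 0.146})
    hemorrhage_prob: dict[str, float] = field(default_factory=lambda: {"RoseBengal": 0.10, "FitC": 0.10})
    depth_levels: tuple[float, ...] = (100.0, 150.0, 200.0)   # µm below pia
    excitation_mean: float = 295.0                            # s
    excitation_sd: float = 270.0                              # s
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_trials.items():
            if n <= 0:
                raise ValueError(f"n_trials for group {g!r} must be positive")
            pb = self.blockage_prob.get(g)
            ph = self.hemorrhage_prob.get(g)
            if pb is None or ph is None:
                raise ValueError(f"missing probabilities for group {g!r}")
            if not (0.0 <= pb <= 1.0) or not (0.0 <= ph <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")
            if pb + ph > 1.0 + 1e-12:
                raise ValueError(f"blockage_prob + hemorrhage_prob > 1 for group {g!r}")
        if not self.depth_levels:
            raise ValueError("depth_levels must be non-empty")
        if self.excitation_mean <= 0 or self.excitation_sd < 0:
            raise ValueError("excitation_mean must be positive, excitation_sd non-negative")


def _sample_excitation(spec: TrialSpec, rng: np.random.Generator, size: int) -> np.ndarray:
    # truncated-at-zero normal via resampling; excitation times are durations
    out = rng.normal(spec.excitation_mean, spec.excitation_sd, size=size)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(spec.excitation_mean, spec.excitation_sd, size=int(bad.sum()))
        bad = out <= 0
    return out


def generate_trial_table(spec: TrialSpec, rng: np.random.Generator | None = None):
    """Sample one record per trial: group, outcome, depth, excitation time.

    Returns a :class:`pandas.DataFrame` with columns
    ``group, outcome, depth_um, excitation_s``.
    """
    import pandas as pd

    if rng is None:
        rng = np.random.default_rng(spec.seed)
    rows = []
    for group, n in spec.n_trials.items():
        pb = spec.blockage_prob[group]
        ph = spec.hemorrhage_prob[group]
        u = rng.uniform(size=n)
        outcomes = np.where(u < pb, OUTCOME_BLOCKAGE,
                            np.where(u < pb + ph, OUTCOME_HEMORRHAGE, OUTCOME_NONE))
        depths = rng.choice(spec.depth_levels, size=n)
        excite = _sample_excitation(spec, rng, n)
        for o, d, e in zip(outcomes, depths, excite):
            rows.append((group, str(o), float(d), float(e)))
    return pd.DataFrame(rows, columns=["group", "outcome", "depth_um", "excitation_s"])


def replay_trial_table(
    counts: dict[str, dict[str, int]],
    depth_um: float = 100.0,
    excitation_s: float = 300.0,
):
    """Deterministic replay mode: emit exact outcome counts per group.

    ``counts`` maps group -> ``{"n": total, "BLOCKAGE": k, "HEMORRHAGE": m}``
    (missing outcome keys default to 0; the remainder is NONE).  Use this to
    reconstruct a reported contingency table, e.g. 57 blockages of 95 trials
    in one group versus 12 of 82 in the other.
    """
    import pandas as pd

    rows = []
    for group, spec in counts.items():
        n = int(spec["n"])
        k_block = int(spec.get(OUTCOME_BLOCKAGE, 0))
        k_hem = int(spec.get(OUTCOME_HEMORRHAGE, 0))
        if k_block < 0 or k_hem < 0 or k_block + k_hem > n:
            raise ValueError(f"invalid counts for group {group!r}")
        outcomes = ([OUTCOME_BLOCKAGE] * k_block + [OUTCOME_HEMORRHAGE] * k_hem
                    + [OUTCOME_NONE] * (n - k_block - k_hem))
        for o in outcomes:
            rows.append((group, o, float(depth_um), float(excitation_s)))
    return pd.DataFrame(rows, columns=["group", "outcome", "depth_um", "excitation_s"])


# ---------------------------------------------------------------------------
# Power sweeps
# ---------------------------------------------------------------------------

def generate_power_sweep(
    order: float,
    coeff: float,
    powers_mw: Sequence[float],
    noise_sd: float = 0.0,
    wavelength_nm: float = 1000.0,
    rng: np.random.Generator | None = None,
):
    """Simulate a fluorescence-vs-power sweep ``I = coeff * P**order * (1+ε)``.

    ``order`` is the multiphoton order of the excitation process (2 for a
    two-photon dye); ε is i.i.d. Gaussian of SD ``noise_sd``.  Returns a
    :class:`capstall.photophysics.PowerSweep`.
    """
    from .photophysics import PowerSweep

    if order <= 0:
        raise ValueError("order must be positive")
    if coeff <= 0:
        raise ValueError("coeff must be positive")
    powers = np.asarray(powers_mw, dtype=float)
    if powers.ndim != 1 or powers.size < 3:
        raise ValueError("need at least 3 power levels")
    if np.any(powers <= 0):
        raise ValueError("powers must be strictly positive")
    if rng is None:
        rng = np.random.default_rng(0)
    intensities = coeff * powers ** order
    if noise_sd > 0:
        intensities = intensities * (1.0 + rng.normal(0.0, noise_sd, size=powers.size))
        intensities = np.clip(intensities, np.finfo(float).tiny, None)
    return PowerSweep(powers=powers, intensities=intensities, wavelength_nm=wavelength_nm)
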