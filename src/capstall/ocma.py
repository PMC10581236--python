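"""Angiographic perfusion mapping, stallograms and longitudinal tracking.

Optical-coherence-microscopy angiography separates moving scatterers
(flowing blood) from static tissue by high-pass temporal filtering of a
repeated frame stack: perfused voxels fluctuate frame to frame, static
ones do not.  A *stallogram* then reads out a single vessel's perfusion
over time as the ratio of its ROI intensity in the perfusion map to a
nearby background ROI — a ratio near 1 means the vessel is
indistinguishable from background, i.e. not perfused.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

__all__ = [
    "FrameStack",
    "Angiogram",
    "StallogramTrace",
    "compute_angiogram",
    "stallogram",
    "track_insult",
    "register_angiograms",
]


@dataclass(frozen=True)
class FrameStack:
    """Repeated intensity frames of one field of view, axis order (time, ...)."""

    frames: np.ndarray
    frame_interval: float       # s
    voxel_size: float = 1.0     # µm

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        if f.ndim not in (3, 4):
            raise ValueError("frames must be (time, y, x) or (time, z, y, x)")
        if f.shape[0] < 4:
            raise ValueError("need at least 4 frames for a perfusion map")
        if self.frame_interval <= 0 or self.voxel_size <= 0:
            raise ValueError("frame_interval and voxel_size must be positive")
        object.__setattr__(self, "frames", f)


@dataclass(frozen=True)
class Angiogram:
    """Non-negative perfusion-contrast map, same spatial shape as the frames."""

    map: np.ndarray
    voxel_size: float = 1.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.map, dtype=float)
        if np.any(m < 0):
            raise ValueError("angiogram values must be non-negative")
        object.__setattr__(self, "map", m)


def compute_angiogram(
    stack: FrameStack,
    cutoff_frames: int | None = None,
    method: str = "first_diff",
) -> Angiogram:
    """Perfusion map by high-pass temporal filtering of a frame stack.

    ``first_diff`` (default): per-voxel mean magnitude of the first
    temporal difference — the simplest high-pass filter; static voxels
    land at the noise floor, flowing ones scale linearly with the
    fluctuation amplitude.  ``rms``: per-voxel RMS after subtracting a
    running temporal mean of length ``cutoff_frames`` (the whole-stack
    mean when None).
    """
    f = stack.frames
    if method == "first_diff":
        amap = np.abs(np.diff(f, axis=0)).mean(axis=0)
    elif method == "rms":
        if cutoff_frames is None or cutoff_frames >= f.shape[0]:
            baseline = f.mean(axis=0, keepdims=True)
        else:
            if cutoff_frames < 2:
                raise ValueError("cutoff_frames must be at least 2")
            kernel = np.ones(cutoff_frames) / cutoff_frames
            baseline = ndimage.convolve1d(f, kernel, axis=0, mode="nearest")
        amap = np.sqrt(((f - baseline) ** 2).mean(axis=0))
    else:
        raise ValueError(f"unknown method {method!r}; use 'first_diff' or 'rms'")
    return Angiogram(
        map=amap,
        voxel_size=stack.voxel_size,
        provenance={"method": method, "cutoff_frames": cutoff_frames,
                    "n_frames": int(f.shape[0])},
    )


def _roi_mask(roi: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    m = np.asarray(roi, dtype=bool)
    if m.shape != shape:
        raise ValueError(f"ROI shape {m.shape} does not match angiogram {shape}")
    if not m.any():
        raise ValueError("ROI is empty")
    return m


@dataclass(frozen=True)
class StallogramTrace:
    """Vessel-over-background intensity ratio per timepoint with stall flags.

    ``normalized_intensity`` near 1 means the vessel ROI is statistically
    indistinguishable from the local background: no perfusion contrast.
    """

    times_s: np.ndarray
    normalized_intensity: np.ndarray
    stalled: np.ndarray
    k_sigma: float


def stallogram(
    angio_series: Sequence[Angiogram],
    vessel_roi: np.ndarray,
    background_roi: np.ndarray,
    times_s: Sequence[float] | None = None,
    k_sigma: float = 2.0,
) -> StallogramTrace:
    """Normalized vessel intensity over a sequence of perfusion maps.

    Per timepoint, normalized intensity = mean(vessel ROI) / mean(background
    ROI); the vessel is flagged *stalled* when this ratio does not exceed
    ``1 + k_sigma * CV_bg`` where CV_bg is the background ROI's coefficient
    of variation — i.e. when the vessel has vanished into the background.
    Both the ratio and the flag are invariant to global multiplicative gain.
    """
    if not angio_series:
        raise ValueError("angio_series is empty")
    shape = angio_series[0].map.shape
    v = _roi_mask(vessel_roi, shape)
    b = _roi_mask(background_roi, shape)
    if np.any(v & b):
        raise ValueError("vessel and background ROIs must be disjoint")
    if times_s is None:
        times_s = np.arange(len(angio_series), dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    if times_s.size != len(angio_series):
        raise ValueError("times_s length must match angio_series")

    norm = np.empty(len(angio_series))
    stalled = np.empty(len(angio_series), dtype=bool)
    for i, angio in enumerate(angio_series):
        if angio.map.shape != shape:
            raise ValueError("all angiograms must share one shape")
        bg = angio.map[b]
        bg_mean = float(bg.mean())
        if bg_mean <= 0:
            raise ValueError("background ROI mean is zero")
        norm[i] = float(angio.map[v].mean()) / bg_mean
        cv = float(bg.std()) / bg_mean
        stalled[i] = norm[i] <= 1.0 + k_sigma * cv
    return StallogramTrace(times_s=times_s, normalized_intensity=norm,
                           stalled=stalled, k_sigma=float(k_sigma))


def track_insult(
    timepoint_angios: Sequence[tuple[str, Angiogram]],
    vessel_roi: np.ndarray,
    background_roi: np.ndarray,
    k_sigma: float = 2.0,
) -> dict:
    """Follow one targeted vessel across labelled longitudinal timepoints.

    Each timepoint's perfusion map is reduced to a PERFUSED / NOT-PERFUSED
    call by the stallogram criterion (ROIs must already be registered to a
    common grid; see :func:`register_angiograms`).  The summary reports the
    first non-perfused timepoint as the insult and the first perfused
    timepoint after it as the recovery.
    """
    if len(timepoint_angios) < 2:
        raise ValueError("need at least 2 timepoints to track an insult")
    labels = [lab for lab, _ in timepoint_angios]
    trace = stallogram([a for _, a in timepoint_angios],
                       vessel_roi, background_roi, k_sigma=k_sigma)
    perfused = ~trace.stalled

    insult_at = recovered_at = None
    for lab, p in zip(labels, perfused):
        if insult_at is None:
            if not p:
                insult_at = lab
        elif recovered_at is None and p:
            recovered_at = lab
    return {
        "labels": labels,
        "perfused": {lab: bool(p) for lab, p in zip(labels, perfused)},
        "normalized_intensity": {lab: float(x) for lab, x in
                                 zip(labels, trace.normalized_intensity)},
        "insult_detected": insult_at is not None,
        "insult_at": insult_at,
        "recovered": recovered_at is not None,
        "recovered_at": recovered_at,
    }


def register_angiograms(reference: Angiogram, moving: Angiogram) -> tuple[Angiogram, np.ndarray]:
    """Translation-only alignment of ``moving`` onto ``reference``.

    The shift is estimated by cross-correlation with sub-pixel refinement
    and applied with spline interpolation, so ROIs drawn on the reference
    can be reused across longitudinal sessions.  Returns the shifted
    angiogram and the applied shift in voxels.
    """
    if reference.map.shape != moving.map.shape:
        raise ValueError("angiograms must share a shape for registration")
    shift, _, _ = phase_cross_correlation(reference.map, moving.map,
                                          upsample_factor=10)
    shifted = ndimage.shift(moving.map, shift, order=1, mode="nearest")
    shifted = np.clip(shifted, 0.0, None)
    prov = dict(moving.provenance)
    prov["registered_shift_vox"] = [float(s) for s in shift]
    return Angiogram(map=shifted, voxel_size=moving.voxel_size, provenance=prov), shift
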