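"""Readers and writers for the pipeline's interchange formats.

Conventions shared by every format here: 0-based, row-major indexing;
kymographs are (time, position) with rows = scanned lines; stacks are
(time, y, x); µm and seconds are the only physical units.  Image data go
to multi-page float32 TIFF with a JSON sidecar carrying the acquisition
metadata — a missing sidecar is an error, never a silent default.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.draw import polygon2mask

from .kymo import HemoTrace, Kymograph
from .ocma import FrameStack, StallogramTrace
from .synthdata import OUTCOMES

__all__ = [
    "write_json", "read_json",
    "write_kymograph", "read_kymograph",
    "write_stack", "read_stack",
    "write_trial_table", "read_trial_table",
    "write_hemo_trace", "read_hemo_trace",
    "write_stallogram_trace",
    "roi_mask_from_json", "write_roi_json",
]


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.bool_):
            return bool(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(path, obj) -> None:
    Path(path).write_text(
        json.dumps(obj, cls=_NumpyEncoder, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _read_sidecar(path: Path, required: tuple[str, ...]) -> dict:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing JSON sidecar {sidecar} for {path}; metadata is required")
    meta = read_json(sidecar)
    missing = [k for k in required if k not in meta]
    if missing:
        raise ValueError(f"sidecar {sidecar} is missing keys {missing}")
    return meta


# -- kymographs -------------------------------------------------------------

def write_kymograph(path, kymo: Kymograph) -> None:
    """TIFF (or CSV, by extension) plus a JSON sidecar with the geometry."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        np.savetxt(path, kymo.image, delimiter=",", fmt="%.6g")
    else:
        tifffile.imwrite(path, kymo.image.astype(np.float32))
    write_json(_sidecar_path(path), {
        "axes": "time,position",
        "line_rate_hz": kymo.line_rate,
        "pixel_pitch_um": kymo.pixel_pitch,
        "metadata": kymo.metadata,
    })


def read_kymograph(path) -> Kymograph:
    path = Path(path)
    meta = _read_sidecar(path, ("line_rate_hz", "pixel_pitch_um"))
    if path.suffix.lower() == ".csv":
        img = np.loadtxt(path, delimiter=",", ndmin=2)
    else:
        img = tifffile.imread(path)
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D (time x position) image, got shape {img.shape}")
    return Kymograph(image=np.asarray(img, dtype=float),
                     line_rate=float(meta["line_rate_hz"]),
                     pixel_pitch=float(meta["pixel_pitch_um"]),
                     metadata=meta.get("metadata", {}))


# -- frame stacks -----------------------------------------------------------

def write_stack(path, stack: FrameStack) -> None:
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    write_json(_sidecar_path(path), {
        "axes": "time,y,x" if stack.frames.ndim == 3 else "time,z,y,x",
        "frame_interval_s": stack.frame_interval,
        "voxel_size_um": stack.voxel_size,
    })


def read_stack(path) -> FrameStack:
    path = Path(path)
    meta = _read_sidecar(path, ("frame_interval_s", "voxel_size_um"))
    frames = tifffile.imread(path)
    expected = meta.get("axes", "time,y,x").count(",") + 1
    if frames.ndim != expected:
        raise ValueError(f"{path}: sidecar declares {expected} axes but data has {frames.ndim}")
    return FrameStack(frames=np.asarray(frames, dtype=float),
                      frame_interval=float(meta["frame_interval_s"]),
                      voxel_size=float(meta["voxel_size_um"]))


# -- trial tables -----------------------------------------------------------

TRIAL_COLUMNS = ["group", "outcome", "depth_um", "excitation_s"]


def write_trial_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, columns=TRIAL_COLUMNS)


def read_trial_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: trial table is missing columns {missing}")
    bad = sorted(set(table["outcome"].astype(str)) - set(OUTCOMES))
    if bad:
        raise ValueError(
            f"{path}: out-of-vocabulary outcome labels {bad}; expected {list(OUTCOMES)}")
    return table


# -- hemodynamic traces -----------------------------------------------------

def write_hemo_trace(path, trace: HemoTrace) -> None:
    path = Path(path)
    pd.DataFrame({
        "t_s": trace.window_centers,
        "flux_cps": trace.flux,
        "speed_mm_s": trace.speed,
        "valid": np.asarray(trace.valid, dtype=int),
    }).to_csv(path, index=False, float_format="%.6g")
    write_json(_sidecar_path(path), {"window_s": trace.window_s, "step_s": trace.step_s})


def read_hemo_trace(path) -> HemoTrace:
    path = Path(path)
    meta = _read_sidecar(path, ("window_s", "step_s"))
    df = pd.read_csv(path)
    return HemoTrace(
        window_centers=df["t_s"].to_numpy(float),
        flux=df["flux_cps"].to_numpy(float),
        speed=df["speed_mm_s"].to_numpy(float),
        valid=df["valid"].to_numpy(int).astype(bool),
        window_s=float(meta["window_s"]),
        step_s=float(meta["step_s"]),
    )


def write_stallogram_trace(path, trace: StallogramTrace) -> None:
    pd.DataFrame({
        "t_s": trace.times_s,
        "norm_intensity": trace.normalized_intensity,
        "stalled": np.asarray(trace.stalled, dtype=int),
    }).to_csv(path, index=False, float_format="%.6g")


# -- ROI polygons -----------------------------------------------------------

def write_roi_json(path, polygons, shape) -> None:
    """Polygon ROIs in pixel coordinates, 0-based (row, col), row-major."""
    write_json(path, {"shape": list(shape),
                      "polygons": [np.asarray(p, float).tolist() for p in polygons]})


def roi_mask_from_json(path, shape=None) -> np.ndarray:
    spec = read_json(path)
    if shape is None:
        shape = tuple(spec["shape"])
    mask = np.zeros(shape, dtype=bool)
    for poly in spec["polygons"]:
        mask |= polygon2mask(shape, np.asarray(poly, float))
    if not mask.any():
        raise ValueError(f"{path}: ROI polygons cover no pixels on shape {shape}")
    return mask
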