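"""Stall-event segmentation and vessel/trial classification.

A capillary *stall* is a transient interruption of RBC flow; a vessel is
called *blocked* only when RBC passage is absent for at least
``min_block_s`` seconds (15 s by default) continuing to the end of the
recording, and a later verification scan — when supplied — also shows no
flow.  "Absence of RBC" is operationalized as zero detected passages in a
trace window, so window length bounds the time resolution of event calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .kymo import HemoTrace

__all__ = [
    "StallEvent",
    "VesselCall",
    "TrialOutcome",
    "STATUS_FLOWING",
    "STATUS_INTERMITTENT",
    "STATUS_BLOCKED",
    "find_stall_events",
    "call_vessel",
    "summarize_excitation_times",
]

STATUS_FLOWING = "FLOWING"
STATUS_INTERMITTENT = "INTERMITTENT"
STATUS_BLOCKED = "BLOCKED"


@dataclass(frozen=True)
class StallEvent:
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("stall event must have positive duration")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class VesselCall:
    status: str
    events: tuple[StallEvent, ...]
    confirmed: bool
    min_block_s: float


@dataclass(frozen=True)
class TrialOutcome:
    category: str               # BLOCKAGE | HEMORRHAGE | NONE
    excitation_s: float
    depth_um: float
    group: str


def _zero_flux_runs(trace: HemoTrace) -> list[tuple[int, int]]:
    """Maximal runs [i, j] (inclusive window indices) of zero flow.

    A run is built from valid zero-flux windows; a *single* invalid window
    inside a run does not break it (motion artifacts should not split
    stalls), two or more consecutive invalid windows do.  Windows with
    positive flux always break runs.
    """
    flux = np.asarray(trace.flux)
    valid = np.asarray(trace.valid, dtype=bool)
    if not valid.any():
        raise ValueError("trace has no valid windows")

    runs: list[tuple[int, int]] = []
    i, n = 0, flux.size
    while i < n:
        if valid[i] and flux[i] == 0:
            j = i
            last_zero = i
            invalid_streak = 0
            while j + 1 < n:
                k = j + 1
                if valid[k] and flux[k] == 0:
                    j = k
                    last_zero = k
                    invalid_streak = 0
                elif not valid[k] and invalid_streak == 0:
                    j = k
                    invalid_streak = 1
                else:
                    break
            runs.append((i, last_zero))
            i = j + 1
        else:
            i += 1
    return runs


def find_stall_events(trace: HemoTrace, min_gap_s: float) -> list[StallEvent]:
    """Extract no-flow intervals of total span >= ``min_gap_s``.

    Event boundaries are the start of the first and the end of the last
    zero-flux window of each run, so timing is exact at window resolution.
    """
    if min_gap_s <= 0:
        raise ValueError("min_gap_s must be positive")
    if len(trace.window_centers) < 1:
        raise ValueError("trace must contain at least one window")
    starts = trace.window_starts
    ends = trace.window_ends
    events = []
    for i, j in _zero_flux_runs(trace):
        a, b = float(starts[i]), float(ends[j])
        if b - a >= min_gap_s - 1e-9:
            events.append(StallEvent(a, b))
    return events


def call_vessel(
    trace: HemoTrace,
    min_block_s: float = 15.0,
    verify_trace: HemoTrace | None = None,
    min_stall_s: float = 2.0,
) -> VesselCall:
    """Classify a vessel as FLOWING, INTERMITTENT or BLOCKED.

    BLOCKED requires a terminal zero-flux run of at least ``min_block_s``
    reaching the end of the trace AND, when a verification trace (taken up
    to minutes later) is supplied, zero flux throughout it.  Any stall
    event of at least ``min_stall_s`` without a confirmed terminal
    blockage yields INTERMITTENT.  ``confirmed`` is True only when a
    verification trace was supplied and itself showed no flow.
    """
    events = tuple(find_stall_events(trace, min_stall_s))

    terminal_block = False
    if math.isfinite(min_block_s):
        runs = _zero_flux_runs(trace)
        if runs:
            i, j = runs[-1]
            reaches_end = j == len(trace.flux) - 1
            span = float(trace.window_ends[j] - trace.window_starts[i])
            terminal_block = reaches_end and span >= min_block_s - 1e-9

    verified = None
    if verify_trace is not None:
        v_flux = np.asarray(verify_trace.flux)
        v_valid = np.asarray(verify_trace.valid, dtype=bool)
        verified = bool(v_valid.any()) and not np.any(v_flux[v_valid] > 0)

    if terminal_block and (verified is None or verified):
        status = STATUS_BLOCKED
    elif events:
        status = STATUS_INTERMITTENT
    else:
        status = STATUS_FLOWING
    return VesselCall(
        status=status,
        events=events,
        confirmed=bool(verified) if verified is not None else False,
        min_block_s=float(min_block_s),
    )


def summarize_excitation_times(
    outcomes: Sequence[TrialOutcome],
    depth_bins_um: Sequence[float],
):
    """Mean +/- SD of excitation time among blockage trials, per depth bin.

    ``depth_bins_um`` are bin edges; trials with category BLOCKAGE are
    binned by depth and summarized with the sample standard deviation
    (ddof=1; NaN with ``sd_defined=False`` for single-trial bins).  Bins
    containing no blockage are omitted from the result.
    """
    if not outcomes:
        raise ValueError("empty outcome list")
    edges = np.asarray(depth_bins_um, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("depth_bins_um must be increasing bin edges")

    blocks = [o for o in outcomes if o.category == "BLOCKAGE"]
    result: dict[tuple[float, float], dict] = {}
    for lo, hi in zip(edges[:-1], edges[1:]):
        times = np.array([o.excitation_s for o in blocks
                          if lo <= o.depth_um < hi], dtype=float)
        if times.size == 0:
            continue
        sd_defined = times.size > 1
        result[(float(lo), float(hi))] = {
            "n": int(times.size),
            "mean_s": float(times.mean()),
            "sd_s": float(times.std(ddof=1)) if sd_defined else float("nan"),
            "sd_defined": sd_defined,
        }
    return result
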