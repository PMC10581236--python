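"""Run configuration and the end-to-end demonstration pipeline.

A :class:`RunConfig` collects every stage parameter in one YAML-friendly
structure that round-trips losslessly and rejects unknown keys, so a run
directory is fully described by its manifest: seed + parameters + input
hashes reproduce every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, io, stallcall, stats
from .kymo import Kymograph, compute_hemo_trace, detect_passages
from .synthdata import (KymoSpec, TrialSpec, generate_kymograph,
                        generate_trial_table, replay_trial_table)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("capstall")

_KYMO_KEYS = {f.name for f in dataclasses.fields(KymoSpec)} - {"seed"}
_TRIAL_KEYS = {f.name for f in dataclasses.fields(TrialSpec)} - {"seed"}
_ANALYSIS_KEYS = {"window_s", "step_s", "contrast_threshold",
                  "min_block_s", "min_stall_s", "stall_min_gap_s"}


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = sorted(set(given) - allowed)
    if unknown:
        raise ValueError(f"unknown keys in config section {section!r}: {unknown}")


@dataclass
class RunConfig:
    """Validated per-run parameters for the synth -> kymo -> stall -> stats demo.

    ``trials_replay`` maps group -> exact outcome counts (deterministic
    replay of a reported contingency table); when empty, trials are
    sampled from ``trials`` probabilities instead.
    """

    seed: int = 0
    log_level: str = "INFO"
    kymo: dict = field(default_factory=dict)            # KymoSpec overrides
    trials: dict = field(default_factory=dict)          # TrialSpec overrides
    trials_replay: dict = field(default_factory=dict)   # group -> counts
    analysis: dict = field(default_factory=dict)        # windowing/thresholds

    def __post_init__(self) -> None:
        if int(self.seed) < 0:
            raise ValueError("config field 'seed' must be a non-negative integer")
        _check_keys("kymo", self.kymo, _KYMO_KEYS)
        _check_keys("trials", self.trials, _TRIAL_KEYS)
        _check_keys("analysis", self.analysis, _ANALYSIS_KEYS)
        # let the spec dataclasses validate values and name the field
        try:
            self.kymo_spec()
            if not self.trials_replay:
                self.trial_spec()
        except (ValueError, TypeError) as exc:
            raise ValueError(f"invalid config value: {exc}") from exc

    def kymo_spec(self) -> KymoSpec:
        kw = dict(self.kymo)
        for key in ("stall_intervals", "artifact_intervals"):
            if key in kw:
                kw[key] = tuple(tuple(iv) for iv in kw[key])
        return KymoSpec(seed=int(self.seed), **kw)

    def trial_spec(self) -> TrialSpec:
        kw = dict(self.trials)
        for key in ("n_trials", "blockage_prob", "hemorrhage_prob"):
            if key in kw:
                kw[key] = dict(kw[key])
        if "depth_levels" in kw:
            kw["depth_levels"] = tuple(kw["depth_levels"])
        return TrialSpec(seed=int(self.seed) + 1, **kw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        allowed = {f.name for f in dataclasses.fields(cls)}
        _check_keys("<top level>", raw, allowed)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute synth -> kymo -> stallcall -> stats and write a run directory.

    Deterministic for a fixed config: the manifest records the package
    version, all parameters, and the SHA-256 of every file written.
    """
    logging.basicConfig(level=config.log_level,
                        format="%(levelname)s %(name)s: %(message)s")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage_s: dict[str, float] = {}

    def _stage(name: str):
        log.info("stage %s ...", name)
        return time.perf_counter()

    # synth: kymograph + trial table
    t0 = _stage("synth")
    kspec = config.kymo_spec()
    image, passages_truth = generate_kymograph(kspec)
    kymo = Kymograph(image=image, line_rate=kspec.line_rate,
                     pixel_pitch=kspec.pixel_pitch)
    io.write_kymograph(out / "kymograph.tif", kymo)
    io.write_json(out / "kymograph_truth.json", {
        "passages": [{"entry_s": p.entry_s, "speed_mm_s": p.speed_mm_s}
                     for p in passages_truth],
        "spec": dataclasses.asdict(kspec),
    })
    if config.trials_replay:
        table = replay_trial_table(
            {g: dict(c) for g, c in config.trials_replay.items()})
    else:
        table = generate_trial_table(config.trial_spec())
    io.write_trial_table(out / "trials.csv", table)
    written += [out / "kymograph.tif", out / "kymograph.tif.json",
                out / "kymograph_truth.json", out / "trials.csv"]
    stage_s["synth"] = time.perf_counter() - t0

    # kymo: passage detection and hemodynamic trace
    t0 = _stage("kymo")
    ana = dict(config.analysis)
    events = detect_passages(kymo, contrast_threshold=ana.get("contrast_threshold", 3.0))
    trace = compute_hemo_trace(events, kymo,
                               window_s=ana.get("window_s", 1.0),
                               step_s=ana.get("step_s"))
    io.write_hemo_trace(out / "hemo_trace.csv", trace)
    written += [out / "hemo_trace.csv", out / "hemo_trace.csv.json"]
    stage_s["kymo"] = time.perf_counter() - t0

    # stallcall: events and vessel status
    t0 = _stage("stallcall")
    stall_events = stallcall.find_stall_events(
        trace, min_gap_s=ana.get("stall_min_gap_s", 5.0))
    call = stallcall.call_vessel(trace,
                                 min_block_s=ana.get("min_block_s", 15.0),
                                 min_stall_s=ana.get("min_stall_s", 2.0))
    io.write_json(out / "vessel_call.json", {
        "status": call.status,
        "confirmed": call.confirmed,
        "events": [{"start_s": e.start_s, "end_s": e.end_s,
                    "duration_s": e.duration_s} for e in stall_events],
    })
    written.append(out / "vessel_call.json")
    stage_s["stallcall"] = time.perf_counter() - t0

    # stats: incidence and z-tests
    t0 = _stage("stats")
    rates = stats.incidence_rates(table, "BLOCKAGE")
    results: dict = {"blockage_rates": rates}
    if table["group"].nunique() == 2:
        order = tuple(sorted(table["group"].unique(), key=lambda g: -rates[g]["rate"]))
        blk = stats.outcome_comparison(table, "BLOCKAGE", group_order=order)
        results["blockage_ztest"] = dataclasses.asdict(blk)
        try:
            hem = stats.hemorrhage_comparison(table, group_order=order)
            results["hemorrhage_ztest"] = dataclasses.asdict(hem)
        except ValueError:
            results["hemorrhage_ztest"] = None
    io.write_json(out / "stats.json", results)
    (out / "summary.txt").write_text(stats.summary_table(table) + "\n")
    written += [out / "stats.json", out / "summary.txt"]
    stage_s["stats"] = time.perf_counter() - t0

    manifest = {
        "package": "capstall",
        "version": __version__,
        "seed": int(config.seed),
        "config": dataclasses.asdict(config),
        "outputs": {p.name: _sha256(p) for p in written},
    }
    io.write_json(out / "manifest.json", manifest)
    for name, dt in stage_s.items():
        log.info("stage %s done in %.2f s", name, dt)
    return manifest
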