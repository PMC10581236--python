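# capstall

Quantitative analysis of **targeted capillary photothrombosis** experiments,
in which a circulating photosensitizer (Rose Bengal) is excited by two-photon
absorption in a line scanned along a single cortical capillary, occluding it
while the same line scan reads out the vessel's hemodynamics. The package is
for experimentalists and analysts working with two-photon line-scan
velocimetry and label-free angiography who need a tested, scriptable pipeline
from raw space–time images to group-level occlusion statistics.

What it computes, stage by stage:

- **photophysics** — multiphoton excitation order as the OLS slope of
  log F vs log P (slope ≈ 2 ⇒ two-photon); two-photon cross sections by the
  reference-ratio method σ_s = σ_ref·(F_s φ_ref C_ref)/(F_ref φ_s C_s);
  per-pulse focal fluence E_pulse / π(0.61 λ/NA)².
- **kymo** — RBC passage detection in kymographs (rows = time, columns =
  position along the vessel), streak slope → speed via a Radon-style
  orientation estimate (slope = 1/v), windowed flux (cells/s) and speed
  (mm/s) traces with motion-artifact rejection, and flux–speed correlation.
- **stallcall** — no-flow (stall) event segmentation and the blockage rule:
  a vessel is BLOCKED when RBCs are absent for ≥ 15 s to the end of the
  recording and a later verification scan agrees.
- **ocma** — perfusion maps from repeated frame stacks by high-pass temporal
  filtering; *stallograms* (vessel-ROI intensity normalized to local
  background, baseline 1 = no flow); longitudinal insult tracking across
  pre / 0 h / 2 h / 4 h / 24 h with translation registration.
- **distmap** — vessel masks (Otsu + small-object removal), exact Euclidean
  tissue-to-vessel distance fields, and the before/after occlusion histogram
  shift (Δmean, Δmedian, Δp95).
- **stats** — per-group incidence rates and the pooled two-proportion z-test,
  z = (p₁−p₂)/√(p̂(1−p̂)(1/n₁+1/n₂)).
- **synthdata** — seeded generators for every input (kymographs, angiogram
  stacks, trial tables, power sweeps) with ground truth retained, standing in
  for the microscope in tests and demonstrations.

## Worked example

Simulate a capillary that stalls twice and ends blocked, then analyse it:

```python
import numpy as np
import capstall as cs

spec = cs.KymoSpec(n_lines=48000, rbc_rate=10.0, noise_sd=0.05,
                   stall_intervals=((10.0, 30.0), (45.0, 60.0)), seed=5)
image, truth = cs.generate_kymograph(spec)
kymo = cs.Kymograph(image=image, line_rate=spec.line_rate,
                    pixel_pitch=spec.pixel_pitch)

events = cs.detect_passages(kymo)
trace = cs.compute_hemo_trace(events, kymo, window_s=1.0)
print(f"{len(truth)} simulated transits, {len(events)} detected")
for e in cs.find_stall_events(trace, min_gap_s=15.0):
    print(f"stall {e.start_s:.0f}-{e.end_s:.0f} s ({e.duration_s:.0f} s)")
print("vessel status:", cs.call_vessel(trace, min_block_s=15.0).status)

speeds = trace.speed[np.isfinite(trace.speed)]
print(f"median RBC speed {np.median(speeds):.2f} mm/s")

res = cs.two_proportion_ztest(57, 95, 12, 82)   # blockages vs control dye
print(f"z = {res.z:.2f}, p = {res.p_value:.1e}")
```

Output:

```
251 simulated transits, 219 detected
stall 10-30 s (20 s)
stall 45-60 s (15 s)
vessel status: BLOCKED
median RBC speed 0.50 mm/s
z = 6.17, p = 6.8e-10
```

The 60 s recording at 800 Hz contains 251 RBC transits; detection finds 219
(cells closer than one shadow width merge and cannot be separated — see
`docs/methods.md`), both 15-s-plus no-flow intervals are recovered at 1 s
resolution, and because the second gap reaches the end of the trace the
vessel is called BLOCKED. The z-test compares 57/95 blockages in the
photosensitizer group against 12/82 in the control-dye group: a 60.0% vs
14.6% incidence, significant at p ≈ 7×10⁻¹⁰.

A command-line front end mirrors the library
(`capstall simulate|kymo|stall|angiogram|stallogram|track|distmap|stats|pipeline`);
`capstall pipeline config.yaml rundir/` runs synth → kymo → stallcall →
stats from a YAML config and writes a manifest with parameter and output
hashes for byte-level reproducibility.

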