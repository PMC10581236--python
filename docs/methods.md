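# Methods

`capstall` implements the quantitative analysis behind targeted
single-capillary photothrombosis experiments: a circulating photosensitizer
(Rose Bengal) is excited by two-photon absorption in a line scanned along one
capillary, RBC hemodynamics are read out of the same line scans, the induced
occlusion is confirmed and followed with label-free angiography, and the
tissue-level consequence is quantified with distance maps and group-level
occlusion statistics. Because the raw in-vivo recordings of such experiments
are not generally available, the package ships a synthetic-data module that
emulates each input with known ground truth; every estimator is validated by
parameter recovery against that ground truth or against an independent
brute-force oracle.

## Synthetic data model

**Line-scan kymographs.** A line of ~15 µm (default pixel pitch 0.25 µm) is
scanned at 800 Hz; the image is stored rows = time, columns = position.
Plasma is bright (level 1.0); each RBC occludes the label and casts a dark
streak of contrast 0.6, rendered as a rectangle of width `shadow_width`
(default 4 µm) with 1-pixel Gaussian edge blur, moving at the cell's speed so
the streak slope is 1/speed. Transits arrive as a homogeneous Poisson process
(default 10 cells/s) thinned to zero inside configurable stall intervals;
speeds are log-normal with mean 0.5 mm/s and CV 0.2, typical of cortical
capillaries. Additive Gaussian noise (default SD 0.05 of the plasma level)
sets the SNR; the plasma-labelling contrast and SNR of real recordings are
free parameters, not calibrated to any particular instrument. Optional
"artifact intervals" multiply whole lines by a gain step (default 1.6),
mimicking an abrupt axial displacement of the preparation.

**Angiographic stacks.** Vessel segments are capsules rasterized on the
voxel grid. Each timepoint yields `frames_per_timepoint` frames: perfused
segments receive i.i.d. per-frame intensity fluctuations of SD
`dynamic_contrast` (default 0.5) on top of a static base image; everything
else is static up to additive noise (default SD 0.05). This reproduces the
single property angiography exploits — moving scatterers decorrelate frame
to frame — and nothing else: no speckle statistics, no optics, no depth
attenuation. Passing tests therefore show the *pipeline logic* is correct,
not that it would segment real OCM data without retuning.

**Trial tables.** Bernoulli outcomes (BLOCKAGE / HEMORRHAGE / NONE) per
group at configurable probabilities, with depths drawn from the stated
levels and excitation times from a truncated normal. A deterministic replay
mode emits exact counts, used to reconstruct reported contingency tables
(57 blockages of 95 trials vs 12 of 82; 57 follows from "60% of 95").

## Line-scan velocimetry

Detection subtracts the per-column median (the static plasma profile) and
thresholds pixels darker than `contrast_threshold` (default 3) robust SDs
(1.4826·MAD) below it; on noiseless images the MAD vanishes and the
threshold falls back to half the deepest shadow. Dark pixels are grouped
into 8-connected components. Each component is one transit unless it leaves
several distinct runs in the central reference column, in which case each
run is one transit — this splits cells that co-occupy the segment. Cells
closer than about one shadow width (≈8–12 ms at default speeds) merge into a
single unresolvable shadow; flux is accordingly biased low by ~10% at
10 cells/s, within the Poisson counting error, and the resolution limit is
two pixels of streak separation.

Streak orientation is a Radon-style estimate: the component window is
projected over a fan of angles and the angle maximizing projection variance
is taken (refined on a 0.1° grid); the streak advances tan θ columns per
row, giving speed = tan θ · pixel_pitch · line_rate. Streaks within 1° of
vertical are flagged stationary (a parked cell, not a transit). Entry times
come from a least-squares line through per-row shadow centroids,
extrapolated to the entry edge of the field; rows where the shadow is
truncated by the field edge are excluded from the fit. Orientation by
projection variance is direction-agnostic, so speed magnitudes survive
mirroring of the scan direction.

Windowed traces report flux = transits per window / window length and
speed = per-window median of transit speeds (median is robust to crossing
streaks); zero-transit windows carry flux 0 and NaN speed. A window is
invalid when the whole-line plasma level jumps by more than 25% between
adjacent lines inside it — the signature of an axial jump. The plasma level
is the line median over non-shadow pixels rather than the plain line
median: with a 15 µm segment, two co-occupying shadows already darken more
than half the line and would otherwise trigger false artifacts. The `valid`
flag marks motion artifacts only; undefined speed is encoded as NaN, so
zero-flow windows remain usable for stall detection.

## Stall and blockage calling

"Absence of RBCs" is operationalized as zero detected transits in a window
(default 1 s, which bounds event-time resolution). Stall events are maximal
runs of zero-flux valid windows; a single invalid window inside a run does
not break it (an artifact should not split a stall), two consecutive
invalid windows do — conservative against artifact-driven false blockages.
A vessel is BLOCKED when a terminal zero-flux run of ≥ `min_block_s`
(default 15 s) reaches the end of the trace *and* the verification trace,
when supplied, shows no flow anywhere; verification showing flow vetoes the
call. Any stall of ≥ `min_stall_s` (default 2 s; a value below the blockage
threshold is needed so that sub-threshold gaps still count as intermittent
stalling) without a confirmed terminal blockage yields INTERMITTENT.
Hemorrhage is accepted only as an input label — it is identified visually
in the experiment and never inferred from trace data.

## Angiography, stallograms, tracking

Perfusion maps use the simplest temporal high-pass: per-voxel mean
magnitude of the first frame difference (an RMS-after-detrending variant is
available via `method="rms"`, with `cutoff_frames` setting the running-mean
baseline). Static structure cancels exactly, so the map is invariant to
any static offset image and linear in the fluctuation amplitude.

A stallogram normalizes the vessel-ROI mean to a disjoint local
background-ROI mean; the ratio is gain-invariant and reads 1 when the
vessel has vanished into the background. The stalled flag fires when the
ratio is ≤ 1 + k·CV of the background (k = 2 by default) — an explicit,
testable version of the visual "vessel vanishes" criterion. On synthetic
series the flags equal the generator's schedule whenever the fluctuation
amplitude is ≥ 5× the noise SD (asserted over a contrast/noise grid).
Longitudinal tracking reduces each labelled timepoint (pre / 0 h / 2 h /
4 h / 24 h) to PERFUSED / NOT-PERFUSED and reports the first non-perfused
timepoint as the insult and the first perfused one after it as the
recovery. ROIs must share one registered grid; translation-only
registration by phase cross-correlation (sub-pixel, ×10 upsampling) is
provided.

## Distance maps

Vessel masks come from Otsu's threshold followed by removal of connected
components below `min_size` (default 8) voxels. The distance field is the
exact Euclidean distance transform of the tissue (non-vessel) domain,
measured centre-to-centre with anisotropic voxel sampling honoured; vessel
voxels carry distance 0 and are excluded from the histogram (bin width
2 µm). Occlusion comparison re-bins both histograms onto shared edges and
reports signed differences of mean, median and 95th percentile (positive =
longer distances after). Because removing vessels can only lengthen
nearest-vessel distances, the after-field dominates the before-field
voxel-wise — tested as a monotonicity invariant and against an O(N²)
all-pairs oracle on 16³ grids.

## Photophysics

The multiphoton order is the unweighted OLS slope of log F vs log P
(invariant to positive rescaling of either axis; exact on noiseless power
laws). Cross sections use the reference-ratio method,
σ_s = σ_ref · (F_s φ_ref C_ref)/(F_ref φ_s C_s), with quantum yields
defaulting to 1 so action cross sections can be passed directly. The focal
fluence calculator divides pulse energy (average power / repetition rate)
by a Rayleigh-criterion focal disc of radius 0.61 λ/NA; repetition rate
(80 MHz, typical Ti:Sapphire) and NA are assumptions echoed in the output
metadata, so the result is an order-of-magnitude estimate — at 87 mW,
1000 nm, NA 1.0 it gives ≈0.09 J/cm², an order of magnitude below the
~1 J/cm² tissue-ablation threshold.

## Group statistics

Incidence rates are simple per-group proportions. The two-proportion z-test
uses the pooled estimator z = (p₁−p₂)/√(p̂(1−p̂)(1/n₁+1/n₂)); two-sided by
default (sidedness is a flag), no continuity correction by default
(optional flag), no multiple-testing adjustment (two unadjusted tests are
reported: blockage and hemorrhage), and trials are pooled across animals —
per-animal clustering is not modelled. Calibration is checked by
simulation: type-I error within the 99% binomial band of α under the null,
and power > 0.99 at the observed effect (0.60 vs 0.146 at n = 95/82,
α = 10⁻³).

## Problem sizes and numerical choices

Test and acceptance runs use 30–60 s kymographs (24 000–48 000 lines at
800 Hz, 60 columns), 40×40–48×48 angiographic planes with 12–16 frames per
timepoint, 15-vessel longitudinal cohorts, 16³ distance-map oracles, and
400–500-replicate z-test simulations — sizes chosen so every stage's
statistical check is well-powered while a full run completes in seconds.
Ties and degenerate inputs: constant kymographs yield empty event lists
(not errors); constant angiograms have no Otsu threshold and are errors;
empty vessel masks are errors for distance fields but only a warning from
segmentation (the caller may have set `min_size` too high); pooled
proportions of 0 or 1 leave z undefined and raise.

## Known limitations

- Flux undercounts cells separated by less than one shadow width; no
  deconvolution of merged shadows is attempted.
- The angiography generator reproduces temporal-variance contrast only;
  numerical equivalence with any particular OCM implementation is not
  claimed, and the angiogram filter is deliberately pluggable.
- Registration is translation-only; rotation or warping between
  longitudinal sessions must be handled upstream.
- The fluence estimate inherits unstated instrument parameters (repetition
  rate, NA, spot model) and should be read as order-of-magnitude.
- Vessel-order classification (upstream/downstream), hemorrhage image
  analysis, and oxygen-transport modelling are out of scope.
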