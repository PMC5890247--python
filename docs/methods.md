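# Methods

## Data model and conventions

One LSFG recording is a stack of 2-D mean-blur-rate (MBR) maps, arbitrary
units (AU), non-negative, nominally 4 s at 30 fps (120 frames) on a
750 × 360 sensor. Stacks live on disk as tab-separated decimal grids (one
file per frame, `%.17g`, so round trips are bit-exact) with a JSON
metadata sidecar; ROIs are JSON polygons/rectangles. Coordinates are
0-based (row, col), row-major. Rectangles are inclusive on all edges;
polygon membership is decided per pixel center by the even-odd rule with
boundary pixels included — a deterministic convention that a brute-force
point-in-polygon oracle can check exactly.

The analyzed per-recording map is the per-pixel temporal mean of the
stack. The commercial instrument composites its own display map by an
unpublished rule; the arithmetic mean is this package's explicit,
testable stand-in, and it commutes with ROI extraction, which the suite
verifies.

## Segmentation and region metrics

A pixel inside the ROI is vascular iff MBR ≥ threshold, with the
threshold fixed at 15 AU by default (inclusive comparison, chosen so the
boundary case is deterministic). MV, MT, MA are arithmetic means over
the vascular, tissue, and all in-ROI pixels; ARBS is the vascular pixel
percentage. The mixture identity MA = (ARBS/100)·MV + (1−ARBS/100)·MT
holds to 1e-9 on every segmented map and is property-tested. An empty
compartment makes its mean UNDEFINED (`None`), never silently zero; the
single reporting exception is MV on a fully non-perfused map, printed as
0 to match the field's convention for "no perfusion".

VPE = ARBS × MV, with VPE ≡ 0 whenever ARBS = 0 (so a map whose vascular
area vanished scores 0 regardless of how bright its last pixels were).

## Laterality, standard range, perfusion index

Two LI definitions are kept distinct by an enum: for healthy fellow eyes,
LI = min/max (symmetric, in [0, 1]; both-zero eyes are defined as LI = 1,
the limit of identical eyes); for an occluded eye, LI =
occluded/fellow-baseline, which may exceed 1. The standard range is
μ ± σ over a normal cohort with the sample (n−1) standard deviation —
this choice reproduces the reference vascular-column sd of 0.25 from the
reference per-eye values. Abnormality is a strict inequality against the
lower limit (boundary behaviour was unspecified; strict is documented
here and fixed by a test). The perfusion index is baseline/occluded of
the same eye; an exactly zero occluded value is signalled as
`CompleteOcclusion` rather than returned as infinity.

## Perfusion staging

Five ordered stages — NORMAL > LIMITED > WEAK > DIMINISHING > NONE — are
assigned from (MV, ARBS): NONE when the reported MV is 0, otherwise by
unrounded ARBS with boundaries 0.5 / 4 / 15 percent (config-overridable).
The boundaries are this package's own choice; they separate the five
reference exemplar maps (ARBS 31, 6, 5, 3, 0 with MV 28.1 … 0) and no
claim is made that they are physiologic cut-points. ARBS is carried
unrounded and only display-rounded in reports. One reference exemplar
pairs ARBS = 0 with MV = 15.6, which cannot arise from threshold
segmentation (ARBS = 0 forces an empty vascular compartment); staging
therefore treats hand-entered metrics of that shape as DIMINISHING while
pipeline-derived maps with no vascular pixels report MV = 0 and stage
NONE.

## Pulse waveform

The ROI series is the mean in-ROI MBR per frame over the full recording
window; no detrending, filtering, or beat segmentation (none is part of
the method being implemented). Max−Mean and Mean−Min are deviations
around the whole-window mean, clamped at 0 against 1-ulp floating-point
overshoot on constant series; Max−Min is defined as their sum, making
the additivity identity exact by construction (it equals max − min to
one ulp). The reference baseline triple 2.77 / 2.71 / 5.49 is internally
consistent with this identity (2.77 + 2.71 = 5.48); the source prose
labels the 5.49 value "Max-Mean" in one sentence, which this package
reads as the peak-to-trough deviation.

## Protocol pipeline

Stages run BASELINE → ECAO → REPERFUSE1 → ICAO → REPERFUSE2 with ≥ 1
(nominally 10) recordings per stage. Recordings aggregate by computing
region metrics per recording and averaging each defined field
(UNDEFINED values excluded pairwise, with counts kept). The reperfusion
gate requires |REPERFUSE1 − BASELINE| / BASELINE ≤ 0.20 (inclusive) on a
configurable parameter, MA by default since the protocol's "blood flow"
is unqualified; failing sessions keep their ICAO/REPERFUSE2 data but
those stages are flagged and excluded from cohort statistics. Cohort
summaries report mean, sample sd, and sem = sd/√n. Vessel-ROI statistics
pool vessels across eyes by default (matching a 56-vessels-from-16-eyes
design; per-eye pooling is a config flag). Paired Student t-tests
(two-sided, p from the t distribution with n−1 df; zero-variance
differences degenerate to p = 1 or p = 0) compare each stage against
baseline, with `*`/`**` markers at 0.05 / 0.001 and no multiple-testing
correction by default (a Bonferroni option exists). Inter-eye agreement
at baseline is summarised by OLS of the lower eye on the higher eye per
parameter with the two-sided slope test.

## Synthetic phantoms

The phantom draws `n_vessels` straight rays of width ~3 px from a
nasally displaced ONH point (30 % across the width, mid-height) over a
tissue background; each ray carries one base MBR, brighter rays
overwrite dimmer ones where they cross. Frames modulate the static
pattern by 1 + a·sin(2πft) and add pixel-wise Gaussian noise truncated
at zero (truncation, not reflection, preserves non-negativity). All
randomness flows from a single integer seed; identical seeds give
bit-identical stacks.

Default calibration (fixed once, from the reference cohort statistics):

| parameter | default | rationale |
|---|---|---|
| vessel MBR | 22.43 ± 8.61 AU | baseline vessel-ROI mean ± sd across 56 vessels |
| tissue MBR | 7.5 ± 2.0 AU | whole-image tissue-compartment mean (7.2–7.9) |
| threshold | 15 AU | the segmentation threshold the metrics assume |
| pulse amplitude | 2.77/22.43 ≈ 0.1235 | makes a 22.43 AU vessel's Max−Mean 2.77 AU; the implied across-vessel Max−Mean sd 0.1235 × 8.61 ≈ 1.06 matches the reference 1.02 |
| pulse rate | 3.5 Hz | ~210 bpm, a resting rabbit heart rate; ~14 beats per 4 s window |
| noise sd | 1.0 AU | keeps single-recording compartment means within ~0.5 AU of truth |
| stage scales | ratios of reference stage means | vessel: 1, 6.00/22.43, 19.18/22.43, 21.12/22.43, 20.98/22.43; tissue: 1, 4.90/10.53, 9.82/10.53, 10.30/10.53, 10.49/10.53 |
| inter-eye correlation | 0.86 | √0.738, the strongest reference inter-eye R² |
| asymmetry | 26.19/24.70 ≈ 1.06 | higher-eye / lower-eye vascular means |
| eye-level flow cv | 0.08 | normal-cohort eye-level dispersion 2.07/24.70 |

Eye pairs share a vessel layout; a latent animal factor with the
configured correlation drives both the per-eye flow scale and the
per-ray vessel deviations, so correlation 1 (with zero texture/noise sd)
yields bit-identical eyes and correlation 0 yields statistically
independent ones. Note the two dispersion scales are different study
designs: 8.61 AU is the pooled across-vessel sd of the occlusion cohort,
while fellow-eye comparisons use the much tighter eye-level cv of 0.08.

What the phantom does *not* emulate: real vessel curvature and branching
hierarchy, speckle statistics (noise is Gaussian, not speckle-
distributed), heart-rate variability and waveform asymmetry (the pulse
is a pure sinusoid), eye motion, and illumination drift. Passing tests
therefore demonstrate that the pipeline recovers known ground truth
under the stated statistical structure, not that it is robust to every
artifact of device data.

## Problem sizes and numerical choices

The test suite and the acceptance script run on reduced geometry chosen
as this package's desk scale: 36 × 75 px grids (1/25 of the sensor) and
12-frame recordings spanning exactly one pulse period at 2.5 Hz, so
temporal means are unbiased by partial periods; the waveform cohort uses
full 120-frame recordings at the default 3.5 Hz, where the 30 fps
sampling grid hits the sine peak and trough exactly and the noiseless
Max−Mean closed form a × ROI-mean is exact. The calibrated waveform
cohort sets noise to zero so its expectation is exactly 2.77 by
construction, with dispersion carried by the per-series vessel draws.
Full sensor geometry is available through `PhantomConfig`.

Ties and degenerate inputs: segmentation at exactly the threshold is
vascular; a rectangle's two corners may coincide (a 1 × 1 ROI); a
polygon covering no pixel center is a validation error, as are empty
ROIs, empty stacks, geometry mismatches, and negative or non-finite MBR.
OLS requires non-constant x (constant y returns slope 0, R² 0 by
convention). Frame files restore exactly through `%.17g`; metric
comparisons in tests use 1e-9 absolute on statistics and 1e-6 on
p-values.

## Known limitations

- The temporal-mean map is a stand-in for the instrument's composite
  map; absolute MV/MT/MA levels from real device exports may differ.
- Stage boundaries and the ONH box placement are calibration choices,
  not anatomy.
- The pipeline assumes registered frames (no eye tracking) and fixed
  ROIs across stages.
- Occlusion laterality pairs eyes only when both eyes of an animal ran
  the protocol; it does not model within-animal carryover between the
  two runs.
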