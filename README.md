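# lsfg — laser speckle flowgraphy perfusion analysis

Quantitative analysis of ocular blood-flow maps from laser speckle
flowgraphy (LSFG), built for preclinical work on retinal ischemia — e.g.
rabbit carotid occlusion models in which one eye is taken through an
occlusion–reperfusion protocol while its fellow eye serves as reference.
LSFG reports a per-pixel **mean blur rate (MBR)**, in arbitrary units (AU),
proportional to local blood flow; this package turns MBR frame stacks into
the biomarkers used to detect and stage retinal hypoperfusion.

## What it computes

A recording (nominally 4 s at 30 fps) is reduced to its temporal-mean map.
An ROI on that map is split by a fixed threshold (default 15 AU) into a
vascular compartment (MBR ≥ 15) and a tissue compartment:

- **MV**, **MT**, **MA** — mean MBR over the vascular pixels, tissue
  pixels, and the whole ROI; **MV−MT** is the compartment contrast.
- **ARBS** — area ratio of blood stream, the percentage of ROI pixels
  classified vascular.
- **VPE = ARBS × MV** — vascular perfusion estimate, a single score that
  collapses *how much* vessel area remains and *how fast* it flows.
- **Laterality index (LI)** — between healthy fellow eyes, lower/higher
  value (∈ [0, 1]); for an occluded eye, occluded/fellow-baseline. Normal
  cohorts define a standard range *S*ₗᵢ = μ ± σ; an LI below the lower
  limit flags abnormal asymmetry.
- **Perfusion index** — pre-occlusion / during-occlusion value of the same
  eye (≥ 1 when flow fell).
- **Pulse-waveform metrics** — per-ROI frame series summarised by
  Max−Mean, Mean−Min and Max−Min (= their sum, exactly).
- **Perfusion stage** — NORMAL / LIMITED / WEAK / DIMINISHING / NONE,
  assigned from (MV, ARBS).

The protocol pipeline orchestrates five stages per eye — baseline,
external carotid artery occlusion (ECAO), reperfusion, internal carotid
artery occlusion (ICAO), reperfusion — averaging the ~10 recordings per
stage, enforcing the reperfusion gate (flow back to ±20 % of baseline
before the second occlusion), and producing cohort statistics: per-stage
mean ± sd/sem, paired t-tests against baseline (`*` p < 0.05, `**`
p < 0.001), normal-pair standard ranges, and inter-eye OLS regressions.

A synthetic phantom module generates optic-nerve-head-like MBR stacks
(radial vessel rays over tissue background, sinusoidal pulse, truncated
Gaussian noise), fellow-eye pairs with controlled correlation and
asymmetry, and whole protocol cohorts — everything here is testable
without device data.

## Worked example

```sh
python examples/segment_and_score.py
```

```
--- ROI: onh
MV    =  28.40 AU   (mean MBR, vascular pixels)
MT    =   7.66 AU   (mean MBR, tissue pixels)
MA    =  12.72 AU   (mean MBR, whole ROI)
MV-MT =  20.74 AU   (compartment contrast)
ARBS  =  24.38 %    (vessel area fraction of the ROI)
VPE   =  692.3      (ARBS x MV)
stage = NORMAL
```

A healthy phantom's optic-nerve-head box keeps roughly a quarter of its
pixels above the vascular threshold at a vascular mean near 28 AU, so the
VPE is high and the perfusion stage is NORMAL. Under an ECAO-like flow
scale the vascular area collapses first, dragging ARBS, VPE and the stage
down — the same behaviour the biomarkers are designed to flag. The other
scripts in `examples/` walk through fellow-eye laterality, pulse
waveforms, and the full five-stage protocol; the library surface they use
(`lsfg.*`) is the primary API, and `lsfg simulate|metrics|laterality|
waveform|protocol` exposes the same steps as a thin CLI.

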