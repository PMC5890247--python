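"""Synthetic optic-nerve-head MBR phantoms, eye pairs, and protocol cohorts.

The phantom is a stylised rabbit optic nerve head: a set of straight vessel
rays radiating from a nasally displaced ONH centre, drawn at a vessel-level
MBR over a dimmer tissue background.  Each frame of a recording modulates
the static pattern with a sinusoidal pulse, ``1 + a*sin(2*pi*f*t)``, and adds
pixel-wise Gaussian noise truncated at zero (MBR is non-negative).

Defaults are calibrated to a healthy adult rabbit cohort: vessel MBR
22.43 +/- 8.61 AU across vessels, tissue background near 7.5 AU, relative
pulse amplitude 2.77/22.43 (so a typical vessel's Max-Mean deviation is
2.77 AU), pulse rate 3.5 Hz (~210 bpm), 4 s recordings at 30 fps.  Stage
effects of the occlusion protocol are multiplicative flow scales whose
defaults are the ratios of the per-stage group means to baseline, separately
for the vessel and tissue compartments.

Everything is deterministic given its seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .datatypes import (Eye, MBRFrameStack, PROTOCOL_ORDER, ROI, ROIKind,
                        ROILabel, RecordingMetadata, StageLabel,
                        full_image_roi)
from .errors import ValidationError
from .protocol import ProtocolSession

#: reference-cohort calibration of the generator (vessel ROIs, AU)
BASELINE_VESSEL_MEAN = 22.43
BASELINE_VESSEL_SD = 8.61
#: baseline Max-Mean pulse deviation of a typical vessel (AU)
BASELINE_MAX_MEAN = 2.77


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, intensity, pulsatility and noise of one phantom eye."""

    height: int = 180
    width: int = 375
    n_vessels: int = 6
    vessel_width: float = 3.0
    vessel_mbr_mean: float = BASELINE_VESSEL_MEAN
    vessel_mbr_sd: float = BASELINE_VESSEL_SD
    tissue_mbr_mean: float = 7.5
    tissue_mbr_sd: float = 2.0
    pulse_amplitude: float = BASELINE_MAX_MEAN / BASELINE_VESSEL_MEAN
    pulse_rate_hz: float = 3.5
    noise_sd: float = 1.0
    fps: float = 30.0
    duration_s: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValidationError("phantom dimensions must be positive")
        if self.n_vessels < 1:
            raise ValidationError("need at least one vessel ray")
        if self.vessel_width <= 0:
            raise ValidationError("vessel_width must be positive")
        for name in ("vessel_mbr_sd", "tissue_mbr_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.vessel_mbr_mean < 0 or self.tissue_mbr_mean < 0:
            raise ValidationError("MBR means must be non-negative")
        if not 0 <= self.pulse_amplitude < 1:
            raise ValidationError("pulse_amplitude must be in [0, 1)")
        if self.pulse_rate_hz < 0:
            raise ValidationError("pulse_rate_hz must be non-negative")
        if self.fps <= 0 or self.duration_s <= 0:
            raise ValidationError("fps and duration_s must be positive")
        if int(round(self.fps * self.duration_s)) < 1:
            raise ValidationError("recording must span at least one frame")

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration_s))


@dataclass(frozen=True)
class StageEffects:
    """Multiplicative flow scale per protocol stage (baseline fixed at 1).

    ``vessel_scales`` applies to the vessel rays, ``tissue_scales`` to the
    background; compartment-specific defaults are the ratios of the reference
    per-stage group means to baseline for each compartment.
    """

    vessel_scales: Mapping[StageLabel, float] = field(default_factory=lambda: {
        StageLabel.BASELINE: 1.0,
        StageLabel.ECAO: 6.00 / 22.43,
        StageLabel.REPERFUSE1: 19.18 / 22.43,
        StageLabel.ICAO: 21.12 / 22.43,
        StageLabel.REPERFUSE2: 20.98 / 22.43,
    })
    tissue_scales: Mapping[StageLabel, float] = field(default_factory=lambda: {
        StageLabel.BASELINE: 1.0,
        StageLabel.ECAO: 4.90 / 10.53,
        StageLabel.REPERFUSE1: 9.82 / 10.53,
        StageLabel.ICAO: 10.30 / 10.53,
        StageLabel.REPERFUSE2: 10.49 / 10.53,
    })

    def __post_init__(self) -> None:
        for scales in (self.vessel_scales, self.tissue_scales):
            if scales.get(StageLabel.BASELINE, 1.0) != 1.0:
                raise ValidationError("BASELINE scale must be 1.0")
            if any(v < 0 for v in scales.values()):
                raise ValidationError("stage scales must be non-negative")

    @classmethod
    def uniform(cls, scales: Mapping[StageLabel, float]) -> "StageEffects":
        """Same scale for both compartments."""
        return cls(vessel_scales=dict(scales), tissue_scales=dict(scales))

    def vessel(self, stage: StageLabel) -> float:
        return float(self.vessel_scales.get(StageLabel(stage), 1.0))

    def tissue(self, stage: StageLabel) -> float:
        return float(self.tissue_scales.get(StageLabel(stage), 1.0))


@dataclass(frozen=True)
class PairConfig:
    """Coupling between fellow eyes of one animal.

    A latent per-animal perfusion factor (coefficient of variation
    ``perfusion_cv``) is shared between the eyes with correlation
    ``inter_eye_correlation``; the designated higher eye is additionally
    scaled by ``asymmetry_factor``.  Defaults follow the normal-cohort
    calibration: correlation 0.86 (an inter-eye R^2 near 0.74) and
    asymmetry 26.19/24.70 ~ 1.06, per-eye flow dispersion 0.08 (the
    normal-cohort eye-level coefficient of variation, 2.07/24.70).
    """

    inter_eye_correlation: float = 0.86
    asymmetry_factor: float = 26.19 / 24.70
    perfusion_cv: float = 0.08
    higher_eye: Eye = Eye.RIGHT

    def __post_init__(self) -> None:
        if not 0.0 <= self.inter_eye_correlation <= 1.0:
            raise ValidationError("inter_eye_correlation must be in [0, 1]")
        if self.asymmetry_factor < 1.0:
            raise ValidationError("asymmetry_factor must be >= 1")
        if self.perfusion_cv < 0:
            raise ValidationError("perfusion_cv must be non-negative")


# ---------------------------------------------------------------------------
# geometry


def _onh_center(config: PhantomConfig) -> Tuple[float, float]:
    # nasally displaced ONH: 30 percent across the width, mid-height
    return (config.height / 2.0, 0.30 * config.width)


def vessel_ray_masks(config: PhantomConfig) -> List[np.ndarray]:
    """Boolean mask of each vessel ray (pixels within half the vessel width
    of the ray segment from the ONH centre to the image border)."""
    cy, cx = _onh_center(config)
    rows, cols = np.mgrid[0:config.height, 0:config.width]
    y = rows.astype(float)
    x = cols.astype(float)
    reach = float(config.height + config.width)
    masks = []
    for k in range(config.n_vessels):
        theta = 0.4 + 2.0 * math.pi * k / config.n_vessels
        dy, dx = math.sin(theta), math.cos(theta)
        t = np.clip((y - cy) * dy + (x - cx) * dx, 0.0, reach)
        d2 = (y - (cy + t * dy)) ** 2 + (x - (cx + t * dx)) ** 2
        masks.append(d2 <= (config.vessel_width / 2.0) ** 2)
    return masks


def _pure_square(mask: np.ndarray, center: Tuple[int, int],
                 max_half: int = 1) -> Optional[Tuple[int, int, int]]:
    """Largest half-size square around ``center`` fully inside ``mask``."""
    r, c = center
    h, w = mask.shape
    for half in range(max_half, -1, -1):
        r0, r1 = r - half, r + half
        c0, c1 = c - half, c + half
        if r0 < 0 or c0 < 0 or r1 >= h or c1 >= w:
            continue
        if mask[r0:r1 + 1, c0:c1 + 1].all():
            return r, c, half
    return None


def phantom_rois(config: PhantomConfig,
                 tissue_block: int = 4) -> List[ROI]:
    """ROIs for a phantom: one small pure-vessel rectangle per ray, one
    vessel-free tissue rectangle, an ONH box around the ray origin, and the
    entire image.

    Vessel ROIs are placed along each ray, away from the ONH centre where
    rays overlap, and shrunk until they contain vessel pixels only, so the
    plain ROI mean reads the ray's MBR without tissue dilution.  The ONH
    box is where the rays converge, giving the high vessel-area fraction
    the perfusion-stage boundaries are anchored to.
    """
    masks = vessel_ray_masks(config)
    any_vessel = np.logical_or.reduce(masks)
    cy, cx = _onh_center(config)
    rois: List[ROI] = [full_image_roi(config.height, config.width)]

    for k, mask in enumerate(masks):
        others = [m for j, m in enumerate(masks) if j != k]
        other = (np.logical_or.reduce(others) if others
                 else np.zeros_like(mask))
        own_only = mask & ~other
        theta = 0.4 + 2.0 * math.pi * k / config.n_vessels
        dy, dx = math.sin(theta), math.cos(theta)
        placed = None
        # walk outward along the ray and keep the farthest workable square
        for frac in (0.60, 0.50, 0.70, 0.40, 0.30, 0.20, 0.80, 0.10):
            reach = float(config.height + config.width)
            r = int(round(cy + frac * reach * dy))
            c = int(round(cx + frac * reach * dx))
            if not (0 <= r < config.height and 0 <= c < config.width):
                continue
            if not own_only[r, c]:
                continue
            placed = _pure_square(own_only, (r, c), max_half=1)
            if placed:
                break
        if placed is None:
            # fall back to any pixel unique to this ray
            idx = np.argwhere(own_only)
            if idx.size == 0:
                idx = np.argwhere(mask)
            if idx.size == 0:
                continue
            r, c = map(int, idx[len(idx) // 2])
            placed = (r, c, 0)
        r, c, half = placed
        rois.append(ROI(name=f"vessel_{k}", kind=ROIKind.RECTANGLE,
                        label=ROILabel.VESSEL,
                        vertices=((r - half, c - half), (r + half, c + half))))

    # tissue ROI: scan for a vessel-free block, preferring the far corner
    b = tissue_block
    found = None
    for r in range(config.height - b, -1, -1):
        for c in range(config.width - b, -1, -1):
            if not any_vessel[r:r + b, c:c + b].any():
                found = (r, c)
                break
        if found:
            break
    if found:
        r, c = found
        rois.append(ROI(name="tissue", kind=ROIKind.RECTANGLE,
                        label=ROILabel.TISSUE,
                        vertices=((r, c), (r + b - 1, c + b - 1))))

    # ONH box around the ray origin
    half = max(3, int(round(0.12 * min(config.height, config.width))))
    r0 = int(max(0, round(cy) - half))
    r1 = int(min(config.height - 1, round(cy) + half))
    c0 = int(max(0, round(cx) - half))
    c1 = int(min(config.width - 1, round(cx) + half))
    rois.append(ROI(name="onh", kind=ROIKind.RECTANGLE, label=ROILabel.ONH,
                    vertices=((r0, c0), (r1, c1))))
    return rois


# ---------------------------------------------------------------------------
# stack generation


def generate_phantom_stack(config: PhantomConfig,
                           stage_scale: float = 1.0,
                           *,
                           vessel_scale: Optional[float] = None,
                           tissue_scale: Optional[float] = None,
                           vessel_values: Optional[Sequence[float]] = None,
                           pulse_phase: float = 0.0,
                           animal_id: str = "phantom",
                           eye: Eye = Eye.LEFT,
                           stage: StageLabel = StageLabel.BASELINE
                           ) -> MBRFrameStack:
    """One recording of one phantom eye.

    ``stage_scale`` multiplies both compartments; ``vessel_scale`` /
    ``tissue_scale`` override it per compartment.  ``vessel_values`` fixes
    the per-ray base MBR (drawn from N(vessel_mbr_mean, vessel_mbr_sd^2)
    otherwise); all randomness comes from ``config.seed``.
    """
    if stage_scale < 0:
        raise ValidationError("stage_scale must be non-negative")
    v_scale = stage_scale if vessel_scale is None else vessel_scale
    t_scale = stage_scale if tissue_scale is None else tissue_scale
    if v_scale < 0 or t_scale < 0:
        raise ValidationError("compartment scales must be non-negative")

    rng = np.random.default_rng(config.seed)
    masks = vessel_ray_masks(config)
    if vessel_values is None:
        values = rng.normal(config.vessel_mbr_mean, config.vessel_mbr_sd,
                            size=config.n_vessels)
    else:
        values = np.asarray(list(vessel_values), dtype=float)
        if values.size != config.n_vessels:
            raise ValidationError(
                f"need {config.n_vessels} vessel values, got {values.size}")
    values = np.clip(values, 0.0, None)

    tissue = rng.normal(config.tissue_mbr_mean, config.tissue_mbr_sd,
                        size=(config.height, config.width))
    base = np.clip(tissue, 0.0, None) * t_scale
    # brighter rays overwrite dimmer ones where they cross
    order = np.argsort(values)
    for k in order:
        base[masks[k]] = values[k] * v_scale

    n = config.n_frames
    t = np.arange(n) / config.fps
    modulation = 1.0 + config.pulse_amplitude * np.sin(
        2.0 * math.pi * config.pulse_rate_hz * t + pulse_phase)
    frames = base[None, :, :] * modulation[:, None, None]
    if config.noise_sd > 0:
        frames = frames + rng.normal(0.0, config.noise_sd, size=frames.shape)
    frames = np.clip(frames, 0.0, None)

    metadata = RecordingMetadata(
        animal_id=animal_id, eye=eye, stage=stage, fps=config.fps,
        duration_s=config.duration_s, height=config.height,
        width=config.width)
    return MBRFrameStack(frames=frames, metadata=metadata)


def generate_eye_pair(config: PhantomConfig, pair: PairConfig,
                      seed: int) -> Tuple[MBRFrameStack, MBRFrameStack]:
    """Baseline recordings of the two eyes of one animal.

    Both eyes share the vessel layout.  A latent animal factor induces the
    configured correlation in both the per-eye flow scale and the per-ray
    vessel values (correlation 1 makes the eyes share everything but pixel
    noise; correlation 0 makes them statistically independent); the
    designated higher eye is scaled by the asymmetry factor on top.
    Returns ``(left, right)``.
    """
    rng = np.random.default_rng(seed)
    rho = pair.inter_eye_correlation
    w_shared, w_own = math.sqrt(rho), math.sqrt(1.0 - rho)
    z_shared = rng.standard_normal()
    dev_shared = rng.normal(0.0, config.vessel_mbr_sd,
                            size=config.n_vessels)
    factors, vessel_values = {}, {}
    for eye in (Eye.LEFT, Eye.RIGHT):
        z = w_shared * z_shared + w_own * rng.standard_normal()
        f = max(1.0 + pair.perfusion_cv * z, 0.05)
        if eye is pair.higher_eye:
            f *= pair.asymmetry_factor
        factors[eye] = f
        dev = (w_shared * dev_shared +
               w_own * rng.normal(0.0, config.vessel_mbr_sd,
                                  size=config.n_vessels))
        vessel_values[eye] = np.clip(config.vessel_mbr_mean + dev, 0.0, None)

    stacks = {}
    for eye in (Eye.LEFT, Eye.RIGHT):
        cfg = replace(config, seed=int(rng.integers(2 ** 31)))
        stacks[eye] = generate_phantom_stack(
            cfg, stage_scale=factors[eye], vessel_values=vessel_values[eye],
            eye=eye, stage=StageLabel.BASELINE)
    return stacks[Eye.LEFT], stacks[Eye.RIGHT]


def generate_protocol_cohort(n_eyes: int,
                             n_vessels_per_eye,
                             effects: StageEffects = StageEffects(),
                             config: PhantomConfig = PhantomConfig(),
                             seed: int = 0,
                             n_recordings: int = 10,
                             stages: Sequence[StageLabel] = PROTOCOL_ORDER
                             ) -> List[ProtocolSession]:
    """Full five-stage cohort of ``n_eyes`` sessions.

    ``n_vessels_per_eye`` is an int or a per-eye sequence (e.g. ``[4]*8 +
    [3]*8`` to spread 56 vessels over 16 eyes).  Each eye draws its per-ray
    vessel MBR once from N(vessel_mbr_mean, vessel_mbr_sd^2); every stage
    re-records the same eye ``n_recordings`` times with the stage's
    compartment scales, a random pulse phase per recording, and fresh noise.
    """
    if n_eyes < 1:
        raise ValidationError("n_eyes must be >= 1")
    if n_recordings < 1:
        raise ValidationError("n_recordings must be >= 1")
    if isinstance(n_vessels_per_eye, int):
        vessels = [n_vessels_per_eye] * n_eyes
    else:
        vessels = [int(v) for v in n_vessels_per_eye]
        if len(vessels) != n_eyes:
            raise ValidationError(
                f"n_vessels_per_eye has {len(vessels)} entries for "
                f"{n_eyes} eyes")

    rng = np.random.default_rng(seed)
    sessions: List[ProtocolSession] = []
    for e, nv in enumerate(vessels):
        cfg = replace(config, n_vessels=nv)
        vessel_values = np.clip(
            rng.normal(cfg.vessel_mbr_mean, cfg.vessel_mbr_sd, size=nv),
            0.0, None)
        animal_id = f"A{e:02d}"
        recordings: Dict[StageLabel, List[MBRFrameStack]] = {}
        for stage in stages:
            stage = StageLabel(stage)
            stage_recs = []
            for _ in range(n_recordings):
                rec_cfg = replace(cfg, seed=int(rng.integers(2 ** 31)))
                stage_recs.append(generate_phantom_stack(
                    rec_cfg,
                    vessel_scale=effects.vessel(stage),
                    tissue_scale=effects.tissue(stage),
                    vessel_values=vessel_values,
                    pulse_phase=float(rng.uniform(0.0, 2.0 * math.pi)),
                    animal_id=animal_id, eye=Eye.LEFT, stage=stage))
            recordings[stage] = stage_recs
        sessions.append(ProtocolSession(
            animal_id=animal_id, eye=Eye.LEFT, recordings=recordings,
            rois=phantom_rois(cfg)))
    return sessions
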