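"""Perfusion biomarkers computed from MBR maps.

Threshold segmentation of a map into vascular and tissue compartments, the
compartment means MV / MT / MA and their difference MV-MT, the vessel area
ratio ARBS, the vascular perfusion estimate VPE = ARBS x MV, both laterality
index (LI) definitions with their mu +/- sigma standard range, the perfusion
index, and a five-level perfusion-stage classification.

Conventions
-----------
* Segmentation is inclusive: a pixel is vascular iff its MBR >= threshold
  (default 15 AU).
* When a compartment is empty its mean is UNDEFINED (``None``) internally and
  never silently zero; report-facing code maps an undefined MV to 0, the
  convention used for a fully non-perfused map.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum, IntEnum
from typing import Optional, Sequence

import numpy as np

from .datatypes import MBRMap, ROI
from .errors import CompleteOcclusion, ValidationError

#: default vascular/tissue MBR threshold in AU
DEFAULT_THRESHOLD = 15.0


class Parameter(str, Enum):
    MV = "MV"
    MT = "MT"
    MA = "MA"
    MV_MT = "MV_MT"
    ARBS = "ARBS"


class LIDefinition(str, Enum):
    #: ratio of the lower to the higher value between healthy fellow eyes
    NORMAL_LOWER_OVER_HIGHER = "NORMAL_LOWER_OVER_HIGHER"
    #: ratio of the occluded eye's value to its fellow eye's baseline
    OCCLUDED_OVER_FELLOW = "OCCLUDED_OVER_FELLOW"


class PerfusionStage(IntEnum):
    """Ordered perfusion levels, from no flow to normal flow."""

    NONE = 0
    DIMINISHING = 1
    WEAK = 2
    LIMITED = 3
    NORMAL = 4


@dataclass(frozen=True)
class StageBoundaries:
    """ARBS (percent, unrounded) cut points for the perfusion stages.

    A map with no vascular signal at all (reported MV of 0) is stage NONE
    regardless of these boundaries.  Boundaries are lower-inclusive:
    ARBS < diminishing_max -> DIMINISHING, ... , ARBS >= limited_max -> NORMAL.
    """

    diminishing_max: float = 0.5
    weak_max: float = 4.0
    limited_max: float = 15.0

    def __post_init__(self) -> None:
        if not (0 < self.diminishing_max < self.weak_max < self.limited_max):
            raise ValidationError("stage boundaries must be increasing")


@dataclass(frozen=True)
class SegmentationResult:
    """Vascular mask of an ROI at a threshold; in-ROI pixels not in the
    vascular mask form the tissue compartment."""

    vascular_mask: np.ndarray
    roi_mask: np.ndarray
    threshold: float
    roi: ROI


@dataclass(frozen=True)
class RegionMetrics:
    """Compartment means of one map + ROI + segmentation.

    ``mv``/``mt``/``mv_mt`` are ``None`` when the corresponding compartment is
    empty; ``ma`` (mean over all in-ROI pixels) and ``arbs`` (percent of
    in-ROI pixels that are vascular) are always defined for a non-empty ROI.
    """

    mv: Optional[float]
    mt: Optional[float]
    ma: float
    mv_mt: Optional[float]
    arbs: float
    n_vascular: float
    n_tissue: float
    threshold: Optional[float] = None

    @property
    def mv_reported(self) -> float:
        """MV under the reporting convention: 0 when no vascular pixels."""
        return 0.0 if self.mv is None else self.mv

    def value(self, parameter: Parameter, *, reported: bool = False
              ) -> Optional[float]:
        parameter = Parameter(parameter)
        if parameter is Parameter.MV:
            return self.mv_reported if reported else self.mv
        if parameter is Parameter.MT:
            return self.mt
        if parameter is Parameter.MA:
            return self.ma
        if parameter is Parameter.MV_MT:
            return self.mv_mt
        return self.arbs


@dataclass(frozen=True)
class StandardRange:
    """mu +/- sigma reference band of a laterality index in a normal cohort."""

    mean: float
    sd: float
    lower: float
    upper: float
    n: int


@dataclass(frozen=True)
class LateralityResult:
    parameter: Parameter
    li: float
    definition: LIDefinition
    abnormal: Optional[bool] = None


def segment_by_threshold(mbr_map: MBRMap, roi: ROI,
                         threshold: float = DEFAULT_THRESHOLD
                         ) -> SegmentationResult:
    """Mark in-ROI pixels with MBR >= threshold as vascular."""
    if threshold <= 0:
        raise ValidationError(f"threshold must be positive, got {threshold}")
    h, w = mbr_map.shape
    roi_mask = roi.mask(h, w)
    if not roi_mask.any():
        raise ValidationError(f"ROI {roi.name!r} covers no pixel centers")
    vascular = roi_mask & (mbr_map.values >= threshold)
    return SegmentationResult(vascular_mask=vascular, roi_mask=roi_mask,
                              threshold=float(threshold), roi=roi)


def compute_region_metrics(mbr_map: MBRMap,
                           seg: SegmentationResult) -> RegionMetrics:
    """MV / MT / MA / MV-MT / ARBS of one segmented map."""
    if seg.roi_mask.shape != mbr_map.shape:
        raise ValidationError("segmentation does not match map dimensions")
    roi_vals = mbr_map.values[seg.roi_mask]
    if roi_vals.size == 0:
        raise ValidationError("ROI covers no pixels")
    tissue_mask = seg.roi_mask & ~seg.vascular_mask
    vas_vals = mbr_map.values[seg.vascular_mask]
    tis_vals = mbr_map.values[tissue_mask]
    n_v = int(vas_vals.size)
    n_t = int(tis_vals.size)
    mv = float(vas_vals.mean()) if n_v else None
    mt = float(tis_vals.mean()) if n_t else None
    mv_mt = (mv - mt) if (mv is not None and mt is not None) else None
    return RegionMetrics(
        mv=mv, mt=mt, ma=float(roi_vals.mean()), mv_mt=mv_mt,
        arbs=100.0 * n_v / (n_v + n_t), n_vascular=n_v, n_tissue=n_t,
        threshold=seg.threshold)


def compute_vpe(metrics: RegionMetrics) -> float:
    """Vascular perfusion estimate, VPE = ARBS x MV (AU x percent).

    When no vascular pixels exist ARBS is 0 and VPE is 0 regardless of MV.
    """
    if metrics.arbs == 0.0:
        return 0.0
    if metrics.mv is None:
        raise ValidationError("ARBS > 0 requires a defined MV")
    return metrics.arbs * metrics.mv


def _require_value(metrics: RegionMetrics, parameter: Parameter) -> float:
    v = metrics.value(parameter)
    if v is None:
        raise ValidationError(f"parameter {Parameter(parameter).value} is "
                              "UNDEFINED (empty compartment)")
    return v


def laterality_index_normal(metrics_a: RegionMetrics,
                            metrics_b: RegionMetrics,
                            parameter: Parameter) -> LateralityResult:
    """LI between healthy fellow eyes: lower value / higher value, in [0, 1].

    Two eyes with identically zero values are treated as identical (LI = 1).
    """
    parameter = Parameter(parameter)
    a = _require_value(metrics_a, parameter)
    b = _require_value(metrics_b, parameter)
    if a < 0 or b < 0:
        raise ValidationError("laterality inputs must be non-negative")
    if a == 0.0 and b == 0.0:
        li = 1.0
    else:
        li = min(a, b) / max(a, b)
    return LateralityResult(parameter=parameter, li=li,
                            definition=LIDefinition.NORMAL_LOWER_OVER_HIGHER)


def laterality_index_occlusion(occluded: RegionMetrics,
                               fellow_baseline: RegionMetrics,
                               parameter: Parameter) -> LateralityResult:
    """LI of an occluded eye: occluded value / fellow-eye baseline value."""
    parameter = Parameter(parameter)
    occ = _require_value(occluded, parameter)
    fel = _require_value(fellow_baseline, parameter)
    if fel <= 0:
        raise ValidationError("fellow-eye baseline must be positive")
    return LateralityResult(parameter=parameter, li=occ / fel,
                            definition=LIDefinition.OCCLUDED_OVER_FELLOW)


def standard_range(li_values: Sequence[float]) -> StandardRange:
    """mu +/- sigma of a set of laterality indices (sample sd, n-1).

    With a single value the sd is 0 and the range collapses to the value.
    """
    values = np.asarray(list(li_values), dtype=float)
    if values.size == 0:
        raise ValidationError("standard range needs at least one LI value")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return StandardRange(mean=mean, sd=sd, lower=mean - sd, upper=mean + sd,
                         n=int(values.size))


def flag_abnormal(li: LateralityResult,
                  rng: StandardRange) -> LateralityResult:
    """Mark an LI abnormal when strictly below the standard range's lower
    limit; a value exactly on the limit is within range."""
    return replace(li, abnormal=bool(li.li < rng.lower))


def perfusion_index(baseline: RegionMetrics, occluded: RegionMetrics,
                    parameter: Parameter) -> float:
    """Ratio of an eye's pre-occlusion value to its value during occlusion
    (>= 1 when flow decreased).  Zero flow during occlusion is signalled as
    :class:`~lsfg.errors.CompleteOcclusion`."""
    parameter = Parameter(parameter)
    base = _require_value(baseline, parameter)
    occ = _require_value(occluded, parameter)
    if occ == 0.0:
        raise CompleteOcclusion(
            f"occluded {parameter.value} is 0; perfusion index undefined")
    return base / occ


def classify_perfusion_stage(metrics: RegionMetrics,
                             boundaries: StageBoundaries = StageBoundaries()
                             ) -> PerfusionStage:
    """Assign one of the five perfusion levels from (MV, ARBS).

    NONE when the reported MV is 0 (no vascular signal anywhere); otherwise
    by unrounded ARBS: below ``diminishing_max`` percent DIMINISHING, then
    WEAK, LIMITED, and NORMAL at ``limited_max`` percent or more.
    """
    if metrics.mv_reported == 0.0:
        return PerfusionStage.NONE
    if metrics.arbs < boundaries.diminishing_max:
        return PerfusionStage.DIMINISHING
    if metrics.arbs < boundaries.weak_max:
        return PerfusionStage.WEAK
    if metrics.arbs < boundaries.limited_max:
        return PerfusionStage.LIMITED
    return PerfusionStage.NORMAL
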