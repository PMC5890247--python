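"""Core containers for laser speckle flowgraphy (LSFG) analysis.

LSFG reports, per pixel, a mean blur rate (MBR) in arbitrary units (AU) that
scales with local blood flow.  One recording is a short frame stack (nominally
4 s at 30 fps); analysis runs on the time-averaged map, on regions of interest
(ROIs) drawn on it, and on per-ROI time series.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import Tuple

import numpy as np

from ._geometry import polygon_mask, rectangle_mask
from .errors import ValidationError


class Eye(str, Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"

    @property
    def fellow(self) -> "Eye":
        return Eye.RIGHT if self is Eye.LEFT else Eye.LEFT


class StageLabel(str, Enum):
    """The five stages of the carotid occlusion-reperfusion protocol."""

    BASELINE = "BASELINE"
    ECAO = "ECAO"
    REPERFUSE1 = "REPERFUSE1"
    ICAO = "ICAO"
    REPERFUSE2 = "REPERFUSE2"


#: protocol order: baseline, external carotid occlusion, reperfusion,
#: internal carotid occlusion, reperfusion
PROTOCOL_ORDER: Tuple[StageLabel, ...] = (
    StageLabel.BASELINE,
    StageLabel.ECAO,
    StageLabel.REPERFUSE1,
    StageLabel.ICAO,
    StageLabel.REPERFUSE2,
)


class ROIKind(str, Enum):
    RECTANGLE = "RECTANGLE"
    POLYGON = "POLYGON"


class ROILabel(str, Enum):
    VESSEL = "VESSEL"
    TISSUE = "TISSUE"
    ENTIRE_IMAGE = "ENTIRE_IMAGE"
    ONH = "ONH"


@dataclass(frozen=True)
class RecordingMetadata:
    """Identity and geometry of one LSFG recording of one eye."""

    animal_id: str
    eye: Eye
    stage: StageLabel
    fps: float
    duration_s: float
    height: int
    width: int
    mbr_units: str = "AU"

    def __post_init__(self) -> None:
        object.__setattr__(self, "eye", Eye(self.eye))
        object.__setattr__(self, "stage", StageLabel(self.stage))
        if self.fps <= 0:
            raise ValidationError(f"fps must be positive, got {self.fps}")
        if self.duration_s <= 0:
            raise ValidationError(
                f"duration_s must be positive, got {self.duration_s}")
        if self.height <= 0 or self.width <= 0:
            raise ValidationError(
                f"image dimensions must be positive, got "
                f"{self.height}x{self.width}")

    @property
    def n_frames(self) -> int:
        """Expected frame count, round(fps * duration_s)."""
        return int(round(self.fps * self.duration_s))


@dataclass
class MBRFrameStack:
    """A time-ordered stack of 2-D MBR maps for one recording.

    ``frames`` has shape (n_frames, height, width); every value is a
    non-negative finite MBR in AU.
    """

    frames: np.ndarray
    metadata: RecordingMetadata

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3:
            raise ValidationError(
                f"frames must be 3-D (time, row, col), got ndim={frames.ndim}")
        if frames.shape[0] < 1:
            raise ValidationError("a frame stack needs at least one frame")
        if frames.shape[1:] != (self.metadata.height, self.metadata.width):
            raise ValidationError(
                f"frame shape {frames.shape[1:]} does not match metadata "
                f"{(self.metadata.height, self.metadata.width)}")
        if frames.shape[0] != self.metadata.n_frames:
            raise ValidationError(
                f"frame count {frames.shape[0]} does not match "
                f"round(fps*duration) = {self.metadata.n_frames}")
        if not np.isfinite(frames).all():
            raise ValidationError("frame stack contains non-finite values")
        if (frames < 0).any():
            raise ValidationError("MBR values must be non-negative")
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class MBRMap:
    """A single 2-D MBR map (typically the temporal mean of a recording)."""

    values: np.ndarray
    metadata: RecordingMetadata

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValidationError(f"map must be 2-D, got ndim={values.ndim}")
        if values.shape != (self.metadata.height, self.metadata.width):
            raise ValidationError(
                f"map shape {values.shape} does not match metadata "
                f"{(self.metadata.height, self.metadata.width)}")
        if not np.isfinite(values).all():
            raise ValidationError("map contains non-finite values")
        if (values < 0).any():
            raise ValidationError("MBR values must be non-negative")
        self.values = values

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class ROI:
    """A region of interest on an MBR map.

    Coordinates are 0-based (row, col) pixel centers.  A RECTANGLE is stored
    as two corner vertices (top-left, bottom-right), inclusive on all edges;
    a POLYGON has at least three vertices and uses even-odd membership with
    boundary pixels included.
    """

    name: str
    kind: ROIKind
    label: ROILabel
    vertices: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", ROIKind(self.kind))
        object.__setattr__(self, "label", ROILabel(self.label))
        verts = tuple((float(r), float(c)) for r, c in self.vertices)
        object.__setattr__(self, "vertices", verts)
        if self.kind is ROIKind.RECTANGLE:
            if len(verts) != 2:
                raise ValidationError(
                    f"RECTANGLE needs exactly 2 corner vertices, "
                    f"got {len(verts)}")
            (r0, c0), (r1, c1) = verts
            if r0 > r1 or c0 > c1:
                raise ValidationError(
                    "RECTANGLE corners must be ordered top-left then "
                    "bottom-right")
        else:
            if len(verts) < 3:
                raise ValidationError(
                    f"POLYGON needs at least 3 vertices, got {len(verts)}")

    def check_bounds(self, height: int, width: int) -> None:
        """Raise ValidationError unless every vertex lies within the image."""
        for r, c in self.vertices:
            if not (0 <= r <= height - 1 and 0 <= c <= width - 1):
                raise ValidationError(
                    f"ROI {self.name!r}: vertex ({r}, {c}) outside "
                    f"{height}x{width} image")

    def mask(self, height: int, width: int) -> np.ndarray:
        """Boolean membership mask of this ROI on a height x width grid."""
        self.check_bounds(height, width)
        if self.kind is ROIKind.RECTANGLE:
            return rectangle_mask(self.vertices, height, width)
        return polygon_mask(self.vertices, height, width)


def full_image_roi(height: int, width: int,
                   name: str = "entire_image") -> ROI:
    """Rectangle ROI covering every pixel of a height x width map."""
    return ROI(name=name, kind=ROIKind.RECTANGLE, label=ROILabel.ENTIRE_IMAGE,
               vertices=((0, 0), (height - 1, width - 1)))
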