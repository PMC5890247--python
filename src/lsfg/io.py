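"""Readers and writers for MBR frame stacks and ROIs, plus basic map ops.

On-disk layout of one recording (one directory per recording):

    metadata.json            recording identity and geometry
    frame_0000.tsv ...       one tab-separated decimal grid per frame,
                             zero-padded 0-based frame index

Frames are written with ``%.17g`` so a write -> read round trip restores
every pixel bit-exactly.  ROIs are single JSON files with keys
``name, kind, label, vertices``.
"""
from __future__ import annotations

import json
import re
from pathlib import Path
from typing import List, Union

import numpy as np

from .datatypes import (MBRFrameStack, MBRMap, RecordingMetadata, ROI)
from .errors import FormatError, ValidationError

_METADATA_KEYS = ("animal_id", "eye", "stage", "fps", "duration_s",
                  "height", "width", "mbr_units")
_FRAME_RE = re.compile(r"frame_(\d+)\.tsv$")

PathLike = Union[str, Path]


def write_mbr_stack(stack: MBRFrameStack, path: PathLike) -> None:
    """Write a frame stack to ``path`` (a directory, created if needed)."""
    if not np.isfinite(stack.frames).all():
        raise ValidationError("refusing to write non-finite MBR values")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = stack.metadata
    payload = {
        "animal_id": meta.animal_id,
        "eye": meta.eye.value,
        "stage": meta.stage.value,
        "fps": meta.fps,
        "duration_s": meta.duration_s,
        "height": meta.height,
        "width": meta.width,
        "mbr_units": meta.mbr_units,
    }
    (path / "metadata.json").write_text(json.dumps(payload, indent=1))
    pad = max(4, len(str(stack.n_frames - 1)))
    for i, frame in enumerate(stack.frames):
        np.savetxt(path / f"frame_{i:0{pad}d}.tsv", frame,
                   fmt="%.17g", delimiter="\t")


def read_mbr_stack(path: PathLike) -> MBRFrameStack:
    """Read a frame stack directory written by :func:`write_mbr_stack`."""
    path = Path(path)
    meta_path = path / "metadata.json"
    if not meta_path.is_file():
        raise FormatError(f"no metadata.json in {path}")
    try:
        raw = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"ill-formed metadata.json in {path}: {exc}") from exc
    missing = [k for k in _METADATA_KEYS if k not in raw]
    if missing:
        raise FormatError(f"metadata.json missing keys: {missing}")
    try:
        metadata = RecordingMetadata(**{k: raw[k] for k in _METADATA_KEYS})
    except (TypeError, ValueError) as exc:
        raise FormatError(f"bad metadata values: {exc}") from exc

    indexed = []
    for f in path.iterdir():
        m = _FRAME_RE.search(f.name)
        if m:
            indexed.append((int(m.group(1)), f))
    if not indexed:
        raise FormatError(f"no frame_*.tsv files in {path}")
    indexed.sort()
    indices = [i for i, _ in indexed]
    if indices != list(range(len(indices))):
        raise FormatError(f"frame indices not contiguous from 0: {indices[:5]}...")

    frames: List[np.ndarray] = []
    for _, f in indexed:
        try:
            frames.append(np.loadtxt(f, delimiter="\t", ndmin=2))
        except ValueError as exc:
            raise FormatError(f"cannot parse frame file {f.name}: {exc}") from exc
    shapes = {fr.shape for fr in frames}
    if len(shapes) > 1:
        raise ValidationError(f"frames disagree in shape: {sorted(shapes)}")
    return MBRFrameStack(frames=np.stack(frames), metadata=metadata)


def temporal_mean(stack: MBRFrameStack) -> MBRMap:
    """Per-pixel arithmetic mean across frames.

    This is the package's definition of the per-recording composite map on
    which segmentation and region metrics are computed.
    """
    if stack.n_frames < 1:
        raise ValidationError("cannot average an empty stack")
    return MBRMap(values=stack.frames.mean(axis=0), metadata=stack.metadata)


def extract_roi_values(mbr_map: MBRMap, roi: ROI) -> np.ndarray:
    """Values of all pixels whose centers lie inside the ROI, row-major."""
    h, w = mbr_map.shape
    mask = roi.mask(h, w)
    if not mask.any():
        raise ValidationError(f"ROI {roi.name!r} covers no pixel centers")
    return mbr_map.values[mask]


def write_roi(roi: ROI, path: PathLike) -> None:
    payload = {
        "name": roi.name,
        "kind": roi.kind.value,
        "label": roi.label.value,
        "vertices": [[r, c] for r, c in roi.vertices],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_roi(path: PathLike) -> ROI:
    try:
        raw = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read ROI file {path}: {exc}") from exc
    for key in ("name", "kind", "label", "vertices"):
        if key not in raw:
            raise FormatError(f"ROI file {path} missing key {key!r}")
    return ROI(name=raw["name"], kind=raw["kind"], label=raw["label"],
               vertices=tuple((r, c) for r, c in raw["vertices"]))
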