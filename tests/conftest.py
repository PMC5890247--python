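"""Shared fixtures and brute-force oracles for the lsfg test suite."""
from __future__ import annotations

import numpy as np
import pytest

from lsfg import (MBRFrameStack, MBRMap, PhantomConfig, RecordingMetadata,
                  RegionMetrics)


def make_metadata(height, width, *, fps=1.0, duration_s=None, n_frames=1,
                  stage="BASELINE", eye="LEFT", animal_id="test"):
    if duration_s is None:
        duration_s = n_frames / fps
    return RecordingMetadata(animal_id=animal_id, eye=eye, stage=stage,
                             fps=fps, duration_s=duration_s,
                             height=height, width=width)


def make_map(values, **meta_kwargs) -> MBRMap:
    values = np.asarray(values, dtype=float)
    meta = make_metadata(*values.shape, **meta_kwargs)
    return MBRMap(values=values, metadata=meta)


def make_stack(frames, *, fps=30.0, **meta_kwargs) -> MBRFrameStack:
    frames = np.asarray(frames, dtype=float)
    meta = make_metadata(frames.shape[1], frames.shape[2], fps=fps,
                         n_frames=frames.shape[0], **meta_kwargs)
    return MBRFrameStack(frames=frames, metadata=meta)


def make_region_metrics(mv, arbs, *, mt=None, ma=None) -> RegionMetrics:
    """RegionMetrics carrying given reference (MV, ARBS) exemplar values."""
    mv_field = None if mv == 0 else float(mv)
    return RegionMetrics(mv=mv_field, mt=mt,
                         ma=float(ma if ma is not None else mv),
                         mv_mt=None if mt is None or mv_field is None
                         else mv_field - mt,
                         arbs=float(arbs), n_vascular=0, n_tissue=0)


def brute_force_region_means(values, roi_mask, threshold):
    """Per-pixel loop oracle for MV / MT / MA / ARBS."""
    vas, tis, allv = [], [], []
    h, w = values.shape
    for r in range(h):
        for c in range(w):
            if not roi_mask[r, c]:
                continue
            v = values[r, c]
            allv.append(v)
            (vas if v >= threshold else tis).append(v)
    mv = float(np.mean(vas)) if vas else None
    mt = float(np.mean(tis)) if tis else None
    return {
        "mv": mv, "mt": mt, "ma": float(np.mean(allv)),
        "arbs": 100.0 * len(vas) / len(allv),
        "n_vascular": len(vas), "n_tissue": len(tis),
    }


@pytest.fixture
def tiny_phantom_config() -> PhantomConfig:
    """Desk-size phantom: 24x48, one pulse period per 12-frame recording."""
    return PhantomConfig(height=24, width=48, n_vessels=3, vessel_width=3,
                         duration_s=0.4, pulse_rate_hz=2.5, seed=7)
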