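"""Pixel-membership geometry for ROIs.

Pixels are addressed by their integer (row, col) centers, 0-based, row-major.
Polygon membership uses the even-odd (ray crossing) rule with pixels whose
centers lie exactly on the boundary counted as inside.
"""
from __future__ import annotations

import numpy as np

#: distance below which a pixel center counts as lying on a polygon edge
_BOUNDARY_TOL = 1e-9


def polygon_mask(vertices, height: int, width: int) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside a polygon.

    Parameters
    ----------
    vertices : sequence of (row, col)
        Polygon vertices in order; the polygon is closed implicitly.
    height, width : int
        Grid dimensions.

    Returns
    -------
    numpy.ndarray of bool, shape (height, width)
    """
    verts = np.asarray(vertices, dtype=float)
    rows, cols = np.mgrid[0:height, 0:width]
    y = rows.ravel().astype(float)
    x = cols.ravel().astype(float)

    inside = np.zeros(y.size, dtype=bool)
    on_edge = np.zeros(y.size, dtype=bool)
    n = len(verts)
    for i in range(n):
        y1, x1 = verts[i]
        y2, x2 = verts[(i + 1) % n]
        dy = y2 - y1
        dx = x2 - x1
        seg2 = dy * dy + dx * dx
        if seg2 == 0.0:
            d2 = (y - y1) ** 2 + (x - x1) ** 2
            on_edge |= d2 <= _BOUNDARY_TOL ** 2
            continue
        # exact point-to-segment distance for the boundary-inclusive rule
        t = np.clip(((y - y1) * dy + (x - x1) * dx) / seg2, 0.0, 1.0)
        d2 = (y - (y1 + t * dy)) ** 2 + (x - (x1 + t * dx)) ** 2
        on_edge |= d2 <= _BOUNDARY_TOL ** 2
        # even-odd crossing count; half-open vertex rule keeps shared
        # vertices from being counted twice
        straddles = (y1 > y) != (y2 > y)
        if np.any(straddles):
            with np.errstate(divide="ignore", invalid="ignore"):
                x_int = x1 + (y - y1) * dx / dy
            inside ^= straddles & (x < x_int)

    return (inside | on_edge).reshape(height, width)


def rectangle_mask(corners, height: int, width: int) -> np.ndarray:
    """Boolean mask of a rectangle given two corners, all edges inclusive."""
    (r0, c0), (r1, c1) = corners
    mask = np.zeros((height, width), dtype=bool)
    ra = int(np.ceil(r0))
    rb = int(np.floor(r1))
    ca = int(np.ceil(c0))
    cb = int(np.floor(c1))
    mask[ra:rb + 1, ca:cb + 1] = True
    return mask
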