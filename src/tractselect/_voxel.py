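"""Exact polyline-to-voxel traversal (Amanatides-Woo grid marching).

Works in continuous voxel coordinates where voxel ``i`` owns the half-open
cell ``[i - 0.5, i + 0.5)`` on each axis; a point's cell is
``floor(v + 0.5)``.  The kernel emits one *entry event* per cell entered, in
traversal order, as linear indices into the grid; cells outside the grid are
dropped.  Uniqueness (first-visit order) is applied by the callers.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["polyline_entry_events", "unique_in_order"]


@njit(cache=True)
def _entry_events(pts, nx, ny, nz, out):
    """Write linear cell indices of entry events for a voxel-space polyline.

    Returns the number of events written.  ``out`` must be large enough
    (callers size it from the per-axis spans).
    """
    n_pts = pts.shape[0]
    n_out = 0
    # cell of the first point
    cx = int(np.floor(pts[0, 0] + 0.5))
    cy = int(np.floor(pts[0, 1] + 0.5))
    cz = int(np.floor(pts[0, 2] + 0.5))
    if 0 <= cx < nx and 0 <= cy < ny and 0 <= cz < nz:
        out[n_out] = (cx * ny + cy) * nz + cz
        n_out += 1
    for k in range(n_pts - 1):
        px, py, pz = pts[k, 0], pts[k, 1], pts[k, 2]
        qx, qy, qz = pts[k + 1, 0], pts[k + 1, 1], pts[k + 1, 2]
        dx, dy, dz = qx - px, qy - py, qz - pz
        if dx == 0.0 and dy == 0.0 and dz == 0.0:
            continue  # degenerate zero-length segment
        ix = int(np.floor(px + 0.5))
        iy = int(np.floor(py + 0.5))
        iz = int(np.floor(pz + 0.5))
        fx = int(np.floor(qx + 0.5))
        fy = int(np.floor(qy + 0.5))
        fz = int(np.floor(qz + 0.5))
        # step direction and parametric distance to the next cell boundary
        if dx > 0.0:
            sx = 1
            tmx = ((ix + 0.5) - px) / dx
            tdx = 1.0 / dx
        elif dx < 0.0:
            sx = -1
            tmx = ((ix - 0.5) - px) / dx
            tdx = -1.0 / dx
        else:
            sx = 0
            tmx = np.inf
            tdx = np.inf
        if dy > 0.0:
            sy = 1
            tmy = ((iy + 0.5) - py) / dy
            tdy = 1.0 / dy
        elif dy < 0.0:
            sy = -1
            tmy = ((iy - 0.5) - py) / dy
            tdy = -1.0 / dy
        else:
            sy = 0
            tmy = np.inf
            tdy = np.inf
        if dz > 0.0:
            sz = 1
            tmz = ((iz + 0.5) - pz) / dz
            tdz = 1.0 / dz
        elif dz < 0.0:
            sz = -1
            tmz = ((iz - 0.5) - pz) / dz
            tdz = -1.0 / dz
        else:
            sz = 0
            tmz = np.inf
            tdz = np.inf
        # march until the end cell of this segment is reached
        guard = 3 * (abs(fx - ix) + abs(fy - iy) + abs(fz - iz)) + 6
        while (ix != fx or iy != fy or iz != fz) and guard > 0:
            guard -= 1
            if tmx <= tmy and tmx <= tmz:
                if tmx > 1.0:
                    break
                ix += sx
                tmx += tdx
            elif tmy <= tmz:
                if tmy > 1.0:
                    break
                iy += sy
                tmy += tdy
            else:
                if tmz > 1.0:
                    break
                iz += sz
                tmz += tdz
            if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
                lin = (ix * ny + iy) * nz + iz
                if n_out == 0 or out[n_out - 1] != lin:
                    out[n_out] = lin
                    n_out += 1
    return n_out


def polyline_entry_events(points_vox: np.ndarray, shape) -> np.ndarray:
    """Linear indices of cells entered by a polyline, in traversal order.

    ``points_vox`` is (n, 3) in continuous voxel coordinates.  Consecutive
    duplicate cells are merged; a cell re-entered after leaving appears again
    (one event per entry).  Cells outside ``shape`` are omitted.
    """
    pts = np.ascontiguousarray(points_vox, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    if pts.shape[0] == 0:
        return np.empty(0, dtype=np.int64)
    nx, ny, nz = (int(s) for s in shape)
    spans = np.abs(np.diff(pts, axis=0)).sum() if pts.shape[0] > 1 else 0.0
    cap = int(spans) + 4 * pts.shape[0] + 8
    out = np.empty(cap, dtype=np.int64)
    n = _entry_events(pts, nx, ny, nz, out)
    return out[:n].copy()


def unique_in_order(events: np.ndarray) -> np.ndarray:
    """First occurrence of each value, preserving first-visit order."""
    if events.size == 0:
        return events
    _, first = np.unique(events, return_index=True)
    return events[np.sort(first)]
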