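"""Streamline-voxel geometry: voxelization, track density, ROIs, masks.

Voxelization is exact grid marching (Amanatides-Woo) in continuous voxel
space, so a streamline's voxel set is the true set of half-open cells its
polyline intersects — not a point-sampling approximation.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from ._voxel import polyline_entry_events, unique_in_order
from .core import BinaryMask, Grid, Tractogram, TrackDensityImage

logger = logging.getLogger(__name__)

__all__ = [
    "voxels_of_streamline",
    "track_density",
    "streamline_hits",
    "sphere_roi",
    "mask_from_tdi",
    "endpoint_voxels",
]


def voxels_of_streamline(streamline: np.ndarray, grid: Grid) -> np.ndarray:
    """Voxel cells intersected by a world-mm polyline, first-visit order.

    Returns an (m, 3) integer array.  Points outside the grid contribute
    nothing; zero-length segments are skipped.
    """
    pts_vox = grid.world_to_voxel(streamline)
    events = polyline_entry_events(pts_vox, grid.shape)
    lin = unique_in_order(events)
    return np.stack(np.unravel_index(lin, grid.shape), axis=1) if lin.size else np.empty((0, 3), dtype=np.int64)


def endpoint_voxels(streamline: np.ndarray, grid: Grid) -> np.ndarray:
    """Voxel cells of the first and last point (may lie outside the grid)."""
    ends = np.asarray(streamline)[[0, -1]]
    v = grid.world_to_voxel(ends)
    return np.floor(v + 0.5).astype(np.int64)


def track_density(
    t: Tractogram, grid: Grid, counting: str = "unique_streamline"
) -> TrackDensityImage:
    """Count streamline visits per voxel.

    ``unique_streamline`` (default) increments a voxel at most once per
    streamline — "number of streamlines" counts streamlines, not passes.
    ``per_visit`` counts every entry into a voxel.
    """
    if counting not in ("unique_streamline", "per_visit"):
        raise ValueError(f"unknown counting mode {counting!r}")
    if len(t) == 0:
        raise ValueError("track_density requires a non-empty tractogram")
    counts_flat = np.zeros(int(np.prod(grid.shape)), dtype=np.int64)
    for s in t.streamlines:
        events = polyline_entry_events(grid.world_to_voxel(s), grid.shape)
        if counting == "unique_streamline":
            events = unique_in_order(events)
        np.add.at(counts_flat, events, 1)
    return TrackDensityImage(grid, counts_flat.reshape(grid.shape), len(t))


def streamline_hits(streamline: np.ndarray, roi: BinaryMask, mode: str = "traverse") -> bool:
    """Does a streamline hit an ROI?

    ``traverse``: any intersected voxel lies in the ROI.
    ``end_in``: the voxel of the first or last point lies in the ROI.
    """
    if mode == "traverse":
        vox = voxels_of_streamline(streamline, roi.grid)
        if vox.size == 0:
            return False
        return bool(roi.data[vox[:, 0], vox[:, 1], vox[:, 2]].any())
    if mode == "end_in":
        ends = endpoint_voxels(streamline, roi.grid)
        inside = roi.grid.contains_voxel(ends)
        ends = ends[inside]
        if ends.size == 0:
            return False
        return bool(roi.data[ends[:, 0], ends[:, 1], ends[:, 2]].any())
    raise ValueError(f"unknown hit mode {mode!r}")


def sphere_roi(center: np.ndarray, radius_mm: float, grid: Grid) -> BinaryMask:
    """Binary mask of voxels whose *centre* lies within ``radius_mm`` of
    ``center`` (world mm), clipped to the grid."""
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    center = np.asarray(center, dtype=float).reshape(3)
    # bounding box in voxel space to avoid scanning the whole grid
    c_vox = grid.world_to_voxel(center)[0]
    margin = radius_mm / grid.voxel_sizes.min() + 1.0
    lo = np.maximum(np.floor(c_vox - margin).astype(int), 0)
    hi = np.minimum(np.ceil(c_vox + margin).astype(int) + 1, np.asarray(grid.shape))
    data = np.zeros(grid.shape, dtype=bool)
    if np.any(lo >= hi):
        logger.warning("sphere ROI at %s entirely outside grid", center)
        return BinaryMask(grid, data)
    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    centres = grid.voxel_to_world(idx)
    inside = np.linalg.norm(centres - center, axis=1) <= radius_mm
    sel = idx[inside]
    data[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    if not data.any():
        logger.warning("sphere ROI at %s contains no voxel centre", center)
    return BinaryMask(grid, data)


def mask_from_tdi(tdi: TrackDensityImage, percentile: float = 5.0) -> BinaryMask:
    """Threshold a track-density image into a binary bundle mask.

    The threshold tau is the nearest-rank ``percentile`` of the distribution
    of *non-zero* voxel counts (tau = ceil(p/100 * n)-th smallest, floor at
    the 1st), and the mask keeps voxels with count >= tau.  Percentile 5
    therefore retains at least 95% of the bundle's non-zero voxels, trimming
    only the lowest-density fringe.
    """
    if not (0.0 <= percentile <= 100.0):
        raise ValueError("percentile must be in [0, 100]")
    nonzero = np.sort(tdi.counts[tdi.counts > 0])
    if nonzero.size == 0:
        raise ValueError("all-zero track-density image has no mask")
    k = max(1, math.ceil(percentile / 100.0 * nonzero.size))
    tau = int(nonzero[k - 1])
    mask = tdi.counts >= tau
    retained = mask.sum() / nonzero.size
    logger.info(
        "TDI mask: percentile=%g tau=%d retained %.1f%% of %d nonzero voxels",
        percentile, tau, 100 * retained, nonzero.size,
    )
    return BinaryMask(tdi.grid, mask)
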