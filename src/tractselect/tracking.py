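"""Probabilistic streamline propagation with tissue priors.

This is a deliberately simple, fully testable tracker: a first-order
(Euler) stochastic propagator over a single-direction orientation field,
with von Mises-Fisher angular jitter standing in for the angular sampling a
full fODF tracker performs.  The anatomical priors are the standard
tissue-constrained ones: streamlines are seeded at the white-matter /
grey-matter interface, must terminate in grey matter at both ends, and are
rejected outright if they enter CSF or leave the tissue model.  Tissue maps
are hard (disjoint) segmentations, which makes every prior assertable
exactly on phantoms.

Direction lookup is nearest-voxel; the field is antipodally symmetric and
each lookup is sign-aligned with the previous step.  Growth is
bidirectional from the seed and the two halves are merged sharing the seed
point, so "both ends terminate in grey matter" is well defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._voxel import polyline_entry_events, unique_in_order
from .core import BinaryMask, Grid

__all__ = [
    "OrientationField",
    "TissueMaps",
    "TrackingParams",
    "SeedingError",
    "Propagation",
    "interface_seeds",
    "interface_mask",
    "propagate",
    "TISSUE_WM",
    "TISSUE_GM",
    "TISSUE_CSF",
]

TISSUE_BG, TISSUE_WM, TISSUE_GM, TISSUE_CSF = 0, 1, 2, 3

_SIX_CONN = ndimage.generate_binary_structure(3, 1)


class SeedingError(RuntimeError):
    """No admissible seed voxels."""


@dataclass
class OrientationField:
    """One unit direction per voxel (antipodally symmetric) plus validity."""

    grid: Grid
    directions: np.ndarray  # (nx, ny, nz, 3)
    validity: np.ndarray  # (nx, ny, nz) bool

    def __post_init__(self) -> None:
        dirs = np.asarray(self.directions, dtype=float)
        valid = np.asarray(self.validity, dtype=bool)
        if dirs.shape != self.grid.shape + (3,):
            raise ValueError("directions must be shape grid.shape + (3,)")
        if valid.shape != self.grid.shape:
            raise ValueError("validity must match grid shape")
        norms = np.linalg.norm(dirs[valid], axis=-1)
        if valid.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("valid directions must be unit vectors (|norm-1| <= 1e-6)")
        self.directions = dirs
        self.validity = valid

    @classmethod
    def from_vectors(cls, grid: Grid, vectors: np.ndarray) -> "OrientationField":
        """Build a field from raw vectors; zero vectors mark invalid voxels."""
        vectors = np.asarray(vectors, dtype=float)
        norms = np.linalg.norm(vectors, axis=-1)
        valid = norms > 1e-12
        dirs = np.zeros_like(vectors)
        dirs[valid] = vectors[valid] / norms[valid][..., None]
        return cls(grid, dirs, valid)


@dataclass
class TissueMaps:
    """Hard (mutually disjoint) WM / GM / CSF segmentation."""

    grid: Grid
    wm: BinaryMask
    gm: BinaryMask
    csf: BinaryMask

    def __post_init__(self) -> None:
        for name, m in (("wm", self.wm), ("gm", self.gm), ("csf", self.csf)):
            self.grid.require_same(m.grid, f"tissue map {name}")
        if (self.wm.data & self.gm.data).any() or (self.wm.data & self.csf.data).any() or (self.gm.data & self.csf.data).any():
            raise ValueError("tissue classes must be disjoint")

    def label_data(self) -> np.ndarray:
        """Single labelled array: 0 background, 1 WM, 2 GM, 3 CSF."""
        lab = np.zeros(self.grid.shape, dtype=np.uint8)
        lab[self.wm.data] = TISSUE_WM
        lab[self.gm.data] = TISSUE_GM
        lab[self.csf.data] = TISSUE_CSF
        return lab


@dataclass
class TrackingParams:
    """Propagation parameters.

    step_mm defaults to half the smallest voxel size of the grid in use;
    dispersion_kappa is the von Mises-Fisher concentration of the per-step
    angular jitter (math.inf = deterministic); max_angle_deg caps per-step
    curvature.
    """

    step_mm: float | None = None
    max_angle_deg: float = 45.0
    dispersion_kappa: float = math.inf
    min_length_mm: float = 10.0
    max_length_mm: float = 250.0
    rng_seed: int = 0

    def resolved_step(self, grid: Grid) -> float:
        step = self.step_mm if self.step_mm is not None else 0.5 * float(grid.voxel_sizes.min())
        if not (0 < step <= grid.voxel_sizes.min() + 1e-12):
            raise ValueError("step_mm must be in (0, min voxel size]")
        return step

    def __post_init__(self) -> None:
        if not (0.0 < self.max_angle_deg < 90.0):
            raise ValueError("max_angle_deg must be in (0, 90)")
        if self.dispersion_kappa <= 0:
            raise ValueError("dispersion_kappa must be positive (math.inf allowed)")
        if not (0 < self.min_length_mm < self.max_length_mm):
            raise ValueError("need 0 < min_length_mm < max_length_mm")


@dataclass
class Propagation:
    """One propagation attempt: polyline, per-end termination codes, verdict."""

    points: np.ndarray
    code_backward: str
    code_forward: str
    length_mm: float
    accepted: bool
    reject_reason: str | None = None


def interface_mask(tissues: TissueMaps, restrict: BinaryMask | None = None) -> BinaryMask:
    """WM voxels 6-adjacent to a GM voxel (optionally intersected with
    ``restrict``) — the seeding surface."""
    gm_dilated = ndimage.binary_dilation(tissues.gm.data, structure=_SIX_CONN)
    data = tissues.wm.data & gm_dilated
    if restrict is not None:
        tissues.grid.require_same(restrict.grid, "restrict mask")
        data = data & restrict.data
    return BinaryMask(tissues.grid, data)


def interface_seeds(
    tissues: TissueMaps,
    restrict: BinaryMask | None,
    n: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` world-mm seed points uniformly from the WM/GM interface.

    A voxel is drawn uniformly (with replacement) from the interface set,
    then the point is jittered uniformly within the voxel cell.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    iface = interface_mask(tissues, restrict)
    idx = np.argwhere(iface.data)
    if idx.shape[0] == 0:
        raise SeedingError("WM/GM interface (after restriction) is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = idx[rng.integers(0, idx.shape[0], size=n)]
    jitter = rng.uniform(-0.5, 0.5, size=(n, 3))
    return tissues.grid.voxel_to_world(chosen + jitter)


def _sample_vmf(mu, kappa: float, rng: np.random.Generator):
    """One draw from a von Mises-Fisher on S^2 with mean direction mu."""
    if math.isinf(kappa):
        return mu
    u = rng.random()
    # w = cos(angle to mu); stable form of the inverse-CDF sampler
    if kappa > 700.0:
        w = 1.0 + math.log(max(u, 1e-300)) / kappa
    else:
        w = 1.0 + math.log(u + (1.0 - u) * math.exp(-2.0 * kappa)) / kappa
    w = max(-1.0, min(1.0, w))
    phi = 2.0 * math.pi * rng.random()
    # orthonormal basis around mu
    mx, my, mz = mu
    if abs(mx) < 0.9:
        ax, ay, az = 1.0, 0.0, 0.0
    else:
        ax, ay, az = 0.0, 1.0, 0.0
    e1x = ay * mz - az * my
    e1y = az * mx - ax * mz
    e1z = ax * my - ay * mx
    n1 = math.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
    e1x, e1y, e1z = e1x / n1, e1y / n1, e1z / n1
    e2x = my * e1z - mz * e1y
    e2y = mz * e1x - mx * e1z
    e2z = mx * e1y - my * e1x
    s = math.sqrt(max(0.0, 1.0 - w * w))
    cp, sp = math.cos(phi), math.sin(phi)
    return (
        w * mx + s * (cp * e1x + sp * e2x),
        w * my + s * (cp * e1y + sp * e2y),
        w * mz + s * (cp * e1z + sp * e2z),
    )


def _march(start, first_dir, ctx, rng):
    """Grow one half-streamline; returns (points list, termination code)."""
    (inv, dirs, valid, tissue, shape, step, cos_max, kappa, max_len) = ctx
    nx, ny, nz = shape
    px, py, pz = start
    dx, dy, dz = first_dir
    pts: list[tuple[float, float, float]] = []
    length = 0.0
    while True:
        vx = inv[0] * px + inv[1] * py + inv[2] * pz + inv[3]
        vy = inv[4] * px + inv[5] * py + inv[6] * pz + inv[7]
        vz = inv[8] * px + inv[9] * py + inv[10] * pz + inv[11]
        ix, iy, iz = int(math.floor(vx + 0.5)), int(math.floor(vy + 0.5)), int(math.floor(vz + 0.5))
        if not (0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz):
            return pts, "exits_volume"
        if not valid[ix, iy, iz]:
            return pts, "no_valid_direction"
        mx = float(dirs[ix, iy, iz, 0])
        my = float(dirs[ix, iy, iz, 1])
        mz = float(dirs[ix, iy, iz, 2])
        if mx * dx + my * dy + mz * dz < 0.0:  # antipodal sign alignment
            mx, my, mz = -mx, -my, -mz
        new_dir = None
        for _ in range(5):
            cand = _sample_vmf((mx, my, mz), kappa, rng)
            if cand[0] * dx + cand[1] * dy + cand[2] * dz >= cos_max:
                new_dir = cand
                break
        if new_dir is None:
            return pts, "no_valid_direction"
        dx, dy, dz = new_dir
        px, py, pz = px + step * dx, py + step * dy, pz + step * dz
        length += step
        if length > max_len:
            return pts, "max_length"
        wx = inv[0] * px + inv[1] * py + inv[2] * pz + inv[3]
        wy = inv[4] * px + inv[5] * py + inv[6] * pz + inv[7]
        wz = inv[8] * px + inv[9] * py + inv[10] * pz + inv[11]
        jx, jy, jz = int(math.floor(wx + 0.5)), int(math.floor(wy + 0.5)), int(math.floor(wz + 0.5))
        if not (0 <= jx < nx and 0 <= jy < ny and 0 <= jz < nz):
            return pts, "exits_volume"
        t = tissue[jx, jy, jz]
        pts.append((px, py, pz))
        if t == TISSUE_GM:
            return pts, "enters_gm"
        if t == TISSUE_CSF:
            return pts, "enters_csf"
        if t == TISSUE_BG:
            # left the tissue model: outside the (synthetic) head
            return pts, "exits_volume"


def _make_context(field: OrientationField, tissues: TissueMaps, params: TrackingParams):
    field.grid.require_same(tissues.grid, "field and tissue maps")
    inv = field.grid.inverse_affine
    inv_flat = (
        inv[0, 0], inv[0, 1], inv[0, 2], inv[0, 3],
        inv[1, 0], inv[1, 1], inv[1, 2], inv[1, 3],
        inv[2, 0], inv[2, 1], inv[2, 2], inv[2, 3],
    )
    step = params.resolved_step(field.grid)
    return (
        inv_flat,
        field.directions,
        field.validity,
        tissues.label_data(),
        field.grid.shape,
        step,
        math.cos(math.radians(params.max_angle_deg)),
        params.dispersion_kappa,
        params.max_length_mm,
    )


def propagate(
    start: np.ndarray,
    field: OrientationField,
    tissues: TissueMaps,
    params: TrackingParams,
    rng: np.random.Generator | None = None,
    _ctx=None,
) -> Propagation:
    """Grow one bidirectional streamline from a world-mm seed point.

    Acceptance requires both ends to terminate in grey matter, total length
    within [min_length_mm, max_length_mm], and — checked exactly on the
    final polyline by grid marching — no intersected voxel in CSF.
    """
    ctx = _ctx if _ctx is not None else _make_context(field, tissues, params)
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    start = np.asarray(start, dtype=float).reshape(3)
    v = field.grid.world_to_voxel(start)[0]
    i = np.floor(v + 0.5).astype(int)
    if not field.grid.contains_voxel(i[None, :])[0]:
        raise ValueError("seed point lies outside the grid")
    if not field.validity[i[0], i[1], i[2]]:
        return Propagation(start[None, :].repeat(2, axis=0), "no_valid_direction",
                           "no_valid_direction", 0.0, False, "no_valid_direction")
    d0 = field.directions[i[0], i[1], i[2]]
    s = tuple(float(x) for x in start)
    fwd_pts, fwd_code = _march(s, (float(d0[0]), float(d0[1]), float(d0[2])), ctx, rng)
    bwd_pts, bwd_code = _march(s, (-float(d0[0]), -float(d0[1]), -float(d0[2])), ctx, rng)
    pts = np.array(list(reversed(bwd_pts)) + [s] + fwd_pts, dtype=float)
    if pts.shape[0] < 2:
        return Propagation(np.vstack([pts, pts]) if pts.size else start[None, :].repeat(2, 0),
                           bwd_code, fwd_code, 0.0, False, "too_short")
    length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    reason = None
    if fwd_code != "enters_gm" or bwd_code != "enters_gm":
        reason = fwd_code if fwd_code != "enters_gm" else bwd_code
    elif not (params.min_length_mm <= length <= params.max_length_mm):
        reason = "length_out_of_range"
    else:
        # exact tissue-prior check on the whole polyline
        events = unique_in_order(
            polyline_entry_events(field.grid.world_to_voxel(pts), field.grid.shape)
        )
        if events.size and tissues.csf.data.ravel()[events].any():
            reason = "enters_csf"
    return Propagation(pts, bwd_code, fwd_code, length, reason is None, reason)


def make_propagation_context(field, tissues, params):
    """Precompute lookup arrays shared across many propagate() calls."""
    return _make_context(field, tissues, params)
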