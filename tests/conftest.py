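import numpy as np
import pytest

from tractselect.core import Grid
from tractselect.phantom import build_canonical


@pytest.fixture(scope="session")
def unit_grid():
    """16^3 grid with 1 mm isotropic voxels, identity affine."""
    return Grid((16, 16, 16), np.eye(4))


@pytest.fixture(scope="session")
def iso2_grid():
    """20^3 grid at 2 mm isotropic."""
    return Grid((20, 20, 20), np.diag([2.0, 2.0, 2.0, 1.0]))


@pytest.fixture(scope="session")
def straight_phantom():
    return build_canonical("straight")


@pytest.fixture(scope="session")
def arc_phantom():
    return build_canonical("arc")


@pytest.fixture(scope="session")
def crossing_phantom():
    return build_canonical("crossing")


@pytest.fixture(scope="session")
def csf_trap_phantom():
    return build_canonical("csf_trap")


@pytest.fixture(scope="session")
def parallel_phantom():
    return build_canonical("parallel")


def resample_oracle_cells(streamline, grid, step_vox=0.01):
    """Voxel cells found by resampling the polyline at ``step_vox`` voxel
    steps and rounding — the point-sampling reference voxelizer."""
    pts = grid.world_to_voxel(streamline)
    cells = set()
    shape = np.asarray(grid.shape)
    for a, b in zip(pts[:-1], pts[1:]):
        seg = np.linalg.norm(b - a)
        n = max(2, int(np.ceil(seg / step_vox)) + 1)
        t = np.linspace(0.0, 1.0, n)[:, None]
        samples = a + t * (b - a)
        v = np.floor(samples + 0.5).astype(int)
        ok = np.all((v >= 0) & (v < shape), axis=1)
        cells.update(map(tuple, v[ok]))
    return cells


def boxclip_oracle_cells(streamline, grid):
    """Exact voxelization oracle: slab-clip every segment against every
    candidate cell box (half-open cells [i-0.5, i+0.5)).  Independent of the
    grid-marching implementation."""
    pts = grid.world_to_voxel(streamline)
    shape = np.asarray(grid.shape)
    cells = set()
    for a, b in zip(pts[:-1], pts[1:]):
        d = b - a
        lo = np.floor(np.minimum(a, b) + 0.5).astype(int)
        hi = np.floor(np.maximum(a, b) + 0.5).astype(int)
        ii, jj, kk = np.meshgrid(
            np.arange(lo[0], hi[0] + 1), np.arange(lo[1], hi[1] + 1),
            np.arange(lo[2], hi[2] + 1), indexing="ij",
        )
        cand = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1).astype(float)
        tmin = np.zeros(cand.shape[0])
        tmax = np.ones(cand.shape[0])
        ok = np.ones(cand.shape[0], dtype=bool)
        for ax in range(3):
            b0 = cand[:, ax] - 0.5
            b1 = cand[:, ax] + 0.5
            if d[ax] == 0.0:
                ok &= (b0 <= a[ax]) & (a[ax] < b1)
            else:
                t0 = (b0 - a[ax]) / d[ax]
                t1 = (b1 - a[ax]) / d[ax]
                lo_t, hi_t = np.minimum(t0, t1), np.maximum(t0, t1)
                tmin = np.maximum(tmin, lo_t)
                tmax = np.minimum(tmax, hi_t)
        ok &= tmin < tmax
        sel = cand[ok].astype(int)
        inb = np.all((sel >= 0) & (sel < shape), axis=1)
        cells.update(map(tuple, sel[inb]))
    return cells


def random_streamlines(rng, n, n_points=50, lo=2.0, hi=30.0, step_scale=0.5):
    """Smooth-ish random polylines in world mm inside [lo, hi]^3."""
    out = []
    for _ in range(n):
        start = rng.uniform(lo, hi, 3)
        steps = rng.normal(scale=step_scale, size=(n_points - 1, 3))
        out.append(np.cumsum(np.vstack([start, steps]), axis=0))
    return out
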