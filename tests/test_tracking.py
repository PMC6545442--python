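import math

import numpy as np
import pytest

from tractselect.core import BinaryMask, Grid
from tractselect.geometry import voxels_of_streamline
from tractselect.phantom import build_phantom, canonical_phantoms
from tractselect.tracking import (
    OrientationField,
    SeedingError,
    TissueMaps,
    TrackingParams,
    _sample_vmf,
    interface_mask,
    interface_seeds,
    propagate,
)


@pytest.fixture(scope="module")
def slab_world():
    """WM slab along x capped by GM plates at both ends, on a 1 mm grid."""
    grid = Grid((40, 11, 11), np.eye(4))
    wm = np.zeros(grid.shape, bool)
    gm = np.zeros(grid.shape, bool)
    wm[5:35, 3:8, 3:8] = True
    gm[2:5, 3:8, 3:8] = True
    gm[35:38, 3:8, 3:8] = True
    csf = np.zeros(grid.shape, bool)
    tissues = TissueMaps(grid, BinaryMask(grid, wm), BinaryMask(grid, gm),
                         BinaryMask(grid, csf))
    vectors = np.zeros(grid.shape + (3,))
    vectors[wm] = [1.0, 0.0, 0.0]
    field = OrientationField.from_vectors(grid, vectors)
    return grid, tissues, field


class TestInterfaceSeeds:
    def test_seeds_lie_in_wm_voxels_adjacent_to_gm(self, slab_world):
        grid, tissues, _ = slab_world
        pts = interface_seeds(tissues, None, 500, seed=1)
        vox = np.floor(grid.world_to_voxel(pts) + 0.5).astype(int)
        iface = interface_mask(tissues)
        assert tissues.wm.data[vox[:, 0], vox[:, 1], vox[:, 2]].all()
        assert iface.data[vox[:, 0], vox[:, 1], vox[:, 2]].all()

    def test_deterministic_and_seed_sensitive(self, slab_world):
        _, tissues, _ = slab_world
        a = interface_seeds(tissues, None, 200, seed=3)
        b = interface_seeds(tissues, None, 200, seed=3)
        c = interface_seeds(tissues, None, 200, seed=4)
        assert np.array_equal(a, b)
        assert not np.allclose(a, c)

    def test_disjoint_restriction_raises(self, slab_world):
        grid, tissues, _ = slab_world
        restrict = BinaryMask(grid, np.zeros(grid.shape, bool))
        with pytest.raises(SeedingError):
            interface_seeds(tissues, restrict, 10, seed=0)


class TestVonMisesFisher:
    def test_infinite_concentration_is_mean_direction(self):
        rng = np.random.default_rng(0)
        mu = (0.0, 0.0, 1.0)
        assert _sample_vmf(mu, math.inf, rng) == mu

    def test_samples_are_unit_and_concentrate(self):
        rng = np.random.default_rng(1)
        mu = np.array([1.0, 0.0, 0.0])
        draws = np.array([_sample_vmf(tuple(mu), 500.0, rng) for _ in range(2000)])
        assert np.allclose(np.linalg.norm(draws, axis=1), 1.0, atol=1e-9)
        mean_cos = draws @ mu
        # E[cos(theta)] for vMF(kappa) ~ 1 - 1/kappa
        assert abs(mean_cos.mean() - (1 - 1 / 500.0)) < 5e-4


class TestPropagate:
    def test_deterministic_limit_matches_euler_oracle(self, slab_world):
        grid, tissues, field = slab_world
        params = TrackingParams(step_mm=0.5, dispersion_kappa=math.inf,
                                min_length_mm=5.0)
        start = np.array([20.3, 5.1, 5.2])
        prop = propagate(start, field, tissues, params)
        assert prop.accepted

        # independent noiseless Euler integrator along the constant field
        def euler(sign):
            pts = []
            pos = start.copy()
            while True:
                pos = pos + sign * 0.5 * np.array([1.0, 0.0, 0.0])
                vox = np.floor(pos + 0.5).astype(int)
                pts.append(pos.copy())
                if tissues.gm.data[tuple(vox)]:
                    return pts

        expected = np.array(euler(-1)[::-1] + [start] + euler(+1))
        assert prop.points.shape == expected.shape
        assert np.allclose(prop.points, expected, atol=1e-6)

    def test_both_endpoints_in_gm_and_no_csf(self, slab_world):
        grid, tissues, field = slab_world
        params = TrackingParams(step_mm=0.5, dispersion_kappa=2000.0,
                                min_length_mm=5.0)
        rng = np.random.default_rng(9)
        n_acc = 0
        for p in interface_seeds(tissues, None, 200, rng):
            prop = propagate(p, field, tissues, params, rng=rng)
            if not prop.accepted:
                continue
            n_acc += 1
            ends = np.floor(prop.points[[0, -1]] + 0.5).astype(int)
            assert tissues.gm.data[ends[:, 0], ends[:, 1], ends[:, 2]].all()
            vox = voxels_of_streamline(prop.points, grid)
            assert not tissues.csf.data[vox[:, 0], vox[:, 1], vox[:, 2]].any()
        assert n_acc > 100

    def test_csf_corridor_rejects_streamline(self):
        """A CSF wall across the slab must terminate and reject tracks."""
        grid = Grid((40, 11, 11), np.eye(4))
        wm = np.zeros(grid.shape, bool)
        gm = np.zeros(grid.shape, bool)
        csf = np.zeros(grid.shape, bool)
        wm[5:35, 3:8, 3:8] = True
        gm[2:5, 3:8, 3:8] = True
        gm[35:38, 3:8, 3:8] = True
        csf[20:22, :, :] = True
        wm &= ~csf
        tissues = TissueMaps(grid, BinaryMask(grid, wm), BinaryMask(grid, gm),
                             BinaryMask(grid, csf))
        vectors = np.zeros(grid.shape + (3,))
        vectors[wm] = [1.0, 0.0, 0.0]
        field = OrientationField.from_vectors(grid, vectors)
        params = TrackingParams(step_mm=0.5, dispersion_kappa=math.inf,
                                min_length_mm=5.0)
        prop = propagate(np.array([10.2, 5.0, 5.0]), field, tissues, params)
        assert not prop.accepted
        assert "enters_csf" in (prop.code_forward, prop.code_backward)
        assert prop.reject_reason == "enters_csf"

    def test_gentle_bend_passes_tight_angle_cap(self):
        """On a 20 mm-radius bend with 1 mm steps the per-step turn is
        ~2.9 degrees, well under a 10-degree cap, so tracking succeeds."""
        grid = Grid((48, 48, 11), np.eye(4))
        centre = np.array([8.0, 8.0])
        wm = np.zeros(grid.shape, bool)
        gm = np.zeros(grid.shape, bool)
        vectors = np.zeros(grid.shape + (3,))
        for i in range(48):
            for j in range(48):
                rel = np.array([i, j], float) - centre
                r = np.linalg.norm(rel)
                ang = math.atan2(rel[1], rel[0])
                if abs(r - 20.0) <= 3.0 and -0.1 <= ang <= math.pi / 2 + 0.1:
                    sl = slice(3, 8)
                    if ang < 0.06:
                        gm[i, j, sl] = True
                    elif ang > math.pi / 2 - 0.06:
                        gm[i, j, sl] = True
                    else:
                        wm[i, j, sl] = True
                        tangent = np.array([-math.sin(ang), math.cos(ang), 0.0])
                        vectors[i, j, sl] = tangent
        tissues = TissueMaps(grid, BinaryMask(grid, wm), BinaryMask(grid, gm),
                             BinaryMask(grid, np.zeros(grid.shape, bool)))
        field = OrientationField.from_vectors(grid, vectors)
        params = TrackingParams(step_mm=1.0, max_angle_deg=10.0,
                                dispersion_kappa=math.inf, min_length_mm=5.0)
        start = np.array([8.0 + 20.0 * math.cos(0.8), 8.0 + 20.0 * math.sin(0.8), 5.0])
        prop = propagate(start, field, tissues, params)
        assert prop.accepted
        # per-step turning stays near the arc's analytic value
        d = np.diff(prop.points, axis=0)
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        angles = np.degrees(np.arccos(np.clip((d[:-1] * d[1:]).sum(axis=1), -1, 1)))
        assert angles.max() < 10.0

    def test_invalid_param_combinations_rejected(self):
        with pytest.raises(ValueError):
            TrackingParams(max_angle_deg=95.0)
        with pytest.raises(ValueError):
            TrackingParams(min_length_mm=100.0, max_length_mm=50.0)
        with pytest.raises(ValueError):
            TrackingParams(dispersion_kappa=0.0)


def test_act_priors_hold_on_csf_trap_phantom(csf_trap_phantom):
    """Dispersed tracking next to a CSF slab: accepted streamlines never
    intersect CSF and always terminate in GM at both ends."""
    vols = csf_trap_phantom
    params = TrackingParams(dispersion_kappa=800.0)
    rng = np.random.default_rng(2)
    grid = vols.tissues.grid
    n_acc = 0
    for p in interface_seeds(vols.tissues, None, 300, rng):
        prop = propagate(p, vols.field, vols.tissues, params, rng=rng)
        if not prop.accepted:
            continue
        n_acc += 1
        vox = voxels_of_streamline(prop.points, grid)
        assert not vols.tissues.csf.data[vox[:, 0], vox[:, 1], vox[:, 2]].any()
        ends = np.floor(grid.world_to_voxel(prop.points[[0, -1]]) + 0.5).astype(int)
        assert vols.tissues.gm.data[ends[:, 0], ends[:, 1], ends[:, 2]].all()
        assert params.min_length_mm <= prop.length_mm <= params.max_length_mm
    assert n_acc > 100
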