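"""Digital tractography phantoms.

Each phantom is a set of curved tube-shaped white-matter bundles embedded
in a tissue-class volume, with grey-matter end caps carrying parcellation
labels, an orientation field following the tube centrelines, optional CSF
regions, and exact ground-truth bundle membership.  This is the toolkit's
synthetic-data generator: every downstream module (tracking, rules,
metrics, ratings) is testable against these phantoms without any imaging
data.

Centrelines are uniform Catmull-Rom interpolations of the control points,
so tangents are analytic (no fitting).  A voxel belongs to a tube when its
centre lies within ``radius_mm`` of the sampled centreline (exact
point-to-segment distance).  Tube overlaps are broken by list order — the
first tube owns the voxel's direction — and recorded.  Grey-matter caps
are solid hemispheres just beyond each tube end, giving the WM/GM
interface that interface seeding requires.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core import BinaryMask, Grid, LabelVolume, Tractogram
from .rules_engine import RuleTable, TractRule
from .tracking import OrientationField, TissueMaps

__all__ = [
    "TubeSpec",
    "PhantomSpec",
    "PhantomVolumes",
    "PhantomConstructionError",
    "build_phantom",
    "canonical_phantoms",
    "canonical_rule_tables",
    "build_canonical",
    "activation_point",
    "reference_streamlines",
    "spec_to_json",
    "spec_from_json",
]

DEFAULT_SHAPE = (64, 64, 64)
DEFAULT_VOXEL_MM = 2.0  # isotropic phantom resolution
CAP_DEPTH_VOXELS = 2.0  # GM cap extent beyond the tube end, in voxels


class PhantomConstructionError(ValueError):
    """Phantom geometry does not fit the grid."""


@dataclass
class TubeSpec:
    name: str
    centerline: np.ndarray  # (k >= 2, 3) control points, world mm
    radius_mm: float
    cap_labels: tuple[str, str]

    def __post_init__(self) -> None:
        pts = np.asarray(self.centerline, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError(f"tube {self.name!r}: need >=2 control points")
        if self.radius_mm <= 0:
            raise ValueError(f"tube {self.name!r}: radius must be positive")
        self.centerline = pts
        self.cap_labels = (str(self.cap_labels[0]), str(self.cap_labels[1]))


@dataclass
class PhantomSpec:
    grid: Grid
    tubes: list[TubeSpec]
    csf_regions: list[dict] = field(default_factory=list)
    rng_seed: int = 0
    name: str = "phantom"

    def __post_init__(self) -> None:
        names = [t.name for t in self.tubes]
        if len(set(names)) != len(names):
            raise ValueError("tube names must be unique")


@dataclass
class PhantomVolumes:
    """Everything a phantom build yields."""

    spec: PhantomSpec
    field: OrientationField
    tissues: TissueMaps
    parcellation: LabelVolume
    ground_truth: dict[str, np.ndarray]  # tube name -> (m, 3) WM voxel indices
    overlap_voxels: np.ndarray  # (m, 3) voxels claimed by >1 tube


def _catmull_rom(control: np.ndarray, spacing_mm: float):
    """Sample a uniform Catmull-Rom curve; returns (points, unit tangents)."""
    control = np.asarray(control, dtype=float)
    if control.shape[0] == 2:
        a, b = control
        n = max(2, int(np.ceil(np.linalg.norm(b - a) / spacing_mm)) + 1)
        t = np.linspace(0.0, 1.0, n)[:, None]
        pts = a + t * (b - a)
        tan = np.tile((b - a) / np.linalg.norm(b - a), (n, 1))
        return pts, tan
    # reflected phantom endpoints give nonzero end tangents
    ext = np.vstack([2 * control[0] - control[1], control, 2 * control[-1] - control[-2]])
    pts_out, tan_out = [], []
    for i in range(1, ext.shape[0] - 2):
        p0, p1, p2, p3 = ext[i - 1], ext[i], ext[i + 1], ext[i + 2]
        seg_len = np.linalg.norm(p2 - p1)
        n = max(2, int(np.ceil(seg_len / spacing_mm)) + 1)
        last = i == ext.shape[0] - 3
        t = np.linspace(0.0, 1.0, n, endpoint=last)[:, None]
        t2, t3 = t * t, t * t * t
        # uniform Catmull-Rom basis
        pts = 0.5 * (
            (2 * p1)
            + (-p0 + p2) * t
            + (2 * p0 - 5 * p1 + 4 * p2 - p3) * t2
            + (-p0 + 3 * p1 - 3 * p2 + p3) * t3
        )
        der = 0.5 * (
            (-p0 + p2)
            + 2 * (2 * p0 - 5 * p1 + 4 * p2 - p3) * t
            + 3 * (-p0 + 3 * p1 - 3 * p2 + p3) * t2
        )
        pts_out.append(pts)
        tan_out.append(der)
    pts = np.vstack(pts_out)
    tan = np.vstack(tan_out)
    tan /= np.linalg.norm(tan, axis=1, keepdims=True)
    return pts, tan


def _voxel_centres_in_bbox(grid: Grid, lo_w, hi_w, margin_vox: float):
    """Integer voxel indices whose cells could intersect a world bbox."""
    corners = np.array(
        [[x, y, z] for x in (lo_w[0], hi_w[0]) for y in (lo_w[1], hi_w[1]) for z in (lo_w[2], hi_w[2])]
    )
    v = grid.world_to_voxel(corners)
    lo = np.maximum(np.floor(v.min(axis=0) - margin_vox).astype(int), 0)
    hi = np.minimum(np.ceil(v.max(axis=0) + margin_vox).astype(int) + 1, np.asarray(grid.shape))
    if np.any(lo >= hi):
        return np.empty((0, 3), dtype=np.int64)
    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    return np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)


def _dist_to_polyline(points_w: np.ndarray, poly: np.ndarray):
    """Exact distance from each point to a polyline; also nearest segment."""
    a = poly[:-1]
    d = poly[1:] - a
    seg_len2 = np.einsum("ij,ij->i", d, d)
    seg_len2[seg_len2 == 0] = 1e-30
    best = np.full(points_w.shape[0], np.inf)
    best_seg = np.zeros(points_w.shape[0], dtype=np.int64)
    # chunk over segments to bound memory
    chunk = max(1, int(2e6 // max(points_w.shape[0], 1)))
    for s0 in range(0, a.shape[0], chunk):
        s1 = min(s0 + chunk, a.shape[0])
        diff = points_w[:, None, :] - a[None, s0:s1, :]
        t = np.clip(np.einsum("psj,sj->ps", diff, d[s0:s1]) / seg_len2[s0:s1], 0.0, 1.0)
        proj = diff - t[..., None] * d[None, s0:s1, :]
        dist = np.sqrt(np.einsum("psj,psj->ps", proj, proj))
        idx = dist.argmin(axis=1)
        val = dist[np.arange(dist.shape[0]), idx]
        upd = val < best
        best[upd] = val[upd]
        best_seg[upd] = idx[upd] + s0
    return best, best_seg


def build_phantom(spec: PhantomSpec) -> PhantomVolumes:
    """Rasterize a phantom spec into field, tissues, parcellation and truth."""
    grid = spec.grid
    vox = grid.voxel_sizes
    vox_max = float(vox.max())
    spacing = 0.25 * float(vox.min())
    shape = grid.shape
    owner = np.full(shape, -1, dtype=np.int32)  # tube index owning the voxel
    vectors = np.zeros(shape + (3,), dtype=float)
    wm = np.zeros(shape, dtype=bool)
    gm = np.zeros(shape, dtype=bool)
    labels = np.zeros(shape, dtype=np.int32)
    names: dict[int, str] = {}
    next_label = 1
    ground_truth: dict[str, np.ndarray] = {}
    claimed_count = np.zeros(shape, dtype=np.int8)

    # world-space bounds of the half-open voxel box
    box_corners = grid.voxel_to_world(
        np.array([[x, y, z] for x in (-0.5, shape[0] - 0.5)
                  for y in (-0.5, shape[1] - 0.5) for z in (-0.5, shape[2] - 0.5)])
    )
    world_lo, world_hi = box_corners.min(axis=0), box_corners.max(axis=0)

    cap_geoms = []  # (tube_index, end_point, outward_normal, label_name)
    tube_samples = []
    for ti, tube in enumerate(spec.tubes):
        poly, tan = _catmull_rom(tube.centerline, spacing)
        tube_samples.append((poly, tan))
        margin = tube.radius_mm + (CAP_DEPTH_VOXELS + 1.0) * vox_max
        if np.any(poly - margin < world_lo) or np.any(poly + margin > world_hi):
            raise PhantomConstructionError(
                f"tube {tube.name!r} (radius + caps) exits the grid"
            )
        idx = _voxel_centres_in_bbox(grid, poly.min(axis=0) - tube.radius_mm,
                                     poly.max(axis=0) + tube.radius_mm, 1.0)
        centres = grid.voxel_to_world(idx)
        dist, seg = _dist_to_polyline(centres, poly)
        inside = dist <= tube.radius_mm
        tube_vox = idx[inside]
        ground_truth[tube.name] = tube_vox
        sel = tuple(tube_vox.T)
        claimed_count[sel] += 1
        fresh = owner[sel] < 0
        owner[sel] = np.where(fresh, ti, owner[sel])
        fresh_vox = tube_vox[fresh]
        seg_in = seg[inside][fresh]
        tangents = 0.5 * (tan[seg_in] + tan[np.minimum(seg_in + 1, tan.shape[0] - 1)])
        tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
        vectors[tuple(fresh_vox.T)] = tangents
        wm[sel] = True
        cap_geoms.append((ti, poly[0], -tan[0], tube.cap_labels[0]))
        cap_geoms.append((ti, poly[-1], tan[-1], tube.cap_labels[1]))

    # WM corridor parcellation labels (owned voxels only)
    for ti, tube in enumerate(spec.tubes):
        lab = next_label
        next_label += 1
        names[lab] = f"{tube.name}_wm"
        owned = ground_truth[tube.name][
            owner[tuple(ground_truth[tube.name].T)] == ti
        ]
        labels[tuple(owned.T)] = lab

    # grey-matter caps: solid hemisphere beyond the end plane
    cap_radius_by_tube = {ti: spec.tubes[ti].radius_mm for ti in range(len(spec.tubes))}
    for ti, end, normal, cap_name in cap_geoms:
        r = cap_radius_by_tube[ti] + CAP_DEPTH_VOXELS * vox_max
        idx = _voxel_centres_in_bbox(grid, end - r, end + r, 1.0)
        centres = grid.voxel_to_world(idx)
        rel = centres - end
        inside = (np.linalg.norm(rel, axis=1) <= r) & (rel @ normal > 0)
        cap_vox = idx[inside]
        sel = tuple(cap_vox.T)
        keep = ~wm[sel]
        cap_vox = cap_vox[keep]
        if cap_vox.shape[0] == 0:
            raise PhantomConstructionError(f"cap {cap_name!r} rasterized to no voxels")
        sel = tuple(cap_vox.T)
        gm[sel] = True
        if cap_name in names.values():
            lab = {v: k for k, v in names.items()}[cap_name]
        else:
            lab = next_label
            next_label += 1
            names[lab] = cap_name
        labels[sel] = lab

    csf = np.zeros(shape, dtype=bool)
    for region in spec.csf_regions:
        kind = region.get("kind", "box")
        if kind == "box":
            lo = grid.world_to_voxel(np.asarray(region["lo"], float))[0]
            hi = grid.world_to_voxel(np.asarray(region["hi"], float))[0]
            lo_i = np.maximum(np.floor(np.minimum(lo, hi) + 0.5).astype(int), 0)
            hi_i = np.minimum(np.floor(np.maximum(lo, hi) + 0.5).astype(int) + 1,
                              np.asarray(shape))
            csf[lo_i[0]:hi_i[0], lo_i[1]:hi_i[1], lo_i[2]:hi_i[2]] = True
        elif kind == "sphere":
            centre = np.asarray(region["center"], float)
            rr = float(region["radius_mm"])
            idx = _voxel_centres_in_bbox(grid, centre - rr, centre + rr, 1.0)
            centres = grid.voxel_to_world(idx)
            sel = idx[np.linalg.norm(centres - centre, axis=1) <= rr]
            csf[tuple(sel.T)] = True
        else:
            raise ValueError(f"unknown CSF region kind {kind!r}")
    csf &= ~(wm | gm)  # tubes and caps take precedence

    overlap = np.argwhere(claimed_count > 1)
    tissues = TissueMaps(
        grid,
        wm=BinaryMask(grid, wm),
        gm=BinaryMask(grid, gm),
        csf=BinaryMask(grid, csf),
    )
    field_ = OrientationField.from_vectors(grid, vectors)
    parcellation = LabelVolume(grid, labels, names)
    return PhantomVolumes(spec, field_, tissues, parcellation, ground_truth, overlap)


def _default_grid() -> Grid:
    aff = np.diag([DEFAULT_VOXEL_MM] * 3 + [1.0])
    return Grid(DEFAULT_SHAPE, aff)


def canonical_phantoms() -> dict[str, PhantomSpec]:
    """The shipped phantom suite.

    * ``straight`` — one straight tube: the sanity-check geometry.
    * ``arc``      — C-shaped bundle, the arcuate-like curved case.
    * ``crossing`` — two orthogonal tubes sharing a corridor.
    * ``csf_trap`` — straight tube with a CSF slab flanking its middle.
    * ``parallel`` — two disjoint parallel tubes, for overlap contrasts.
    """
    g = _default_grid()
    c = 63.0  # mid-plane world coordinate of the 64^3, 2 mm grid
    r = 4.0
    specs: dict[str, PhantomSpec] = {}

    straight = TubeSpec(
        "straight",
        np.array([[26.0, c, c], [100.0, c, c]]),
        r,
        ("straight_origin", "straight_target"),
    )
    specs["straight"] = PhantomSpec(g, [straight], name="straight")

    theta = np.linspace(-1.05, 1.05, 7)
    arc_pts = np.stack(
        [c - 38.0 * np.cos(theta) + 20.0, c + 38.0 * np.sin(theta), np.full_like(theta, c)],
        axis=1,
    )
    arc = TubeSpec("arc", arc_pts, r, ("arc_origin", "arc_target"))
    specs["arc"] = PhantomSpec(g, [arc], name="arc")

    tube_x = TubeSpec(
        "cross_x", np.array([[26.0, c, c], [100.0, c, c]]), r,
        ("cross_x_origin", "cross_x_target"),
    )
    tube_y = TubeSpec(
        "cross_y", np.array([[c, 26.0, c], [c, 100.0, c]]), r,
        ("cross_y_origin", "cross_y_target"),
    )
    specs["crossing"] = PhantomSpec(g, [tube_x, tube_y], name="crossing")

    trap_tube = TubeSpec(
        "trapped",
        np.array([[26.0, c, c], [100.0, c, c]]),
        r,
        ("trapped_origin", "trapped_target"),
    )
    csf_slab = {
        "kind": "box",
        "lo": [46.0, c - 10.0, c + r + 1.0],
        "hi": [80.0, c + 10.0, c + r + 9.0],
    }
    specs["csf_trap"] = PhantomSpec(g, [trap_tube], [csf_slab], name="csf_trap")

    par_a = TubeSpec(
        "par_a", np.array([[26.0, c - 16.0, c], [100.0, c - 16.0, c]]), r,
        ("par_a_origin", "par_a_target"),
    )
    par_b = TubeSpec(
        "par_b", np.array([[26.0, c + 16.0, c], [100.0, c + 16.0, c]]), r,
        ("par_b_origin", "par_b_target"),
    )
    specs["parallel"] = PhantomSpec(g, [par_a, par_b], name="parallel")
    return specs


def canonical_rule_tables() -> dict[str, RuleTable]:
    """Exemplar rule table for each canonical phantom."""
    tables: dict[str, RuleTable] = {}

    def rule(tract, seed, include, exclude=()):
        return TractRule(
            tract=tract,
            seed_regions=[seed],
            includes=[(include, "end_in")],
            excludes=list(exclude),
        )

    tables["straight"] = RuleTable([rule("straight", "straight_origin", "straight_target")])
    tables["arc"] = RuleTable([rule("arc", "arc_origin", "arc_target")])
    tables["crossing"] = RuleTable(
        [
            rule("cross_x", "cross_x_origin", "cross_x_target",
                 ("cross_y_origin", "cross_y_target")),
            rule("cross_y", "cross_y_origin", "cross_y_target",
                 ("cross_x_origin", "cross_x_target")),
        ]
    )
    tables["csf_trap"] = RuleTable([rule("trapped", "trapped_origin", "trapped_target")])
    tables["parallel"] = RuleTable(
        [
            rule("par_a", "par_a_origin", "par_a_target"),
            rule("par_b", "par_b_origin", "par_b_target"),
        ]
    )
    return tables


_canonical_cache: dict[str, PhantomVolumes] = {}


def build_canonical(name: str) -> PhantomVolumes:
    """Build (and memoize) one canonical phantom by name."""
    if name not in _canonical_cache:
        specs = canonical_phantoms()
        if name not in specs:
            raise KeyError(f"unknown canonical phantom {name!r}")
        _canonical_cache[name] = build_phantom(specs[name])
    return _canonical_cache[name]


def activation_point(
    spec: PhantomSpec,
    bundle: str,
    offset_mm: float = 0.0,
    end: str = "end",
    volumes: PhantomVolumes | None = None,
) -> np.ndarray:
    """Synthetic fMRI activation maximum near a bundle terminus.

    Returns the GM end-cap centroid displaced ``offset_mm`` along the
    outward cap normal.  ``end`` picks which terminus ("start"/"end").
    """
    tube = next((t for t in spec.tubes if t.name == bundle), None)
    if tube is None:
        raise KeyError(f"phantom has no bundle {bundle!r}")
    if end not in ("start", "end"):
        raise ValueError("end must be 'start' or 'end'")
    vols = volumes if volumes is not None else build_phantom(spec)
    cap_name = tube.cap_labels[0] if end == "start" else tube.cap_labels[1]
    cap = vols.parcellation.mask_of(cap_name)
    idx = np.argwhere(cap.data)
    centroid = spec.grid.voxel_to_world(idx).mean(axis=0)
    poly, tan = _catmull_rom(tube.centerline, 0.25 * float(spec.grid.voxel_sizes.min()))
    normal = -tan[0] if end == "start" else tan[-1]
    return centroid + offset_mm * np.asarray(normal)


def reference_streamlines(
    spec: PhantomSpec, n_per_tube: int = 50, seed: int = 0
):
    """Analytic ground-truth streamlines: each tube's centreline plus
    random parallel offsets inside the tube, labelled by generating tube.

    These are construction-time truth (no tracking involved), for testing
    selection rules against known membership.
    """
    rng = np.random.default_rng(seed)
    spacing = 0.5 * float(spec.grid.voxel_sizes.min())
    vox_max = float(spec.grid.voxel_sizes.max())
    streamlines, labels = [], []
    for tube in spec.tubes:
        poly, tan = _catmull_rom(tube.centerline, spacing)
        # extend into the GM caps so endpoints terminate there, as tracked
        # streamlines would; the lateral offset converges back to the axis
        # at the caps
        ext = tube.radius_mm + vox_max
        head = poly[0] - ext * tan[0]
        tail = poly[-1] + ext * tan[-1]
        for k in range(n_per_tube):
            if k == 0:
                off = np.zeros(3)
            else:
                # random offset perpendicular to the mean axis; capped at
                # half the radius so offset copies stay well inside the tube
                axis = tan.mean(axis=0)
                axis /= np.linalg.norm(axis)
                raw = rng.normal(size=3)
                raw -= raw @ axis * axis
                nrm = np.linalg.norm(raw)
                raw = raw / nrm if nrm > 1e-12 else np.array([0.0, 0.0, 1.0])
                off = raw * rng.uniform(0.0, 0.5 * tube.radius_mm)
            streamlines.append(np.vstack([head, poly + off, tail]))
            labels.append(tube.name)
    return Tractogram(streamlines, spec.grid, {"bundle": labels})


def spec_to_json(spec: PhantomSpec, path: str) -> None:
    """Serialize a phantom spec as a human-editable JSON config."""
    doc = {
        "name": spec.name,
        "rng_seed": spec.rng_seed,
        "grid": {"shape": list(spec.grid.shape), "affine": spec.grid.affine.tolist()},
        "tubes": [
            {
                "name": t.name,
                "centerline": t.centerline.tolist(),
                "radius_mm": t.radius_mm,
                "cap_labels": list(t.cap_labels),
            }
            for t in spec.tubes
        ],
        "csf_regions": spec.csf_regions,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def spec_from_json(path: str) -> PhantomSpec:
    with open(path) as fh:
        doc = json.load(fh)
    grid = Grid(tuple(doc["grid"]["shape"]), np.asarray(doc["grid"]["affine"], float))
    tubes = [
        TubeSpec(
            t["name"], np.asarray(t["centerline"], float), float(t["radius_mm"]),
            tuple(t["cap_labels"]),
        )
        for t in doc["tubes"]
    ]
    return PhantomSpec(
        grid, tubes, doc.get("csf_regions", []), doc.get("rng_seed", 0),
        doc.get("name", "phantom"),
    )
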