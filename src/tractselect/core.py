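"""Shared spatial containers.

Every object in the toolkit lives in one coordinate convention: world
millimetres, RAS+, with voxel centres at integer indices (0-based).  A world
point ``w`` maps to the continuous voxel coordinate ``v = affine^-1 @ w`` and
belongs to the voxel cell ``floor(v + 0.5)`` — i.e. half-open cells
``[i - 0.5, i + 0.5)`` along each axis.  Streamline formats that use other
conventions (TRK voxel-mm, corner origin) are converted on load and never
operated on in their native space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Grid",
    "Tractogram",
    "LabelVolume",
    "BinaryMask",
    "TrackDensityImage",
    "GridMismatchError",
]


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


@dataclass(frozen=True)
class Grid:
    """A 3-D sampling grid: shape plus voxel->world affine.

    Parameters
    ----------
    shape : tuple of 3 int
        Voxels per axis.
    affine : (4, 4) ndarray
        Maps homogeneous 0-based voxel indices to world mm (RAS+).
        Must be invertible with bottom row (0, 0, 0, 1).
    """

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.allclose(aff[3], [0.0, 0.0, 0.0, 1.0]):
            raise ValueError("affine bottom row must be (0, 0, 0, 1)")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", aff)
        aff.setflags(write=False)

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Voxel edge lengths in mm (norms of the affine's spatial columns)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def inverse_affine(self) -> np.ndarray:
        return np.linalg.inv(self.affine)

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points to continuous voxel coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        inv = self.inverse_affine
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, voxels: np.ndarray) -> np.ndarray:
        """Map (possibly continuous) voxel coordinates to world mm."""
        vox = np.atleast_2d(np.asarray(voxels, dtype=float))
        return vox @ self.affine[:3, :3].T + self.affine[:3, 3]

    def contains_voxel(self, idx: np.ndarray) -> np.ndarray:
        """Elementwise test that integer voxel indices lie inside the grid."""
        idx = np.atleast_2d(np.asarray(idx))
        return np.all((idx >= 0) & (idx < np.asarray(self.shape)), axis=1)

    def same_as(self, other: "Grid", tol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=tol
        )

    def require_same(self, other: "Grid", what: str = "volumes") -> None:
        if not self.same_as(other):
            raise GridMismatchError(f"{what} are defined on different grids")


def _check_streamline(pts: np.ndarray) -> np.ndarray:
    pts = np.asarray(pts, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise ValueError("a streamline is an (n>=2, 3) array of world-mm points")
    if not np.all(np.isfinite(pts)):
        raise ValueError("streamline contains non-finite coordinates")
    return pts


@dataclass
class Tractogram:
    """An ordered collection of streamlines in world mm, plus reference grid.

    ``per_streamline_meta`` holds optional parallel lists (e.g. generating
    bundle name, seed label), each of length ``len(streamlines)``.
    """

    streamlines: list[np.ndarray]
    grid: Grid
    per_streamline_meta: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.streamlines = [_check_streamline(s) for s in self.streamlines]
        for key, vals in self.per_streamline_meta.items():
            if len(vals) != len(self.streamlines):
                raise ValueError(f"meta column {key!r} length mismatch")

    def __len__(self) -> int:
        return len(self.streamlines)

    def subset(self, indices) -> "Tractogram":
        indices = list(indices)
        return Tractogram(
            [self.streamlines[i] for i in indices],
            self.grid,
            {k: [v[i] for i in indices] for k, v in self.per_streamline_meta.items()},
        )


@dataclass
class LabelVolume:
    """Integer-labelled 3-D volume with a label<->name dictionary.

    Label 0 is reserved for background and never named.
    """

    grid: Grid
    data: np.ndarray
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.shape != self.grid.shape:
            raise ValueError("label data shape does not match grid shape")
        if not np.issubdtype(data.dtype, np.integer):
            raise TypeError("label data must be integer-typed")
        self.data = data
        present = set(np.unique(data).tolist()) - {0}
        missing = present - set(self.names)
        if missing:
            self.names = dict(self.names)
            for lab in sorted(missing):
                self.names[lab] = f"label_{lab}"
        if 0 in self.names:
            raise ValueError("label 0 is reserved for background")
        vals = list(self.names.values())
        if len(set(vals)) != len(vals):
            raise ValueError("region names must be unique")

    @property
    def labels_by_name(self) -> dict[str, int]:
        return {v: k for k, v in self.names.items()}

    def mask_of(self, region_names) -> "BinaryMask":
        """Union binary mask of the named regions."""
        if isinstance(region_names, str):
            region_names = [region_names]
        lookup = self.labels_by_name
        missing = [n for n in region_names if n not in lookup]
        if missing:
            raise KeyError(f"unknown region name(s): {missing}")
        labels = [lookup[n] for n in region_names]
        return BinaryMask(self.grid, np.isin(self.data, labels))


@dataclass
class BinaryMask:
    grid: Grid
    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid shape")
        self.data = data.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        self.grid.require_same(other.grid, "masks")
        return BinaryMask(self.grid, self.data & other.data)

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        self.grid.require_same(other.grid, "masks")
        return BinaryMask(self.grid, self.data | other.data)

    def __invert__(self) -> "BinaryMask":
        return BinaryMask(self.grid, ~self.data)


@dataclass
class TrackDensityImage:
    """Per-voxel streamline visitation counts for one tractogram."""

    grid: Grid
    counts: np.ndarray
    n_streamlines: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != self.grid.shape:
            raise ValueError("TDI shape does not match grid shape")
        if counts.min(initial=0) < 0:
            raise ValueError("TDI counts must be non-negative")
        self.counts = counts.astype(np.int64)
        self.n_streamlines = int(self.n_streamlines)
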