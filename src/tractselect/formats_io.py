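"""Reading and writing external formats (TCK, TRK, NIfTI-1, rule tables).

Everything is normalized on load into the toolkit's single internal
convention: world mm, RAS+, voxel centres at integer 0-based indices.
TRK files, which natively store voxel-mm coordinates with a corner origin,
are converted by nibabel on load/save and are never operated on in their
native space.  TCK carries no reference grid in its standard header, so we
stash the grid in two extra header fields (``grid_shape``,
``grid_affine``) on write and recover it on read; files from other tools
without these fields need an explicit ``grid=`` argument.
"""

from __future__ import annotations

import logging
import os

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel.streamlines import TckFile, TrkFile
from nibabel.streamlines import Tractogram as NibTractogram

from .core import BinaryMask, Grid, LabelVolume, Tractogram, TrackDensityImage
from .rules_engine import RuleTable, TractRule, VALID_SEMANTICS, DEFAULT_TARGET_COUNT

logger = logging.getLogger(__name__)

__all__ = [
    "read_tractogram",
    "write_tractogram",
    "read_label_volume",
    "write_label_volume",
    "write_mask",
    "write_tdi",
    "read_rule_table",
    "write_rule_table",
    "TractogramFormatError",
]

RULE_COLUMNS = [
    "tract",
    "hemisphere",
    "seed_regions",
    "include_regions",
    "include_semantics",
    "exclude_regions",
    "notes",
]


class TractogramFormatError(ValueError):
    """Malformed or unsupported streamline file."""


def _detect_dialect(path: str, dialect: str) -> str:
    if dialect != "auto":
        if dialect not in ("tck", "trk"):
            raise TractogramFormatError(f"unknown dialect {dialect!r}")
        return dialect
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tck", ".trk"):
        return ext[1:]
    raise TractogramFormatError(f"cannot infer dialect from extension of {path!r}")


def _grid_to_tck_fields(grid: Grid) -> dict[str, str]:
    return {
        "grid_shape": " ".join(str(s) for s in grid.shape),
        "grid_affine": " ".join(repr(float(v)) for v in grid.affine.ravel()),
    }


def _grid_from_tck_fields(header: dict) -> Grid | None:
    if "grid_shape" not in header or "grid_affine" not in header:
        return None
    try:
        shape = tuple(int(v) for v in str(header["grid_shape"]).split())
        affine = np.array([float(v) for v in str(header["grid_affine"]).split()]).reshape(4, 4)
    except (ValueError, TypeError) as exc:
        raise TractogramFormatError(f"malformed grid header fields: {exc}") from exc
    return Grid(shape, affine)


def read_tractogram(path: str, dialect: str = "auto", grid: Grid | None = None) -> Tractogram:
    """Load a TCK or TRK file; all points come back in world mm RAS+.

    ``grid`` overrides the reference grid; for TRK it defaults to the
    header's grid, for TCK to the grid stored by :func:`write_tractogram`
    (a 1 mm identity grid spanning the data is improvised otherwise, with a
    warning).
    """
    fmt = _detect_dialect(path, dialect)
    try:
        f = nib.streamlines.load(path)
    except Exception as exc:  # nibabel raises several header error types
        raise TractogramFormatError(f"cannot parse {path!r}: {exc}") from exc
    if fmt == "trk" and not isinstance(f, TrkFile):
        raise TractogramFormatError(f"{path!r} is not a TRK file")
    if fmt == "tck" and not isinstance(f, TckFile):
        raise TractogramFormatError(f"{path!r} is not a TCK file")
    streamlines = [np.asarray(s, dtype=float) for s in f.tractogram.streamlines]
    if grid is None:
        if fmt == "trk":
            hdr = f.header
            grid = Grid(tuple(int(d) for d in hdr["dimensions"]), np.asarray(hdr["voxel_to_rasmm"], float))
        else:
            grid = _grid_from_tck_fields(dict(f.header))
        if grid is None:
            logger.warning("%s carries no grid metadata; improvising identity grid", path)
            if streamlines:
                hi = np.ceil(np.max([s.max(axis=0) for s in streamlines], axis=0)).astype(int) + 2
                hi = np.maximum(hi, 1)
            else:
                hi = np.array([1, 1, 1])
            grid = Grid(tuple(hi), np.eye(4))
    streamlines = [s for s in streamlines if s.shape[0] >= 2]
    return Tractogram(streamlines, grid)


def write_tractogram(t: Tractogram, path: str, dialect: str = "auto") -> None:
    """Write a tractogram as TCK or TRK; header geometry from ``t.grid``."""
    fmt = _detect_dialect(path, dialect)
    nib_t = NibTractogram([np.asarray(s, np.float32) for s in t.streamlines],
                          affine_to_rasmm=np.eye(4))
    if fmt == "tck":
        f = TckFile(nib_t, header=_grid_to_tck_fields(t.grid))
    else:
        header = {
            "voxel_to_rasmm": t.grid.affine.copy(),
            "voxel_sizes": tuple(float(v) for v in t.grid.voxel_sizes),
            "dimensions": tuple(int(s) for s in t.grid.shape),
            "voxel_order": "".join(nib.aff2axcodes(t.grid.affine)),
        }
        f = TrkFile(nib_t, header=header)
    f.save(path)


def read_label_volume(path: str, names: str | dict | None = None) -> LabelVolume:
    """Load an integer-valued NIfTI volume as a LabelVolume.

    ``names`` may be a {label: name} dict or the path of a two-column
    ``label,name`` CSV.  Float-stored integers are accepted to 1e-6.
    """
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path!r}: expected 3-D label volume, got {data.ndim}-D")
    rounded = np.rint(data)
    if np.abs(data - rounded).max(initial=0.0) > 1e-6:
        raise TypeError(f"{path!r}: voxel values are not integers (tolerance 1e-6)")
    grid = Grid(tuple(int(s) for s in data.shape), np.asarray(img.affine, float))
    name_map: dict[int, str] = {}
    if isinstance(names, dict):
        name_map = {int(k): str(v) for k, v in names.items()}
    elif isinstance(names, str):
        df = pd.read_csv(names)
        if df.shape[1] < 2:
            raise ValueError(f"lookup {names!r} needs columns label,name")
        name_map = dict(zip(df.iloc[:, 0].astype(int), df.iloc[:, 1].astype(str)))
    return LabelVolume(grid, rounded.astype(np.int32), name_map)


def _save_nifti(data: np.ndarray, grid: Grid, path: str) -> None:
    nib.save(nib.Nifti1Image(data, grid.affine), path)


def write_label_volume(vol: LabelVolume, path: str, lookup_path: str | None = None) -> None:
    _save_nifti(vol.data.astype(np.int32), vol.grid, path)
    if lookup_path is not None:
        pd.DataFrame(
            {"label": list(vol.names), "name": list(vol.names.values())}
        ).to_csv(lookup_path, index=False)


def write_mask(mask: BinaryMask, path: str) -> None:
    _save_nifti(mask.data.astype(np.uint8), mask.grid, path)


def write_tdi(tdi: TrackDensityImage, path: str) -> None:
    _save_nifti(tdi.counts.astype(np.int32), tdi.grid, path)


def _split_cell(cell) -> list[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return []
    return [tok.strip() for tok in str(cell).split(";") if tok.strip()]


def read_rule_table(path: str) -> RuleTable:
    """Parse a CSV/TSV rule table (one row per bundle).

    Columns: tract, hemisphere, seed_regions, include_regions,
    include_semantics, exclude_regions, notes; multi-valued cells are
    ';'-separated, with include_semantics parallel to include_regions
    (missing semantics default to ``traverse``).
    """
    sep = "\t" if path.lower().endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in ("tract", "seed_regions") if c not in df.columns]
    if missing:
        raise ValueError(f"rule table {path!r} missing required columns: {missing}")
    rows = []
    for idx, row in df.iterrows():
        regions = _split_cell(row.get("include_regions"))
        semantics = _split_cell(row.get("include_semantics"))
        if len(semantics) < len(regions):
            semantics += ["traverse"] * (len(regions) - len(semantics))
        for sem in semantics:
            if sem not in VALID_SEMANTICS:
                raise ValueError(
                    f"rule table {path!r} row {idx + 2}: unknown semantics {sem!r} "
                    f"(expected one of {VALID_SEMANTICS})"
                )
        target = row.get("target_count")
        notes = row.get("notes")
        rows.append(
            TractRule(
                tract=str(row["tract"]).strip(),
                hemisphere=str(row.get("hemisphere") or "both").strip() or "both",
                seed_regions=_split_cell(row["seed_regions"]),
                includes=list(zip(regions, semantics)),
                excludes=_split_cell(row.get("exclude_regions")),
                target_count=int(target) if target and not pd.isna(target) else DEFAULT_TARGET_COUNT,
                notes="" if notes is None or pd.isna(notes) else str(notes),
            )
        )
    return RuleTable(rows, source_path=path)


def write_rule_table(table: RuleTable, path: str) -> None:
    sep = "\t" if path.lower().endswith((".tsv", ".txt")) else ","
    records = []
    for r in table.rows:
        records.append(
            {
                "tract": r.tract,
                "hemisphere": r.hemisphere,
                "seed_regions": ";".join(r.seed_regions),
                "include_regions": ";".join(reg for reg, _ in r.includes),
                "include_semantics": ";".join(sem for _, sem in r.includes),
                "exclude_regions": ";".join(r.excludes),
                "target_count": r.target_count,
                "notes": r.notes,
            }
        )
    pd.DataFrame(records).to_csv(path, sep=sep, index=False)
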