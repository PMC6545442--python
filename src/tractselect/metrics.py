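"""Overlap-based validation: Cohen's kappa, Dice, Jaccard, and the
functional-seed overlap ratio.

Cohen's kappa is chance-corrected agreement between two binary voxel
labelings; its chance term depends on how many *background* voxels are in
play, so the evaluation domain must be supplied explicitly (e.g. the
phantom's tissue mask, or a brain mask) — a whole-grid kappa is only
available by explicit request.  Interpretation bands follow Landis & Koch
("moderate" 0.4-0.6, "substantial" 0.6-0.8).

The overlap ratio is the asymmetric quantity used for agreement between a
pipeline bundle mask and a functionally-seeded reference:
|tract AND reference| / |tract| — intersection normalized by the pipeline
tract mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BinaryMask, Tractogram
from .geometry import mask_from_tdi, sphere_roi, track_density
from .tracking import (
    OrientationField,
    SeedingError,
    TissueMaps,
    TrackingParams,
    interface_seeds,
    make_propagation_context,
    propagate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable2x2",
    "OverlapReport",
    "contingency",
    "cohen_kappa",
    "dice",
    "jaccard",
    "overlap_ratio",
    "landis_koch_band",
    "overlap_report",
    "track_from_sphere",
    "fmri_overlap_pipeline",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Voxel counts over an evaluation domain: both, A-only, B-only, neither."""

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.total == 0:
            raise ValueError("contingency table over an empty domain")

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


@dataclass(frozen=True)
class OverlapReport:
    kappa: float
    dice: float
    jaccard: float
    domain_size: int
    interpretation: str


def contingency(a: BinaryMask, b: BinaryMask, domain: BinaryMask) -> ContingencyTable2x2:
    """2x2 agreement table of two masks restricted to ``domain``."""
    a.grid.require_same(b.grid, "masks")
    a.grid.require_same(domain.grid, "mask and domain")
    d = domain.data
    if not d.any():
        raise ValueError("evaluation domain is empty")
    av, bv = a.data[d], b.data[d]
    n11 = int((av & bv).sum())
    n10 = int((av & ~bv).sum())
    n01 = int((~av & bv).sum())
    n00 = int((~av & ~bv).sum())
    return ContingencyTable2x2(n11, n10, n01, n00)


def landis_koch_band(kappa: float) -> str:
    """Landis-Koch agreement band for a kappa value."""
    if kappa < 0.0:
        return "poor"
    if kappa < 0.2:
        return "slight"
    if kappa < 0.4:
        return "fair"
    if kappa < 0.6:
        return "moderate"
    if kappa < 0.8:
        return "substantial"
    return "almost perfect"


def cohen_kappa(ct: ContingencyTable2x2) -> float:
    """kappa = (p_o - p_e) / (1 - p_e), chance term from the marginals."""
    n = ct.total
    p_o = (ct.n11 + ct.n00) / n
    pa = (ct.n11 + ct.n10) / n
    pb = (ct.n11 + ct.n01) / n
    p_e = pa * pb + (1 - pa) * (1 - pb)
    if p_e >= 1.0 - 1e-15:
        return 1.0  # both marginals degenerate => observed agreement is 1
    return (p_o - p_e) / (1 - p_e)


def dice(ct: ContingencyTable2x2) -> float:
    denom = 2 * ct.n11 + ct.n10 + ct.n01
    return 2 * ct.n11 / denom if denom else 0.0


def jaccard(ct: ContingencyTable2x2) -> float:
    denom = ct.n11 + ct.n10 + ct.n01
    return ct.n11 / denom if denom else 0.0


def overlap_report(a: BinaryMask, b: BinaryMask, domain: BinaryMask) -> OverlapReport:
    ct = contingency(a, b, domain)
    k = cohen_kappa(ct)
    return OverlapReport(
        kappa=k, dice=dice(ct), jaccard=jaccard(ct),
        domain_size=ct.total, interpretation=landis_koch_band(k),
    )


def overlap_ratio(tract_mask: BinaryMask, reference_mask: BinaryMask) -> float:
    """|tract AND reference| / |tract| (asymmetric; pipeline-mask denominator)."""
    tract_mask.grid.require_same(reference_mask.grid, "masks")
    n_tract = tract_mask.n_voxels
    if n_tract == 0:
        raise ValueError("tract mask is empty")
    return int((tract_mask.data & reference_mask.data).sum()) / n_tract


def track_from_sphere(
    center: np.ndarray,
    radius_mm: float,
    field: OrientationField,
    tissues: TissueMaps,
    params: TrackingParams,
    n_streamlines: int,
    seed: int | np.random.Generator,
    attempt_factor: int = 100,
) -> Tractogram:
    """Seeded tracking restricted to (sphere AND WM/GM interface).

    Mirrors functionally-seeded tractography: a spherical ROI around an
    activation maximum, seeding on the interface voxels it covers.  Returns
    possibly fewer than ``n_streamlines`` if the budget runs out, and an
    empty tractogram if the sphere misses the interface entirely.
    """
    sphere = sphere_roi(center, radius_mm, tissues.grid)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ctx = make_propagation_context(field, tissues, params)
    kept: list[np.ndarray] = []
    attempts = 0
    budget = attempt_factor * n_streamlines
    while len(kept) < n_streamlines and attempts < budget:
        n = min(max(64, n_streamlines // 4), budget - attempts)
        try:
            starts = interface_seeds(tissues, sphere, n, rng)
        except SeedingError:
            logger.warning("sphere at %s misses the WM/GM interface", np.asarray(center))
            break
        for p in starts:
            if len(kept) >= n_streamlines or attempts >= budget:
                break
            attempts += 1
            prop = propagate(p, field, tissues, params, rng=rng, _ctx=ctx)
            if prop.accepted:
                kept.append(prop.points)
    return Tractogram(kept, tissues.grid)


def fmri_overlap_pipeline(
    tract_bundles: dict[str, Tractogram],
    activation_points: dict[str, np.ndarray],
    field: OrientationField,
    tissues: TissueMaps,
    params: TrackingParams,
    percentile: float = 5.0,
    sphere_radius_mm: float = 5.0,
    n_streamlines: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Task x tract matrix of overlap ratios.

    Each task's activation point becomes a spherical seed ROI; a
    ``n_streamlines``-streamline tractogram is tracked from it, converted
    to a density mask at the given percentile, and compared against each
    bundle's density mask with the asymmetric overlap ratio.
    """
    tract_masks = {
        name: mask_from_tdi(track_density(t, tissues.grid), percentile)
        for name, t in tract_bundles.items()
        if len(t) > 0
    }
    rows = {}
    rng = np.random.default_rng(seed)
    for task in sorted(activation_points):
        point = activation_points[task]
        task_tract = track_from_sphere(
            point, sphere_radius_mm, field, tissues, params, n_streamlines, rng
        )
        if len(task_tract) == 0:
            rows[task] = {name: 0.0 for name in tract_masks}
            continue
        task_mask = mask_from_tdi(track_density(task_tract, tissues.grid), percentile)
        rows[task] = {
            name: overlap_ratio(tract_masks[name], task_mask) for name in tract_masks
        }
    return pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)
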