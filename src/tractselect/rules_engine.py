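"""Rule-table-driven bundle segmentation.

A :class:`TractRule` is the machine form of one spreadsheet row of
anatomical criteria for a named bundle: seed regions (where streamlines
must originate/terminate), inclusion regions each with its own semantics
(``traverse`` — pass through anywhere; ``end_in`` — terminate inside), and
exclusion regions (any traversal rejects the streamline).  Region names
refer to parcellation *names*, not label integers, so a rule table survives
re-parcellation.

The same acceptance predicate drives both modes of bundle construction:

* ``select_bundle`` filters an existing whole-brain tractogram;
* ``generate_bundle`` seeds tracking at the WM/GM interface under the seed
  regions and keeps accepted streamlines until the target count is reached.

Inclusion criteria are conjunctive (all must hold); the default semantics
is ``traverse``, the weaker choice — for surgical use oversegmentation is
preferred to undersegmentation.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._voxel import polyline_entry_events, unique_in_order
from .core import BinaryMask, Grid, LabelVolume, Tractogram
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
    "TractRule",
    "RuleTable",
    "CompiledRule",
    "BundleResult",
    "RuleCompilationError",
    "compile_rule",
    "select_bundle",
    "generate_bundle",
]

VALID_SEMANTICS = ("traverse", "end_in")
DEFAULT_TARGET_COUNT = 5000
DEFAULT_ATTEMPT_FACTOR = 100  # attempt budget = factor * target_count


class RuleCompilationError(KeyError):
    """A rule names regions absent from the parcellation."""


@dataclass
class TractRule:
    """Seed / include / exclude criteria for one bundle."""

    tract: str
    hemisphere: str = "both"
    seed_regions: list[str] = field(default_factory=list)
    includes: list[tuple[str, str]] = field(default_factory=list)  # (region, semantics)
    excludes: list[str] = field(default_factory=list)
    target_count: int = DEFAULT_TARGET_COUNT
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.seed_regions:
            raise ValueError(f"rule {self.tract!r}: seed_regions must be non-empty")
        if self.hemisphere not in ("left", "right", "both"):
            raise ValueError(f"rule {self.tract!r}: bad hemisphere {self.hemisphere!r}")
        for region, sem in self.includes:
            if sem not in VALID_SEMANTICS:
                raise ValueError(
                    f"rule {self.tract!r}: unknown include semantics {sem!r}"
                )
        overlap = {r for r, _ in self.includes} & set(self.excludes)
        if overlap:
            raise ValueError(
                f"rule {self.tract!r}: regions in both includes and excludes: {sorted(overlap)}"
            )
        if self.target_count < 1:
            raise ValueError("target_count must be positive")

    @property
    def key(self) -> tuple[str, str]:
        return (self.tract, self.hemisphere)


@dataclass
class RuleTable:
    rows: list[TractRule]
    source_path: str = "<memory>"

    def __post_init__(self) -> None:
        keys = [r.key for r in self.rows]
        dupes = [k for k, c in Counter(keys).items() if c > 1]
        if dupes:
            raise ValueError(f"duplicate (tract, hemisphere) rows: {dupes}")

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def get(self, tract: str, hemisphere: str = "both") -> TractRule:
        for r in self.rows:
            if r.key == (tract, hemisphere):
                return r
        raise KeyError((tract, hemisphere))


@dataclass
class CompiledRule:
    """Rule resolved against a parcellation into binary masks."""

    rule: TractRule
    seed: BinaryMask
    includes: list[tuple[BinaryMask, str, str]]  # (mask, semantics, region name)
    exclude: BinaryMask


@dataclass
class BundleResult:
    rule: TractRule
    tractogram: Tractogram
    provenance: list[str]  # reason code per *examined* candidate
    attempts: int

    @property
    def n_kept(self) -> int:
        return len(self.tractogram)

    @property
    def acceptance_rate(self) -> float:
        return self.n_kept / self.attempts if self.attempts else 0.0

    def reason_histogram(self) -> dict[str, int]:
        return dict(Counter(self.provenance))


def compile_rule(rule: TractRule, parcellation: LabelVolume) -> CompiledRule:
    """Resolve a rule's region names into masks (union over named labels)."""
    lookup = parcellation.labels_by_name
    wanted = set(rule.seed_regions) | {r for r, _ in rule.includes} | set(rule.excludes)
    missing = sorted(n for n in wanted if n not in lookup)
    if missing:
        raise RuleCompilationError(
            f"rule {rule.tract!r}: regions not in parcellation: {missing}"
        )
    seed = parcellation.mask_of(rule.seed_regions)
    includes = [
        (parcellation.mask_of(region), sem, region) for region, sem in rule.includes
    ]
    if rule.excludes:
        exclude = parcellation.mask_of(rule.excludes)
    else:
        exclude = BinaryMask(parcellation.grid, np.zeros(parcellation.grid.shape, bool))
    return CompiledRule(rule, seed, includes, exclude)


def _evaluate(streamline: np.ndarray, compiled: CompiledRule, grid: Grid) -> str:
    """Shared acceptance predicate.

    Returns "accepted" or the FIRST failing criterion, evaluated in order
    seed -> includes (table order) -> excludes.  Seed criterion: at least
    one endpoint voxel lies in the seed mask.  Includes: traverse = any
    intersected voxel in the mask; end_in = an endpoint voxel in the mask.
    Excludes: traversal of any exclude voxel rejects.
    """
    events = unique_in_order(
        polyline_entry_events(grid.world_to_voxel(streamline), grid.shape)
    )
    ends = np.floor(grid.world_to_voxel(np.asarray(streamline)[[0, -1]]) + 0.5).astype(np.int64)
    inside = grid.contains_voxel(ends)
    end_lin = np.ravel_multi_index(ends[inside].T, grid.shape) if inside.any() else np.empty(0, np.int64)

    flat_seed = compiled.seed.data.ravel()
    if not (end_lin.size and flat_seed[end_lin].any()):
        return "seed_endpoint"
    for mask, sem, region in compiled.includes:
        flat = mask.data.ravel()
        if sem == "traverse":
            ok = events.size and flat[events].any()
        else:  # end_in
            ok = end_lin.size and flat[end_lin].any()
        if not ok:
            return f"include:{region}"
    if events.size and compiled.exclude.data.ravel()[events].any():
        return "exclude"
    return "accepted"


def select_bundle(
    t: Tractogram, rule: TractRule, parcellation: LabelVolume
) -> BundleResult:
    """Filter an existing tractogram down to the streamlines obeying a rule."""
    compiled = compile_rule(rule, parcellation)
    grid = parcellation.grid
    reasons = []
    kept = []
    for i, s in enumerate(t.streamlines):
        code = _evaluate(s, compiled, grid)
        reasons.append(code)
        if code == "accepted":
            kept.append(i)
    result = BundleResult(rule, t.subset(kept), reasons, attempts=len(t))
    if result.n_kept == 0:
        logger.warning("rule %s selected no streamlines from %d", rule.tract, len(t))
    return result


def generate_bundle(
    rule: TractRule,
    parcellation: LabelVolume,
    field_: OrientationField,
    tissues: TissueMaps,
    params: TrackingParams,
    seed: int,
    attempt_factor: int = DEFAULT_ATTEMPT_FACTOR,
) -> BundleResult:
    """Track streamlines from the seed regions until ``rule.target_count``
    pass the rule's acceptance predicate (or the attempt budget runs out).

    Seeds are drawn on the WM/GM interface adjacent to the seed regions:
    the compiled seed mask (typically grey matter) is dilated by one voxel
    (6-connectivity) before intersecting the interface, so GM seed regions
    select the WM interface voxels that border them.  Deterministic given
    ``seed``.
    """
    compiled = compile_rule(rule, parcellation)
    parcellation.grid.require_same(field_.grid, "parcellation and field")
    near_seed = BinaryMask(
        parcellation.grid,
        ndimage.binary_dilation(
            compiled.seed.data, structure=ndimage.generate_binary_structure(3, 1)
        ),
    )
    rng = np.random.default_rng(seed)
    ctx = make_propagation_context(field_, tissues, params)
    budget = attempt_factor * rule.target_count
    kept_streamlines: list[np.ndarray] = []
    reasons: list[str] = []
    attempts = 0
    batch = max(64, rule.target_count // 4)
    while len(kept_streamlines) < rule.target_count and attempts < budget:
        n = min(batch, budget - attempts)
        try:
            starts = interface_seeds(tissues, near_seed, n, rng)
        except SeedingError:
            logger.warning("rule %s: empty seeding surface", rule.tract)
            break
        for p in starts:
            if len(kept_streamlines) >= rule.target_count or attempts >= budget:
                break
            attempts += 1
            prop = propagate(p, field_, tissues, params, rng=rng, _ctx=ctx)
            if not prop.accepted:
                reasons.append(f"tracking:{prop.reject_reason}")
                continue
            code = _evaluate(prop.points, compiled, parcellation.grid)
            reasons.append(code)
            if code == "accepted":
                kept_streamlines.append(prop.points)
    if len(kept_streamlines) < rule.target_count:
        logger.warning(
            "rule %s: budget exhausted, %d/%d accepted (rate %.3f)",
            rule.tract, len(kept_streamlines), rule.target_count,
            len(kept_streamlines) / max(attempts, 1),
        )
    tract = Tractogram(
        kept_streamlines,
        parcellation.grid,
        {"bundle": [rule.tract] * len(kept_streamlines)},
    )
    return BundleResult(rule, tract, reasons, attempts)
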