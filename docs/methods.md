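# Methods

This note documents the models, conventions and numerical choices behind
`tractselect`, and what the phantom-based tests do and do not demonstrate
about behaviour on real diffusion MRI data.

## Coordinate convention

Everything operates in one space: world millimetres, RAS+, voxel centres at
integer 0-based indices.  A world point `w` has continuous voxel coordinate
`v = A⁻¹w` (A the voxel→world affine) and belongs to the half-open cell
`[i−0.5, i+0.5)³`, i.e. voxel `floor(v + 0.5)`.  TRK files (voxel-mm,
corner origin) are converted by nibabel on load/save and never processed
natively; TCK files carry no reference grid in their standard header, so
the grid is stashed in two extra header fields (`grid_shape`,
`grid_affine`) on write and recovered on read — foreign TCK files need an
explicit grid argument.

## Voxelization

Streamline→voxel mapping is exact 3-D grid marching (Amanatides–Woo DDA)
per segment in continuous voxel space: the reported set is the exact set of
half-open cells the polyline intersects, each cell once in first-visit
order.  Tests verify it two ways: a dense 0.01-voxel resampling oracle must
find no cell the DDA misses, and an independent segment/box slab-clipping
oracle must agree cell-for-cell.  (Point resampling alone is not a complete
oracle: about 0.3% of cell crossings are corner grazes shorter than the
sampling step, which the exact traversal finds and sampling misses.)

Track-density images count, per voxel, either distinct streamlines
(`unique_streamline`, the default — "number of streamlines" names
streamlines, not passes) or every entry event (`per_visit`).

## Density masks

A bundle mask keeps voxels with count ≥ τ, where τ is the nearest-rank
p-th percentile (`ceil(p/100·n)`-th smallest, floored at the 1st) of the
bundle's *non-zero* voxel counts; the default p=5 keeps ≥95% of non-zero
voxels.  Two deliberate choices: nearest rank (integer counts; no
interpolation ambiguity), and non-zero support only — a percentile over
the whole volume would be 0 almost surely and make the operation vacuous.
Both τ and the retained fraction are logged per call.

## Rule engine

A rule row is `(tract, hemisphere, seed_regions, includes, excludes,
target_count)`, with region *names* resolving against the parcellation so
tables survive re-parcellation.  The acceptance predicate, shared verbatim
by selection and generation modes:

1. **seed** — at least one endpoint voxel lies in the seed mask (endpoint
   semantics: in generation mode streamlines originate at the interface
   under the seed regions, so endpoint membership is the faithful
   selection-mode analogue);
2. **includes** — conjunctive, each with `traverse` (any intersected voxel)
   or `end_in` (an endpoint voxel) semantics; `traverse` is the default —
   the weaker, oversegmentation-friendly reading appropriate when false
   negatives are the costly error (surgical planning);
3. **excludes** — traversal of any exclude voxel rejects (this includes
   endpoint voxels, since endpoints are intersected cells).

Rejections record only the first failing criterion, in the order above,
giving a cheap deterministic QC histogram.  Generation seeds on the WM/GM
interface voxels bordering the seed regions (the compiled seed mask —
typically grey matter — dilated by one voxel, 6-connectivity, then
intersected with the interface), and stops at `target_count` accepted
streamlines (default 5000) or after `100 × target_count` attempts.

## Tracking model and its fidelity

The propagator is deliberately a surrogate, not a spherical-deconvolution
tracker: a single fixed orientation per voxel (antipodally symmetric,
nearest-voxel lookup, no interpolation), first-order (Euler) steps of
0.5 × min voxel size, per-step von Mises–Fisher jitter of concentration κ
around the field direction, a per-step curvature cap (45° default, 5
resampling retries), bidirectional growth from the seed with the two
halves sharing the seed point.  Tissue priors are the standard
anatomically constrained set over *hard* (disjoint) WM/GM/CSF masks:
terminate on entering GM, reject on CSF, on leaving the tissue model, or
on length outside [10, 250] mm; acceptance additionally re-checks the
assembled polyline by exact voxelization so that "no accepted streamline
intersects a CSF voxel" holds exactly, not just at step points.

`dispersion_kappa` defaults to ∞ (the deterministic limit).  Rationale:
seeds are jittered uniformly within interface voxel cells, so at *any*
finite κ a fixed fraction of seeds starts arbitrarily close to a cell
boundary whose neighbour is background and dies there (measured straight-
tube acceptance: 0.86 at κ=1000, 0.979 at κ=60000, 1.000 at ∞); the
deterministic default is the one setting whose near-total acceptance is a
construction guarantee.  Probabilistic runs pass κ explicitly — the demo
and the functional arm use κ=3000 (≈1° per-step SD), which costs ~7%
acceptance on straight tubes and visibly broadens density masks.

What this surrogate preserves from real pipelines: interface seeding,
tissue priors, probabilistic dispersion, curvature capping, the
target-count retry loop.  What it does not model: fODF shape and crossing
resolution (the field holds one direction per voxel; at tube crossings the
first-listed tube owns the voxel, so the second tube cannot be *tracked*
through a crossing — crossing geometry is exercised in selection mode),
second-order integration, partial-volume tissue maps, backtracking.

## Phantoms

Tubes are uniform Catmull–Rom interpolations of control points (analytic
tangents, reflected phantom endpoints), rasterized by exact point-to-
segment distance of voxel centres to the finely sampled centreline
(≤ radius ⇒ WM, direction = tangent at nearest segment).  Grey-matter caps
are solid hemispheres of radius (tube radius + 2 voxels) beyond each tube
end, excluding WM, labelled in the parcellation; WM corridors are labelled
per tube (overlaps owned by the first tube and recorded).  Optional CSF
boxes/spheres carve non-tube tissue; background stays unlabeled.  The
default scale is 64³ voxels at 2 mm isotropic.

Five canonical phantoms ship with matching exemplar rule tables: straight
tube, C-shaped arc, two orthogonal crossing tubes, a tube flanked by a CSF
slab, and two disjoint parallel tubes.  `reference_streamlines` yields
analytic ground-truth streamlines (centreline plus perpendicular offsets
capped at half the radius, extended into the caps so endpoints terminate
in GM as tracked streamlines do); the offset cap leaves a ≥1-voxel margin
so an offset streamline can never clip a neighbouring tube's corridor
cells — that margin is what makes membership F1 = 1.0 a construction
guarantee rather than a statistical observation.  `activation_point`
returns a cap centroid displaced along the outward cap normal, a stand-in
for a task-fMRI activation maximum near a tract terminus.

What phantom results do *not* show: robustness to realistic fODF noise,
partial voluming, susceptibility distortion, or anatomical variability;
they certify the machinery (rule semantics, priors, counters, statistics),
not clinical accuracy.

## Overlap statistics

κ uses the 2×2 voxel contingency table over an *explicit* evaluation
domain; there is no silent whole-grid default because the chance-agreement
term depends on the background count: for fixed masks, κ → Dice as the
domain grows (≈0 for near-disjoint masks), never to 1, and the reported
value is only reproducible if the domain is stated.  The demo uses the
phantom's tissue mask.  Bands: <0 poor, then slight/fair/moderate/
substantial/almost-perfect in 0.2 steps.  Dice and Jaccard of two empty
masks are defined as 0 to avoid NaNs in batch reports.  The functional
overlap ratio |tract ∩ reference| / |tract| is asymmetric by design —
normalized by the pipeline tract mask, because the functional seed is much
smaller than the anatomical seed regions and can only ever recruit part of
the bundle.

## Rating model

Responses are Bernoulli with `logit P(y=1) = β₀ + β_method + β_rater + b_subject`,
`b ~ N(0, σ²)`, reference method AU and reference rater the first in sorted
order.  Rater is a fixed effect (rater differences are a tested contrast);
tract enters optionally (`include_tract_effect`) and is off by default —
only patient-level clustering is modelled as random.  The marginal
likelihood is maximized by adaptive Gauss–Hermite quadrature (default 8
nodes; 1 node = Laplace): per-subject posterior modes by Newton iteration,
nodes recentred/rescaled at the mode, L-BFGS-B over (β, log σ) with
log σ ∈ [log 10⁻⁴, log 50].  Standard errors come from the inverse
numerical Hessian of the negative marginal log-likelihood (central
differences, h=10⁻⁴); intervals are Wald on the log-odds scale,
exponentiated to odds ratios, matching the conventional "OR (95% CI)"
presentation (profile intervals are not implemented).  The implementation
is cross-checked in the test suite against `lme4::glmer` (nAGQ=8) through
Rscript: coefficients and SEs agree to ~10⁻³.

Complete separation is detected *before* fitting (any method×response cell
empty, or all responses identical) and raised as a data error naming the
cell — small rating tables make separation likely, and an explicit error
beats a silently divergent fit.  The simulator draws from exactly the
fitted model (AU log-odds as baseline, independent per-question subject
intercepts), which is what makes parameter-recovery and coverage tests
meaningful: measured over replicates, method log-odds bias is ~0.01 at 100
subjects and 95% Wald coverage is ~95% at the 10-subject design.

## Blinding

Each subject gets an independent uniform random bijection between set
codes {A,B,C} and methods {AU,H1,H2}.  Blinding is bookkeeping only — the
likelihood is invariant under relabelling, verified by fitting blinded
records after unblinding.

## Problem sizes and determinism

Default problem sizes used throughout the demo, tests and the acceptance
script: 5000 streamlines per bundle, 64³×2 mm phantoms, 5th-percentile
masks, 5 mm activation spheres; the rating simulation studies use 20–100
replicates at 10–200 subjects (5 tracts × 5 raters × 3 methods).  Every
stochastic entry point takes an explicit seed; identical seeds give
bit-identical streamlines, volumes, CSVs and JSON (no timestamps in any
output; provenance headers carry the package version and a config hash).

## Known limitations

- The tracker is a surrogate (see above); no fODF estimation, no real-data
  ingestion beyond the file formats.
- Single-direction fields cannot represent crossings; crossing bundles can
  be selected but not generated through the crossing.
- Exemplar rule tables cover the phantoms; real anatomical criteria for
  AF/IFOF/ILF/MLF/UF must be supplied by the user as a CSV against their
  parcellation's names.
- κ comparisons require both mask sets on one grid; no resampling is
  provided.
- The rating model assumes binary responses and a single random-intercept
  level; no ordinal or crossed-random-effects extensions.
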