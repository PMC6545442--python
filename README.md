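# tractselect

Automated white-matter bundle reconstruction from anatomical criteria, with
the three validation arms such a pipeline needs — overlap agreement,
blinded expert-rating statistics, and functional-seed overlap — all
exercisable end-to-end on digital tractography phantoms.

## Who this is for

Clinical tractography for surgery planning (e.g. preserving language
pathways in temporal-lobe-epilepsy resections) needs bundle segmentations
that do not depend on an expert drawing regions of interest by hand.  The
standard automated recipe is *atlas/rule based*: each bundle (arcuate
fasciculus AF, inferior fronto-occipital fasciculus IFOF, inferior and
middle longitudinal fasciculi ILF/MLF, uncinate fasciculus UF, ...) is
described by one spreadsheet row of anatomical criteria over a
parcellation — seed regions, inclusion regions, exclusion regions — which
drives probabilistic, anatomically constrained tracking.  This package
implements that rule engine and everything needed to validate it without
patient data.

## What it computes

- **Rule-driven bundles.** A rule row names parcellation regions:
  `seed` (streamline termini), `include` (each with `traverse` or `end_in`
  semantics, conjunctive), `exclude` (any traversal rejects).  One shared
  acceptance predicate either *filters* an existing tractogram
  (`select_bundle`) or *drives* seeded tracking until 5000 streamlines are
  accepted (`generate_bundle`).
- **Tissue-constrained tracking.** A first-order stochastic propagator over
  a per-voxel orientation field with von Mises–Fisher angular jitter,
  seeded at the white-matter/grey-matter interface; streamlines must end
  in grey matter at both ends and never touch CSF.
- **Track-density masks.** A bundle's density image is thresholded at the
  nearest-rank 5th percentile of its non-zero voxel counts, keeping ≥95%
  of the bundle's voxels and trimming the low-density fringe.
- **Overlap statistics.** Cohen's κ = (p_o − p_e)/(1 − p_e) over an
  explicit evaluation domain, with Landis–Koch bands ("moderate"
  0.4–0.6, "substantial" 0.6–0.8), plus Dice and Jaccard; and the
  asymmetric functional overlap ratio |tract ∩ reference| / |tract|.
- **Blinded ratings model.** Binary expert ratings (correct connections,
  morphology, spurious tracts) for methods {automated AU, experts H1, H2}
  behind per-subject randomized set codes, analysed with a mixed-effects
  logistic regression — fixed effects for method (reference AU) and rater,
  per-subject (patient-level) random intercept — fitted by adaptive
  Gauss–Hermite maximum likelihood with Wald odds-ratio intervals.
- **Digital phantoms.** Curved tube bundles (Catmull–Rom centrelines) with
  grey-matter end caps, parcellation labels, CSF traps and exact
  ground-truth membership, so every claim above is testable by
  construction.

## Worked example

```bash
tractselect demo --out demo_out --seed 5
```

builds the arc-shaped phantom, reconstructs its bundle twice (noiseless and
with angular dispersion κ=3000), compares the two density masks, runs the
functional-seed arm on a two-bundle phantom, and simulates + fits blinded
ratings.  It prints (abridged):

```json
{
  "fmri_overlap": {
    "par_a": {"task_linked": 0.9838, "task_far": 0.0},
    "par_b": {"task_linked": 0.0,    "task_far": 0.0}
  },
  "overlap": {
    "kappa": 0.9183, "dice": 0.9785, "jaccard": 0.9578,
    "band": "almost perfect"
  }
}
```

Reading: the noiseless and dispersed reconstructions of the same bundle
agree almost perfectly (κ=0.92 — far above the "substantial" band floor of
0.6), a tractogram seeded from a 5 mm sphere at bundle `par_a`'s terminus
overlaps 98% of that bundle's mask and 0% of the disjoint bundle
`par_b`, and a distant activation point yields no overlap at all.
`demo_out/method_contrasts.csv` holds the rating-model odds ratios in
"OR (CI low to CI high)" form per question.

Other subcommands: `tractselect phantom | bundles | validate-overlap |
validate-fmri | ratings` (see `--help` for each).

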