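# Methods

This note records the statistical model behind `tractdelta`, the choices
made where the design was genuinely open, and what the synthetic validation
does and does not establish.

## Problem setting

The input is a streamline bundle (TRK/TCK, world millimetres) plus one
scalar diffusion-metric volume (NIfTI) per time-point, all co-registered to
a common space. The package asks, per cross-section of the bundle, whether
the distribution of per-fiber metric values has changed between a reference
time-point and a follow-up — and which fibers carry the change. FA is the
metric used throughout the documentation, but nothing restricts the code to
it beyond the default search range [0, 1].

## Bundle preparation

1. **Endpoint clustering.** K-means with k = 2 on the pooled first/last
   points of all fibers (scikit-learn, 10 restarts, caller-supplied seed).
   Cluster R1 is the lexicographically smaller centroid, making the R1/R2
   labels deterministic. Fibers whose two endpoints fall in the same
   cluster do not link the two regions and are removed; the rest are
   reoriented to run R1 → R2.
2. **Resampling.** Each fiber is resampled to c = 100 points equidistant in
   arc length, linear interpolation between vertices, endpoints preserved
   exactly. Linear (rather than spline) interpolation is the simplest
   scheme consistent with equidistant nodes; on smooth streamlines it
   preserves arc length to well under 0.5 %.
3. **Outlier removal.** The mean skeleton holds, per node, the coordinate
   mean p_mu and the spread p_sigma of fibers around it. The source
   description of the spread is ambiguous; the default reads it as the SD
   of the per-fiber Euclidean distances to p_mu (one scalar per node, as
   the notation demands), and the rejection rule is distance >
   mean_distance + k·p_sigma with k = 3, applied in a single pass (the
   skeleton is not recomputed after removal). A per-coordinate variant
   (spread = norm of the per-axis SDs, rule = distance > k·spread) is
   available via `skeleton_method="coordinate"`. p_sigma is floored at
   1e-6 mm so a bundle of identical fibers does not reject itself.
   Note the 3-SD rule is distribution-dependent: on a bundle with
   Gaussian transverse spread it trims a small percentage of genuine
   fibers by construction.
4. **Metric sampling.** Every node takes the value of its single nearest
   voxel (inverse affine, round-half-up per axis — deterministic across
   platforms); no interpolation, matching the one-voxel-per-point
   convention of along-tract analysis. Out-of-volume nodes carry NaN and
   are excluded from the affected cross-sections only, so a fiber that
   clips the volume edge still contributes everywhere else.

## Cross-section model

The m values of one cross-section at one time-point are treated as a sample
from a univariate Gaussian mixture, fitted by EM on the raw values (never
on binned counts, so no bin width exists). n = 1 uses the closed-form MLE.
For n ≥ 2, EM runs from 5 random initialisations (means drawn around the
sample mean, uniform weights, pooled variance) with a variance floor of
1e-6 to prevent degeneracy on near-duplicate values — duplicates are
routine here because many fibers share a voxel. The per-iteration
log-likelihood trace is retained and is nondecreasing by the EM guarantee.
`fit_gmm_nodes` runs the same EM vectorised over all cross-sections and
restarts at once; it is the engine behind every full-bundle analysis.

**Component-count selection.** Both time-points must share one n. For each
n in 1..n_max (default 5, capped so each sample keeps ≥ 5n points), both
samples are fitted and scored by negated BIC; the Pareto-nondominated
counts over the two scores are found by exhaustive enumeration (the search
space is at most n_max points, so enumeration is the exact solution of the
bi-objective problem and no evolutionary search is warranted). The
selected n maximises the combined score and is provably a member of the
front, with ties broken toward smaller n. A smallest-front-member rule was
rejected: whenever the reference is unimodal, n = 1 is nondominated
regardless of the follow-up, so that rule can never react to one-sided
multimodality — precisely the signature of a lesion appearing at follow-up.
A `raw` objective mode scores by in-sample log-likelihood and applies the
literal smallest-front-member rule; raw likelihood is near-monotone in n,
so this mode drifts toward n_max and exists for fidelity experiments only.

## Detection test

Given fitted mixtures D_ref and D_new and the tolerated error ζ, the test
seeks the interval [β, γ] maximising P_D = ∫_β^γ D_new subject to
P_F = ∫_β^γ D_ref ≤ ζ and P_D > P_F.

* `fixed_zero` (default; targets FA decreases): β = 0 and the optimum is
  γ* = the ζ-quantile of D_ref, computed by bracketed root finding on the
  mixture CDF (Σ w_j Φ((x − μ_j)/σ_j)), so P_F equals ζ up to the
  (negligible) reference mass below zero. γ* is monotone in ζ.
* `free`: exhaustive search on a uniform grid (step 0.001 over [0, 1] by
  default). Among admissible cells the largest P_D wins; ties prefer the
  narrower interval, then the smaller β. The grid makes the solution exact
  on its own lattice and fully reproducible; a brute-force double loop over
  the same grid reproduces it cell for cell.

**Finite-sample guard.** The constraint P_D > P_F compares two *fitted*
models. With finitely many fibers — and, after nearest-voxel sampling, far
fewer distinct voxels (a 100-fiber cross-section typically spans only
~25 voxels) — the two fits differ a little even when nothing changed, and
the raw inequality holds on roughly half of all unchanged cross-sections.
A detector with a ~50 % false-alarm floor is useless, so feasibility
additionally requires evidence in the data itself. Because the time-points
are co-registered, fibers are paired across them; collapsing fibers that
share a voxel (identical value pairs) gives one paired observation per
distinct voxel. Under no change, a voxel outside [β, γ] at reference lands
inside at follow-up only through acquisition noise; the noise scale is
estimated robustly from the paired differences (1.4826 × MAD), each
outside-voxel's flip-in probability follows from the Gaussian noise model,
and their sum λ bounds the null in-flip count by a Poisson law (Le Cam:
the Poisson tail is conservative for a sum of independent Bernoullis). The
observed in-flip count b is significant when the Poisson upper tail at b
is ≤ `pair_alpha` (default 0.01, a conventional level; on 100-node
bundles it yields well below one spurious detection run per analysis on
null phantoms). When per-fiber samples are unavailable (model-only calls)
the guard falls back to a one-sided two-proportion z-margin (z = 1.645) on
the models' sample counts. `pair_alpha=1` with `margin_z=0` restores the
literal unguarded rule.

**Labelling and iteration.** At a detected node, fibers with
β ≤ value ≤ γ (inclusive) are *changed*; NaN values are *excluded*; with no
feasible interval everything is *unchanged*. A fiber is changed at the
bundle level when changed at ≥ `min_changed_nodes` nodes (default 1 —
the least committal reading of per-node labels; configurable). The whole
analysis can be re-run on the changed subset: restricting the reference
sample to those fibers narrows D_ref and moves γ*, which is what lets a
second, subtler event inside the subset surface even when the full-bundle
test cannot see it.

**Multiple comparisons.** No correction is applied across the c nodes or
the k − 1 time-points. ζ and the influx-test level are the only error
controls; users scanning many bundles should account for this.

## Synthetic phantoms

The validation data of the original study (real control-subject FA maps
with lesions injected on atlas bundles) is not distributable, so the
simulator builds a parametric stand-in with the same contrast regime:

* 64 × 64 × 40 grid at 2 mm isotropic (the nominal resolution of a typical
  DTI acquisition), holding a quadratic-arc centerline ~100 mm long;
* a fiber-occupied tube of radius 5.5 mm (the scale of major projection /
  association tracts), 100 fibers, each a smoothly jittered copy of the
  centerline confined to the tube;
* a static FA field — 0.55 ± 0.05 inside the bundle, 0.30 ± 0.05 outside,
  clipped to [0, 1] — fixed across time-points, with FA elevated for an
  extra 2 mm partial-volume rim so nearest-voxel lookup from any fiber
  point lands on bundle-level FA;
* per-time-point acquisition noise of SD 0.02; a follow-up is the same
  static field plus a fresh noise draw, never a reused one.

Lesions multiply FA by α inside a sphere of radius 2 voxels
(voxel-center distance, inclusive — 33 voxels on an isotropic grid), with
the order field → noise → lesion, so the post/pre FA ratio inside the
sphere is exactly α. Validation sets place one lesion per follow-up,
centers uniform over the bundle's own voxels, pairwise ≥ 2 radii apart and
≥ 1 radius from the tract ends, with α values assigned in balanced counts.

What the phantom does **not** model: crossing-fiber geometry, tensor-level
signal formation, spatially correlated noise, registration error, and
partial-volume averaging at the lesion boundary. Passing the validation
therefore shows the detection machinery behaves as designed under its own
assumptions — clean pairing, Gaussian noise, known ground truth — not that
clinical sensitivity will match these numbers.

## Validation protocol and expected behaviour

`scripts/acceptance.py` (and the acceptance test suite) runs 20 radius-2
lesions at α = 0.5, ζ = 0.12, β = 0 over three phantom seeds, scoring at
lesion level: a planted lesion is a true positive when at least one
detected node has a changed-fiber point inside the lesion mask; detected
nodes touching no lesion form maximal consecutive runs, one false positive
each; true negatives are nodes with neither detection nor lesion overlap.
Node-level counting is available behind `unit="node"`. Only lesions whose
mask is actually traversed by the bundle enter the sensitivity denominator.
Problem sizes (20 lesions × 3 seeds, 100 fibers × 100 nodes, 10 null
phantoms at 50 nodes) keep the full study in the minutes range on one CPU
while leaving ≥ 55 scoreable lesions.

The mean ± SD band comparator is scored on the same runs and detects
(essentially) none of the radius-2 lesions: a lesion covering a fraction p
of a cross-section shifts the mean by ~0.275·p while inflating the
follow-up SD, and with the default geometry p never reaches the level where
the one-SD bands separate.

One deliberate departure from the published validation's tabulated trend:
there, detection rates *rise* as α → 1 (weaker lesions found more often),
which is consistent with an unguarded P_D > P_F rule whose null behaviour
is a coin flip, not with detectability. Under the guarded test the
direction inverts — strong reductions (low α) are detected reliably, while
α near 1 moves values by less than the noise floor and must fail. The
sweep utilities therefore assert the physically coherent direction.

## Numerical choices

* Variance floor 1e-6 (metric² units); spread floor 1e-6 mm.
* EM: 5 restarts, ≤ 200 iterations, convergence at |Δ log L| < 1e-6·m.
* Quantiles via `brentq` at xtol 1e-12 on a bracket widened from
  μ ± 10σ.
* Free-search grid step 0.001 (FA units), configurable.
* K-means ties resolved by scikit-learn's best-of-10 inertia rule plus the
  lexicographic R1 convention.
* All randomness flows from caller-supplied integer seeds through
  `numpy.random.default_rng`; per-node/per-time-point seeds are derived
  with fixed prime multipliers, keeping every derived seed below 2^31.
* Degenerate inputs fail loudly: coincident endpoints, zero-length fibers,
  all-fiber removal, < 10 valid samples at a node (that node reports an
  infeasible interval with a note), overlapping or out-of-bounds lesion
  spheres.

## Known limitations

* The influx guard assumes approximately Gaussian, voxel-independent
  acquisition noise; heavy spatial noise correlation would make it
  anti-conservative.
* Distinct-voxel collapsing identifies voxels by exact value-pair
  equality, which is sound for nearest-voxel sampling but would break if
  interpolated sampling were added.
* Lesions are scored per planted sphere; extended or confluent lesions
  have no ground-truth representation here.
* `iterate_on_changed_subset` requires ≥ 10 changed fibers (below that the
  cross-section mixtures are not meaningfully estimable) and skips with a
  notice otherwise.
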