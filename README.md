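# tractdelta

Detection of small longitudinal changes of diffusion metrics (chiefly
fractional anisotropy, FA) along white-matter fiber bundles.

Along-tract ("tractometry") studies summarise a bundle by the mean ± SD of a
diffusion metric at each of *c* cross-sections and flag change where the two
time-points' bands separate. That *mean method* is blind to alterations that
touch only a few fibers of the bundle — a small demyelinating lesion shifts
a handful of values without moving the cross-section mean. `tractdelta`
implements a finer, fiber-resolved analysis for co-registered longitudinal
data (e.g. multiple-sclerosis follow-up): every cross-section's histogram of
per-fiber FA values is modelled, compared between time-points, and the
individual fibers driving a change are labelled.

## Method

For a bundle of *m* fibers resampled to *c* = 100 equidistant nodes, the
FA samples of cross-section *i* at the reference time-point and at a
follow-up are fitted independently by univariate Gaussian mixtures
D<sub>ref</sub> and D<sub>new</sub> (maximum likelihood via EM; a common
component count *n* is chosen by enumerating *n* = 1…n<sub>max</sub>,
scoring both fits by BIC and keeping the best Pareto-nondominated count).
Change is then sought as an interval [β, γ] solving

```
max_{β,γ}  P_D = ∫_β^γ D_new     s.t.  P_F = ∫_β^γ D_ref ≤ ζ,   P_D > P_F
```

where ζ, the *tolerated error*, bounds the reference mass inside the
interval. With β fixed at 0 (the configuration for detecting FA decreases)
the optimum is simply γ* = the ζ-quantile of D<sub>ref</sub>. Because the
two scans are co-registered, each distinct voxel of the cross-section yields
a paired (reference, follow-up) observation, and a candidate interval only
counts as a detection if the number of voxels flipping into [β, γ] exceeds
what acquisition noise explains (an exact one-sided Poisson-bound test;
see `docs/methods.md`). Fibers whose follow-up value lies in a detected
interval are labelled *changed*; the analysis can then be re-run on the
changed subset alone to expose secondary events.

Bundle preparation follows standard tractometry practice: k-means (k = 2)
endpoint clustering, reorientation of every fiber from region R1 to R2 and
removal of fibers that do not link the two regions, arc-length resampling to
*c* nodes, rejection of fibers straying more than 3 SD from the bundle's
mean skeleton, and nearest-voxel metric sampling.

A lesion simulator generates synthetic phantoms (a tubular bundle in an FA
volume) and plants spherical lesions of radius 2 voxels that multiply FA by
a reduction coefficient α ∈ [0, 1], supporting sensitivity / precision /
F-Measure validation against ground truth.

## Worked example

```python
import numpy as np
from tractdelta import (PhantomSpec, generate_phantom, make_followup,
                        insert_lesions, LesionSpec, process_bundle,
                        run_longitudinal_analysis)

spec = PhantomSpec(seed=10)                     # 64x64x40 grid, 2 mm voxels
bundle, w1 = generate_phantom(spec)             # 100 fibers, FA 0.55 tube
w2 = make_followup(w1, spec.noise_sd, seed=77)  # independent re-scan
mid = w1.meta["centerline"][250] / spec.voxel_size
center = (int(mid[0] + 0.5), int(mid[1] + 0.5) + 2, int(mid[2] + 0.5))
w2, mask = insert_lesions(w2, [LesionSpec(center, radius=2, alpha=0.5)])

pb = process_bundle(bundle, {"w1": w1, "w2": w2}, seed=10)
res = run_longitudinal_analysis(pb, "w1", zeta=0.12, seed=10)
det = res.detected_nodes("w2")
print("detected nodes:", det)
print("changed fibers:", len(res.changed_fiber_ids("w2")))
iv = res.intervals["w2"][det[0]]
print(f"gamma={iv.gamma:.3f}  P_D={iv.p_d:.3f}  P_F={iv.p_f:.3f}")
print("mean-method nodes:", res.mean_detected["w2"])
```

prints

```
detected nodes: [50]
changed fibers: 33
gamma=0.483  P_D=0.330  P_F=0.120
mean-method nodes: []
```

An off-axis lesion halving FA (α = 0.5) near the bundle midpoint is found
at the cross-section it is centred on: the interval [0, 0.483] holds 12 %
of the reference model's mass (exactly the ζ budget) but 33 % of the
follow-up's, and the 33 fibers passing low enough through that
cross-section are labelled changed. The mean ± SD band method sees nothing
on the same data — the per-node mean drops by far less than one SD.

The same pipeline is scriptable from a shell:

```bash
tractdelta simulate --n-lesions 2 --alphas 0.5 --seed 7 --out phantom/
tractdelta process  --bundle phantom/bundle.tck \
    --volumes phantom/w1.nii.gz,phantom/w2_case000.nii.gz --out run/bundle.npz
tractdelta detect   --bundle run/bundle.npz --ref tp0 --zeta 0.12 --out run/report/
tractdelta evaluate --zetas 0.05,0.12 --alphas 0.2:0.8:0.2 --n-lesions 5 --out sweep/
```

Every output directory carries a `provenance.json` (config, seeds, input
digests); identical configs and seeds reproduce reports byte for byte.

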