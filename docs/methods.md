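# Methods

`kneeshape` implements a 3D imaging-biomarker pipeline for knee
osteoarthritis on triangulated, landmark-corresponded bone surfaces, and a
cross-modality (MR vs CT) agreement analysis, exercised end-to-end on a
synthetic paired-modality generator with known ground truth. This note
records the models, the defaults and why, the numerical choices, and what
the synthetic data can and cannot show.

## Shape model and scores

A population of corresponded surfaces (identical topology, ordered
landmarks) is aligned by generalized Procrustes analysis. For shape
*scoring* the alignment normalizes centroid size (the default,
`with_scale=True`), so the aligned frame is dimensionless with the mean at
centroid size ~1; this is what makes the scores scale-independent —
uniformly scaling every input surface leaves shape parameters unchanged to
1e-6. Geometric measures (bone area, joint-space width) are always taken
on the original, unnormalized surfaces in mm. The GPA initialization is
the average of the centered (size-normalized) shapes, which makes the
result invariant to population order; iteration stops when the mean moves
by less than 1e-7 (RMS per coordinate).

PCA of the flattened aligned coordinates about the Procrustes mean gives
orthonormal modes with non-increasing variances; the retained mode count
is the smallest reaching `variance_retained` (default 0.98, configurable —
the count the original models used is not public). Mode signs are fixed so
each mode's largest-magnitude training coefficient is positive, making
models bit-reproducible across runs.

The **OA vector** is the line in parameter space through the mean
parameters of a non-OA group and an OA group. A shape's score is its
signed projection onto the unit direction (positive toward OA), divided by
the standard deviation (ddof=1) of the non-OA group's projections, with
origin at the non-OA mean: a z-score in non-OA SD units. For the femur
this is the B-score (observable range roughly −3 to +7); the tibial
analogue is called the z-score here. The direction is pooled across
strata; origins and unit scales can be computed per stratum (e.g. a
sex-like key) — pooling the direction keeps it identifiable with small
per-stratum groups.

**Cross-modality pathway.** MR surfaces share the model topology and are
scored by direct projection. CT surfaces are treated as raw triangulated
targets: `fit_model_to_surface` fits the MR-trained model to the CT
surface and the fitted parameters are projected onto the MR-built OA
vector. This asymmetry — MR model fitted to the CT result, never a
CT-native model — is the method's defining step and is preserved
everywhere, including the reported fit residual (mean absolute
point-to-surface distance of the fitted instance to its target).

### Fit-to-surface

The fit alternates pose, correspondence and shape. Correspondences are
**bidirectional**: every model landmark pairs with its closest point on
the target surface, and every `reverse_stride`-th target vertex (default
3, weighted by the stride) pairs with its closest point on the current
instance, expressed in barycentric coordinates of the instance triangle.
One-directional closest-point fitting admits "sliding" fixed points —
landmark sets lying on the target surface but tangentially displaced —
which we measured at tens of percent relative error in the parameters;
the reverse constraints require the instance to cover the target and
remove them. The pose update is a closed-form similarity (rigid when the
model is not size-normalized) over the pooled pairs; the shape update is
linear least squares for b with an optional box clamp at
`|b_k| <= 3 sqrt(variance_k)` (the clamp is the exact box-constrained
minimizer in the forward term because the modes are orthonormal).
Convergence is declared when the pooled RMS paired distance, divided by
the pose scale so the criterion is independent of target size, improves by
less than `tol` (default 1e-9; the pooled RMS history is non-increasing).
Initialization matches centroid and centroid size, then refines with a
few similarity-ICP pose-only iterations — a rigid pre-alignment would be
degenerate against a size-normalized model frame.

## Geometric measures

**Regions** are named vertex-index sets on a model topology. On
corresponded surfaces they propagate by index identity; across topologies
they transfer by rigid ICP of the two mean surfaces, with a target vertex
joining the region iff its nearest transformed-source vertex is a member
within a cap of twice the target's median edge length. A triangle belongs
to a region iff all three of its vertices do (deterministic areas).

**ICP** is point-to-point and rigid, nearest-vertex correspondence via a
KD-tree, closed-form pose updates, tolerance 1e-6 mm on the RMS residual
change, at most 200 iterations. Plain centroid initialization has a
convergence basin of roughly 15 degrees, so the pose is initialized by
principal-axes alignment: the four proper axis-sign assignments each get a
15-iteration trial and the best (earliest on near-ties, so the trivial
alignment beats a symmetry flip) is refined. With this, randomly drawn
rigid perturbations up to 30 degrees / 20 mm are recovered to within
0.5 degree / 0.1 mm in 100/100 seeded trials.

**3D joint-space width** casts a ray from every central-region tibial
vertex along its outward area-weighted vertex normal (raw normals, not
smoothed; winding-orientation is made pose-robust by flipping the block if
the region's mean normal points away from the femoral centroid) and
records the first femoral intersection within `max_dist` (default 15 mm,
generous for a knee). A non-intersection is an explicit MISS, never a
sentinel distance: misses are counted, excluded from the regional mean,
and a result with more than 50% MISS is flagged invalid; zero hits is an
error. The measure is exactly invariant under a common rigid motion of
both bones, and raising the femur by Δ along the normals of a
parallel-plane fixture raises the mean by exactly Δ.

## Agreement statistics

Differences are MR minus CT throughout. Bland-Altman: bias = mean
difference, limits of agreement = bias ± z·SD (SD with n−1), z = 1.96 by
default (classic presentation; a t-quantile is configurable for small n).
CIs: bias ± z·SD/√n; LOA ± z·SD·√(3/n) (the large-sample approximation —
published CI digits are not regenerable without the raw data, and only the
exact LOA symmetry upper = 2·bias − lower is asserted against the bundled
published table). Lin's CCC uses population (1/n) moments:
2·cov/(var_x + var_y + (mean_x − mean_y)²). R² is the squared Pearson
correlation. SDD = 1.96 × SD of test-retest differences; alternative
conventions (e.g. 1.96·√2·within-subject SD) exist, and the multiplier is
configurable, but this default matters for comparability. Repeated
acquisitions of the same subject are pooled as independent pairs, a
deliberate replication of the published analysis' simplification.

## Synthetic generator

The generator is the stand-in for restricted clinical images; it emulates
mechanisms, not anatomy.

*Template.* A schematic distal femur (two condylar Gaussian lobes, a
two-facet trochlear band, a rim curling away from the joint) above a
proximal tibia (two gently dished plateau patches with a convex rolled
rim), both open rectangular-grid patches at landmark spacing 2.6 mm /
`resolution`. Central regions cMT/cLT are 11 mm discs under the condyles
and must hold ≥ 200 vertices — resolution 2 (the default) is the minimum;
at resolution 7 they reach the order of 2000 landmarks. Deliberate
asymmetries: the medial condyle is shorter anteroposteriorly than the
lateral (this is what makes external tibial rotation reposition the medial
compartment more), and the medial dish is deeper/wider than the lateral
(exact mirror symmetry would make medial/lateral registration ambiguous).
Area regions (MF/LF/MT/LT/TrFMed/TrFLat) run to the patch margin: the
convex rim is where marginal growth and offset-induced area change live.

*Severity.* Latent t ~ Uniform(−2, 7) (the observable score range); the
OA deformation field is a marginal bulge along vertex normals
(0.35 mm per unit t, e-folding 4 mm from the margin) plus partial
flattening of the dish/condylar relief (6% per unit t). This is geometric
fiction whose only purpose is to give shape scores a recoverable
ground-truth direction; bone area increases monotonically with t. Group
labels by thresholds (non-OA t ≤ 0.5, OA t ≥ 2.5, between =
intermediate) stand in for radiographic grading with no claim of
equivalence; the "moderate severity" stratum (OA with t ≤ 5.5) mirrors a
trial-like subset. Per-subject anatomy noise is a smooth random field
(SD 0.5 mm, length scale 30 mm) and sizes are lognormal (SD 5%).

*Modality rendering.* CT: truth + smooth per-scan noise (SD 0.1 mm —
inside the sub-millimetre segmentation-accuracy regime reported for these
models), extended pose plus a small whole-knee repositioning. MR: the
surface is offset **inward** by δ = 0.2 mm along vertex normals (the MR
bone boundary lies inside the CT one; the offset errors if it would flip
a triangle), warped by one shared low-frequency random displacement field
(amplitude 0.3 mm, length scale 40 mm — the field-inhomogeneity
analogue; no published magnitude exists, so this is a free parameter, not
asserted as realistic), plus noise; the femur is flexed 5 degrees and the
tibia externally rotated 15 degrees about its long axis (screw-home
analogue; positive rotation is clockwise seen from above — a right-knee
convention chosen so the medial compartment repositions more). These
mechanisms produce, by construction: MR areas smaller than CT on every
(net convex) region; joint space wider on MR by ≈ 2δ plus a
rotation-driven medial excess; and pose changes that shape scores ignore
(Procrustes removes them) while geometric measures do not.

*Test-retest.* Replicates re-render the same truth with independent noise
and a fresh small repositioning; 20 knees by default contribute replicate
pairs to the SDD.

Everything derives from `numpy.random.SeedSequence(seed)` spawns, so a
configuration is bit-reproducible, including re-rendering any single knee.

**What passing tests do and do not show.** The generator shares the real
data's *mechanisms* (inward boundary offset, smooth distortion, pose
difference, test-retest noise) but none of its anatomy, its KLG-based
group definitions, its voxel-level segmentation pathway, or its
multi-site variability. Sign and ordering results (area biases negative,
joint-space biases positive and medial-dominant, |B-score bias| < SDD)
are reproductions of mechanism, not of the published magnitudes; no
magnitude from the published table is asserted against synthetic output.

## Pipeline and problem sizes

`run_full_comparison` runs: simulate → build per-bone MR shape models →
OA vectors from the MR non-OA/OA groups → score every knee through both
pathways → six tAB areas and two 3DJSW per modality → test-retest SDD →
agreement tables (all knees, and the moderate stratum). Outputs are CSVs
(3-decimal formatted plus full-precision raw copies), the config YAML, a
provenance JSON (config hash, seed, mode counts, fit-residual summary)
and a log. Any stage failure aborts with the stage name after persisting
partial records.

Reference study conditions are n = 60 knees at resolution 2 (the spec's
stated default cohort); the byte-identical determinism check runs the
same pipeline end-to-end at n = 8, since the property does not depend on
cohort size. Score-pathway fits use max_iterations = 150, tol = 1e-9;
the parameter-recovery check runs the fit deeper (250 iterations,
tol = 1e-10).

## Known limitations

- Surface-only: no image search, no appearance model, no voxel data.
- The fit's parameter recovery is limited by genuine surface-fit
  ambiguity in low-variance modes; bidirectional correspondence bounds it
  (≤ 1–2% on in-model targets) but cannot remove it.
- The tibia z-score shows a larger synthetic cross-modality bias than the
  femur B-score, qualitatively like the published result but not
  calibrated to it.
- LOA confidence intervals use large-sample formulas; for n < ~30 the
  t-based option should be preferred.
- The generator's medial/lateral geometry is tuned only to produce the
  documented sign pattern; regional magnitudes are not anatomically
  meaningful.
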