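# Methods

This note records the models, estimators, parameter choices and known
limitations behind cortmorph's four surface indices and two statistical
stages, and what the synthetic validation does and does not establish.

## Meshes and validation

All geometry lives on oriented triangle meshes in millimeter coordinates
in an arbitrary rigid frame; no volume geometry is interpreted, since
every index here is invariant to rigid motion (and LGI to uniform
scaling).  Validation checks edge-manifoldness (every edge on at most two
faces; exactly two for closed surfaces), consistent winding (shared edges
traversed in opposite directions), absence of degenerate/duplicate faces
(area > 1e-12 mm²), and the Euler characteristic χ = V − E + F (2 for
closed genus-0 surfaces, 1 for bounded sheets).  Vertex indices are
0-based internally; 1-based file dialects are converted at the boundary.
The FreeSurfer reader supports the binary triangle variant (magic
0xFFFFFE, big-endian float32) only.

## Intrinsic curvature

**Estimator.** At each vertex a tangent frame is built from the
area-weighted vertex normal and a full quadric height function
z = ax² + bxy + cy² + dx + ey is fit by least squares over the 2-ring
neighborhood.  Principal curvatures are the eigenvalues of the exact
shape operator of that graph surface at the origin (generalized
symmetric eigenproblem of the second against the first fundamental
form), signed so convex-outward is positive.  A quadric fit is used, not
angle deficit, because the resolution filter needs k₁ and k₂ separately;
the angle-deficit estimate (exact in the Gauss–Bonnet aggregate) is kept
as an independent cross-check.  Vertices with fewer than 5 usable
neighbors or rank-deficient fits are invalidated.  The estimator's
truncation bias scales like (h/ℓ)² for mesh edge h and surface feature
wavelength ℓ; oracle fixtures are meshed at h ≲ ℓ/30 where percent-level
accuracy is asserted.

**Resolution filter.** A curvature whose osculating radius is below the
mean edge length cannot be supported by the tessellation.  A vertex is
removed when min(1/|k₁|, 1/|k₂|, 1/κ_edge) < f·(mean edge length), with
default factor f = 1.0 exposed in configuration.  κ_edge is the largest
per-edge circumscribed-circle normal curvature 2(n·(p−q))/|p−q|²
(exact on spheres); it is included because a ring-neighborhood quadric
averages away single-vertex spikes and creases that the filter exists to
catch.  The factor is a declared convention, not a value inherited from
any prior software; sensitivity to it can be swept via the config key.

**Summary.** Absolute values are taken first, then the regional
distribution of |K| on valid vertices is summarized by the population
moment skewness g₁ = m₃/m₂^{3/2} (no small-sample correction — regions
hold thousands of vertices).  g₁ is scale-free, hence dimensionless.
Summaries from fewer than 10 valid vertices are flagged unusable, never
fabricated.

## Thickness and area

Thickness at vertex i is the symmetric average of the two directed
closest distances (white_i → pial surface, pial_i → white surface) for
corresponding meshes; a directed variant is available by flag.  Closest
distance is the exact point-to-triangle minimum, KD-tree-pruned with a
provable radius bound so it matches an exhaustive scan to machine
precision.  Vertices where the surfaces locally cross (minority-sign
offsets against the pair's dominant orientation) are flagged and zeroed
rather than fatal, since real reconstructions contain rare defects; a
15 mm sanity bound flags the rest.  Finite facets bias the distance low
by the facet sagitta ≈ h²/(8R); at FreeSurfer-like 1 mm edges this is
microns.

Surface area apportions one-third of each triangle to each of its
vertices, so regional sums conserve total area exactly.  Area is
computed on the white surface by default (pial by flag), with the choice
stamped in provenance.

## Local gyrification index

The outer hull is built by voxelizing the pial interior (dense
barycentric shell rasterization; shell voxels kept only if their center
is on the inner side of the nearest surface sample, removing the
half-voxel outward bias of a touched-voxel shell), filling, and closing
with a Euclidean ball — realized exactly and fast by two distance
transforms — then marching cubes and 10 umbrella-Laplacian smoothing
iterations.  Defaults: voxel 1 mm, closing diameter 15 mm (bridges
sulci while following gyral crowns), all stamped into provenance.

At every 100th hull vertex, the LGI sample is
area(pial ∩ ball)/area(hull ∩ ball) with ball diameter 10 mm.  Patch
areas count fully-inside triangles whole and subdivide boundary
triangles once, culling sub-triangles by centroid — a second-order
approximation at millimeter triangles, covered by the analytic-oracle
tolerance in tests.  Ratios propagate to each pial vertex as the
inverse-distance-weighted mean over the samples whose ball contained it
(distance to the sample's outward normal line, floored at 1 mm);
vertices in no ball inherit the nearest sample's value and are flagged.
Regional LGI is the area-weighted vertex mean.

**Limitation.** A 10 mm ROI cannot see cortex buried deeper than ~5 mm
below the hull, so LGI is compressed for folds deeper than the ROI
radius; the 25 mm ROI common elsewhere in the literature is a first-class
configuration (`roi_diameter`).  The very-large-ROI limit reproduces the
global pial/hull area ratio exactly, which anchors the scale.

## Regions and the metrics table

Atlas parcels merge into six lobar regions (frontal 11 parcels, parietal
5, temporal 9, occipital 4, cingulate 4, insula 1) through a user-
editable mapping; the shipped composition is the conventional
gyral-parcel-to-lobe assignment and is a declared convention.  Unmapped
parcels are an error, not silently dropped.  Indices are computed per
hemisphere and averaged (SA hemispheric average is the mean; total SA is
the sum over regions and hemispheres).  A paired t-test screens each
index for left/right differences; flagged regions can be analyzed per
hemisphere.  Tables are deterministic given meshes and configuration.

## Associations

For each region and unordered index pair, an OLS model of A on B with
age and sex (optionally IQ) supplies B's coefficient, t and two-sided p;
the effect size shown in the grid is the Pearson partial correlation of
A and B given age (residual-on-residual with intercept), which equals
the single-covariate recursion formula to machine precision.  Sex is an
indicator with reference level female (alphabetical), stamped in output.
Family clustering is ignored at this stage, mirroring the cross-
sectional convention; complete cases only.  The Bonferroni cutoff is
α/m truncated to one significant figure (0.05/36 → 0.001,
0.05/24 → 0.002), with the exact value carried alongside; the rendered
grid stars cells at 1e-3 / 3e-4 / 3e-5.

## Penalized-spline mixed models

Each regional index is modeled as y = f(age) + sex + scanner
(+ total SA, + IQ, optional) + family intercept + residual.  The smooth
uses k = 10 cubic B-splines on **uniformly spaced unclamped knots** over
the observed age range with a second-difference coefficient penalty
(rank k−2).  Uniform knots are load-bearing: their equally spaced
Greville abscissae make the penalty null space exactly
{constant, linear-in-age}, so the smooth splits cleanly into an
unpenalized linear fixed term plus an iid "wiggle" random block, and the
infinite-smoothing limit reproduces the plain linear model exactly
(verified to 1e-8 against OLS).  Quantile knots would break this
identity, which is why they are not used.

Smoothing and clustering are estimated in one pass: the wiggle block
(variance σ²/λ) and the family intercepts (variance σ_f²) are random
effects, and (λ, λ_f) maximize the restricted likelihood with σ²
profiled out; optimization is Nelder–Mead on the log scale from three
starts, tolerance 1e-8.  The family variance is pinned to zero with a
warning when fewer than two families have two or more members.
Effective degrees of freedom are diag((XᵀX+P)⁻¹XᵀX); the smooth's edf
(1 = linear … k−1) is the sum over its columns.  The implementation was
cross-validated against an independent reference GAM implementation on a
shared fixture (fitted values to ~1e-5 RMSE, edf to three decimals); the
cross-check lives in the test suite only.

**Tests.** The age smooth gets a Wald-type F on the smooth coefficient
block using its posterior covariance at rank ⌈edf⌉, with residual dof
n − total edf; linear terms get t tests on the same covariance.  Both
are approximations: the smooth test's rejection rate is calibrated by
simulation (0.03–0.08 at nominal 0.05) but its p-value *distribution*
under the null is a mixture over the selected rank and is measurably
non-uniform — a known property of edf-based reference distributions, so
smooth p-values near a threshold deserve simulation-based confirmation.
Fixed-effect t p-values are uniform under the null.  Full-model R² is
the squared correlation of observed and fitted values including
predicted family intercepts, in percent.

The age×sex option fits a separate smooth per sex sharing one smoothing
parameter (implemented as sex-interacted linear and wiggle columns); IQ
enters as a linear main effect.  Fitted age curves are predicted at the
reference scanner with centered numeric covariates, per sex, with
pointwise SEs from the posterior covariance; grid points outside the
fitted range are flagged as extrapolation.

## Synthetic data

**Oracle surfaces.**  Icospheres (K = 1/r²), concentric parallel pairs
(exact thickness), developable waves z = A sin(2πx/λ) (K = 0, bending
k = f″/(1+f′²)^{3/2}), egg-crate sheets (graph-surface closed form
K = (f_xx f_yy − f_xy²)/(1+f_x²+f_y²)²), and gyrified spheres
r(u) = R + A·sin(ωu_x)sin(ωu_y)sin(ωu_z) on the unit direction u.  The
triple-sine folding field is the restriction of an analytic function of
position, hence smooth everywhere on the sphere — a latitude/longitude
sinusoid was rejected because its azimuthal wavelength collapses at the
poles, giving unbounded curvature that no refinement level can resolve.
Its exact curvature follows from the radial-surface fundamental forms
with chain-rule derivatives of the field.  Geometry fixtures:
Gauss–Bonnet uses ω = 4, A = 2 mm at R = 30 mm (resolvable at level-4
refinement, h ≈ 3 mm); the LGI amplitude sweep uses ω = 12
(fold wavelength ≈ 16 mm) at level 5.

**Synthetic subjects.**  Mirrored gyrified-sphere hemispheres with the
white surface offset 2.5 mm inward along vertex normals (parallel where
fold curvature radii ≫ offset) and six azimuthal sector regions assigned
on the left hemisphere and carried to the right by vertex
correspondence, so mirrored regions match anatomically.

**Cohorts.**  218 subjects in 126 families — 51 singletons and 75
sibling sets (58 of two, 17 of three); ages truncated-normal
(mean 16.5, SD 3.4, bounds 8–29) with females drawn 1.4 y older;
111 males; 139/79 scanner-site split; IQ ~ N(106, 14).  A latent
brain-size factor (male shift 1.2 SD) generates total SA and everything
that loads on it: regional SA (3000 mm²/SD) and, via the mediation
path, LGI (0.12 units/SD) — so sex reaches SA and LGI only through
brain size, and LGI–SA correlations are strong while curvature and
thickness are size-independent.  Index models: IC skew intercept 4.0,
+0.06/y age slope, small direct sex offset −0.10; CT 2.80 mm, −0.025
mm/y; LGI 2.60, −0.012/y; SA 20,000 mm², age-stable.  Residual and
family SDs (0.50/0.10, 0.145/0.04, 0.10/0.03, 2000/600) were calibrated
once so the fitted full-model R² lands in the 15–40% range typical of
regional morphometry at this n.  All generators are deterministic given
a seed.

**What passing tests show.**  The synthetic surfaces exercise the exact
geometric regimes the indices must distinguish (positive, zero, mixed
intrinsic curvature; folding at fixed hull), but they are far smoother
and more regular than cortex: no reconstruction noise, no topology
defects, no spatially varying thickness, a single fold scale, and
sector "regions" rather than gyral parcels.  The cohort simulator
mirrors the covariate structure and effect-size regime of a
cross-sectional developmental study but generates indices directly from
the linear-plus-smooth model family; it validates the statistical
machinery (calibration, recovery, mediation logic), not the biology.

## Problem sizes and numerical conventions

Default validation sizes: level-4 icospheres (2,562 vertices) for
curvature/thickness/area oracles; level-5 gyrified spheres (10,242
vertices) for the LGI sweep; 500-replicate null calibrations at n = 200
(GAM) and 1,000 at n = 500 (associations); 200 replicates for
variance-component recovery; 100 simulated cohorts for the mediation
pattern.  Ties and degeneracies: zero-variance IC distributions raise;
all-identical hemisphere pairs give t = 0, p = 1 by convention; the
closing radius below one voxel degenerates to no bridging; empty LGI
samples are dropped with a warning and an empty sample set raises.
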