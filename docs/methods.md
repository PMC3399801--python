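# Methods

`trabkit` reimplements, at desk scale, a comparative workflow for asking
whether subarticular trabecular bone architecture carries a locomotor
signal across anthropoid primates. The chain is: joint-scaled volume of
interest (VOI) → isodata segmentation → model-independent morphometry →
voxel-size correction of trabecular thickness → allometric
residualization against body mass → phylogenetic-signal screening
(Blomberg's K) → canonical/stepwise discriminant analysis of locomotor
groups. Because no real scan archive ships with the package, every stage
is driven and validated by synthetic phantoms with analytic ground truth.

## VOI protocol

The articular surface (a triangulated mesh) is bounded by an axis-aligned
box; the VOI centre is the box midpoint and the cube edge is 1/6 of the
proximodistal (z) height of the articular surface, so the measurement
region scales with joint size. All statistics are evaluated on the sphere
inscribed in the cube, which avoids corner effects. The cube is snapped
to the voxel grid with an odd edge count so the centre voxel is defined
(the discretization itself is our choice; the protocol does not prescribe
one). A continuum check flags VOIs whose sphere spans fewer than three
intertrabecular lengths (Tb.Th + Tb.Sp).

## Segmentation

Thresholds come from the Ridler–Calvard (isodata) fixed point
T ← (mean below + mean above)/2, iterated from the masked global mean to
a tolerance of 0.5 intensity units (≤ 100 iterations) using **only**
voxels inside the sphere. The same threshold serves every downstream
operator. `purge` keeps the largest 26-connected bone component and fills
6-connected background cavities that do not reach the sphere boundary;
dual connectivity (26 foreground / 6 background) avoids topological
paradoxes in the Euler computation. By default purging is applied only
before connectivity density, where a single component without voids is a
precondition, and is configurable elsewhere.

## Morphometry

All structural computations run on the unmasked cubic crop — so
trabeculae are not artificially cut by the spherical boundary — while all
means and counts are restricted to the sphere.

- **BV/TV** — bone voxels / sphere voxels.
- **Tb.Th, Tb.Sp** — sphere-fitting local thickness: the thickness at a
  point is the diameter of the largest sphere containing the point that
  fits in the phase. We sweep distance-transform level sets from the
  largest radius downward (a voxel within distance r of a point whose
  distance map is ≥ r lies in an r-sphere); level sets are quantised to
  at most 48 radii, bounding the discretization error well under half a
  voxel. The distance transform treats everything beyond the crop as
  background ("bounded-structure" convention): exact on phantoms whose
  plates/rods are wholly contained, conservative (thickness
  underestimated within one maximal-sphere radius of the crop face) on
  real crops that cut trabeculae. Tb.Th is the volume-weighted mean over
  the bone phase (per-voxel maps weight voxels equally, which is the
  volume weighting for isotropic voxels).
- **Tb.N** — inverse mean spacing between trabecular mid-axes. Mid-axes
  are the plateau local maxima of the distance map (a distance *ridge*;
  curve-thinning skeletons are unusable here because they collapse an
  unbounded plate to a point). Spacing is the local thickness of the
  non-axis space plus 1.5 voxels for the finite ridge width. This is
  exact on parallel plates, whose mid-surfaces sit one period apart, and
  is cross-checked against the plate-model identity
  Tb.N ≈ 1/(Tb.Th + Tb.Sp) (within 15 % on periodic phantoms). On open
  square rod lattices the maximal sphere between four axes has diameter
  √2·pitch, so the sphere-fitting spacing reads up to 41 % above the
  nearest-axis distance; Tb.N recovery is therefore validated on plate
  phantoms, where the definition is unambiguous.
- **Conn.D** — Euler characteristic χ of the (purged) bone by the
  standard 26-connectivity octant counting; for one component without
  cavities the first Betti number is β₁ = 1 − χ, and Conn.D = β₁ divided
  by the sphere volume in mm³.
- **SMI** — 6·S′·V/S² where S′ = (S(ε) − S)/ε under displacement of every
  iso-surface vertex by ε (default half a voxel) along its outward
  normal. The binary cube is Gaussian-smoothed (σ = 1 voxel) before
  marching cubes to suppress staircase facets, and only triangles whose
  centroids lie inside the sphere contribute — with edge-replication
  padding, structures spanning the VOI behave as unbounded, so an ideal
  plate carries no artificial rim area and scores 0 (rods 3, spheres 4).
- **DA** — mean intercept length (MIL). 128 quasi-uniform hemisphere
  directions (Fibonacci lattice under a seeded random rotation); per
  direction, parallel test lines at 2-voxel spacing sampled at 1-voxel
  steps through the sphere; MIL(ω) = intercepted length / number of
  bone↔background crossings. Directions with no crossings are dropped
  (legitimate for plate-parallel rays; > 20 % dropped aborts). The
  ellipsoid 1/MIL²(ω) = ωᵀAω is fitted by least squares; fabric
  eigenvalues are 1/√eig(A) and DA = mil₁/mil₃ ≥ 1. A mean intercept
  cannot exceed the sphere diameter, so measured MILs are capped there
  and eigenvalues floored at the corresponding bound — this keeps the
  tensor positive definite for ideal plates, whose in-plane MIL diverges.

All operators are scale-equivariant in the voxel size and invariant under
90° axis permutations (verified by tests).

## Voxel-size correction

Coarser voxels inflate Tb.Th through partial-volume effects. The
correction multiplies measured Tb.Th by a linear factor of voxel size;
the default coefficients are the published calibration
(factor = −4.4856·voxel + 1.0805, R² = 0.998, calibrated over
0.014–0.07 mm). Note the printed line does not pass through 1 at the
reference voxel size (f(0.014) = 1.0177); we apply it as printed rather
than rescale. `calibrate_correction` reproduces the calibration design —
measure at native resolution, Lanczos-resample (windowed sinc) to a
coarser grid, re-measure, regress the per-resolution mean ratio on voxel
size — so users with their own reference scans can fit a replacement
model. Self-calibration on phantoms confirms the ratios decrease
monotonically with voxel size.

## Body mass and allometric residuals

Body mass is estimated from femoral-head calipers with published
taxon-specific regressions: the human equations are linear in
anteroposterior breadth with sex-specific coefficients and a 0.9
downward adjustment; the remaining sets are log-linear in superoinferior
height, exponentiated and multiplied by their ratio corrections
(quasi-maximum-likelihood back-transformation bias factors). The
equation sets carry an explicit output-unit flag: the haplorhine source
regression predicts grams (a ~14 mm femoral head must map to a
howler-sized ~6 kg animal, which only the grams reading satisfies),
the others kilograms.

Size correction regresses log₁₀ of each trabecular variable on log₁₀ body
mass by one pooled OLS across all specimens; the unstandardized residuals
are the size-corrected traits entering K and the discriminant analysis.
Residuals are exactly zero on noise-free power laws and the fitted
exponent recovers the truth within two standard errors on noisy data.

## Phylogenetic signal

Blomberg's K on species means:
ā = (1ᵀC⁻¹x)/(1ᵀC⁻¹1), MSE0 = (x−ā)ᵀ(x−ā)/(n−1),
MSE = (x−ā)ᵀC⁻¹(x−ā)/(n−1), and K = (MSE0/MSE) divided by its Brownian
expectation [tr(C) − n/(1ᵀC⁻¹1)]/(n−1), where C is the Brownian
covariance of the tree (shared root-to-ancestor path lengths). Linear
solves use factorizations, never explicit inverses. K is invariant to
affine trait transforms and to global branch-length rescaling; on an
equal-branch star tree K = 1 identically, and the mean K of Brownian
simulations on the default tree is 1 within ±0.05 — the module's
parameter-recovery check. A tip-permutation randomization p-value is
provided but is statistically meaningful only from ~20 tips.

The default 8-genus tree is assembled from divergence dates
(Homo–Pan 6 Myr, Pongo 14, hylobatid 18, catarrhine 25,
cercopithecine–colobine 14, Macaca–Papio 10, platyrrhine 35), every date
overridable — the tree is configuration, not code.

## Discriminant analysis

`CanonicalDiscriminant.fit` eigen-decomposes W⁻¹B (within/between SSCP)
with functions scaled to unit pooled within-group score variance;
Wilks' Λ for successive function sets uses Bartlett's χ² approximation;
the structure matrix holds pooled within-group correlations between
variables and canonical scores. Classification minimises the Mahalanobis
distance to group means under the pooled within-group covariance,
penalised by −2·ln(prior); priors are equal by default (group sizes are
sampling artefacts), proportional on request; resubstitution is the
default report, leave-one-out available. `fit_stepwise` performs greedy
Wilks-Λ minimisation with F-to-enter 3.84 / F-to-remove 2.71 (classic
defaults of the statistical package the original workflow used).
Pairwise group separation uses
F = [(n−g−p+1)/(p(n−g))]·[nᵢnⱼ/(nᵢ+nⱼ)]·D²ᵢⱼ with DF = (p, n−g−p+1) —
for 115 specimens, 7 groups and 3 retained variables, DF = (3, 106).

Parameter recovery: with seven groups whose centroids differ by 2.5
pooled SD in at least two of five variables (minimum separation 2.5·√2),
stepwise fitting at n = 15/group classifies ≥ 90 % correctly on
resubstitution; with coincident centroids, held-out accuracy converges to
chance (1/7). Held-out evaluation is used for the chance check because
resubstitution at p = 5, g = 7, n = 105 is optimistic by ~10 points even
with zero separation. Classification agrees exactly with a brute-force
per-group Mahalanobis oracle and with an independent LDA implementation.

## Synthetic data: what it emulates, and what it does not

- **Plate/rod phantoms** — periodic slabs and square rod lattices with
  closed-form BV/TV, Tb.Th, Tb.Sp, Tb.N, SMI limits and fabric axes. Rod
  lattices are phased so axes pass through voxel centres (symmetric
  discretization).
- **Isotropic phantoms** — thresholded smoothed Gaussian random fields;
  the threshold is the (1 − BV/TV) quantile, so the realised fraction is
  essentially exact; anisotropic variants stretch the smoothing kernel.
- **Grayscale degradation** — plateau intensities 190/60 (fixed so
  isodata fixed points are predictable; real scanner scales are
  device-specific), Gaussian blur for the point-spread/partial-volume
  effect, additive Gaussian noise, all seeded.
- **Articular caps** — triangulated spherical caps, apex proximal, with
  cap area = 2πr²·coverage; they exercise the bounding-box/height logic.
- **Brownian traits / group tables** — multivariate normal draws with
  covariance σ²C(tree), and labelled draws sharing one within-group
  covariance (exactly the LDA data model).

What passing these suites shows: the operators are correct on structures
whose morphometry is known analytically, and the statistical chain
recovers parameters under its own model assumptions. What they do not
show: performance on real trabecular networks (irregular, heteroscedastic
intensity, beam hardening, ring artefacts), mesh selection by a human
operator, or classification accuracy for real locomotor groups — the
published accuracy figures are reproduced here only as worked arithmetic
on the printed classification tables, not re-derived from scans.

## Numerical choices and degenerate inputs

Isodata tolerance 0.5 intensity units; thickness level quantisation ≤ 48
radii; MIL 128 directions / 2-voxel line spacing / 1-voxel sampling step;
SMI ε = 0.5 voxel with σ = 1 voxel pre-smoothing; eigen-solves on
symmetric definite pencils; a constant image rejects thresholding;
empty phases reject thickness; a single spanning blob in Tb.N falls back
to 1/(VOI extent) with a warning; operator failures inside `summarize`
yield NaN for that variable plus an error entry in the provenance log
rather than aborting the specimen.

Problem sizes in the shipped checks (128³ phantom suites, 1000-replicate
K calibration, 100-replicate chance-level classification, 100-specimen
allometric recovery) were chosen as the sizes at which the measured
quantities plateau on pilot phantoms; all are overridable.

## Known limitations

- Thickness underestimates within one maximal-sphere radius of crop
  faces on real (boundary-cut) structures; Tb.N's sphere-fitting spacing
  overestimates nearest-axis distance on open rod lattices (see above).
- SMI is surface-curvature-based and inherits marching-cubes smoothing
  bias for features thinner than ~4 voxels.
- The default correction model is a fixed published line; applying it
  outside 0.014–0.08 mm voxels extrapolates (warned).
- The randomization p for K is underpowered at 8 taxa and is not used
  for inference, matching the original workflow's choice.
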