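# Methods

This note documents the models behind `otomorph`, the parameters that
matter, and the design choices made where the methodology was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Landmarking and semilandmark sliding

Each semicircular canal is digitized as a centerline polyline (anterior
canal from the anterior ampulla to the crus communis junction, posterior
canal from the crus junction to the posterior ampulla, lateral canal from
the lateral ampulla to its confluence with the pars inferior). Curves are
treated as piecewise linear and arc length as the chord sum; 20 landmarks
per canal are placed at equal arc-length spacing (60 per labyrinth), the six
curve endpoints fixed and the 54 interior points designated sliding
semilandmarks. Right labyrinths substitute for missing left ones after
reflection through the sagittal plane.

Sliding minimizes thin-plate-spline bending energy against the sample
consensus. The bending matrix is the upper-left block of the inverse TPS
L-matrix on the consensus landmarks with the 3D kernel U(r) = −r (the sign
that yields a positive semi-definite form; its null space is exactly the
affine maps, so only non-affine deformation is penalized). Each outer
iteration re-estimates the Procrustes consensus, then solves, per specimen,
the quadratic program for slide amounts along each semilandmark's local
tangent, caps each step at half the local landmark spacing (the tangent
linearization is only locally valid), re-projects moved points onto the
specimen's original polyline, and backtracks (step halving) if the
re-projection raised the energy. Iteration stops when the relative energy
decrease falls below `tol` (default 1e−6, `max_iter` 10) or when consensus
drift makes a step counter-productive, in which case the step is reverted
and the plateau treated as converged. Whether sliding should target a fixed
reference or an updated consensus is not settled practice; the updated
consensus was chosen as the more common modern treatment. Reported energies
are therefore non-increasing by construction.

## Alignment and ordination

Generalized Procrustes analysis removes translation, scales every
configuration to unit centroid size (centroid size = root summed squared
landmark distances from the centroid), and applies proper rotations only
(determinant +1; a mirrored chiral shape keeps a positive residual).
Consensus and rotations are iterated to 1e−10. Shapes are projected into
the tangent space by removing the component along the unit consensus vector,
and the centered tangent coordinates are decomposed by SVD (stable for
n ≪ p = 180). PC signs are fixed so each loading's largest-magnitude element
is positive, making outputs deterministic. The number of nonzero axes is at
most n − 1; the retained count k is the smallest number of PCs reaching the
95% cumulative-variance threshold (configurable).

## Time calibration and phylogenetic signal

The topology is fixed; branch durations come from fossil occurrences.
Extinction rate q is the maximum-likelihood exponential rate of taxon
stratigraphic durations (half-interval continuity correction for point
occurrences); the fossil sampling rate r follows from the singleton-taxon
fraction p1 via r = q(1 − p1)/p1, since under Poisson sampling along an
exponential lifetime the number of occupied intervals (given ≥ 1) is
geometric with success q/(q + r). Speciation is assumed equal to extinction.
Calibration is a stochastic surrogate for three-rate paleontological
time-scaling: tips sit at their last appearance, every internal node is
floored at its oldest descendant first appearance, and each internal node is
pushed root-ward by an Exponential(r) increment above the maximum of its
floor and its children's ages — so denser sampling (larger r) implies less
unsampled history and smaller extensions, and every replicate honors
stratigraphy by construction. 250 replicate trees (default) are averaged
node-age-wise into a consensus. The full branch-wise bookkeeping of the
original three-rate method is deliberately not reproduced; the scientific
role of the tree here (a plausible time-scaled phylogeny for K and PGLS) is
preserved, and the surrogate is seed-reproducible and testable.

Phylogenetic signal uses the multivariate generalization of Blomberg's K:
the ratio of ordinary to phylogenetically-corrected mean squared error about
the GLS root state (traces over all trait columns), divided by its
Brownian-motion expectation, so K = 1 under BM. Significance comes from tip
permutations with the add-one convention p = (b + 1)/(n_perm + 1) (1000
permutations by default). Ancestral states for phylomorphospace are the GLS
projections a + c_vᵀC⁻¹(X − 1a).

## Shape ~ ecology models

Procrustes ANCOVA fits shape ~ ecology + size + ecology:size with
sequential (Type I) sums of squares in that order (matching common defaults;
centroid size enters untransformed — a log-size switch was considered and
left out because the analysis chain scales shapes to unit size already, and
no transform is standard here). Significance uses residual randomization in
a permutation procedure: for each term, reduced-model residuals are permuted,
added back to the reduced fit, and the term's F recomputed; p-values use the
add-one convention and Z-scores are standard-normal quantiles of the
observed F's position in the permutation distribution. PGLS whitens the data
and all design columns by C^(−1/2) (eigendecomposition of the BM covariance)
and applies the identical machinery, so a star phylogeny reproduces the
ordinary ANCOVA exactly. All p-value families are Bonferroni-corrected;
corrected levels are truncated (not rounded) to three significant figures
for reporting (0.05/3 → 0.0166).

Because the permutation models and the CVA both require at least two
specimens per group, the pipeline drops singleton ecology groups once,
before the linear models, rather than only before the CVA.

## Classification

CVA is fitted on the first k PC scores of the training taxa: canonical axes
are generalized eigenvectors of the between/within covariance pair, scaled
to unit pooled within-group variance and sign-fixed for determinism; there
are min(g − 1, k) axes, and k is additionally capped at n − g − 1 so the
pooled within-group covariance stays invertible. Fossils of unknown ecology
are projected affinely onto the canonical axes. Group affinity uses
Mahalanobis distance under the pooled within-group covariance (per-group
covariances would demand far larger groups than comparative datasets offer).
Typicality probabilities bootstrap within-group member distances to their
own group mean (10000 draws by default; the resampling unit is the group
member, the least-assumption reading of "resampling permutations");
assignment likelihoods are equal-prior Gaussian densities normalized to
sum to 1. Confidence ellipses are chi-square(2 df) contours of a group's 2D
canonical-score covariance. Classification accuracy is reported both as
resubstitution and leave-one-out; resubstitution is optimistically biased at
small n, which the test suite demonstrates rather than hides.

## Synthetic data

The generator emulates a ~60-taxon comparative study. The template labyrinth
is three near-orthogonal circular arcs (anterior/posterior canal planes
meeting at 90°, a smaller near-horizontal lateral canal) with plausible
ampulla/crus endpoints. Landmark vectors evolve by Brownian motion along a
simulated time tree (random joins with exponential waiting times; a fraction
of tips truncated into fossils with consistent occurrence records), are
offset by a fixed orthonormal deformation field per ecology class scaled by
the effect size, and blurred with iid Gaussian landmark noise. The
deformation fields are seeded by a package constant so planted effects are
identical across runs and versions; fossil tips get ecology labels
independent of the tree so phylogeny-only and ecology-only worlds can be
simulated factorially.

Defaults: 61 taxa; group proportions 0.20/0.25/0.15/0.05/0.35
(aerial/aquatic/arboreal/fossorial/terrestrial — one dominant terrestrial
class and a rare fossorial class, mirroring typical reptile comparative
samples); bm_rate 5e−5 per coordinate per Myr and landmark noise SD 0.005
(template radius ≈ 1), giving visible but non-degenerate shape variation
over ~100-Myr trees; ecology effect size 0.3 in landmark units. A
configuration whose total deviation exceeds half the template's centroid
size is rejected as no longer a recognizable canal system. The hearing
generator draws x uniformly on [−1.2, −0.2] (the occupied band for reptiles
and birds), builds strictly linear responses with Gaussian noise (default
slope 3391.3 Hz/log-unit, intercept 4026.8 Hz, σ = 700 Hz, n = 30), and
includes one taxon with missing duct length to exercise the exclusion rule.

What the generator does *not* emulate: biomechanically realistic canal
cross-sections, digitization error correlated along curves, intraspecific
variation (one specimen per taxon), or ecology effects entangled with
phylogeny. Passing tests therefore demonstrate correctness of the machinery
and its statistical calibration under the stated model, not that real
labyrinth data meet those assumptions.

## Numerical choices and degenerate inputs

Log base 10 for the hearing transform (the convention of the source
auditory dataset; natural log exposed via configuration). Reported
frequencies are rounded half-away-from-zero at 0.1 Hz after snapping to six
decimals, because binary floats under-represent values like 330.55; full
precision is retained internally. Zero-length curves, coincident TPS
reference landmarks, degenerate (zero-size) configurations, constant shape
matrices, singleton groups, singular within-group or phylogenetic
covariances, and missing occurrence records all raise typed errors naming
the offending specimen, landmark or stage. Every stochastic operation takes
an explicit integer seed; the pipeline derives per-stage seeds from the run
seed via a seed sequence, and identical inputs + configuration + seed give
byte-identical outputs (fixed float formatting, sorted orders).

Default problem sizes in the test suite (20–61 taxa, 99–200 permutations,
200–500 replicates for calibration checks) were chosen as the smallest
scales at which the statistical properties under test are stable.

## Known limitations

- The time-calibration surrogate reproduces the estimand, not the exact
  algorithmic path, of three-rate stochastic time-scaling; interval binning
  for the duration-frequency fit is likewise idealized to continuous
  durations with a resolution parameter.
- Sliding is along-curve only (no surface semilandmarks) and stops at
  energy plateaus induced by consensus drift; it does not search past them.
- Tangent-space projection is orthogonal at the consensus; for very
  dispersed samples the small-variation assumption of tangent PCA weakens.
- The CVA assumes a shared within-group covariance; likelihood assignments
  use equal priors.
- The paper-scale dataset (61 real labyrinths and the extant hearing
  reference data) is not distributed; dataset-specific published values
  (PC percentages, K values, R² tables, the ~85% accuracy) are outside what
  this package can or does reproduce.
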