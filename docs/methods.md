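# Methods

This note documents the models and procedures implemented in `osteomorph`,
the assumptions behind them, the defaults and why they were chosen, and what
the synthetic validation does and does not demonstrate.

## Superimposition

Pairwise alignment uses the closed-form least-squares similarity transform
(Kabsch/Umeyama): rotation from the SVD of the cross-covariance with a
determinant correction so reflections are never produced, optional uniform
scale, translation from the centroids. Generalized Procrustes analysis (GPA)
iterates alignment of all configurations to an evolving mean until the RMS
change of the mean falls below `tol` (default 10⁻⁷ mm) or 100 iterations;
non-convergence warns but does not fail, because the residual mean drift at
that point is far below measurement noise. Scale is *retained* by default:
in skeletal data the first principal component is size and is biologically
meaningful (it is also the strongest sex discriminator); removal is available
via `allow_scale=True`, which normalizes configurations to unit centroid
size.

Two numerical conventions matter downstream:

* **Rotational gauge.** After convergence the mean is rotated to the
  principal axes of the mean configuration, with axis signs fixed by the
  third moment of the projected coordinates. This makes serialized models
  comparable across runs and input orderings (GPA is otherwise only defined
  up to a global rotation). Ground-truth comparisons of displacement fields
  must map template-frame fields through this gauge
  (`osteomorph.synthetic.field_in_frame`).
* **Flattening layout.** Shape vectors interleave coordinates
  (x₁,y₁,z₁,x₂,…); every matrix module depends on this layout and the model
  container records it.

Reflection negates x (inputs are required in a right-handed frame with x the
lateral axis) followed by a relabeling that maps each landmark to its
mirror-homologous partner. A non-planar configuration can only be an exact
fixed point of reflect-plus-relabel when the relabel map swaps mirror pairs;
templates are therefore built from explicit mirror pairs with
`mirror_relabel_map` providing the involution. An identity map leaves only
planar configurations fixed — a geometric fact, not a modeling choice.

## The point-distribution model

The model is the eigendecomposition of the sample covariance of the aligned
shape vectors, computed through the thin SVD of the centered data matrix
(never the explicit 3K×3K covariance; K can be 10⁴–10⁵ for dense
quasi-landmarks). Eigenvalues use the n−1 normalization; this scales λ but
no variance-fraction quantity. Modes with λ below 10⁻¹² of the leading
eigenvalue are treated as numerical null space and dropped — consequently a
sample of identical shapes has zero modes, and training rows are spanned to
sub-micron residue rather than to machine epsilon (GPA leaves a tiny
nonlinear component outside the mode span at finite deformation amplitude).

Random shapes are sampled with independent zero-mean normal weights of
variance λ_m truncated at ±3 sd. The ±3 sd default keeps samples inside the
plausible population (the variance of the truncated draw is 0.9733 λ, which
the sampling tests assert); the truncation bound is exposed because its
natural parameterization is in sd units, while variance-unit bounds are
dimensionally inconsistent.

## Goodness metrics

All four metrics are RMSE distances over corresponding points, in mm,
reported as mean ± sd:

* **Accuracy(M)**: per-training-shape RMSE of the M-mode reconstruction.
  Mode selection uses the joint rule "smallest M with accuracy ≤ 0.6 mm
  *and* cumulative variance ≥ 95%"; 0.6 mm is below the resolution of
  clinical CT, so further modes describe noise more than anatomy.
* **Compactness(M)**: cumulative eigenvalue fraction; size dominance is the
  PC1 fraction.
* **Generalization**: leave-one-out reconstruction error. GPA is re-run on
  every training subset — slower than reusing the full-sample alignment, but
  the held-out shape must not influence the fold's frame. The default fold
  fitter alternates rigid alignment and orthonormal projection (targets in
  leave-one-out are fully corresponded); the robust ICP fitter can be
  substituted. The training-size curve repeats this with `repetitions`
  (default 20) independent random target/subset draws per size.
* **Convergence rule**: the curve is smoothed with a 3-point moving average
  (raw Monte-Carlo curves are noisy), improvements are normalized per added
  training sample, and the convergence size is the smallest tabulated size
  after which every later improvement stays below 10⁻³ mm. The last grid
  point cannot witness convergence (it has no successor); a curve still
  improving at the end returns "not converged".
* **Specificity**: 10,000 sampled shapes by default; nearest training
  neighbor by corresponded-point RMSE (not surface distance — inputs are
  corresponded landmarks), computed in blocks to bound memory.

## Robust fitting

Fitting an unseen configuration alternates three steps per annealing stage:
robust rigid alignment to the current reconstruction, correspondence
estimation, and a least-squares solve of the stacked correspondence
equations P_j b = target_i − mean_j via the pseudoinverse (minimum-norm with
a warning on rank deficiency). The stage schedule doubles the active mode
count from 1 up to the 95%-variance count; each stage iterates to an RMSE
change below 10⁻⁴ mm or 10 inner iterations, and a stage-over-stage RMSE
increase above 10% aborts with the anneal trace.

Outlier handling interprets "exclusion at the 0.05 level" as a two-sided
normal-theory bound on the inlier residual distribution: points with
residual above mean + z₀.₉₇₅·sd are excluded, iterating until the mask is
stable (at most 20 passes), with failure if fewer than half the landmarks
survive. Two refinements proved necessary in practice and are deliberate
design choices:

* Inside the annealed fit, the first solve uses plain alignment on all
  points, and later iterations run a *single* exclusion pass each (seeded
  with the previous mask). Full iterative trimming against a partial
  reconstruction treats genuine, not-yet-explained deformation as outliers
  and cascades below the 50% floor; interleaving one pass per coefficient
  update lets the model explain deformation while still rejecting true
  outliers (the 6 mm bump fixtures are excluded exactly).
* Exact alignments floor the exclusion threshold at 10⁻⁹ mm so numerically
  identical configurations never lose points to rounding noise.

Fully corresponded targets use identity correspondences (flag); unlabeled
targets use bidirectional nearest-neighbor ICP with ties broken to the
lowest index for determinism. ICP inherits the usual local-minimum behavior
under large initial rotations; targets should be roughly posed first.

## Bilateral symmetry

Paired left/right bones are separate chiral structures, so *matching*
symmetry applies: mirror and relabel the left, superimpose all 2n
configurations jointly (one GPA, so all subjects share a frame), and define
per subject the consensus as the arithmetic mean of its two aligned sides.
This makes the decomposition exact: consensus + residual reproduces each
side to machine precision and the two residuals are coordinate-wise
negatives. The consensus is "perfectly symmetric" in the operational sense
that (consensus, mirrored consensus) is a perfectly symmetric pair; it is
not a reflection-invariant shape — no chiral bone is, and no averaging of
two chiral sides can be.

Asymmetry is analyzed from one residual vector per subject (the right-side
residual; using both sides would duplicate every vector with its negative).
The population-mean residual (directional asymmetry) is *not* subtracted by
default, so the leading asymmetry mode mixes directional and fluctuating
components; `center=True` isolates fluctuating asymmetry. The per-vertex map
is the across-subject mean residual magnitude, exportable as CSV or as a
color-mapped PLY for heat-map rendering.

## Sex dimorphism

Mode weights (default: the modes covering 95% of variance, size mode
included — size is a legitimate and in practice dominant sex discriminator)
are related to the ±1 sex factor three ways:

* **Canonical correlation**: with a single response this is the multiple
  correlation of sex on the weights. The reported *effect direction* is the
  canonical structure vector — the normalized cross-covariance of weights
  with sex, equal to the class-mean difference direction. The raw canonical
  weight vector is Σ⁻¹-scaled and therefore noise-amplified on low-variance
  modes; the structure vector is the stable, interpretable quantity and is
  what effect-shape visualization needs. Significance is reported both from
  Bartlett's χ² approximation and from a 1000-shuffle permutation test; the
  permutation value is authoritative because mode weights need not be
  normal. With M ≥ n/5 the solve is ridge-regularized.
* **PLS variance explained**: one-component PLS regression of the centered
  weights on sex; with a single binary predictor the captured fraction
  equals the between-class sum of squares over the total — the quantity that
  "percent of variance explained by sex" names. (Defining it as the
  predictor variance captured by the component would add within-class
  variance along the component and not recover a constructed ground-truth
  fraction.)
* **LDA leave-one-out accuracy** per class, with empirical priors. The
  leave-one-out loop is computed exactly in closed form (Sherman-Morrison
  downdate of the pooled scatter), reproducing a naive refit loop
  prediction-for-prediction at O(nM²) cost — this is what makes
  1000-permutation null calibration affordable. Singular or high-dimensional
  (M ≥ n/5) cases fall back to a per-fold shrinkage discriminant. Note two
  properties of the null distribution that calibration experiments must
  respect: unequal class counts bias per-class accuracy away from 50%
  through the prior term, and leave-one-out itself is slightly pessimistic.
* **Effect shapes**: class-mean canonical scores along the effect direction,
  amplified (default ×2) about the overall mean and reconstructed through
  the model — the male/female caricatures used for heat maps.

## Synthetic populations

The generator emulates the statistical structure of a bilateral skeletal
cohort rather than bone geometry:

* **Template**: deterministic mirror-paired point sets (ellipsoid, tube, or
  a flared "bone-like" tube ~160 mm long), centered, with an explicit
  pair-swap relabel map.
* **Size mode**: isotropic scaling about the centroid linearized as the
  radial displacement field, so it is a genuine linear PCA mode at the
  amplitudes used (a few percent size variation).
* **Tail modes**: random low-order polynomial displacement fields,
  orthonormalized against the rigid-motion subspace and the size mode so
  Procrustes alignment cannot alias them. Default tail spectrum
  (9, 4, 2, 1) mm².
* **Sex effect**: a class-mean displacement along a carrier mode (default
  mode 2) specified in Mahalanobis units relative to the within-class
  variance including consensus noise, so the optimal classification rate is
  Φ(d/2) in closed form (default d = 2 → 84.1%).
* **Asymmetry**: a Gaussian bump with compact support on the 10 landmarks
  nearest a deterministic off-midline center, directed radially, with
  subject amplitudes N(0, 2 mm²) — 2 mm is the displacement magnitude the
  localized-asymmetry recovery fixtures are specified at. An optional
  sex-linked mean amplitude realizes a requested fraction of residual
  variance explained by sex.
* **Noise and pose**: iid 0.3 mm Gaussian coordinate noise per side
  (consistent with sub-voxel segmentation error of clinical CT) and an
  independent random rigid pose per configuration.
* **Calibration**: the size-mode eigenvalue is solved so that the *consensus
  shape* population — after pair averaging halves the noise and the
  residual retains half the asymmetry — carries the requested size fraction
  (default 0.80, the long-bone regime). Defaults mirror a 271-subject cohort
  with a 181:90 male:female split.

What passing the synthetic tests shows: the pipeline recovers spectra,
subspaces, size dominance, sex effects at their analytic Bayes rate, and
localized asymmetry, under realistic noise, at desk-scale sample sizes. What
it does not show: behavior under correspondence error (landmarks here are
homologous by construction), non-Gaussian or nonlinear shape variation,
segmentation artifacts, or real anatomical covariance structure — the
convergence sizes observed on the 5-mode synthetic population (tens of
samples) are therefore smaller than what a real skeletal cohort requires
(on the order of 200), and the generalization-curve tests check *behavior*
(decay, convergence, sensitivity to spectrum richness), not those absolute
numbers.

## Reproducibility

Every randomized stage draws from a generator seeded by (root seed, CRC32 of
the stage name), so adding a stage never perturbs another, and identical
configuration plus seed yields byte-identical CSV reports. The model
container (`.npz`) round-trips mean, eigenvectors and eigenvalues
bit-faithfully. Problem sizes in the test suite (cohorts of 100–400
subjects, 40–100 landmarks; 10 curve repetitions) were chosen as the
smallest at which the statistical contracts are sharp.
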