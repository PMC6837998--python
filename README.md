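# osteomorph

Statistical shape modeling of skeletal anatomy for population studies:
point-distribution models of dense corresponded landmarks, the standard
model-goodness metrics, the training-size analysis that decides when a model
covers its population, bilateral left/right asymmetry decomposition, and
morphometric sex discrimination.

## Who this is for

Researchers in geometric morphometrics, orthopedic biomechanics, forensics
and anthropology who work with homologous 3D landmark sets (dense
quasi-landmarks placed by mapping a template onto segmented bone surfaces,
one configuration per bone per side per subject) and need to answer:

* How well does a PCA shape model describe the training anatomy, and with how
  few modes? (accuracy, compactness)
* Can it represent *unseen* members of the population, and how many training
  samples are enough? (generalization, convergence of the training-size curve)
* Does it only generate realistic shapes? (specificity)
* How do the sexes differ in shape, and how asymmetric are left and right
  bones within a subject?

## The model

Landmark configurations are superimposed by generalized Procrustes analysis
(translation and rotation removed; size retained by default, since the first
principal component of skeletal data is size and carries real signal). Each
shape vector S (ordered x, y, z coordinates of K landmarks) is then modeled
as

    S = S̄ + P b

where S̄ is the mean shape, the columns of P are the eigenvectors of the
sample covariance of the aligned shapes, and b are per-subject mode weights
with Var(b_m) = λ_m, the eigenvalues. On top of this the package computes:

* **Accuracy(M)** — mean per-shape RMSE between each training shape and its
  M-mode reconstruction; mode counts are chosen to reach a target accuracy
  (default 0.6 mm, below CT image resolution) while covering at least 95% of
  variance.
* **Compactness(M)** — cumulative explained-variance fraction; **size
  dominance** is the fraction on PC1.
* **Generalization** — leave-one-out reconstruction error, with Procrustes
  re-run on every training subset so no alignment information leaks; the
  training-size curve repeats this with growing random subsets, and a
  convergence rule (improvement < 10⁻³ mm per added sample) estimates the
  sample size needed for population coverage.
* **Specificity** — mean RMSE from 10,000 model-sampled shapes (truncated
  normal mode weights) to their nearest training member.
* **Robust fitting** — unseen targets are fitted by deterministic annealing
  over a growing mode count, with bidirectional ICP correspondences and
  iterative outlier exclusion at the 0.05 level so a localized dysmorphology
  (a "Pinocchio" bump of a few mm) cannot corrupt the global pose; the
  overdetermined correspondence equations are solved with the Moore-Penrose
  pseudoinverse.
* **Bilateral symmetry** — matching symmetry for paired bones: the left side
  is mirrored and relabeled, the pair is jointly superimposed, and each side
  splits exactly into the symmetric consensus plus an asymmetry residual;
  asymmetry is analyzed by PCA of the residuals and per-vertex maps.
* **Sex dimorphism** — canonical correlation of mode weights with sex,
  PLS variance explained by sex, leave-one-out LDA accuracy per class, and
  amplified male/female effect shapes for visualization.

A synthetic population generator (`osteomorph.synthetic`) produces bilateral
landmark cohorts with known ground truth — size-dominated spectrum, sex
effect in Mahalanobis units (so the Bayes classification rate is known in
closed form), localized asymmetry bump, measurement noise — so the whole
pipeline is testable without any data download.

## Worked example

```python
from osteomorph import (SyntheticPopulationSpec, simulate_population,
                        decompose_population, PointDistributionModel,
                        SexDimorphism)

spec = SyntheticPopulationSpec(n_subjects=271, n_landmarks=100, seed=1)
dataset, truth = simulate_population(spec)

# symmetric consensus per subject, then the shape model on the consensus set
decomps, consensus = decompose_population(dataset.pairs, dataset.relabel_map)
results = PointDistributionModel(consensus).fit()
print(results.summary())

M = results.modes_for_variance(0.95)
dim = SexDimorphism(results.training_coefficients(M),
                    [c.sex for c in consensus.configs],
                    model=results.model, structure="bone").fit(rng=0)
print(dim.summary())
```

prints

```
Point-Distribution Model Results
============================================
structure                   bone
training shapes (n)         271
landmarks (K)               100
retained modes (t)          270
scale removed               False
total variance (mm^2)       229.5546
size dominance (PC1, %)     83.16
modes for 95% variance      13
modes for 0.60 mm           13
accuracy at that M (mm)     0.3370 +/- 0.0149
============================================

Sex Dimorphism Results
============================================
structure                         bone
subjects                          271
coefficients used (M)             13
canonical r (sex-shape)           0.660
permutation p                     0.000999
Bartlett p                        2.21e-25
% variance explained by sex       3.01
% correct male (LOO LDA)          90.21
% correct female (LOO LDA)        66.23
============================================
```

Reading this: 13 eigenmodes suffice to describe every consensus shape of the
cohort to 0.34 mm (below image resolution) while covering 95% of variance;
83% of all shape variance is size (PC1), as expected for long bones. The
canonical correlation of shape with sex is 0.66 (permutation p ≈ 0.001) and
leave-one-out LDA classifies 90% of males and 66% of females correctly —
close to the Bayes rate implied by the generator's Mahalanobis-2 sex effect
given the 2:1 male:female cohort imbalance.

The same pipeline runs from the shell:

```sh
osteomorph simulate --out cohort/ --n-subjects 271 --n-landmarks 100 --seed 1
osteomorph build cohort/landmarks.csv --out model.npz
osteomorph dimorphism cohort/landmarks.csv
osteomorph run --config pipeline.json
```

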