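# Methods

This note documents the statistical model behind `spectrabench`, the
defaults and why they were chosen, the numerical conventions, and what the
synthetic data can and cannot say about real tissue spectra.

## The generative model for raw spectra

A diffuse-reflectance spectrum is a smooth function of wavelength sampled
on a uniform grid (default: 1150 points from 350.14 to 649.98 nm, ~0.26 nm
steps). The synthetic raw table reproduces the factorial acquisition
design — 12 animals × 8 tissue types × 6 spots × 30 repetitions — with each
spectrum decomposed as

    x(w) = m_c(w) + a + d(w) + s + ε(w)

| component | meaning | default |
|---|---|---|
| m_c(w) | tissue mean curve | baseline + Gaussian bumps |
| a | animal-level vertical shift, N(0, σ_a²), constant in w | σ_a = 2.0 |
| d(w) | smooth per-(animal, tissue) deviation, squared-exponential process | length 80 nm, amplitude 0.5 |
| s | spot-level vertical shift, N(0, σ_s²), constant in w | σ_s = 0.5 |
| ε(w) | repetition noise, i.i.d. per wavelength | σ_ε = 0.05 |

All quantities are in reflectance units on the 0–60 scale of the measured
data. The SD ordering σ_ε ≪ σ_s ≤ σ_a encodes the two qualitative facts the
averaging step rests on: repetitions of one spot barely vary, and spots of
one animal differ almost exclusively by a constant vertical offset. The
smooth deviation d(w) is shared by all spots of an animal (so it cancels in
spot differences) and gives each class a covariance richer than the rank-one
shift alone. Reflectance is clipped at 0 from below only; the 0–60 band is
typical, not a hard bound, so no upper clip is applied.

**Mean curves.** Each tissue's curve is a shared base curve (baseline 25,
three broad bumps) plus `separation` times a tissue-specific deviation built
from 3–6 Gaussian bumps. Deviations are normalized to unit root-mean-square
amplitude and rejection-sampled so that no two tissues' deviations have
correlation above 0.5 and no deviation exceeds 2.5 in absolute value. The
consequences are that (i) every pairwise L2 distance between mean curves
scales linearly with `separation`, with a guaranteed floor of one
`separation` unit of per-wavelength RMS difference, and (ii) curves stay
smooth and inside the plausible band. The default `separation = 6.0`
reflectance units makes tissue curves visually distinct bands on the 0–60
scale — clearly separated relative to the 2.0-unit animal shifts, as in the
measured data, where most algorithms already discriminate most tissue pairs
well.

**Seeding.** One integer seed is split (via `numpy` `SeedSequence` spawning)
into an independent substream per (animal, tissue), so any cell of the
design can be regenerated stably and the whole table is bit-reproducible.

## Averaging

The 180 spectra of one (animal, tissue) are collapsed to their unweighted
per-wavelength arithmetic mean — with a balanced design this equals the mean
of spot means. The result is 96 spectra, one per animal and tissue; rows are
sorted by (tissue, animal) so downstream splits are reproducible. No
smoothing, baseline correction, or normalization is applied.

## Gaussian estimation and simulation

Each class c is modelled as N_p(μ_c, Σ_c). The estimators are the column
mean and the mean-centered sample covariance with divisor n_c − 1. With
n_c = 12 and p = 1150 the covariance has rank ≤ 11, so sampling uses a
symmetric square-root factor: from data, the SVD of the centered class
matrix (exact, O(n²p)); from an explicit covariance, an eigendecomposition
with eigenvalues below 10⁻¹⁰·λ_max clipped to zero and anything
meaningfully negative rejected as non-positive-semidefinite. Draws are
μ̂_c + Fz with z standard normal, and therefore live exactly on the affine
subspace the data support.

Estimation datasets contain m_c = 100 draws per class (800 rows for 8
classes), with a class-stratified 50/50 train/test split; stratification
guarantees every class appears in training, which the per-class confusion
rows require. The original 96 spectra are not reused downstream. Each of
the n_datasets (default 1000) datasets draws from its own spawned
substream, so any prefix of the sequence is stable.

## PCA and the average-eigenvalue criterion

PCA is computed from the covariance of unscaled variables (all share
reflectance units), through the SVD of the centered data; eigenvector signs
are fixed by making each vector's largest-magnitude entry positive. The
score dimension q is the number of eigenvalues strictly greater than the
mean of all p eigenvalues, with a fallback of q = 1 when all are equal.
q is recomputed for every dataset — it is an outcome, not an input. By
default PCA is fit on training rows only and test rows are projected with
the training model, avoiding information leakage; a `pca_on="pooled"`
switch exists for sensitivity checks.

## Classifiers

LDA, QDA and PDA are implemented directly from their discriminant
functions (see README). Conventions:

- priors are training-class frequencies (1/8 in balanced simulations), with
  an override;
- the pooled covariance uses divisor N − C; per-class covariances n_c − 1;
- solves go through Cholesky factorizations; a factorization of a
  numerically singular matrix is rejected explicitly (smallest pivot²
  < 10⁻¹⁰ × largest pivot²), since LAPACK can otherwise succeed on a tiny
  rounded pivot;
- QDA covariances get a single jitter of 10⁻¹⁰ × mean diagonal only if
  factorization fails, and the event is logged;
- PDA penalizes with the identity matrix, Σ + λI (ridge type); a
  second-difference roughness penalty is intentionally out of scope;
- argmax ties resolve in class-label order.

KNN uses Euclidean distance; distance ties in neighbor selection break by
training-row order (stable sort), vote ties by the smallest summed distance
among tied classes, then label order — deterministic and documented rather
than random.

Tree, forest and neural-net baselines delegate to scikit-learn
(`DecisionTreeClassifier`, `RandomForestClassifier`, `MLPClassifier`),
pinned to: binary Gini splits with cost-complexity pruning; B bootstrap
trees (default 500) with mtry split candidates and majority vote; one
hidden layer of M logistic units with softmax outputs. The tree complexity
here is scikit-learn's cost-complexity `ccp_alpha`, which shares the
pruning semantics of the classical relative complexity parameter (0 = full
tree, large values = root tree) but not its scale. The network optimizer
settings (L-BFGS, 200 iterations, L2 stabilizer 10⁻⁴) are adapter defaults,
chosen for determinism and speed on few hundred rows.

## Tuning

k, λ and M are selected by fitting every grid candidate on the training
half and taking the lowest misclassification on the held-out half; the
grids are k ∈ {1..10}, λ ∈ {10⁻⁶, …, 10³}, M ∈ {1..4} on spectra and
{1..10} on PC scores. In the simulation benchmark the held-out half **is**
the test half of the same dataset, and the reported rate is the selected
candidate's rate on it — mirroring the single-split design rather than
adding a third partition. This carries an optimistic bias for the tuned
methods; it is accepted and documented. Inside cross-validation, where the
test fold must stay untouched, tuning instead uses an internal stratified
50/50 split of the training fold and the chosen value is refit on the full
fold.

mtry is searched by factor-2 stepping from floor(√p), continuing while the
out-of-bag error improves by ≥ 1% relative; ties and the final choice go to
the lowest recorded OOB error. The tree's α comes from the cost-complexity
pruning path of a deep tree (grown at 10⁻⁶), scored by internal 5-fold
cross-validation. Trees run **untuned** in the default benchmark spec list
(deep, effectively unpruned) — the benchmark's headline comparison treats
them that way, and tuned mode remains available per spec. All grid ties
resolve to the earliest candidate in grid order, favoring simpler models.

## Evaluation

The misclassification rate is the exact mismatch proportion. Confusion
matrices have true tissue in rows and predicted tissue in columns, each row
divided by its support, so rows sum to 1; zero-support rows are flagged,
never silently normalized. (The orientation follows the convention in which
row percentages sum to 1.) Averaged confusion matrices are element-wise
means over datasets. Rate vectors are summarized into the five-number
quantile summary (min, quartiles, median, max) with linear interpolation.

Repeated k-fold CV partitions the 96 averaged spectra plainly at random
(not stratified — exact stratification of 8 balanced classes into groups of
10 and 9 is impossible) into six groups of 10 and four of 9 for k = 10;
each repeat reports total errors / n (equal to the size-weighted mean of
fold rates), and the result is the mean and SD over repeats (default 50).
PCA is refit inside each training fold.

## Problem sizes used in tests and the acceptance script

The full study conditions (1150 wavelengths, 1000 datasets) are the
defaults of the respective objects. The shipped acceptance run and the
heavier tests use a deliberately scaled-down instance — a 200-point grid,
50 simulated datasets, 100-tree forests, 5 CV repeats — which preserves
every structural property being checked while keeping a complete run in
the minutes range on one core. Structural counts (17 280 / 96 / 800 / 400,
fold sizes) are checked at full scale.

## What the synthetic data do and do not show

The generator reproduces the *design* and the *correlation structure* of
the measured data (smoothness, vertical-shift dominance, within-class rank
deficiency), not the actual pig spectra: tissue mean curves are invented,
there is no optical model of absorption or scattering, and within-class
variation is exactly Gaussian by construction. Consequently, tests passing
on synthetic data validate the pipeline's correctness and reproduce the
qualitative algorithm ranking (penalized discriminant analysis on spectra
and QDA on PC scores best; untuned trees and spectra-fed neural networks
worst), but the absolute error levels are properties of the synthetic
ground truth — near-zero for most algorithms under the default separation —
and do not estimate real-tissue error rates. The Gaussian simulation also
structurally favors Gaussian-model classifiers (LDA/QDA/PDA), which is why
the pipeline includes the confirmatory cross-validation on the original
(here: synthetic original) 96 spectra as the honest small-sample check.

## Known limitations

- Non-Gaussian simulation alternatives are not implemented.
- Functional-data methods (smoothness-penalized eigenfunctions, functional
  PCA) are out of scope.
- The tuned methods' simulated rates carry the single-split optimistic bias
  described above.
- The neural-network baseline on raw spectra is known-weak by design (M
  capped at 4 for cost); it serves as a reference point, not a serious
  contender.
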