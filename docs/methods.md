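# Methods

## Model and update rules

The core is fuzzy c-means (FCM) over an $n \times d$ feature matrix with
the fuzzifier fixed at $m = 2$: the membership and center updates used here
are written in terms of squared memberships and the squared-distance ratio
$D_{ik}^2 / D_{jk}^2$, and no other fuzzifier value is expressible in that
form, so $m$ is deliberately not a parameter. Distances are squared
Euclidean from cluster center to sample.

Two semisupervised variants accept a labeled indicator $b_k$ and prior
membership columns $f_{ik}$:

* **`paper`** (default): $A'_{ik} = \frac{1}{1+\alpha}[A^{\mathrm{FCM}}_{ik}
  + \alpha f_{ik} b_k]$, then each column is renormalized to sum to one.
  This bare form omits the correction factor
  $1 + \alpha(1 - b_k \sum_j f_{jk})$ of the standard closed form, so on
  labeled columns it does not natively sum to one; renormalization restores
  column-stochasticity without changing the ranking of memberships within a
  column. The variant is kept, and kept as the default, because it is the
  update this package sets out to provide as published behavior; the
  discrepancy with the standard form is documented rather than silently
  repaired.
* **`pedrycz`**: the standard semisupervised closed form. Its membership
  update minimizes the penalized objective
  $J = \sum A^2 D^2 + \alpha \sum (A - fb)^2 D^2$ over column-stochastic
  memberships for fixed centers; descent of $J$ additionally requires the
  matching center update with weights $A_{ik}^2 + \alpha (A_{ik} - f_{ik}
  b_k)^2$, which `fit` uses in this mode. (With the plain fuzzifier-2
  weighted-mean centers instead, $J$ measurably increases on a majority of
  random instances, so pairing the two halves of the same objective is the
  only coherent choice.) For unlabeled samples the penalized weights reduce
  to $(1+\alpha) A_{ik}^2$, so with no labeled samples, or with
  $\alpha = 0$, both center updates coincide exactly and all three modes
  produce bitwise-identical trajectories from a shared initialization.

**Zero distances.** If a sample coincides with one or more centers its FCM
term is split uniformly over the zero-distance clusters and set to zero
elsewhere — the standard convention; it also makes the update scale-free.
For numerical robustness the FCM term is computed from distance ratios
normalized by the column minimum, which keeps memberships finite for
denormal or enormous distances (the update depends only on ratios).

**Convergence.** $\lVert U^t - U^{t-1} \rVert$ is read as the Chebyshev
(max absolute elementwise) norm — the cheapest norm consistent with the
unadorned notation. Defaults: $\varepsilon = 10^{-5}$, `max_iter` 100,
$\alpha = 1$. None of these has a published value; $\alpha = 1$ weights the
supervision penalty equally with the clustering term, which fully corrects
labeled pixels without distorting unlabeled ones.

**Initialization.** Unlabeled membership columns are drawn from a flat
Dirichlet with a seeded generator; labeled columns start at their priors;
centers are then computed from that membership matrix. The iteration
counter increments once per membership-plus-center sweep. Degenerate input
($n < c$) is a hard error, as is a cluster whose total squared membership
mass reaches zero.

## Image pipeline

Features default to raw pixel intensity ($d = 1$) after min-max
normalization to $[0, 1]$; an optional second feature, the edge-replicated
3×3 neighborhood mean, adds mild spatial smoothing for noisy images.
Background exclusion is a simple threshold on normalized intensity
(default 0.01) — no skull stripping or bias-field correction is attempted.
Pixels are flattened row-major; label maps reserve 0 for background and
1..c for tissue classes, written as indexed PNG (2-D) or integer NIfTI
(3-D) with exact load-back.

## Phantom generator

The phantom stands in for axial brain slices: nested axis-aligned ellipses
(semi-axes 0.42 and 0.38 of the image sides) whose radii shrink as
$\sqrt{(c-j+1)/c}$, giving every tissue class the same in-brain area —
three balanced classes by default, mirroring the coarse
CSF/gray-matter/white-matter arrangement an intensity clusterer sees. Class
means default to 0.3, 0.55 and 0.8 with additive Gaussian noise
($\sigma = 0.05$ by default; benchmarks use 0.10, about 2.5 noise SDs
between neighboring class means — a realistic moderate-SNR setting), an
optional smooth multiplicative bias field, and clipping to $[0,1]$.
Geometry depends only on shape and class count; the seed drives noise, so
ground truth is identical across seeds. What the phantom does **not**
emulate: anatomical shape variability, partial-volume voxels, lesions,
Rician noise statistics, and inter-rater label noise — passing tests here
show the algorithmic machinery is correct, not that clinical-grade accuracy
transfers to real MRI.

Supervision is sampled from the truth: $\lceil \text{fraction} \cdot n
\rceil$ in-brain pixels, stratified per class by largest-remainder
apportionment (each class at least one), with crisp priors. Stratification
avoids degenerate priors; how labeled pixels arise in practice (expert
clicks) is outside the model.

## Evaluation

Cluster indices are arbitrary, so accuracy is computed after the
agreement-maximizing cluster-to-class assignment — exhaustive over
permutations up to 8 classes, Hungarian beyond. Accuracy is percent
agreement over in-brain pixels (background excluded); per-class Dice
complements it. The benchmark scores each configuration per replicate and
averages, rather than pooling pixels across replicates. Expert reference
segmentations are replaced by phantom ground truth; wall-clock runtime is
deliberately not a metric (hardware-dependent), iteration counts are kept.

On the default benchmark (128×128, $\sigma = 0.10$, 5% supervision,
$\alpha = 1$, 10 replicates) the semisupervised modes beat plain FCM by
about 0.7 percentage points (≈86.5% vs ≈85.8%). That margin is structural,
not tunable: with near-optimal centers the semisupervised update corrects
essentially only the labeled pixels, so the gain is bounded by
(supervision fraction) × (FCM error rate) ≈ 0.05 × 14% and is insensitive
to $\alpha$. Larger gains require either more supervision or regimes where
plain FCM misplaces centers. On noiseless phantoms every mode reaches 100%.

## Cohort statistics

The clinical tables behind the imaging use case publish only group
summaries, so the tests are recomputed from summary data: pooled-variance
Student *t* from $(\bar{x}, s, n)$ pairs and uncorrected Pearson
$\chi^2 = N(ad-bc)^2/((a{+}b)(c{+}d)(a{+}c)(b{+}d))$ on 2×2 counts. These
defaults reproduce all eleven targeted published statistics at 3-decimal
rounding. The published maternal-age *t* (0.103) instead matches the Welch
statistic (pooled gives 0.097) — that row is annotated in the replication
report and excluded from the pass/fail criterion, since the remaining rows
all follow the pooled procedure. Welch and Yates variants are exposed as
options. P-values come from the reference $t$ and $\chi^2_1$ distributions;
the published p = 1.000 for the RDS row suggests an exact test was used
there, which is noted but not chased.

## Problem sizes and determinism

Default test and benchmark sizes — 128×128 phantoms (≈8.2k in-brain
pixels), 10 replicates, oracle checks at $n \le 10$, $c \le 3$ — are chosen
so the full suite and the reproduction script each run in seconds on one
CPU while keeping the noisy-phantom accuracy estimates stable to well under
0.1 percentage points (replicate SD ≈ 0.16). All randomness flows through
seeded NumPy generators: identical configuration and seed reproduce
bitwise-identical fits, phantoms, CSVs and label-map files (output files
contain no timestamps).

## Known limitations

* Fuzzifier fixed at 2; no kernelized or spatially regularized variants.
* The `paper` update's renormalization is a pragmatic repair of a
  non-stochastic update; its fixed points differ slightly from the
  `pedrycz` form on labeled columns.
* Background handling is a plain intensity threshold.
* The phantom is geometric, not anatomical; accuracy numbers on it do not
  transfer to clinical MRI.
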