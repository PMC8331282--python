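# fcmseg

Semisupervised fuzzy c-means segmentation of intensity images — built for
intensity-based tissue segmentation of brain MRI slices (e.g. grading
neonatal hypoxic-ischemic encephalopathy, HIE), but applicable to any
grayscale image whose regions differ in mean intensity. The package bundles:

* plain fuzzy c-means (FCM) and two **semisupervised membership updates**
  that exploit a handful of expert-labeled pixels,
* a seeded **synthetic phantom generator** with exact ground truth, so the
  whole pipeline is testable without any image download,
* **permutation-matched evaluation** (accuracy after optimal
  cluster-to-class assignment, per-class Dice) and a multi-mode benchmark,
* a **summary-statistics module** that recomputes, from published group
  summaries, the two-sample *t* and Pearson chi-square statistics of the
  clinical cohort that motivates the imaging use case (38 infants exposed to
  multiple antenatal dexamethasone courses vs 62 exposed to a single
  course).

## The model

Given samples $x_k \in \mathbb{R}^d$ (pixel features), FCM with fuzzifier
$m = 2$ alternates, for clusters $i = 1..c$:

$$A_{ik} = \Big[ \sum_{j=1}^{c} D_{ik}^2 / D_{jk}^2 \Big]^{-1}, \qquad
  B_i = \frac{\sum_k A_{ik}^2 x_k}{\sum_k A_{ik}^2},$$

with $D_{ik}^2 = \lVert B_i - x_k \rVert^2$, stopping when
$\lVert U^t - U^{t-1} \rVert_\infty < \varepsilon$. Partial supervision
enters through prior memberships $f_{ik}$ on labeled samples
($b_k \in \{0,1\}$) with coupling weight $\alpha \ge 0$:

* `mode="paper"` — the bare penalized update
  $A'_{ik} = \frac{1}{1+\alpha}\big[A_{ik} + \alpha f_{ik} b_k\big]$,
  renormalized per column;
* `mode="pedrycz"` — the standard closed form
  $A'_{ik} = \frac{1}{1+\alpha}\big[(1 + \alpha(1 - b_k \sum_j f_{jk}))
  A_{ik} + \alpha f_{ik} b_k\big]$, paired with the penalized center update
  so the objective
  $J = \sum_{ik} A_{ik}^2 D_{ik}^2 + \alpha \sum_{ik} (A_{ik} - f_{ik}
  b_k)^2 D_{ik}^2$ is non-increasing.

Both reduce exactly to plain FCM when $\alpha = 0$ or no sample is labeled.

## Worked example

```python
from fcmseg import (FuzzyCMeans, PhantomSpec, generate_phantom,
                    sample_supervision, extract_features, labels_to_map,
                    evaluate_segmentation)

phantom = generate_phantom(PhantomSpec(noise_sigma=0.10, seed=42))
mask = phantom.truth.labels > 0
features, index_map = extract_features(phantom.image, mask=mask)
supervision = sample_supervision(phantom.truth, fraction=0.05, seed=42)

model = FuzzyCMeans(features, n_clusters=3, mode="paper", alpha=1.0,
                    seed=0, supervision=supervision)
res = model.fit()
print(res.summary())

seg = labels_to_map(res.labels, index_map, phantom.truth.shape, mask)
report = evaluate_segmentation(seg, phantom.truth, res.iterations, "paper")
print(f"matched accuracy: {report.accuracy_percent:.2f}%")
```

prints

```
Fuzzy c-means fit
=================
mode:           paper
samples (n):    8228
features (d):   1
clusters (c):   3
alpha:          1
labeled:        412
epsilon:        1e-05
seed:           0
iterations:     30
converged:      True
final delta:    8.490e-06
centers:
  B_0: 0.280233
  B_1: 0.54928
  B_2: 0.816606
matched accuracy: 86.45%
```

The 8228 in-brain pixels of a noisy 128×128 three-tissue phantom (true
class intensities 0.3, 0.55, 0.8; noise SD 0.10) are clustered with 5% of
pixels labeled (412); the recovered centers sit on the true class means and
86.45% of pixels land in the right tissue after optimal cluster-to-class
matching. Same pipeline from a shell:

```sh
fcmseg phantom --out-dir demo --noise-sigma 0.10 --seed 42
fcmseg segment demo/image.tiff --out demo/labels.png \
    --clusters 3 --mode paper --supervision demo/supervision.png
fcmseg benchmark --out bench.csv --modes fcm,paper,pedrycz --replicates 10
fcmseg reproduce-stats
```

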