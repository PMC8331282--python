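"""Segmentation scoring against ground truth.

Cluster indices carry no meaning, so scoring first finds the cluster-to-
class assignment that maximizes total pixel agreement over the in-brain
region (truth label > 0): exhaustively over all permutations for small
class counts, by the Hungarian assignment algorithm otherwise.  Accuracy is
the matched percent pixel agreement; per-class Dice coefficients complement
it.  :func:`run_comparison` benchmarks several clustering configurations on
replicated phantoms, every configuration seeing identical images,
supervision and initialization seed within a replicate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .clustering import FitConfig, FuzzyCMeans
from .image import InputError, SegmentationMap, extract_features, labels_to_map
from .phantom import PhantomSpec, generate_phantom, sample_supervision

__all__ = [
    "EvaluationReport",
    "match_labels",
    "segmentation_accuracy",
    "dice_coefficient",
    "evaluate_segmentation",
    "run_comparison",
]

#: Class counts up to which label matching enumerates all permutations.
_EXHAUSTIVE_LIMIT = 8


@dataclass(frozen=True)
class EvaluationReport:
    """Scores of one segmentation against ground truth."""

    accuracy_percent: float
    dice_per_class: tuple
    iterations: int
    mode: str
    matching: tuple


def _contingency(
    predicted: SegmentationMap, truth: SegmentationMap
) -> np.ndarray:
    if predicted.shape != truth.shape:
        raise InputError("predicted and truth shapes differ")
    mask = truth.labels > 0
    if not mask.any():
        raise InputError("truth has no in-brain pixels")
    c = max(predicted.n_classes, truth.n_classes)
    p = predicted.labels[mask]
    t = truth.labels[mask]
    # rows: predicted class 1..c; pixels predicted as background never match
    keep = p > 0
    m = np.zeros((c, c), dtype=np.int64)
    np.add.at(m, (p[keep] - 1, t[keep] - 1), 1)
    return m


def match_labels(
    predicted: SegmentationMap, truth: SegmentationMap
) -> tuple:
    """Agreement-maximizing cluster -> class assignment.

    Returns a tuple ``perm`` with ``perm[p - 1]`` the truth class assigned
    to predicted class ``p``.  Class-count mismatches are padded with empty
    classes.  Exhaustive for up to 8 classes, Hungarian beyond.
    """
    m = _contingency(predicted, truth)
    c = m.shape[0]
    if c <= _EXHAUSTIVE_LIMIT:
        best, best_score = None, -1
        for perm in itertools.permutations(range(c)):
            score = m[range(c), perm].sum()
            if score > best_score:
                best, best_score = perm, score
        assignment = np.asarray(best)
    else:
        _, assignment = linear_sum_assignment(-m)
    return tuple(int(j) + 1 for j in assignment)


def _relabel(predicted: SegmentationMap, matching: tuple) -> np.ndarray:
    lut = np.zeros(len(matching) + 1, dtype=np.int64)
    lut[1:] = matching
    return lut[predicted.labels]


def segmentation_accuracy(
    predicted: SegmentationMap,
    truth: SegmentationMap,
    matching: Optional[tuple] = None,
) -> float:
    """Matched percent pixel agreement over the in-brain region."""
    if matching is None:
        matching = match_labels(predicted, truth)
    mask = truth.labels > 0
    relabeled = _relabel(predicted, matching)
    agree = int((relabeled[mask] == truth.labels[mask]).sum())
    return 100.0 * agree / int(mask.sum())


def dice_coefficient(
    predicted: SegmentationMap,
    truth: SegmentationMap,
    class_id: int,
    matching: Optional[tuple] = None,
) -> float:
    """Dice overlap 2|P&T| / (|P|+|T|) of one class after matching.

    Returns NaN when the class is absent from the truth (undefined).
    """
    if matching is None:
        matching = match_labels(predicted, truth)
    t = truth.labels == class_id
    if not t.any():
        return float("nan")
    p = _relabel(predicted, matching) == class_id
    return 2.0 * int((p & t).sum()) / (int(p.sum()) + int(t.sum()))


def evaluate_segmentation(
    predicted: SegmentationMap,
    truth: SegmentationMap,
    iterations: int = 0,
    mode: str = "",
) -> EvaluationReport:
    """Score one segmentation: matched accuracy and per-class Dice."""
    matching = match_labels(predicted, truth)
    acc = segmentation_accuracy(predicted, truth, matching)
    dice = tuple(
        dice_coefficient(predicted, truth, j, matching)
        for j in range(1, truth.n_classes + 1)
    )
    return EvaluationReport(
        accuracy_percent=acc,
        dice_per_class=dice,
        iterations=iterations,
        mode=mode,
        matching=matching,
    )


def run_comparison(
    spec: PhantomSpec,
    configs: Sequence[FitConfig],
    supervision_fraction: float = 0.05,
    replicates: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Benchmark clustering modes on replicated phantoms.

    For each replicate a fresh phantom (new noise realization, same
    geometry) and one supervision sample are drawn; every configuration is
    fitted on the identical feature matrix with the identical
    initialization seed, semisupervised modes receiving the identical
    supervision.  Returns one row per configuration with mean +/- SD
    accuracy, mean Dice (averaged over classes) and mean iteration count.
    """
    if not configs:
        raise InputError("need at least one configuration")
    if replicates < 1:
        raise InputError("replicates must be >= 1")
    rep_seeds = np.random.SeedSequence(seed).generate_state(3 * replicates)
    rep_seeds = (rep_seeds % np.int64(2**31)).reshape(replicates, 3)

    acc: dict[int, list] = {i: [] for i in range(len(configs))}
    dice: dict[int, list] = {i: [] for i in range(len(configs))}
    iters: dict[int, list] = {i: [] for i in range(len(configs))}
    for r in range(replicates):
        phantom_seed, sup_seed, init_seed = (int(s) for s in rep_seeds[r])
        phantom = generate_phantom(replace(spec, seed=phantom_seed))
        mask = phantom.truth.labels > 0
        features, index_map = extract_features(phantom.image, mask=mask)
        supervision = sample_supervision(
            phantom.truth, supervision_fraction, seed=sup_seed
        )
        for i, cfg in enumerate(configs):
            model = FuzzyCMeans.from_config(
                features,
                replace(cfg, seed=init_seed),
                supervision=None if cfg.mode == "fcm" else supervision,
            )
            res = model.fit()
            predicted = labels_to_map(
                res.labels, index_map, phantom.truth.shape, mask
            )
            report = evaluate_segmentation(
                predicted, phantom.truth, res.iterations, cfg.mode
            )
            acc[i].append(report.accuracy_percent)
            dice[i].append(float(np.nanmean(report.dice_per_class)))
            iters[i].append(res.iterations)

    rows = []
    for i, cfg in enumerate(configs):
        a = np.asarray(acc[i])
        rows.append(
            {
                "mode": cfg.mode,
                "accuracy_mean": a.mean(),
                "accuracy_sd": a.std(ddof=1) if replicates > 1 else 0.0,
                "dice_mean": float(np.mean(dice[i])),
                "iterations_mean": float(np.mean(iters[i])),
                "replicates": replicates,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)
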