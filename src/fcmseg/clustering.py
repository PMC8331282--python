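"""Fuzzy c-means clustering with optional partial supervision.

Implements classic fuzzy c-means (FCM) with fuzzifier m = 2 and two
semisupervised variants that pull the memberships of labeled samples toward
prior membership columns ``f`` with a coupling weight ``alpha``:

``mode="paper"``
    The bare penalized update
    ``A'_ik = (1/(1+alpha)) * [FCM_ik + alpha * f_ik * b_k]``
    followed by per-column renormalization.  This form omits the correction
    factor of the standard closed-form semisupervised update and therefore
    does not sum to one on labeled columns by itself; renormalization
    restores column-stochasticity.

``mode="pedrycz"``
    The standard semisupervised closed form
    ``A_ik = (1/(1+alpha)) * [(1 + alpha*(1 - b_k * sum_j f_jk)) * FCM_ik
    + alpha * f_ik * b_k]``,
    which minimizes the penalized objective
    ``J = sum A^2 D^2 + alpha * sum (A - f b)^2 D^2``
    over column-stochastic memberships for fixed centers.

Both variants reduce exactly to plain FCM when ``alpha = 0`` or when no
sample is labeled.  The public surface follows the model/results pattern:
build a :class:`FuzzyCMeans` from a feature matrix, call :meth:`fit`, and
read estimates off the returned :class:`FCMResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "MODES",
    "ConfigurationError",
    "DegenerateClusterError",
    "NumericalError",
    "FitConfig",
    "SupervisionInfo",
    "FuzzyCMeans",
    "FCMResults",
    "squared_distances",
    "update_membership",
    "update_centers",
    "update_centers_penalized",
    "check_convergence",
    "hard_labels",
    "pedrycz_objective",
]

MODES = ("fcm", "paper", "pedrycz")

#: Fuzzifier exponent. The update formulas use squared memberships and the
#: squared-distance ratio, so no other value is expressible here.
FUZZIFIER = 2


class ConfigurationError(ValueError):
    """Invalid parameter or shape configuration."""


class DegenerateClusterError(RuntimeError):
    """A cluster lost all membership mass (sum_k A_ik^2 == 0)."""


class NumericalError(ArithmeticError):
    """Non-finite values appeared during iteration."""


# ---------------------------------------------------------------------------
# configuration / supervision containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitConfig:
    """Parameters of one clustering run.

    Parameters
    ----------
    n_clusters : int
        Number of clusters ``c`` (>= 1).
    alpha : float
        Supervision coupling weight, >= 0.  ``alpha = 0`` reduces every mode
        to plain FCM.
    epsilon : float
        Convergence tolerance on the Chebyshev norm of the membership change.
    max_iter : int
        Iteration cap.
    seed : int
        Seed of the membership initialization.
    mode : str
        One of ``"fcm"``, ``"paper"``, ``"pedrycz"``.
    """

    n_clusters: int
    alpha: float = 1.0
    epsilon: float = 1e-5
    max_iter: int = 100
    seed: int = 0
    mode: str = "paper"

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ConfigurationError("n_clusters must be a positive integer")
        if self.alpha < 0:
            raise ConfigurationError("alpha must be nonnegative")
        if self.epsilon <= 0:
            raise ConfigurationError("epsilon must be positive")
        if self.max_iter < 1:
            raise ConfigurationError("max_iter must be a positive integer")
        if self.mode not in MODES:
            raise ConfigurationError(
                f"mode must be one of {MODES}, got {self.mode!r}"
            )

    @property
    def fuzzifier(self) -> int:
        return FUZZIFIER


@dataclass(frozen=True)
class SupervisionInfo:
    """Partial labeling of the samples.

    ``labeled`` is a length-n 0/1 vector (``b_k``); ``priors`` is a c x n
    matrix of prior memberships (``f_ik``).  Labeled columns of ``priors``
    must sum to one; unlabeled columns must be all-zero.
    """

    labeled: np.ndarray
    priors: np.ndarray

    def __post_init__(self) -> None:
        labeled = np.asarray(self.labeled)
        priors = np.asarray(self.priors, dtype=float)
        object.__setattr__(self, "labeled", labeled.astype(float))
        object.__setattr__(self, "priors", priors)
        if priors.ndim != 2 or labeled.ndim != 1:
            raise ConfigurationError("priors must be c x n, labeled length n")
        if priors.shape[1] != labeled.shape[0]:
            raise ConfigurationError("priors and labeled disagree on n")
        if not np.isin(labeled, (0.0, 1.0)).all():
            raise ConfigurationError("labeled must be a binary vector")
        if (priors < 0).any() or (priors > 1).any():
            raise ConfigurationError("prior memberships must lie in [0, 1]")
        mask = labeled.astype(bool)
        sums = priors[:, mask].sum(axis=0)
        if sums.size and not np.allclose(sums, 1.0, atol=1e-9):
            raise ConfigurationError("labeled prior columns must sum to 1")
        if priors[:, ~mask].any():
            raise ConfigurationError("unlabeled prior columns must be zero")

    @property
    def n_labeled(self) -> int:
        return int(self.labeled.sum())

    @classmethod
    def none(cls, n_clusters: int, n_samples: int) -> "SupervisionInfo":
        """All-unlabeled supervision (b_k = 0, f = 0)."""
        return cls(
            labeled=np.zeros(n_samples),
            priors=np.zeros((n_clusters, n_samples)),
        )

    @classmethod
    def from_labels(
        cls,
        labels: Sequence[int],
        n_clusters: int,
        labeled_mask: Optional[np.ndarray] = None,
    ) -> "SupervisionInfo":
        """Crisp supervision from integer class labels.

        ``labels`` holds a class index in ``0..c-1`` per sample; samples
        where ``labeled_mask`` is False (or label < 0) stay unlabeled.
        """
        labels = np.asarray(labels)
        n = labels.shape[0]
        if labeled_mask is None:
            labeled_mask = labels >= 0
        labeled_mask = np.asarray(labeled_mask, dtype=bool)
        priors = np.zeros((n_clusters, n))
        idx = np.flatnonzero(labeled_mask)
        priors[labels[idx], idx] = 1.0
        return cls(labeled=labeled_mask.astype(float), priors=priors)


# ---------------------------------------------------------------------------
# elementary update operations
# ---------------------------------------------------------------------------


def squared_distances(data: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances from each center to each sample.

    Returns a c x n matrix with entry ``(i, k) = ||B_i - x_k||^2``.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if data.shape[1] != centers.shape[1]:
        raise ConfigurationError(
            f"dimensionality mismatch: data has d={data.shape[1]}, "
            f"centers have d={centers.shape[1]}"
        )
    diff = centers[:, None, :] - data[None, :, :]
    out = np.einsum("ikd,ikd->ik", diff, diff)
    # exact zeros matter for the zero-distance convention; clamp rounding dust
    return np.maximum(out, 0.0)


def _fcm_term(dist_sq: np.ndarray) -> np.ndarray:
    """Classic fuzzifier-2 memberships 1 / sum_j (D_ik^2 / D_jk^2).

    Columns containing one or more exact zero distances follow the
    zero-distance convention: membership is split uniformly over the
    zero-distance clusters and is zero elsewhere.
    """
    dist_sq = np.asarray(dist_sq, dtype=float)
    if (dist_sq < 0).any():
        raise ConfigurationError("squared distances must be nonnegative")
    out = np.empty_like(dist_sq)
    zero = dist_sq == 0.0
    singular = zero.any(axis=0)
    regular = ~singular
    if regular.any():
        sub = dist_sq[:, regular]
        # scale each column by its smallest distance: the update depends
        # only on distance ratios, and this keeps 1/d^2 finite for
        # denormal or huge inputs (ratios that still overflow mean a
        # cluster infinitely farther than the nearest; it gets 0)
        with np.errstate(over="ignore"):
            ratio = sub / sub.min(axis=0)
            inv = 1.0 / ratio
        out[:, regular] = inv / inv.sum(axis=0)
    if singular.any():
        z = zero[:, singular].astype(float)
        out[:, singular] = z / z.sum(axis=0)
    return out


def update_membership(
    dist_sq: np.ndarray,
    supervision: Optional[SupervisionInfo],
    alpha: float,
    mode: str,
) -> np.ndarray:
    """One membership update; returns a column-stochastic c x n matrix."""
    if mode not in MODES:
        raise ConfigurationError(f"unknown mode {mode!r}")
    base = _fcm_term(dist_sq)
    if mode == "fcm":
        return base / base.sum(axis=0)
    c, n = base.shape
    if supervision is None:
        supervision = SupervisionInfo.none(c, n)
    if supervision.priors.shape != (c, n):
        raise ConfigurationError(
            f"supervision priors shape {supervision.priors.shape} does not "
            f"match distances shape {(c, n)}"
        )
    b = supervision.labeled
    f = supervision.priors
    if mode == "paper":
        u = (base + alpha * f * b) / (1.0 + alpha)
    else:  # pedrycz
        correction = 1.0 + alpha * (1.0 - b * f.sum(axis=0))
        u = (correction * base + alpha * f * b) / (1.0 + alpha)
    return u / u.sum(axis=0)


def update_centers(memberships: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Fuzzifier-2 weighted-mean center update.

    ``B_i = sum_k A_ik^2 x_k / sum_k A_ik^2``; each center is a convex
    combination of the samples and therefore lies in the data bounding box.
    """
    u = np.asarray(memberships, dtype=float)
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if u.shape[1] != data.shape[0]:
        raise ConfigurationError(
            f"memberships cover {u.shape[1]} samples but data has "
            f"{data.shape[0]} rows"
        )
    w = u**2
    mass = w.sum(axis=1)
    dead = np.flatnonzero(mass <= 0)
    if dead.size:
        raise DegenerateClusterError(
            f"cluster {dead[0]} has zero total squared membership"
        )
    return (w @ data) / mass[:, None]


def update_centers_penalized(
    memberships: np.ndarray,
    data: np.ndarray,
    supervision: SupervisionInfo,
    alpha: float,
) -> np.ndarray:
    """Center update matching the penalized objective of ``pedrycz`` mode.

    ``B_i = sum_k w_ik x_k / sum_k w_ik`` with
    ``w_ik = A_ik^2 + alpha (A_ik - f_ik b_k)^2``, the exact minimizer of
    the penalized objective over centers for fixed memberships; together
    with the ``pedrycz`` membership update this makes the objective
    non-increasing.  For unlabeled samples the weights are
    ``(1 + alpha) A_ik^2``, so with no labeled samples (or ``alpha = 0``)
    the centers coincide with :func:`update_centers`.
    """
    u = np.asarray(memberships, dtype=float)
    data = np.atleast_2d(np.asarray(data, dtype=float))
    fb = supervision.priors * supervision.labeled
    w = u**2 + alpha * (u - fb) ** 2
    mass = w.sum(axis=1)
    dead = np.flatnonzero(mass <= 0)
    if dead.size:
        raise DegenerateClusterError(
            f"cluster {dead[0]} has zero total membership weight"
        )
    return (w @ data) / mass[:, None]


def check_convergence(
    current: np.ndarray, previous: np.ndarray, epsilon: float
) -> tuple[bool, float]:
    """Chebyshev-norm stopping rule ``max |U^t - U^(t-1)| < epsilon``."""
    current = np.asarray(current, dtype=float)
    previous = np.asarray(previous, dtype=float)
    if current.shape != previous.shape:
        raise ValueError(
            f"membership shapes differ: {current.shape} vs {previous.shape}"
        )
    delta = float(np.abs(current - previous).max())
    return delta < epsilon, delta


def hard_labels(memberships: np.ndarray) -> np.ndarray:
    """Per-sample argmax cluster label; ties go to the lowest index."""
    return np.argmax(np.asarray(memberships), axis=0)


def pedrycz_objective(
    memberships: np.ndarray,
    dist_sq: np.ndarray,
    supervision: SupervisionInfo,
    alpha: float,
) -> float:
    """Penalized objective J = sum A^2 D^2 + alpha sum (A - f b)^2 D^2."""
    u = np.asarray(memberships, dtype=float)
    d2 = np.asarray(dist_sq, dtype=float)
    fb = supervision.priors * supervision.labeled
    return float((u**2 * d2).sum() + alpha * ((u - fb) ** 2 * d2).sum())


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class FuzzyCMeans:
    """Fuzzy c-means model over a feature matrix.

    Parameters
    ----------
    data : array_like, shape (n, d)
        One row per sample.  1-D input is treated as n samples of one
        feature.
    n_clusters : int
        Number of clusters ``c``; requires ``n >= c``.
    mode : {"fcm", "paper", "pedrycz"}
        Plain FCM or one of the semisupervised updates (see module
        docstring).
    alpha, epsilon, max_iter, seed
        See :class:`FitConfig`.
    supervision : SupervisionInfo, optional
        Partial labels; ignored in ``"fcm"`` mode, treated as all-unlabeled
        when absent in the semisupervised modes.

    Examples
    --------
    >>> x = np.r_[np.zeros(5), np.full(5, 10.0)]
    >>> res = FuzzyCMeans(x, n_clusters=2, mode="fcm").fit()
    >>> sorted(np.round(res.centers.ravel(), 6))
    [0.0, 10.0]
    """

    def __init__(
        self,
        data: np.ndarray,
        n_clusters: int = 2,
        *,
        mode: str = "paper",
        alpha: float = 1.0,
        epsilon: float = 1e-5,
        max_iter: int = 100,
        seed: int = 0,
        supervision: Optional[SupervisionInfo] = None,
    ) -> None:
        config = FitConfig(
            n_clusters=n_clusters,
            alpha=alpha,
            epsilon=epsilon,
            max_iter=max_iter,
            seed=seed,
            mode=mode,
        )
        self._init(data, config, supervision)

    def _init(self, data, config, supervision):
        arr = np.asarray(data, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.ndim != 2:
            raise ConfigurationError("data must be an n x d matrix")
        if not np.isfinite(arr).all():
            raise ConfigurationError("data must be finite")
        if arr.shape[0] < config.n_clusters:
            raise ConfigurationError(
                f"need at least n_clusters={config.n_clusters} samples, "
                f"got n={arr.shape[0]}"
            )
        if supervision is not None:
            if supervision.priors.shape != (config.n_clusters, arr.shape[0]):
                raise ConfigurationError(
                    "supervision shape does not match (n_clusters, n)"
                )
        self.data = arr
        self.config = config
        self.supervision = supervision

    @classmethod
    def from_config(
        cls,
        data: np.ndarray,
        config: FitConfig,
        supervision: Optional[SupervisionInfo] = None,
    ) -> "FuzzyCMeans":
        model = cls.__new__(cls)
        model._init(data, config, supervision)
        return model

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def _initial_memberships(self, rng: np.random.Generator) -> np.ndarray:
        """Seeded start: flat-Dirichlet columns; labeled columns = priors."""
        c, n = self.config.n_clusters, self.n_samples
        u = rng.dirichlet(np.ones(c), size=n).T
        sup = self._effective_supervision()
        if sup is not None:
            mask = sup.labeled.astype(bool)
            u[:, mask] = sup.priors[:, mask]
        return u

    def _effective_supervision(self) -> Optional[SupervisionInfo]:
        if self.config.mode == "fcm":
            return None
        return self.supervision

    def fit(
        self,
        seed: Optional[int] = None,
        initial_memberships: Optional[np.ndarray] = None,
    ) -> "FCMResults":
        """Run the alternating update loop to convergence or ``max_iter``.

        Parameters
        ----------
        seed : int, optional
            Overrides the config seed for initialization.
        initial_memberships : array_like, optional
            Explicit c x n starting memberships (bypasses the seeded
            initialization); must be column-stochastic.
        """
        cfg = self.config
        if seed is not None:
            cfg = replace(cfg, seed=seed)
        sup = self._effective_supervision()
        if cfg.mode != "fcm" and sup is None:
            sup = SupervisionInfo.none(cfg.n_clusters, self.n_samples)

        if initial_memberships is None:
            rng = np.random.default_rng(cfg.seed)
            u = self._initial_memberships(rng)
        else:
            u = np.array(initial_memberships, dtype=float)
            if u.shape != (cfg.n_clusters, self.n_samples):
                raise ConfigurationError(
                    "initial_memberships must be (n_clusters, n)"
                )
        # pedrycz mode pairs its membership update with the penalized center
        # update so the objective descends; with no labels or alpha=0 both
        # center updates coincide and all modes reduce to plain FCM exactly
        penalized = (
            cfg.mode == "pedrycz"
            and cfg.alpha > 0
            and sup is not None
            and sup.n_labeled > 0
        )

        def centers_step(memberships):
            if penalized:
                return update_centers_penalized(
                    memberships, self.data, sup, cfg.alpha
                )
            return update_centers(memberships, self.data)

        centers = centers_step(u)
        delta_trace: list[float] = []
        converged = False
        iterations = 0
        for iterations in range(1, cfg.max_iter + 1):
            dist_sq = squared_distances(self.data, centers)
            u_new = update_membership(dist_sq, sup, cfg.alpha, cfg.mode)
            centers = centers_step(u_new)
            converged, delta = check_convergence(u_new, u, cfg.epsilon)
            delta_trace.append(delta)
            u = u_new
            if converged:
                break
        if not (np.isfinite(u).all() and np.isfinite(centers).all()):
            raise NumericalError("non-finite values during iteration")
        return FCMResults(
            model=self,
            memberships=u,
            centers=centers,
            iterations=iterations,
            converged=converged,
            delta_trace=tuple(delta_trace),
            config=cfg,
        )


@dataclass(frozen=True)
class FCMResults:
    """Estimates from one :meth:`FuzzyCMeans.fit` run."""

    model: FuzzyCMeans
    memberships: np.ndarray
    centers: np.ndarray
    iterations: int
    converged: bool
    delta_trace: tuple
    config: FitConfig
    labels: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", hard_labels(self.memberships))

    @property
    def final_delta(self) -> float:
        return self.delta_trace[-1] if self.delta_trace else math.nan

    def objective(self) -> float:
        """Penalized objective at the fitted state (plain-FCM J if alpha=0)."""
        sup = self.model._effective_supervision()
        if sup is None:
            sup = SupervisionInfo.none(
                self.config.n_clusters, self.model.n_samples
            )
        dist_sq = squared_distances(self.model.data, self.centers)
        return pedrycz_objective(
            self.memberships, dist_sq, sup, self.config.alpha
        )

    def summary(self) -> str:
        cfg = self.config
        sup = self.model._effective_supervision()
        n_lab = sup.n_labeled if sup is not None else 0
        lines = [
            "Fuzzy c-means fit",
            "=================",
            f"mode:           {cfg.mode}",
            f"samples (n):    {self.model.n_samples}",
            f"features (d):   {self.model.n_features}",
            f"clusters (c):   {cfg.n_clusters}",
            f"alpha:          {cfg.alpha:g}",
            f"labeled:        {n_lab}",
            f"epsilon:        {cfg.epsilon:g}",
            f"seed:           {cfg.seed}",
            f"iterations:     {self.iterations}",
            f"converged:      {self.converged}",
            f"final delta:    {self.final_delta:.3e}",
            "centers:",
        ]
        for i, row in enumerate(np.atleast_2d(self.centers)):
            lines.append(
                f"  B_{i}: " + ", ".join(f"{v:.6g}" for v in row)
            )
        return "\n".join(lines)

    def plot_convergence(self, ax=None):
        """Plot the membership-change trace against iteration number."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.semilogy(
            range(1, len(self.delta_trace) + 1), self.delta_trace, "o-"
        )
        ax.axhline(self.config.epsilon, ls="--", color="grey")
        ax.set_xlabel("iteration")
        ax.set_ylabel(r"$\max |U^t - U^{t-1}|$")
        ax.set_title(f"mode={self.config.mode}")
        return ax
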