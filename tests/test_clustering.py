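"""Unit and property tests of the clustering updates and the fit loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from hypothesis.extra.numpy import arrays

from fcmseg.clustering import (
    ConfigurationError,
    DegenerateClusterError,
    FitConfig,
    FuzzyCMeans,
    SupervisionInfo,
    check_convergence,
    hard_labels,
    pedrycz_objective,
    squared_distances,
    update_centers,
    update_centers_penalized,
    update_membership,
)

# ---------------------------------------------------------------------------
# independent scalar-loop oracles
# ---------------------------------------------------------------------------


def dist_oracle(data, centers):
    c, n, d = len(centers), len(data), len(data[0])
    out = np.zeros((c, n))
    for i in range(c):
        for k in range(n):
            out[i, k] = sum(
                (centers[i][m] - data[k][m]) ** 2 for m in range(d)
            )
    return out


def membership_oracle(dist_sq, sup, alpha, mode):
    c, n = dist_sq.shape
    out = np.zeros((c, n))
    for k in range(n):
        zeros = [i for i in range(c) if dist_sq[i, k] == 0.0]
        for i in range(c):
            if zeros:
                base = 1.0 / len(zeros) if i in zeros else 0.0
            else:
                base = 1.0 / sum(
                    dist_sq[i, k] / dist_sq[j, k] for j in range(c)
                )
            if mode == "fcm":
                out[i, k] = base
            elif mode == "paper":
                out[i, k] = (
                    base + alpha * sup.priors[i, k] * sup.labeled[k]
                ) / (1.0 + alpha)
            else:  # pedrycz
                corr = 1.0 + alpha * (
                    1.0
                    - sup.labeled[k]
                    * sum(sup.priors[j, k] for j in range(c))
                )
                out[i, k] = (
                    corr * base + alpha * sup.priors[i, k] * sup.labeled[k]
                ) / (1.0 + alpha)
        out[:, k] /= out[:, k].sum()
    return out


def centers_oracle(u, data):
    c, n = u.shape
    d = data.shape[1]
    out = np.zeros((c, d))
    for i in range(c):
        mass = sum(u[i, k] ** 2 for k in range(n))
        for m in range(d):
            out[i, m] = (
                sum(u[i, k] ** 2 * data[k, m] for k in range(n)) / mass
            )
    return out


def random_instance(seed, with_labels=True):
    g = np.random.default_rng(seed)
    n = int(g.integers(3, 11))
    c = int(g.integers(2, 4))
    d = int(g.integers(1, 4))
    data = g.normal(size=(n, d))
    centers = g.normal(size=(c, d))
    if with_labels:
        labels = np.where(g.random(n) < 0.4, g.integers(0, c, n), -1)
    else:
        labels = np.full(n, -1)
    sup = SupervisionInfo.from_labels(labels, c)
    return data, centers, sup


# ---------------------------------------------------------------------------
# squared distances
# ---------------------------------------------------------------------------


def test_distance_zero_when_center_equals_sample():
    d = squared_distances([[1.0, 2.0]], [[1.0, 2.0]])
    assert d[0, 0] == 0.0


def test_distance_hand_checked_1d():
    d = squared_distances(np.array([[0.0], [4.0]]), np.array([[0.0], [4.0]]))
    np.testing.assert_array_equal(d, [[0.0, 16.0], [16.0, 0.0]])


@pytest.mark.parametrize("seed", range(5))
def test_distance_matches_loop_oracle(seed):
    g = np.random.default_rng(seed)
    data, centers = g.normal(size=(5, 3)), g.normal(size=(2, 3))
    np.testing.assert_allclose(
        squared_distances(data, centers),
        dist_oracle(data, centers),
        atol=1e-12,
    )


def test_distance_dimension_mismatch():
    with pytest.raises(ConfigurationError, match="dimensionality"):
        squared_distances(np.zeros((4, 2)), np.zeros((2, 3)))


# ---------------------------------------------------------------------------
# membership update
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("mode", ["fcm", "paper", "pedrycz"])
def test_equidistant_unlabeled_is_uniform(mode):
    dist_sq = np.array([[4.0], [4.0]])
    sup = SupervisionInfo.none(2, 1)
    u = update_membership(dist_sq, sup, 1.0, mode)
    np.testing.assert_allclose(u[:, 0], [0.5, 0.5])


def test_coincident_sample_gets_crisp_membership():
    dist_sq = np.array([[0.0], [9.0]])
    u = update_membership(dist_sq, None, 0.0, "fcm")
    np.testing.assert_array_equal(u[:, 0], [1.0, 0.0])


def test_zero_distance_split_over_tied_centers():
    dist_sq = np.array([[0.0], [0.0], [4.0]])
    u = update_membership(dist_sq, None, 0.0, "fcm")
    np.testing.assert_allclose(u[:, 0], [0.5, 0.5, 0.0])


@pytest.mark.parametrize("mode", ["paper", "pedrycz"])
def test_alpha_zero_collapses_to_fcm(mode):
    g = np.random.default_rng(1)
    dist_sq = g.random((3, 6)) + 0.1
    sup = SupervisionInfo.from_labels([0, 1, 2, -1, -1, 0], 3)
    u0 = update_membership(dist_sq, None, 0.0, "fcm")
    u = update_membership(dist_sq, sup, 0.0, mode)
    np.testing.assert_array_equal(u, u0)


@pytest.mark.parametrize("mode", ["fcm", "paper", "pedrycz"])
@pytest.mark.parametrize("seed", range(4))
def test_membership_matches_scalar_oracle(mode, seed):
    data, centers, sup = random_instance(seed)
    dist_sq = squared_distances(data, centers)
    u = update_membership(dist_sq, sup, 1.0, mode)
    np.testing.assert_allclose(
        u, membership_oracle(dist_sq, sup, 1.0, mode), atol=1e-10
    )


def test_labeled_crisp_prior_small_case():
    # 3 clusters, 4 samples, alpha=1, one labeled sample with a crisp prior
    dist_sq = np.array(
        [[1.0, 2.0, 4.0, 1.0], [2.0, 1.0, 1.0, 3.0], [4.0, 4.0, 2.0, 2.0]]
    )
    sup = SupervisionInfo.from_labels([2, -1, -1, -1], 3)
    for mode in ("paper", "pedrycz"):
        u = update_membership(dist_sq, sup, 1.0, mode)
        np.testing.assert_allclose(
            u, membership_oracle(dist_sq, sup, 1.0, mode), atol=1e-12
        )
        # supervision must dominate the labeled column
        assert u[:, 0].argmax() == 2


@settings(max_examples=50, deadline=None)
@given(
    dist_sq=arrays(
        float,
        (3, 5),
        elements=hst.floats(0.0, 100.0, allow_nan=False),
    ),
    alpha=hst.floats(0.0, 10.0),
    mode=hst.sampled_from(["fcm", "paper", "pedrycz"]),
)
def test_columns_sum_to_one(dist_sq, alpha, mode):
    sup = SupervisionInfo.from_labels([0, 1, 2, -1, -1], 3)
    if (dist_sq.sum(axis=0) == 0).any():
        dist_sq = dist_sq + np.where(dist_sq.sum(axis=0) == 0, 1.0, 0.0)
    u = update_membership(dist_sq, sup, alpha, mode)
    np.testing.assert_allclose(u.sum(axis=0), 1.0, atol=1e-9)
    assert ((u >= 0) & (u <= 1 + 1e-12)).all()


# ---------------------------------------------------------------------------
# center update
# ---------------------------------------------------------------------------


def test_crisp_memberships_give_hard_means(blobs):
    data, labels = blobs
    u = np.zeros((3, len(data)))
    u[labels, np.arange(len(data))] = 1.0
    centers = update_centers(u, data)
    for i in range(3):
        np.testing.assert_allclose(centers[i], data[labels == i].mean(axis=0))


def test_uniform_memberships_give_global_mean(rng):
    data = rng.normal(size=(10, 2))
    u = np.full((4, 10), 0.25)
    centers = update_centers(u, data)
    for row in centers:
        np.testing.assert_allclose(row, data.mean(axis=0))


@pytest.mark.parametrize("seed", range(4))
def test_centers_match_loop_oracle_and_bounding_box(seed):
    g = np.random.default_rng(seed)
    data = g.normal(size=(6, 2))
    u = g.dirichlet(np.ones(3), size=6).T
    centers = update_centers(u, data)
    np.testing.assert_allclose(centers, centers_oracle(u, data), atol=1e-12)
    assert (centers >= data.min(axis=0) - 1e-12).all()
    assert (centers <= data.max(axis=0) + 1e-12).all()


def test_degenerate_cluster_raises_with_index():
    u = np.array([[1.0, 1.0], [0.0, 0.0]])
    with pytest.raises(DegenerateClusterError, match="cluster 1"):
        update_centers(u, np.zeros((2, 1)))


# ---------------------------------------------------------------------------
# convergence check and hard labels
# ---------------------------------------------------------------------------


def test_identical_matrices_converge():
    u = np.full((2, 3), 0.5)
    ok, delta = check_convergence(u, u, 1e-12)
    assert ok and delta == 0.0


def test_single_entry_difference():
    u = np.full((2, 2), 0.5)
    v = u.copy()
    v[0, 0] += 0.01
    ok, delta = check_convergence(v, u, 0.001)
    assert not ok
    assert delta == pytest.approx(0.01)


def test_delta_is_chebyshev_norm(rng):
    a, b = rng.random((3, 7)), rng.random((3, 7))
    _, delta = check_convergence(a, b, 1.0)
    expected = max(
        abs(a[i, k] - b[i, k]) for i in range(3) for k in range(7)
    )
    assert delta == expected


def test_convergence_shape_mismatch():
    with pytest.raises(ValueError, match="shapes differ"):
        check_convergence(np.zeros((2, 3)), np.zeros((3, 2)), 1e-5)


def test_hard_labels_and_tie_break(rng):
    assert hard_labels(np.array([[0.7], [0.3]]))[0] == 0
    assert hard_labels(np.array([[0.5], [0.5]]))[0] == 0  # tie -> lowest
    u = rng.dirichlet(np.ones(4), size=20).T
    expected = [max(range(4), key=lambda i: u[i, k]) for k in range(20)]
    np.testing.assert_array_equal(hard_labels(u), expected)


# ---------------------------------------------------------------------------
# fit loop
# ---------------------------------------------------------------------------


def test_two_blob_fit_recovers_centers():
    g = np.random.default_rng(0)
    data = np.r_[g.normal(0.0, 0.01, 100), g.normal(10.0, 0.01, 100)]
    res = FuzzyCMeans(data, 2, mode="fcm", seed=0).fit()
    centers = np.sort(res.centers.ravel())
    assert abs(centers[0] - data[:100].mean()) < 0.1
    assert abs(centers[1] - data[100:].mean()) < 0.1
    assert res.converged


def test_identical_points_single_cluster():
    data = np.full(8, 3.25)
    res = FuzzyCMeans(data, 1, mode="fcm").fit()
    assert res.centers[0, 0] == pytest.approx(3.25)
    assert res.converged and res.iterations <= 2


def test_fit_is_deterministic(blobs):
    data, labels = blobs
    sup = SupervisionInfo.from_labels(
        np.where(np.arange(75) % 7 == 0, labels, -1), 3
    )
    runs = [
        FuzzyCMeans(data, 3, mode="paper", seed=42, supervision=sup).fit()
        for _ in range(2)
    ]
    assert (runs[0].memberships == runs[1].memberships).all()
    assert (runs[0].centers == runs[1].centers).all()
    assert runs[0].delta_trace == runs[1].delta_trace
    assert runs[0].iterations == runs[1].iterations


def test_fit_result_contracts(blobs):
    data, _ = blobs
    res = FuzzyCMeans(data, 3, mode="fcm", max_iter=50).fit()
    assert res.iterations <= 50
    if res.converged:
        assert res.delta_trace[-1] < res.config.epsilon
    np.testing.assert_allclose(res.memberships.sum(axis=0), 1.0, atol=1e-9)
    assert (res.centers >= data.min(axis=0) - 1e-12).all()
    assert (res.centers <= data.max(axis=0) + 1e-12).all()


@pytest.mark.parametrize("mode", ["paper", "pedrycz"])
def test_reduction_alpha_zero_is_bitwise(blobs, mode):
    data, labels = blobs
    sup = SupervisionInfo.from_labels(
        np.where(np.arange(75) % 5 == 0, labels, -1), 3
    )
    u0 = np.random.default_rng(1).dirichlet(np.ones(3), size=75).T
    ref = FuzzyCMeans(data, 3, mode="fcm").fit(initial_memberships=u0)
    res = FuzzyCMeans(
        data, 3, mode=mode, alpha=0.0, supervision=sup
    ).fit(initial_memberships=u0)
    assert (res.memberships == ref.memberships).all()
    assert (res.centers == ref.centers).all()


@pytest.mark.parametrize("mode", ["paper", "pedrycz"])
def test_reduction_without_labels(blobs, mode):
    data, _ = blobs
    u0 = np.random.default_rng(2).dirichlet(np.ones(3), size=75).T
    ref = FuzzyCMeans(data, 3, mode="fcm").fit(initial_memberships=u0)
    res = FuzzyCMeans(
        data, 3, mode=mode, alpha=1.0,
        supervision=SupervisionInfo.none(3, 75),
    ).fit(initial_memberships=u0)
    np.testing.assert_allclose(
        res.memberships, ref.memberships, atol=1e-12
    )


@pytest.mark.parametrize("seed", range(6))
def test_pedrycz_objective_nonincreasing(seed):
    g = np.random.default_rng(seed)
    data = g.normal(size=(40, 2)) + g.integers(0, 3, 40)[:, None] * 3.0
    labels = np.where(g.random(40) < 0.3, g.integers(0, 3, 40), -1)
    sup = SupervisionInfo.from_labels(labels, 3)
    u = np.random.default_rng(seed + 50).dirichlet(np.ones(3), size=40).T
    centers = update_centers_penalized(u, data, sup, 1.0)
    previous = np.inf
    for _ in range(40):
        dist_sq = squared_distances(data, centers)
        u = update_membership(dist_sq, sup, 1.0, "pedrycz")
        centers = update_centers_penalized(u, data, sup, 1.0)
        j = pedrycz_objective(
            u, squared_distances(data, centers), sup, 1.0
        )
        assert j <= previous + 1e-9 * max(abs(previous), 1.0)
        previous = j


def test_supervision_validation():
    with pytest.raises(ConfigurationError):
        SupervisionInfo(
            labeled=np.array([1.0, 0.0]),
            priors=np.array([[0.4, 0.0], [0.4, 0.0]]),  # sums to 0.8
        )
    with pytest.raises(ConfigurationError):
        SupervisionInfo(
            labeled=np.array([0.0, 0.0]),
            priors=np.array([[0.5, 0.0], [0.5, 0.0]]),  # unlabeled nonzero
        )


def test_config_validation():
    with pytest.raises(ConfigurationError):
        FitConfig(n_clusters=0)
    with pytest.raises(ConfigurationError):
        FitConfig(n_clusters=2, alpha=-1.0)
    with pytest.raises(ConfigurationError):
        FitConfig(n_clusters=2, mode="kernel")
    assert FitConfig(n_clusters=2).fuzzifier == 2


def test_fewer_samples_than_clusters_rejected():
    with pytest.raises(ConfigurationError, match="at least"):
        FuzzyCMeans(np.zeros((2, 1)), 3)
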