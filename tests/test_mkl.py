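import itertools

import numpy as np
import pytest

import multirep_ner as m
from multirep_ner.kernels import KernelSpec
from multirep_ner.mkl import predict as mkl_predict


def _psd(rng, n):
    A = rng.standard_normal((n, n))
    return A @ A.T / n


def _objective(K, y, lam, gamma):
    yg = y * gamma
    return (1 - lam) * float(yg @ K @ yg) + lam * float(gamma @ gamma)


# ---------------------------------------------------------------------------
# solve_gamma


def test_lambda_one_gives_uniform_per_class_closed_form(rng):
    """At lam = 1 the objective is pure ||gamma||^2: the optimum is the
    uniform distribution on each class (centroid distance), exactly."""
    y = np.array([1, 1, 1, -1, -1])
    gamma = m.solve_gamma(_psd(rng, 5), y, lam=1.0)
    np.testing.assert_array_equal(gamma, [1 / 3, 1 / 3, 1 / 3, 1 / 2, 1 / 2])


@pytest.mark.parametrize("lam", [0.0, 0.3, 1.0])
def test_two_points_bisimplex_is_a_single_point(rng, lam):
    gamma = m.solve_gamma(_psd(rng, 2), np.array([1, -1]), lam)
    np.testing.assert_allclose(gamma, [1.0, 1.0], atol=1e-8)


@pytest.mark.parametrize("lam", [0.0, 0.25, 0.5, 0.9])
def test_gamma_matches_brute_force_grid_on_small_problems(rng, lam):
    """On a 2+2-point problem the bi-simplex has two free parameters;
    exhaustive grid search bounds the attainable objective."""
    y = np.array([1, 1, -1, -1])
    K = _psd(rng, 4)
    gamma = m.solve_gamma(K, y, lam)
    best = np.inf
    grid = np.linspace(0, 1, 201)
    for a, b in itertools.product(grid, grid):
        g = np.array([a, 1 - a, b, 1 - b])
        best = min(best, _objective(K, y, lam, g))
    assert _objective(K, y, lam, gamma) <= best + 1e-4


def test_gamma_feasibility_and_determinism(rng):
    y = np.array([1] * 4 + [-1] * 6)
    K = _psd(rng, 10)
    g1 = m.solve_gamma(K, y, 0.5)
    g2 = m.solve_gamma(K, y, 0.5)
    np.testing.assert_array_equal(g1, g2)
    assert g1.min() >= -1e-12
    assert g1[y > 0].sum() == pytest.approx(1.0, abs=1e-8)
    assert g1[y < 0].sum() == pytest.approx(1.0, abs=1e-8)


def test_gamma_rejects_one_class_and_bad_lambda(rng):
    with pytest.raises(m.ContractError):
        m.solve_gamma(_psd(rng, 3), np.array([1, 1, 1]), 0.5)
    with pytest.raises(m.ContractError):
        m.solve_gamma(_psd(rng, 2), np.array([1, -1]), 1.5)


# ---------------------------------------------------------------------------
# compute_weights


def test_weights_hand_example_identity_vs_all_ones():
    y = np.array([1, -1])
    gamma = np.array([1.0, 1.0])
    # gamma' Y I Y gamma = 2 ; gamma' Y 1 Y gamma = (1 - 1)^2 = 0
    mu = m.compute_weights([np.eye(2), np.ones((2, 2))], gamma, y)
    np.testing.assert_allclose(mu, [1.0, 0.0])


def test_weights_identical_kernels_are_uniform(rng):
    K = _psd(rng, 6)
    y = np.array([1, 1, 1, -1, -1, -1])
    gamma = m.solve_gamma(K, y, 0.5)
    mu = m.compute_weights([K, K, K], gamma, y)
    np.testing.assert_allclose(mu, [1 / 3] * 3)


def test_weights_are_a_distribution(rng):
    y = np.array([1, 1, -1, -1, -1])
    gamma = m.solve_gamma(_psd(rng, 5), y, 0.2)
    mu = m.compute_weights([_psd(rng, 5) for _ in range(7)], gamma, y)
    assert mu.min() >= 0
    assert mu.sum() == pytest.approx(1.0)
    # degenerate all-zero kernels fall back to uniform
    mu0 = m.compute_weights([np.zeros((5, 5))] * 4, gamma, y)
    np.testing.assert_allclose(mu0, 0.25)


# ---------------------------------------------------------------------------
# easymkl_fit / predict


def _two_view_kernels(rng, n=40, sep=4.0, noise_dim=6):
    y = np.array([1] * (n // 2) + [-1] * (n // 2))
    X1 = y[:, None] * sep / 2 + rng.standard_normal((n, 2))
    X2 = rng.standard_normal((n, noise_dim))
    k1 = m.cosine_normalize(m.linear_gram(X1))
    k2 = m.cosine_normalize(m.linear_gram(X2))
    return [k1, k2], y


def test_identical_kernels_get_uniform_weights_and_same_predictions(rng):
    X = rng.standard_normal((20, 4))
    y = np.where(X[:, 0] > 0, 1, -1)
    K = m.cosine_normalize(m.linear_gram(X))
    model = m.easymkl_fit([K, K, K], y, lam=0.3)
    np.testing.assert_allclose(model.mu_, 1 / 3)
    single = m.easymkl_fit([K], y, lam=0.3)
    np.testing.assert_array_equal(
        model.predict([K, K, K]), single.predict([K])
    )


def test_informative_view_outweighs_noise_across_seeds():
    wins = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        kernels, y = _two_view_kernels(rng)
        model = m.easymkl_fit(kernels, y, lam=0.5)
        wins += model.mu_[0] > model.mu_[1]
    assert wins >= 18


def test_mu_simplex_along_the_lambda_grid(rng):
    kernels, y = _two_view_kernels(rng)
    for lam in (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0):
        model = m.easymkl_fit(kernels, y, lam=lam)
        assert model.mu_.min() >= 0
        assert model.mu_.sum() == pytest.approx(1.0)
        g = model.gamma_
        assert g[y > 0].sum() == pytest.approx(1.0, abs=1e-8)
        assert g[y < 0].sum() == pytest.approx(1.0, abs=1e-8)


def test_increasing_separation_never_decreases_informative_weight():
    mus = []
    for sep in (0.0, 1.0, 2.0, 4.0, 8.0):
        rng = np.random.default_rng(77)  # identical noise at every level
        kernels, y = _two_view_kernels(rng, sep=sep)
        mus.append(m.easymkl_fit(kernels, y, lam=0.5).mu_[0])
    assert all(b >= a - 1e-9 for a, b in zip(mus, mus[1:]))


def test_training_labels_recovered_on_separable_fixture(rng):
    kernels, y = _two_view_kernels(rng, sep=6.0)
    model = m.easymkl_fit(kernels, y, lam=0.2)
    scores, labels = mkl_predict(model, kernels)
    np.testing.assert_array_equal(labels, y)
    assert scores.shape == (len(y),)


def test_mu_selection_reduces_to_single_kernel(rng):
    X = rng.standard_normal((16, 3))
    y = np.where(X[:, 0] + 0.2 * rng.standard_normal(16) > 0, 1, -1)
    if len(set(y)) < 2:
        y[0] = -y[0]
    K = m.cosine_normalize(m.linear_gram(X))
    model = m.easymkl_fit([K], y, lam=0.4)
    np.testing.assert_array_equal(model.mu_, [1.0])


def test_predict_is_permutation_equivariant(rng):
    kernels, y = _two_view_kernels(rng)
    model = m.easymkl_fit(kernels, y, lam=0.5)
    test_vals = [k.values[:, :10] for k in kernels]
    base = model.predict(test_vals)
    perm = np.array([3, 1, 0, 2, 9, 8, 4, 5, 7, 6])
    permuted = model.predict([v[:, perm] for v in test_vals])
    np.testing.assert_array_equal(permuted, base[perm])


def test_misaligned_test_kernels_are_rejected(rng):
    X = rng.standard_normal((10, 3))
    ids = [f"c{i}" for i in range(10)]
    K = m.cosine_normalize(m.linear_gram(X, row_ids=ids))
    y = np.array([1] * 5 + [-1] * 5)
    model = m.easymkl_fit([K], y, lam=0.5)
    bad = m.GramMatrix(
        K.values, [f"z{i}" for i in range(10)], list("abcdefghij"),
        KernelSpec("", "linear"),
    )
    with pytest.raises(m.AlignmentError):
        model.predict([bad])


# ---------------------------------------------------------------------------
# the margin classifier


def test_two_separable_points_are_both_support_vectors():
    X = np.array([[1.0, 0.0], [-1.0, 0.0]])
    y = np.array([1, -1])
    clf = m.train_margin_classifier(m.linear_gram(X).values, y)
    np.testing.assert_array_equal(clf.predict(m.linear_gram(X).values), y)
    assert len(clf.support_) == 2


def test_xor_separable_under_degree_two_polynomial_kernel():
    X = np.array([[1.0, 1.0], [-1.0, -1.0], [1.0, -1.0], [-1.0, 1.0]])
    y = np.array([1, 1, -1, -1])
    K = m.polynomial_gram(X, degree=2).values
    clf = m.train_margin_classifier(K, y)
    np.testing.assert_array_equal(clf.predict(K), y)


def test_contradictory_labels_converge_without_exception():
    X = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
    y = np.array([1, -1, 1, -1])
    clf = m.train_margin_classifier(m.linear_gram(X).values, y)
    assert clf.predict(m.linear_gram(X).values).shape == (4,)
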