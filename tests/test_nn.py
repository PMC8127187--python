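import numpy as np
import pytest

import multirep_ner as m
from multirep_ner.nn import DEPTH_GRID, WIDTH_GRID


def _separable(rng, n=60, dim=2, sep=4.0):
    y = np.array([1] * (n // 2) + [0] * (n // 2))
    X = (2 * y[:, None] - 1) * sep / 2 + rng.standard_normal((n, dim))
    return X, y


# ---------------------------------------------------------------------------
# grids and specs


def test_network_grid_enumerates_twelve_specs_deterministically():
    grid = m.enumerate_network_grid(10)
    assert len(grid) == len(DEPTH_GRID) * len(WIDTH_GRID) == 12
    assert grid == m.enumerate_network_grid(10)
    assert [s.depth for s in grid[:3]] == [1, 1, 1]


def test_hidden_width_rounding_floors_at_one():
    assert m.NetworkSpec(2, 1, 0.5).hidden_width == 1
    assert m.NetworkSpec(3, 1, 0.5).hidden_width == 2  # half-up rounding
    assert m.NetworkSpec(10, 2, 1.5).hidden_layer_sizes == (15, 15)


def test_spec_rejects_out_of_grid_depth():
    with pytest.raises(m.ContractError):
        m.NetworkSpec(4, 5, 1.0)


# ---------------------------------------------------------------------------
# plain networks


def test_separable_fixture_reaches_perfect_training_accuracy(rng):
    X, y = _separable(rng)
    net = m.train_network(m.NetworkSpec(2, 1, 1.0), X, y, seed=0)
    assert (net.predict(X) == y).mean() == 1.0


def test_same_seed_gives_identical_weights_and_predictions(rng):
    X, y = _separable(rng)
    nets = [
        m.MLPBinaryClassifier(hidden_layer_sizes=(4,), seed=9).fit(X, y)
        for _ in range(2)
    ]
    for a, b in zip(nets[0].params_, nets[1].params_):
        np.testing.assert_array_equal(a, b)
    np.testing.assert_array_equal(nets[0].predict_proba(X), nets[1].predict_proba(X))


def test_probability_half_tie_resolves_negative():
    net = m.MLPBinaryClassifier(hidden_layer_sizes=(2,))
    # force an all-zero network: logits 0 -> probability exactly 0.5
    net.params_ = [np.zeros((3, 2)), np.zeros(2), np.zeros((2, 1)), np.zeros(1)]
    proba, labels = m.predict_network(net, np.ones((4, 3)))
    np.testing.assert_array_equal(proba, 0.5)
    np.testing.assert_array_equal(labels, 0)


def test_prediction_is_permutation_equivariant(rng):
    X, y = _separable(rng)
    net = m.train_network(m.NetworkSpec(2, 1, 1.0), X, y, seed=3)
    perm = np.random.default_rng(0).permutation(len(X))
    np.testing.assert_array_equal(
        net.predict_proba(X[perm]), net.predict_proba(X)[perm]
    )


def test_label_shuffled_fixture_validates_near_chance():
    """Permutation null: with labels shuffled independently of the features
    the validation accuracy hovers around 0.5."""
    accs = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        X, y = _separable(rng, n=80)
        y_shuffled = rng.permutation(y)
        X_val, y_val = X[60:], y_shuffled[60:]
        net = m.MLPBinaryClassifier(hidden_layer_sizes=(4,), seed=seed, max_epochs=60)
        net.fit(X[:60], y_shuffled[:60], X_val, y_val)
        accs.append((net.predict(X_val) == y_val).mean())
    assert abs(np.mean(accs) - 0.5) <= 0.15


def test_early_stopping_keeps_best_validation_state(rng):
    X, y = _separable(rng, n=100)
    net = m.MLPBinaryClassifier(hidden_layer_sizes=(4,), seed=1, max_epochs=200)
    net.fit(X[:70], y[:70], X[70:], y[70:])
    assert net.best_loss_ == min(net.loss_curve_)


# ---------------------------------------------------------------------------
# the ensemble


def test_build_ensemble_wiring():
    specs = [m.NetworkSpec(5, 1, 1.0), m.NetworkSpec(3, 2, 1.0), m.NetworkSpec(7, 1, 0.5)]
    ens = m.build_ensemble(specs)
    assert len(ens.local_specs) == 3
    assert [s.input_dim for s in ens.local_specs] == [5, 3, 7]
    assert ens.shared_width == 5 + 3 + 4
    with pytest.raises(m.ContractError):
        m.build_ensemble([])


def test_ensemble_learns_two_view_fixture(rng):
    X1, y = _separable(rng, n=80, dim=3)
    X2 = rng.standard_normal((80, 4))  # pure noise view
    ens = m.MultiViewEnsembleClassifier(seed=0, max_epochs=150, learning_rate=3e-3)
    ens.fit([X1, X2], y)
    assert (ens.predict([X1, X2]) == y).mean() >= 0.95
    assert len(ens.locals_) == 2
    # branch input dims preserved end-to-end
    assert ens.locals_[0].params_[0].shape[0] == 3
    assert ens.locals_[1].params_[0].shape[0] == 4


def test_single_branch_ensemble_degenerates_to_plain_network(rng):
    X, y = _separable(rng, n=60)
    ens = m.MultiViewEnsembleClassifier(seed=4, max_epochs=80)
    ens.fit([X], y)
    assert (ens.predict([X]) == y).mean() == 1.0


def test_ensemble_seeded_determinism(rng):
    X1, y = _separable(rng, n=40)
    X2 = rng.standard_normal((40, 3))
    runs = [
        m.MultiViewEnsembleClassifier(seed=5, max_epochs=30).fit([X1, X2], y)
        for _ in range(2)
    ]
    np.testing.assert_array_equal(
        runs[0].predict_proba([X1, X2]), runs[1].predict_proba([X1, X2])
    )


def test_fine_tune_pass_runs_and_keeps_separation(rng):
    X1, y = _separable(rng, n=60)
    X2 = rng.standard_normal((60, 3))
    ens = m.MultiViewEnsembleClassifier(
        seed=2, max_epochs=150, learning_rate=3e-3, fine_tune=True
    )
    ens.fit([X1, X2], y)
    assert (ens.predict([X1, X2]) == y).mean() >= 0.95
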