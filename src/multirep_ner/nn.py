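"""Feed-forward networks and the multi-view ensemble combiner.

Plain fully-connected networks serve the single-representation and
concatenation schemes; the combination scheme uses an ensemble of small
local networks, one per base representation, whose final hidden layers are
merged by a shared layer feeding a single logistic output unit. Local
networks are first trained and validated on their own representation; the
shared head is then trained on their (frozen) hidden activations, with an
optional joint fine-tuning pass over the whole stack.

Everything is implemented directly on numpy: rectifier hidden units, a
logistic output with cross-entropy loss, Adam updates, mini-batches of 32,
early stopping on validation loss. All training is deterministic given the
seed (no other source of randomness exists).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import ContractError, NumericError

DEPTH_GRID = (1, 2, 3, 4)
WIDTH_GRID = (0.5, 1.0, 1.5)


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of a plain feed-forward network."""

    input_dim: int
    depth: int
    width_multiplier: float

    def __post_init__(self) -> None:
        if self.depth not in DEPTH_GRID:
            raise ContractError(f"depth must be in {DEPTH_GRID}")
        if self.input_dim < 1:
            raise ContractError("input_dim must be >= 1")

    @property
    def hidden_width(self) -> int:
        # half-up rounding, floored at one unit
        return max(1, int(np.floor(self.width_multiplier * self.input_dim + 0.5)))

    @property
    def hidden_layer_sizes(self) -> tuple[int, ...]:
        return (self.hidden_width,) * self.depth


def enumerate_network_grid(input_dim: int) -> list[NetworkSpec]:
    """All depth x width-multiplier combinations, in deterministic order
    (depth ascending, then width ascending): 12 specs."""
    return [
        NetworkSpec(input_dim, depth, width)
        for depth in DEPTH_GRID
        for width in WIDTH_GRID
    ]


# ---------------------------------------------------------------------------
# numpy layer machinery


def _init_params(rng: np.random.Generator, dims: Sequence[int]) -> list[np.ndarray]:
    """He-initialized weights and zero biases, flattened as [W0, b0, W1, ...]."""
    params: list[np.ndarray] = []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        params.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, fan_out)))
        params.append(np.zeros(fan_out))
    return params


def _forward(params: Sequence[np.ndarray], X: np.ndarray) -> list[np.ndarray]:
    """Activations per layer; hidden layers rectified, last layer raw logits."""
    acts = [X]
    n_layers = len(params) // 2
    for i in range(n_layers):
        z = acts[-1] @ params[2 * i] + params[2 * i + 1]
        acts.append(np.maximum(z, 0.0) if i < n_layers - 1 else z)
    return acts


def _backward(
    params: Sequence[np.ndarray], acts: Sequence[np.ndarray], delta: np.ndarray
) -> tuple[list[np.ndarray], np.ndarray]:
    """Gradients for every parameter given the output-layer delta; also
    returns the gradient with respect to the input (for ensemble wiring)."""
    grads = [np.zeros_like(p) for p in params]
    n_layers = len(params) // 2
    for i in range(n_layers - 1, -1, -1):
        grads[2 * i] = acts[i].T @ delta
        grads[2 * i + 1] = delta.sum(axis=0)
        delta = delta @ params[2 * i].T
        if i > 0:
            delta = delta * (acts[i] > 0)
    return grads, delta


def _bce_with_logits(logits: np.ndarray, y01: np.ndarray) -> float:
    z = logits.ravel()
    return float(np.mean(np.maximum(z, 0) - z * y01 + np.log1p(np.exp(-np.abs(z)))))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


class _Adam:
    def __init__(self, params: Sequence[np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        for i, g in enumerate(grads):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / (1 - self.beta1**self.t)
            vhat = self.v[i] / (1 - self.beta2**self.t)
            params[i] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _as01(y) -> np.ndarray:
    return (np.asarray(y) > 0).astype(np.float64)


class MLPBinaryClassifier(BaseEstimator, ClassifierMixin):
    """Deterministic numpy MLP for binary candidate filtering.

    Labels may be given as {0, 1} or {-1, +1}; predictions are returned as
    {0, 1} with the probability-0.5 tie resolved to the negative class.
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (8,),
        seed: int = 0,
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        max_epochs: int = 200,
        patience: int = 10,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.seed = seed
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience

    def fit(self, X, y, X_val=None, y_val=None) -> "MLPBinaryClassifier":
        X = np.asarray(X, dtype=np.float64)
        y01 = _as01(y)
        monitor_val = X_val is not None and y_val is not None
        if monitor_val:
            X_val = np.asarray(X_val, dtype=np.float64)
            y_val01 = _as01(y_val)
        rng = np.random.default_rng(self.seed)
        dims = [X.shape[1], *self.hidden_layer_sizes, 1]
        params = _init_params(rng, dims)
        opt = _Adam(params, self.learning_rate)
        best_loss, best_params, strikes = np.inf, [p.copy() for p in params], 0
        self.loss_curve_ = []
        n = len(X)
        for _ in range(self.max_epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                acts = _forward(params, X[idx])
                delta = (_sigmoid(acts[-1]) - y01[idx, None]) / len(idx)
                grads, _ = _backward(params, acts, delta)
                opt.step(params, grads)
            if monitor_val:
                loss = _bce_with_logits(_forward(params, X_val)[-1], y_val01)
            else:
                loss = _bce_with_logits(_forward(params, X)[-1], y01)
            if not np.isfinite(loss):
                raise NumericError("training diverged: non-finite loss")
            self.loss_curve_.append(loss)
            if loss < best_loss - 1e-8:
                best_loss, strikes = loss, 0
                best_params = [p.copy() for p in params]
            else:
                strikes += 1
                if strikes >= self.patience:
                    break
        self.params_ = best_params
        self.best_loss_ = best_loss
        return self

    def _logits(self, X) -> np.ndarray:
        return _forward(self.params_, np.asarray(X, dtype=np.float64))[-1].ravel()

    def predict_proba(self, X) -> np.ndarray:
        return _sigmoid(self._logits(X))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) > 0.5).astype(int)

    def hidden_activations(self, X) -> np.ndarray:
        """Final hidden-layer activations (the tensor the ensemble merges)."""
        return _forward(self.params_, np.asarray(X, dtype=np.float64))[-2]


@dataclass(frozen=True)
class EnsembleSpec:
    """Wiring of the multi-view ensemble: local specs plus shared width."""

    local_specs: tuple[NetworkSpec, ...]
    shared_width: int

    def __post_init__(self) -> None:
        if not self.local_specs:
            raise ContractError("at least one local network is required")
        if self.shared_width < 1:
            raise ContractError("shared width must be >= 1")


def build_ensemble(
    local_specs: Sequence[NetworkSpec], shared_width: int | None = None
) -> EnsembleSpec:
    """Wire local branches to a concatenation point feeding the shared
    layer and a 1-unit output head. Default shared width matches the
    concatenated hidden dimension."""
    specs = tuple(local_specs)
    if shared_width is None:
        shared_width = max(1, sum(s.hidden_width for s in specs))
    return EnsembleSpec(specs, shared_width)


class MultiViewEnsembleClassifier(BaseEstimator, ClassifierMixin):
    """The combination-scheme network: P local branches merged by a shared
    layer.

    Each local network is trained on its own representation; the shared
    head (one rectified layer plus a logistic unit) is then trained on the
    concatenation of the locals' final hidden activations with the locals
    frozen. ``fine_tune=True`` adds a joint pass updating all parameters.
    """

    def __init__(
        self,
        ensemble_spec: EnsembleSpec | None = None,
        seed: int = 0,
        fine_tune: bool = False,
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        max_epochs: int = 200,
        patience: int = 10,
    ):
        self.ensemble_spec = ensemble_spec
        self.seed = seed
        self.fine_tune = fine_tune
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience

    def _spec_for(self, views: Sequence[np.ndarray]) -> EnsembleSpec:
        if self.ensemble_spec is not None:
            if len(self.ensemble_spec.local_specs) != len(views):
                raise ContractError(
                    f"{len(self.ensemble_spec.local_specs)} local specs for "
                    f"{len(views)} views"
                )
            return self.ensemble_spec
        return build_ensemble(
            [NetworkSpec(v.shape[1], 1, 1.0) for v in views]
        )

    def fit(self, views: Sequence, y, views_val=None, y_val=None) -> "MultiViewEnsembleClassifier":
        views = [np.asarray(v, dtype=np.float64) for v in views]
        spec = self._spec_for(views)
        self.spec_ = spec
        has_val = views_val is not None and y_val is not None
        if has_val:
            views_val = [np.asarray(v, dtype=np.float64) for v in views_val]
        self.locals_ = []
        for i, (local_spec, X) in enumerate(zip(spec.local_specs, views)):
            net = MLPBinaryClassifier(
                hidden_layer_sizes=local_spec.hidden_layer_sizes,
                seed=self.seed * 1000 + i,
                learning_rate=self.learning_rate,
                batch_size=self.batch_size,
                max_epochs=self.max_epochs,
                patience=self.patience,
            )
            net.fit(X, y, views_val[i] if has_val else None, y_val if has_val else None)
            self.locals_.append(net)
        H = self._merged(views)
        H_val = self._merged(views_val) if has_val else None
        self.head_ = MLPBinaryClassifier(
            hidden_layer_sizes=(spec.shared_width,),
            seed=self.seed * 1000 + 999,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
        )
        self.head_.fit(H, y, H_val, y_val if has_val else None)
        if self.fine_tune:
            self._joint_finetune(views, _as01(y))
        return self

    def _merged(self, views: Sequence[np.ndarray]) -> np.ndarray:
        return np.hstack(
            [net.hidden_activations(X) for net, X in zip(self.locals_, views)]
        )

    def _joint_finetune(self, views: Sequence[np.ndarray], y01: np.ndarray) -> None:
        """Joint gradient pass over branch hidden stacks and the head."""
        branch_params = [net.params_[:-2] for net in self.locals_]  # drop logit head
        head_params = self.head_.params_
        flat = [p for ps in branch_params for p in ps] + list(head_params)
        opt = _Adam(flat, self.learning_rate)
        rng = np.random.default_rng(self.seed * 1000 + 777)
        n = len(y01)
        best_loss, best, strikes = np.inf, [p.copy() for p in flat], 0
        widths = [net.params_[-2].shape[0] for net in self.locals_]
        for _ in range(self.max_epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                branch_acts = []
                pieces = []
                offset = 0
                for ps in branch_params:
                    nb = len(ps)
                    acts = self._branch_forward(flat[offset : offset + nb], views[len(branch_acts)][idx])
                    branch_acts.append(acts)
                    pieces.append(acts[-1])
                    offset += nb
                H = np.hstack(pieces)
                head = flat[offset:]
                head_acts = _forward(head, H)
                delta = (_sigmoid(head_acts[-1]) - y01[idx, None]) / len(idx)
                head_grads, dH = _backward(head, head_acts, delta)
                grads = []
                col = 0
                offset = 0
                for ps, acts, width in zip(branch_params, branch_acts, widths):
                    d = dH[:, col : col + width] * (acts[-1] > 0)
                    bgrads, _ = _backward(flat[offset : offset + len(ps)], acts, d)
                    grads.extend(bgrads)
                    col += width
                    offset += len(ps)
                grads.extend(head_grads)
                opt.step(flat, grads)
            logits = self._stack_logits(flat, views, branch_params, widths)
            loss = _bce_with_logits(logits, y01)
            if not np.isfinite(loss):
                raise NumericError("fine-tuning diverged: non-finite loss")
            if loss < best_loss - 1e-8:
                best_loss, strikes = loss, 0
                best = [p.copy() for p in flat]
            else:
                strikes += 1
                if strikes >= self.patience:
                    break
        # write the tuned parameters back into locals and head
        offset = 0
        for net, ps in zip(self.locals_, branch_params):
            net.params_[: len(ps)] = best[offset : offset + len(ps)]
            offset += len(ps)
        self.head_.params_ = best[offset:]

    @staticmethod
    def _branch_forward(params: Sequence[np.ndarray], X: np.ndarray) -> list[np.ndarray]:
        """Hidden stack of a branch: every layer rectified (no logit head)."""
        acts = [X]
        for i in range(len(params) // 2):
            acts.append(np.maximum(acts[-1] @ params[2 * i] + params[2 * i + 1], 0.0))
        return acts

    def _stack_logits(self, flat, views, branch_params, widths) -> np.ndarray:
        pieces = []
        offset = 0
        for i, ps in enumerate(branch_params):
            acts = self._branch_forward(flat[offset : offset + len(ps)], views[i])
            pieces.append(acts[-1])
            offset += len(ps)
        return _forward(flat[offset:], np.hstack(pieces))[-1]

    def predict_proba(self, views: Sequence) -> np.ndarray:
        views = [np.asarray(v, dtype=np.float64) for v in views]
        return self.head_.predict_proba(self._merged(views))

    def predict(self, views: Sequence) -> np.ndarray:
        return (self.predict_proba(views) > 0.5).astype(int)


def train_network(
    spec: NetworkSpec, X, y, X_val=None, y_val=None, seed: int = 0, **kwargs
) -> MLPBinaryClassifier:
    """Train a plain feed-forward network with the given architecture."""
    net = MLPBinaryClassifier(
        hidden_layer_sizes=spec.hidden_layer_sizes, seed=seed, **kwargs
    )
    return net.fit(X, y, X_val, y_val)


def predict_network(net: MLPBinaryClassifier, X) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and {0, 1} labels (0.5 ties resolve negative)."""
    proba = net.predict_proba(X)
    return proba, (proba > 0.5).astype(int)
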