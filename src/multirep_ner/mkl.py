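"""EasyMKL: margin-based learning of a non-negative kernel combination.

The algorithm maximizes over kernel weights mu the regularized margin

    max_mu  min_gamma  (1 - lam) * gamma' Y (sum_r mu_r K_r) Y gamma
                       + lam * ||gamma||^2

where gamma lives on the bi-simplex (a probability distribution over the
positive examples and one over the negatives) and Y = diag(y). The problem
is solved in its standard relaxed two-step form: the inner minimization is
solved once on the unweighted sum of the base kernels, then each kernel's
weight is its margin contribution d_r = gamma' Y K_r Y gamma, normalized to
the unit simplex. The combined kernel finally feeds a hard-margin SVM
(realized as a precomputed-kernel SVC with a very large C).

The inner problem is a convex QP over a product of two simplices; it is
solved by an accelerated projected-gradient method (FISTA) with exact
Euclidean simplex projections — deterministic, no random initialization.
At lam = 1 the objective reduces to ||gamma||^2 and the solution is the
closed-form uniform distribution per class (the distance between class
centroids); the solver's uniform start makes that case exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC

from .errors import AlignmentError, ContractError, NumericError
from .kernels import GramMatrix

HARD_MARGIN_C = 1e6


@dataclass(frozen=True)
class TrainingSet:
    """Labeled candidate ids with labels in {+1, -1}."""

    ids: tuple[str, ...]
    y: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.y)
        if len(self.ids) != len(y):
            raise ContractError("ids and labels differ in length")
        if not set(np.unique(y)) <= {-1, 1}:
            raise ContractError("labels must be +1 / -1")
        if len(set(np.unique(y))) < 2:
            raise ContractError("both classes must be present")


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto {x : x >= 0, sum x = 1} (sort-based)."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u)
    rho = np.nonzero(u * np.arange(1, len(v) + 1) > (css - 1.0))[0][-1]
    theta = (css[rho] - 1.0) / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


def _project_bisimplex(gamma: np.ndarray, pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    out = np.empty_like(gamma)
    out[pos] = _project_simplex(gamma[pos])
    out[neg] = _project_simplex(gamma[neg])
    return out


def _as_values(K) -> np.ndarray:
    return K.values if isinstance(K, GramMatrix) else np.asarray(K, dtype=np.float64)


def solve_gamma(
    K,
    y: np.ndarray,
    lam: float,
    tol: float = 1e-8,
    max_iter: int = 50_000,
) -> np.ndarray:
    """Minimize (1-lam) * gamma' Y K Y gamma + lam * ||gamma||^2 over the
    bi-simplex. Returns the optimal gamma (deterministic).

    Convergence is declared when the fixed-point residual
    ``max_i |gamma_i - proj(gamma - step * grad)_i|`` falls below *tol*
    (the projection fixed point is exactly the KKT point of the QP);
    non-convergence raises NumericError carrying the residual.
    """
    if not 0.0 <= lam <= 1.0:
        raise ContractError(f"lambda must be in [0, 1], got {lam}")
    y = np.asarray(y, dtype=np.float64)
    pos = y > 0
    neg = y < 0
    if not pos.any() or not neg.any():
        raise ContractError("both classes must be present")
    Kv = _as_values(K)
    Kv = 0.5 * (Kv + Kv.T)  # guard against asymmetric round-off

    # quadratic form gamma' Q gamma with Q = (1-lam) YKY + lam I
    YKY = Kv * np.outer(y, y)
    Q = (1.0 - lam) * YKY + lam * np.eye(len(y))
    Q = 0.5 * (Q + Q.T)

    gamma = np.where(pos, 1.0 / pos.sum(), 1.0 / neg.sum())
    lip = 2.0 * max(float(np.linalg.eigvalsh(Q)[-1]), 1e-12)
    step = 1.0 / lip

    def _residual(g: np.ndarray) -> float:
        mapped = _project_bisimplex(g - step * 2.0 * (Q @ g), pos, neg)
        return float(np.max(np.abs(g - mapped)))

    if _residual(gamma) <= tol:  # e.g. lam = 1: uniform start is the optimum
        return gamma
    z = gamma.copy()
    t = 1.0
    for it in range(1, max_iter + 1):
        grad = 2.0 * (Q @ z)
        gamma_next = _project_bisimplex(z - step * grad, pos, neg)
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        z = gamma_next + ((t - 1.0) / t_next) * (gamma_next - gamma)
        gamma, t = gamma_next, t_next
        if it % 20 == 0 and _residual(gamma) <= tol:
            return gamma
    residual = _residual(gamma)
    if residual <= tol:
        return gamma
    raise NumericError(
        f"gamma solver did not converge: fixed-point residual "
        f"{residual:.3e} > tol {tol:.1e}"
    )


def compute_weights(
    kernels: Sequence, gamma: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Per-kernel margin contributions d_r = gamma' Y K_r Y gamma, clipped
    at 0 and normalized to the unit simplex (uniform if all are 0)."""
    y = np.asarray(y, dtype=np.float64)
    yg = y * gamma
    d = np.array([max(float(yg @ _as_values(K) @ yg), 0.0) for K in kernels])
    total = d.sum()
    if total <= 0.0:
        return np.full(len(d), 1.0 / len(d))
    return d / total


def train_margin_classifier(
    K_combined, y: np.ndarray, hardness: float = HARD_MARGIN_C
) -> SVC:
    """Fit the max-margin classifier on a precomputed combined kernel.

    Hard margin is approximated by a large finite regularization magnitude;
    on separable data the solution coincides with the true hard margin. An
    iteration cap keeps non-separable inputs from cycling indefinitely."""
    svc = SVC(kernel="precomputed", C=hardness, max_iter=200_000)
    svc.fit(_as_values(K_combined), np.asarray(y))
    return svc


class EasyMKL(BaseEstimator, ClassifierMixin):
    """Margin-maximizing multiple kernel learning classifier.

    Parameters
    ----------
    lam : float in [0, 1]
        Margin regularization. 0 maximizes the distance between the class
        convex hulls, 1 the distance between the class centroids.
    hardness : float
        Regularization magnitude of the downstream max-margin classifier.
    tol, max_iter : solver controls for the inner QP.

    Attributes (after fit)
    ----------------------
    mu_ : ndarray, non-negative kernel weights summing to 1.
    gamma_ : ndarray, the optimal bi-simplex distribution.
    classifier_ : the fitted precomputed-kernel SVC.
    train_ids_ : manifest of the training candidates (when Gram matrices
        with manifests were supplied).
    """

    def __init__(
        self,
        lam: float = 0.1,
        hardness: float = HARD_MARGIN_C,
        tol: float = 1e-8,
        max_iter: int = 50_000,
    ):
        self.lam = lam
        self.hardness = hardness
        self.tol = tol
        self.max_iter = max_iter

    # -- helpers ---------------------------------------------------------
    def _check_bank(self, kernels, training: bool):
        values = [_as_values(K) for K in kernels]
        manifests = [K for K in kernels if isinstance(K, GramMatrix)]
        for K in manifests[1:]:
            if K.row_ids != manifests[0].row_ids or K.col_ids != manifests[0].col_ids:
                raise AlignmentError("kernel manifests differ within the bank")
        if training and manifests:
            self.train_ids_ = list(manifests[0].row_ids)
        if not training and manifests and getattr(self, "train_ids_", None):
            if manifests[0].row_ids != self.train_ids_:
                raise AlignmentError(
                    "test kernels are not aligned train-rows x test-columns"
                )
        if not training:
            specs = [K.spec for K in kernels if isinstance(K, GramMatrix)]
            if specs and getattr(self, "specs_", None):
                if specs != self.specs_:
                    raise AlignmentError(
                        "test kernel specs differ from the training bank"
                    )
        return values

    # -- estimator API ---------------------------------------------------
    def fit(self, kernels: Sequence, y) -> "EasyMKL":
        """Fit from a sequence of square training kernels (GramMatrix or
        plain arrays) and labels in {+1, -1}."""
        if len(kernels) == 0:
            raise ContractError("at least one kernel is required")
        self.train_ids_ = None
        values = self._check_bank(kernels, training=True)
        y = np.asarray(y)
        K_sum = np.sum(values, axis=0)
        self.gamma_ = solve_gamma(K_sum, y, self.lam, self.tol, self.max_iter)
        self.mu_ = compute_weights(values, self.gamma_, y)
        self.specs_ = [
            K.spec if isinstance(K, GramMatrix) else None for K in kernels
        ]
        if any(s is None for s in self.specs_):
            self.specs_ = None
        combined = np.zeros_like(values[0])
        for w, Kv in zip(self.mu_, values):
            combined += w * Kv
        self.classifier_ = train_margin_classifier(combined, y, self.hardness)
        self.y_train_ = y
        return self

    def decision_function(self, kernels: Sequence) -> np.ndarray:
        """Decision scores for test kernels given as train-rows x
        test-columns matrices (the GramMatrix orientation produced by
        cross_kernel_bank)."""
        values = self._check_bank(kernels, training=False)
        if len(values) != len(self.mu_):
            raise AlignmentError(
                f"model has {len(self.mu_)} kernels, got {len(values)}"
            )
        combined = np.zeros_like(values[0], dtype=np.float64)
        for w, Kv in zip(self.mu_, values):
            combined += w * Kv
        return self.classifier_.decision_function(combined.T)

    def predict(self, kernels: Sequence) -> np.ndarray:
        scores = self.decision_function(kernels)
        return np.where(scores > 0, 1, -1)

    def weight_by_representation(self) -> dict[str, float]:
        """Aggregate learned weight mass per base representation (requires
        Gram matrices with specs at fit time)."""
        if not getattr(self, "specs_", None):
            raise ContractError("fit was called without kernel specs")
        masses: dict[str, float] = {}
        for spec, w in zip(self.specs_, self.mu_):
            masses[spec.representation_name] = (
                masses.get(spec.representation_name, 0.0) + float(w)
            )
        return masses


def easymkl_fit(
    kernels: Sequence, train: TrainingSet | np.ndarray, lam: float,
    hardness: float = HARD_MARGIN_C,
) -> EasyMKL:
    """Functional wrapper: fit an EasyMKL model on a kernel bank."""
    y = train.y if isinstance(train, TrainingSet) else train
    return EasyMKL(lam=lam, hardness=hardness).fit(kernels, y)


def predict(model: EasyMKL, test_kernels: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """Decision scores and {+1, -1} labels for a fitted model."""
    scores = model.decision_function(test_kernels)
    return scores, np.where(scores > 0, 1, -1)
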