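"""Base-kernel bank construction, normalization and combination.

Each base representation induces kernels: its plain linear Gram and, for the
non-spectrum representations, homogeneous polynomial kernels
k(x, z) = <x, z>**d with degrees 2..5. All kernels are cosine-normalized
before combination so that no view dominates by scale alone. Gram matrices
carry a candidate-id manifest and refuse silent misalignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import AlignmentError, ConfigurationError, ContractError
from .representations import RepresentationBank

POLYNOMIAL_DEGREES = (2, 3, 4, 5)


@dataclass(frozen=True)
class KernelSpec:
    """Identity of a base kernel: which representation, which form."""

    representation_name: str
    form: str  # "linear" | "polynomial"
    degree: int | None = None

    def __post_init__(self) -> None:
        if self.form == "linear":
            if self.degree is not None:
                raise ConfigurationError("linear kernel takes no degree")
        elif self.form == "polynomial":
            if not isinstance(self.degree, int) or self.degree < 2:
                raise ConfigurationError(
                    f"polynomial degree must be an integer >= 2, "
                    f"got {self.degree!r}"
                )
        else:
            raise ConfigurationError(f"unknown kernel form {self.form!r}")

    @property
    def label(self) -> str:
        if self.form == "linear":
            return f"{self.representation_name}:linear"
        return f"{self.representation_name}:poly{self.degree}"


@dataclass
class GramMatrix:
    """A kernel matrix with its generating spec and id manifests.

    Square train kernels have ``row_ids == col_ids``; cross kernels between
    training rows and test columns keep both manifests.
    """

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    spec: KernelSpec
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise AlignmentError(
                f"Gram shape {self.values.shape} does not match manifests "
                f"({len(self.row_ids)}, {len(self.col_ids)})"
            )

    @property
    def is_square(self) -> bool:
        return self.row_ids == self.col_ids


def _pairwise(X: np.ndarray, Z: np.ndarray, spec: KernelSpec) -> np.ndarray:
    if X.shape[1] != Z.shape[1]:
        raise AlignmentError(
            f"column mismatch: {X.shape[1]} vs {Z.shape[1]} features"
        )
    gram = X @ Z.T
    if spec.form == "polynomial":
        gram = gram**spec.degree
    return gram


def _self_diag(X: np.ndarray, spec: KernelSpec) -> np.ndarray:
    diag = np.einsum("ij,ij->i", X, X)
    if spec.form == "polynomial":
        diag = diag**spec.degree
    return diag


def _ids(X: np.ndarray, ids: Sequence[str] | None) -> list[str]:
    return list(ids) if ids is not None else [str(i) for i in range(len(X))]


def linear_gram(
    X: np.ndarray,
    Z: np.ndarray | None = None,
    *,
    row_ids: Sequence[str] | None = None,
    col_ids: Sequence[str] | None = None,
    representation_name: str = "",
) -> GramMatrix:
    """Plain inner-product Gram of X against Z (Z defaults to X)."""
    spec = KernelSpec(representation_name, "linear")
    X = np.asarray(X, dtype=np.float64)
    Z = X if Z is None else np.asarray(Z, dtype=np.float64)
    rows = _ids(X, row_ids)
    cols = rows if Z is X else _ids(Z, col_ids)
    return GramMatrix(_pairwise(X, Z, spec), rows, cols, spec)


def polynomial_gram(
    X: np.ndarray,
    Z: np.ndarray | None = None,
    *,
    degree: int,
    row_ids: Sequence[str] | None = None,
    col_ids: Sequence[str] | None = None,
    representation_name: str = "",
) -> GramMatrix:
    """Homogeneous polynomial Gram: entry (i, j) = <x_i, z_j> ** degree."""
    spec = KernelSpec(representation_name, "polynomial", degree)
    X = np.asarray(X, dtype=np.float64)
    Z = X if Z is None else np.asarray(Z, dtype=np.float64)
    rows = _ids(X, row_ids)
    cols = rows if Z is X else _ids(Z, col_ids)
    return GramMatrix(_pairwise(X, Z, spec), rows, cols, spec)


def cosine_normalize(K: GramMatrix) -> GramMatrix:
    """Rescale a square Gram to unit diagonal: K_ij / sqrt(K_ii K_jj).

    Rows whose self-kernel is 0 (e.g. all-zero feature vectors) keep a unit
    diagonal entry and zero off-diagonals, so the result stays PSD.
    """
    if not K.is_square:
        raise ContractError("cosine_normalize requires a square Gram")
    diag = np.diag(K.values).copy()
    scale = np.sqrt(np.where(diag > 0, diag, 1.0))
    values = K.values / np.outer(scale, scale)
    np.fill_diagonal(values, np.where(diag > 0, np.diag(values), 1.0))
    return GramMatrix(values, K.row_ids, K.col_ids, K.spec, normalized=True)


def _cross_normalize(
    values: np.ndarray, row_self: np.ndarray, col_self: np.ndarray
) -> np.ndarray:
    rs = np.sqrt(np.where(row_self > 0, row_self, 1.0))
    cs = np.sqrt(np.where(col_self > 0, col_self, 1.0))
    return values / np.outer(rs, cs)


def kernel_specs_for_bank(
    names: Sequence[str], mode: str = "mkl_default"
) -> list[KernelSpec]:
    """The kernel bank layout for a set of representation names.

    ``mkl_default``: every non-spectrum representation contributes its
    linear form plus polynomial degrees 2..5; spectrum representations
    contribute their linear form only (the 10-entry default bank thus
    yields 30 kernels). ``one_per_representation``: one linear kernel each.
    """
    if mode == "one_per_representation":
        return [KernelSpec(name, "linear") for name in names]
    if mode != "mkl_default":
        raise ConfigurationError(f"unknown kernel bank mode {mode!r}")
    specs = []
    for name in names:
        specs.append(KernelSpec(name, "linear"))
        if not name.startswith("spectrum_"):
            specs.extend(
                KernelSpec(name, "polynomial", d) for d in POLYNOMIAL_DEGREES
            )
    return specs


def build_kernel_bank(
    bank: RepresentationBank,
    mode: str = "mkl_default",
    normalize: bool = True,
) -> list[GramMatrix]:
    """Compute the (square, training-side) kernel bank over a representation
    bank, cosine-normalized by default."""
    kernels = []
    for spec in kernel_specs_for_bank(bank.names, mode):
        X = bank.matrix(spec.representation_name)
        gram = GramMatrix(
            _pairwise(X, X, spec), list(bank.ids), list(bank.ids), spec
        )
        kernels.append(cosine_normalize(gram) if normalize else gram)
    return kernels


def cross_kernel_bank(
    train_bank: RepresentationBank,
    test_bank: RepresentationBank,
    specs: Sequence[KernelSpec],
    normalize: bool = True,
) -> list[GramMatrix]:
    """Train-rows x test-columns kernels for the given specs, normalized
    with each side's own self-kernels (consistent with cosine_normalize)."""
    if train_bank.names != test_bank.names:
        raise AlignmentError("train and test banks list different entries")
    kernels = []
    for spec in specs:
        X = train_bank.matrix(spec.representation_name)
        Z = test_bank.matrix(spec.representation_name)
        values = _pairwise(X, Z, spec)
        if normalize:
            values = _cross_normalize(
                values, _self_diag(X, spec), _self_diag(Z, spec)
            )
        kernels.append(
            GramMatrix(
                values, list(train_bank.ids), list(test_bank.ids), spec,
                normalized=normalize,
            )
        )
    return kernels


def combine(
    kernels: Sequence[GramMatrix], weights: np.ndarray
) -> GramMatrix:
    """Non-negative linear combination sum_r mu_r K_r of aligned kernels."""
    if not kernels:
        raise ContractError("no kernels to combine")
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (len(kernels),):
        raise ContractError(
            f"{len(kernels)} kernels but {weights.shape} weights"
        )
    if np.any(weights < 0):
        raise ContractError("combination weights must be non-negative")
    first = kernels[0]
    for k in kernels[1:]:
        if k.row_ids != first.row_ids or k.col_ids != first.col_ids:
            raise AlignmentError("kernel manifests differ; refusing to combine")
    values = np.zeros_like(first.values)
    for w, k in zip(weights, kernels):
        values += w * k.values
    spec = KernelSpec("combined", "linear")
    return GramMatrix(
        values, list(first.row_ids), list(first.col_ids), spec,
        normalized=all(k.normalized for k in kernels),
    )
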