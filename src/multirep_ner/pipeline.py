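"""End-to-end orchestration: training sets, hold-out model selection over
the three aggregation schemes, and entity-level evaluation.

The three schemes mirror the study design:

* single representation -- validation picks one base representation (and
  the learner's hyper-parameters);
* concatenation -- all representations are column-concatenated into one
  static feature space;
* combination -- EasyMKL over the 30-kernel bank, or the multi-view
  ensemble network.

Model selection is an 80/20 stratified hold-out on the training candidates;
the selection metric is candidate-level F1. Ties resolve to the earliest
grid cell (bank order, then smaller C / shallower and narrower network).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .errors import ContractError
from .gazetteer import (
    LabeledCandidate, LabelingResult, build_matcher, find_candidates,
    label_candidates,
)
from .io import Document, Lexicon, Mention
from .kernels import build_kernel_bank, cross_kernel_bank, kernel_specs_for_bank
from .mkl import EasyMKL, TrainingSet
from .nn import (
    MLPBinaryClassifier, MultiViewEnsembleClassifier, NetworkSpec,
    build_ensemble, enumerate_network_grid,
)
from .representations import (
    RepresentationBank, RepresentationConfig, build_representation_bank,
)

C_GRID = tuple(10.0**i for i in range(-5, 6))
LAMBDA_GRID = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


@dataclass(frozen=True)
class ModelSelectionConfig:
    """Hyper-parameter grids and hold-out controls."""

    c_grid: tuple[float, ...] = C_GRID
    lambda_grid: tuple[float, ...] = LAMBDA_GRID
    holdout_fraction: float = 0.8
    seed: int = 0
    hardness: float = 1e6
    nn_max_epochs: int = 200
    nn_patience: int = 10
    nn_learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        if not self.c_grid or not self.lambda_grid:
            raise ContractError("hyper-parameter grids must be non-empty")
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ContractError("holdout fraction must be in (0, 1)")


def make_training_set(labeled: Sequence[LabeledCandidate]) -> TrainingSet:
    """Candidates to a TrainingSet: positives +1, negatives -1, order kept."""
    from .representations import mention_id

    y = np.array([lc.label for lc in labeled])
    if len(set(y.tolist())) < 2:
        raise ContractError("training set needs both positive and negative candidates")
    return TrainingSet(tuple(mention_id(lc.mention) for lc in labeled), y)


def holdout_split(
    train: TrainingSet, fraction: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified, deterministic index split into fit / validation parts."""
    idx = np.arange(len(train.y))
    fit_idx, val_idx = train_test_split(
        idx, train_size=fraction, random_state=seed, stratify=train.y
    )
    return np.sort(fit_idx), np.sort(val_idx)


def _f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(np.sum((y_true > 0) & (y_pred > 0)))
    fp = int(np.sum((y_true <= 0) & (y_pred > 0)))
    fn = int(np.sum((y_true > 0) & (y_pred <= 0)))
    return _prf(tp, fp, fn)[2]


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


# ---------------------------------------------------------------------------
# fitted-model wrappers (uniform predict_bank interface, labels in {+1, -1})


@dataclass
class FittedSingle:
    scheme: str
    learner: str
    representation: str
    model: object
    c: float | None = None
    spec: NetworkSpec | None = None

    def predict_bank(self, bank: RepresentationBank) -> np.ndarray:
        X = bank.matrix(self.representation)
        pred = self.model.predict(X)
        return np.where(np.asarray(pred) > 0, 1, -1)


@dataclass
class FittedConcat:
    scheme: str
    learner: str
    model: object
    c: float | None = None
    spec: NetworkSpec | None = None

    def predict_bank(self, bank: RepresentationBank) -> np.ndarray:
        pred = self.model.predict(bank.concatenated())
        return np.where(np.asarray(pred) > 0, 1, -1)


@dataclass
class FittedMKL:
    scheme: str
    learner: str
    model: EasyMKL
    train_bank: RepresentationBank
    lam: float

    def predict_bank(self, bank: RepresentationBank) -> np.ndarray:
        kernels = cross_kernel_bank(
            self.train_bank, bank, kernel_specs_for_bank(self.train_bank.names)
        )
        return self.model.predict(kernels)

    def weight_by_representation(self) -> dict[str, float]:
        return self.model.weight_by_representation()


@dataclass
class FittedEnsemble:
    scheme: str
    learner: str
    model: MultiViewEnsembleClassifier
    names: list[str]

    def predict_bank(self, bank: RepresentationBank) -> np.ndarray:
        views = [bank.matrix(n) for n in self.names]
        return np.where(self.model.predict(views) > 0, 1, -1)


# ---------------------------------------------------------------------------
# schemes


def _svc(c: float) -> SVC:
    # iteration cap keeps near-hard-margin fits on non-separable views from
    # stalling the grid; such cells lose validation anyway
    return SVC(kernel="linear", C=c, max_iter=100_000)


def _nn(spec: NetworkSpec, seed: int, config: ModelSelectionConfig) -> MLPBinaryClassifier:
    return MLPBinaryClassifier(
        hidden_layer_sizes=spec.hidden_layer_sizes,
        seed=seed,
        learning_rate=config.nn_learning_rate,
        max_epochs=config.nn_max_epochs,
        patience=config.nn_patience,
    )


def run_single_representation(
    bank: RepresentationBank,
    train: TrainingSet,
    config: ModelSelectionConfig,
    learner: str = "svm",
) -> FittedSingle:
    """Pick the best (representation, hyper-parameter) cell on validation,
    then refit on all training candidates."""
    fit_idx, val_idx = holdout_split(train, config.holdout_fraction, config.seed)
    y = train.y
    best = (-1.0, None)  # (score, payload); strict > keeps first grid cell on ties
    for name in bank.names:
        X = bank.matrix(name)
        if learner == "svm":
            for c in config.c_grid:
                model = _svc(c).fit(X[fit_idx], y[fit_idx])
                score = _f1(y[val_idx], model.predict(X[val_idx]))
                if score > best[0]:
                    best = (score, ("svm", name, c, None))
        elif learner == "nn":
            for spec in enumerate_network_grid(X.shape[1]):
                net = _nn(spec, config.seed, config)
                net.fit(X[fit_idx], y[fit_idx], X[val_idx], y[val_idx])
                pred = np.where(net.predict(X[val_idx]) > 0, 1, -1)
                score = _f1(y[val_idx], pred)
                if score > best[0]:
                    best = (score, ("nn", name, None, spec))
        else:
            raise ContractError(f"unknown learner {learner!r}")
    _, (kind, name, c, spec) = best
    X = bank.matrix(name)
    if kind == "svm":
        model = _svc(c).fit(X, y)
    else:
        model = _nn(spec, config.seed, config)
        model.fit(X[fit_idx], y[fit_idx], X[val_idx], y[val_idx])
    return FittedSingle("single", learner, name, model, c, spec)


def run_concatenation(
    bank: RepresentationBank,
    train: TrainingSet,
    config: ModelSelectionConfig,
    learner: str = "svm",
) -> FittedConcat:
    """Learner on the column-concatenation of all base representations."""
    fit_idx, val_idx = holdout_split(train, config.holdout_fraction, config.seed)
    X = bank.concatenated()
    y = train.y
    best = (-1.0, None)
    if learner == "svm":
        for c in config.c_grid:
            model = _svc(c).fit(X[fit_idx], y[fit_idx])
            score = _f1(y[val_idx], model.predict(X[val_idx]))
            if score > best[0]:
                best = (score, c)
        model = _svc(best[1]).fit(X, y)
        return FittedConcat("concatenation", learner, model, c=best[1])
    if learner == "nn":
        for spec in enumerate_network_grid(X.shape[1]):
            net = _nn(spec, config.seed, config)
            net.fit(X[fit_idx], y[fit_idx], X[val_idx], y[val_idx])
            pred = np.where(net.predict(X[val_idx]) > 0, 1, -1)
            score = _f1(y[val_idx], pred)
            if score > best[0]:
                best = (score, spec)
        model = _nn(best[1], config.seed, config)
        model.fit(X[fit_idx], y[fit_idx], X[val_idx], y[val_idx])
        return FittedConcat("concatenation", learner, model, spec=best[1])
    raise ContractError(f"unknown learner {learner!r}")


def run_combination(
    bank: RepresentationBank,
    train: TrainingSet,
    config: ModelSelectionConfig,
    learner: str = "mkl",
):
    """The combination scheme: EasyMKL over the default kernel bank with
    lambda chosen on validation, or the multi-view ensemble network built
    from per-representation validated locals."""
    fit_idx, val_idx = holdout_split(train, config.holdout_fraction, config.seed)
    y = train.y
    if learner == "mkl":
        kernels = build_kernel_bank(bank)
        sub = [k.values[np.ix_(fit_idx, fit_idx)] for k in kernels]
        cross = [k.values[np.ix_(fit_idx, val_idx)] for k in kernels]
        best = (-1.0, None)
        for lam in config.lambda_grid:
            model = EasyMKL(lam=lam, hardness=config.hardness).fit(sub, y[fit_idx])
            score = _f1(y[val_idx], model.predict(cross))
            if score > best[0]:
                best = (score, lam)
        lam = best[1]
        model = EasyMKL(lam=lam, hardness=config.hardness).fit(kernels, y)
        return FittedMKL("combination", "mkl", model, bank, lam)
    if learner == "nn_ensemble":
        local_specs = []
        for name in bank.names:
            X = bank.matrix(name)
            best = (-1.0, None)
            for spec in enumerate_network_grid(X.shape[1]):
                net = _nn(spec, config.seed, config)
                net.fit(X[fit_idx], y[fit_idx], X[val_idx], y[val_idx])
                pred = np.where(net.predict(X[val_idx]) > 0, 1, -1)
                score = _f1(y[val_idx], pred)
                if score > best[0]:
                    best = (score, spec)
            local_specs.append(best[1])
        ensemble = MultiViewEnsembleClassifier(
            ensemble_spec=build_ensemble(local_specs),
            seed=config.seed,
            learning_rate=config.nn_learning_rate,
            max_epochs=config.nn_max_epochs,
            patience=config.nn_patience,
        )
        views = [bank.matrix(n) for n in bank.names]
        ensemble.fit(
            [v[fit_idx] for v in views], y[fit_idx],
            [v[val_idx] for v in views], y[val_idx],
        )
        return FittedEnsemble("combination", "nn_ensemble", ensemble, list(bank.names))
    raise ContractError(f"unknown learner {learner!r}")


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvalReport:
    """Entity-level counts and metrics for one entity type."""

    entity_type: str
    tp: int
    fp: int
    fn: int
    dictionary_missed: int
    precision: float
    recall: float
    f1: float
    candidate_counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "entity_type": self.entity_type,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "dictionary_missed": self.dictionary_missed,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "candidate_counts": self.candidate_counts,
        }


def evaluate(
    predicted: Iterable[Mention],
    gold: Iterable[Mention],
    dictionary_missed: int = 0,
    entity_type: str = "",
) -> EvalReport:
    """Entity-level evaluation by exact (document, span, type) match.

    *gold* holds the gold mentions that reached the classifier stage;
    *dictionary_missed* counts gold mentions the look-up never proposed —
    they are unreachable and charged as additional false negatives.
    """
    pred_keys = {m.key() for m in predicted}
    gold_keys = {m.key() for m in gold}
    tp = len(pred_keys & gold_keys)
    fp = len(pred_keys - gold_keys)
    fn = len(gold_keys - pred_keys) + dictionary_missed
    p, r, f = _prf(tp, fp, fn)
    return EvalReport(entity_type, tp, fp, fn, dictionary_missed, p, r, f)


# ---------------------------------------------------------------------------
# end-to-end experiment


@dataclass
class ExperimentResult:
    report: EvalReport
    model: object
    labeling_train: LabelingResult
    labeling_test: LabelingResult
    predicted: list[Mention]


def run_experiment(
    train_docs: Sequence[Document],
    test_docs: Sequence[Document],
    gold_train: Sequence[Mention],
    gold_test: Sequence[Mention],
    lexicon: Lexicon,
    rep_config: RepresentationConfig,
    ms_config: ModelSelectionConfig,
    scheme: str = "combination",
    learner: str = "mkl",
    case_mode: str = "exact",
) -> ExperimentResult:
    """Full pipeline for one entity type: dictionary look-up, labeling,
    representations, model selection, prediction and entity-level scoring."""
    etype = lexicon.entity_type
    matcher = build_matcher(lexicon, case_mode)
    train_cands = [
        m for d in train_docs for m in find_candidates(d, matcher)
    ]
    test_cands = [m for d in test_docs for m in find_candidates(d, matcher)]
    gold_train = [g for g in gold_train if g.entity_type == etype]
    gold_test = [g for g in gold_test if g.entity_type == etype]
    labeling_train = label_candidates(train_cands, gold_train)
    labeling_test = label_candidates(test_cands, gold_test)

    train_set = make_training_set(labeling_train.labeled)
    train_bank = build_representation_bank(train_cands, rep_config)
    test_bank = build_representation_bank(test_cands, rep_config)

    if scheme == "single":
        fitted = run_single_representation(train_bank, train_set, ms_config, learner)
    elif scheme == "concatenation":
        fitted = run_concatenation(train_bank, train_set, ms_config, learner)
    elif scheme == "combination":
        fitted = run_combination(train_bank, train_set, ms_config, learner)
    else:
        raise ContractError(f"unknown scheme {scheme!r}")

    pred_labels = fitted.predict_bank(test_bank)
    predicted = [m for m, p in zip(test_cands, pred_labels) if p > 0]

    y_true = np.array([lc.label for lc in labeling_test.labeled])
    cand_tp = int(np.sum((y_true > 0) & (pred_labels > 0)))
    cand_fp = int(np.sum((y_true <= 0) & (pred_labels > 0)))
    cand_fn = int(np.sum((y_true > 0) & (pred_labels <= 0)))
    report = evaluate(
        predicted,
        [lc.mention for lc in labeling_test.labeled if lc.label > 0],
        dictionary_missed=labeling_test.n_missed,
        entity_type=etype,
    )
    cp, cr, cf = _prf(cand_tp, cand_fp, cand_fn)
    report.candidate_counts = {
        "tp": cand_tp, "fp": cand_fp, "fn": cand_fn,
        "precision": cp, "recall": cr, "f1": cf,
    }
    return ExperimentResult(report, fitted, labeling_train, labeling_test, predicted)


def dictionary_recall(labeling: LabelingResult) -> float:
    """Fraction of gold mentions the dictionary look-up proposed at all —
    the hard upper bound on the recall of the whole system."""
    n_gold_found = sum(1 for lc in labeling.labeled if lc.label > 0)
    total = n_gold_found + labeling.n_missed
    return n_gold_found / total if total else 0.0
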