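"""Cross-validated outcome prediction: logistic regression per feature
type, the CNF probability-averaging ensemble, and the subsample
learning-curve experiment.

Performance is the area under the ROC curve (AUC) — the probability that a
random poor-outcome patient is scored above a random good-outcome patient,
with ties credited 0.5 — chosen because the cohorts are class-imbalanced.
The protocol is repeated stratified k-fold cross-validation (default 10
repetitions of 5 folds). Within every training fold, features are z-score
standardized on the training patients only and an L2-regularized logistic
regression is fit; held-out patients are then scored. No feature selection
is performed anywhere.

CNF (Combined Network Features) fits one logistic model per component
feature type — MEAN, MAX, MIN, MED for both the co-expression and the PPI
network, eight models — on identical fold splits and averages their
predicted probabilities per held-out patient before computing AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .data_io import ExpressionDataset, ValidationError
from .features import CNF_COMPONENT_NAMES, FeatureMatrix, compute_features
from .network import GeneNetwork

logger = logging.getLogger(__name__)


@dataclass
class CVConfig:
    n_folds: int = 5
    n_repetitions: int = 10
    seed: int = 0
    stratified: bool = True
    regularization_strength: float = 1.0  # sklearn C (inverse regularization)
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")
        if self.n_repetitions < 1:
            raise ValidationError("n_repetitions must be >= 1")
        if self.regularization_strength <= 0:
            raise ValidationError("regularization_strength must be positive")


@dataclass
class EvaluationResult:
    """Per-fold AUCs of one configuration (repetitions x folds)."""

    feature_type: str
    per_fold_auc: np.ndarray
    config: CVConfig

    @property
    def mean_auc(self) -> float:
        return float(self.per_fold_auc.mean())

    def to_frame(self) -> pd.DataFrame:
        reps, folds = self.per_fold_auc.shape
        return pd.DataFrame(
            {
                "feature_type": self.feature_type,
                "repetition": np.repeat(np.arange(reps), folds),
                "fold": np.tile(np.arange(folds), reps),
                "auc": self.per_fold_auc.ravel(),
            }
        )


@dataclass
class SubsampleConfig:
    percentages: tuple[float, ...] = (0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1)
    n_subsamples: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(0 < p <= 1 for p in self.percentages):
            raise ValidationError("percentages must lie in (0, 1]")
        if self.n_subsamples < 1:
            raise ValidationError("n_subsamples must be >= 1")


# -- AUC --------------------------------------------------------------------


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-statistic AUC: P(random positive outranks random negative),
    ties counted 0.5. Equals the Mann-Whitney U statistic / (n1 * n2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValidationError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


# -- cross-validation -------------------------------------------------------


def _repetition_seeds(config: CVConfig) -> list[int]:
    """One fold-shuffling seed per repetition, derived from the master seed."""
    state = np.random.SeedSequence(config.seed).generate_state(config.n_repetitions)
    return [int(s) % (2**31 - 1) for s in state]


def fold_assignments(labels: Sequence[int], config: CVConfig) -> list[list[np.ndarray]]:
    """Test-index arrays for every repetition x fold, fully seed-determined."""
    y = np.asarray(labels)
    dummy = np.zeros((len(y), 1))
    out = []
    for rep_seed in _repetition_seeds(config):
        cls = StratifiedKFold if config.stratified else KFold
        splitter = cls(n_splits=config.n_folds, shuffle=True, random_state=rep_seed)
        out.append([test for _, test in splitter.split(dummy, y)])
    return out


def fit_fold_model(
    X_train: np.ndarray, y_train: np.ndarray, config: CVConfig
) -> tuple[StandardScaler, LogisticRegression]:
    """Standardize on the training patients only, then fit the classifier."""
    scaler = StandardScaler().fit(X_train)
    model = LogisticRegression(  # default penalty is L2
        C=config.regularization_strength,
        solver="lbfgs",
        max_iter=config.max_iter,
        random_state=0,
    ).fit(scaler.transform(X_train), y_train)
    return scaler, model


def _check_fold(y: np.ndarray, test_idx: np.ndarray, rep: int, fold: int) -> None:
    for part, idx in (("test", test_idx), ("train", np.setdiff1d(np.arange(len(y)), test_idx))):
        if len(np.unique(y[idx])) < 2:
            raise ValidationError(
                f"degenerate {part} split (single class) in repetition {rep}, fold {fold}"
            )


def run_cv(
    features: FeatureMatrix, outcome: Sequence[int], config: CVConfig
) -> EvaluationResult:
    """Repeated stratified k-fold CV AUC of one feature type.

    Fully reproducible: (seed, config, data) determine every fold split and
    every AUC.
    """
    X = features.values.to_numpy(dtype=float).T  # patients x features
    y = np.asarray(outcome)
    aucs = np.empty((config.n_repetitions, config.n_folds))
    for rep, folds in enumerate(fold_assignments(y, config)):
        for fold, test_idx in enumerate(folds):
            _check_fold(y, test_idx, rep, fold)
            train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
            scaler, model = fit_fold_model(X[train_idx], y[train_idx], config)
            scores = model.predict_proba(scaler.transform(X[test_idx]))[:, 1]
            aucs[rep, fold] = auc(scores, y[test_idx])
    return EvaluationResult(features.ftype.name, aucs, config)


# -- CNF ensemble -----------------------------------------------------------


def cnf_predict(component_probabilities: Sequence[Sequence[float]]) -> np.ndarray:
    """Elementwise arithmetic mean of the component probability vectors."""
    mats = [np.asarray(p, dtype=float) for p in component_probabilities]
    lengths = {len(m) for m in mats}
    if len(lengths) != 1:
        raise ValidationError(f"component vectors differ in length: {sorted(lengths)}")
    stacked = np.vstack(mats)
    if np.any((stacked < 0) | (stacked > 1)):
        raise ValidationError("probabilities must lie in [0, 1]")
    return stacked.mean(axis=0)


def cnf_feature_matrices(
    dataset: ExpressionDataset, networks: Mapping[str, GeneNetwork]
) -> dict[str, FeatureMatrix]:
    """The eight CNF component matrices (MEAN/MAX/MIN/MED x CE/PPI)."""
    for ctx in ("CE", "PPI"):
        if ctx not in networks:
            raise ValidationError(f"CNF needs a {ctx} network")
    return {
        name: compute_features(
            dataset, name, networks["CE" if name.startswith("CE") else "PPI"]
        )
        for name in CNF_COMPONENT_NAMES
    }


def run_cnf_cv(
    dataset: ExpressionDataset,
    networks: Mapping[str, GeneNetwork],
    config: CVConfig,
    component_matrices: Optional[Mapping[str, FeatureMatrix]] = None,
) -> EvaluationResult:
    """CV AUC of the CNF ensemble.

    All eight component models share identical fold splits within a
    repetition, so the ensemble probability is a well-defined per-held-out-
    patient average. Pass precomputed ``component_matrices`` to avoid
    recomputing features across repeated calls.
    """
    if dataset.outcome is None:
        raise ValidationError("dataset has no outcome labels")
    if component_matrices is None:
        component_matrices = cnf_feature_matrices(dataset, networks)
    Xs = {
        name: fm.values.to_numpy(dtype=float).T for name, fm in component_matrices.items()
    }
    y = dataset.outcome.to_numpy()
    aucs = np.empty((config.n_repetitions, config.n_folds))
    for rep, folds in enumerate(fold_assignments(y, config)):
        for fold, test_idx in enumerate(folds):
            _check_fold(y, test_idx, rep, fold)
            train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
            probs = []
            for name in component_matrices:
                X = Xs[name]
                scaler, model = fit_fold_model(X[train_idx], y[train_idx], config)
                probs.append(model.predict_proba(scaler.transform(X[test_idx]))[:, 1])
            aucs[rep, fold] = auc(cnf_predict(probs), y[test_idx])
    return EvaluationResult("CNF", aucs, config)


def evaluate_feature_type(
    dataset: ExpressionDataset,
    ftype_name: str,
    networks: Mapping[str, GeneNetwork],
    config: CVConfig,
) -> EvaluationResult:
    """CV AUC of a single named feature type (or "CNF")."""
    if dataset.outcome is None:
        raise ValidationError("dataset has no outcome labels")
    if ftype_name == "CNF":
        return run_cnf_cv(dataset, networks, config)
    network = None
    if ftype_name != "Gene":
        network = networks["CE" if ftype_name.startswith("CE") else "PPI"]
    fm = compute_features(dataset, ftype_name, network)
    return run_cv(fm, dataset.outcome.to_numpy(), config)


# -- subsample learning curve ----------------------------------------------


def stratified_subsample(
    dataset: ExpressionDataset, fraction: float, rng: np.random.Generator
) -> ExpressionDataset:
    """Class-stratified draw without replacement preserving the class ratio
    to the nearest patient."""
    if dataset.outcome is None:
        raise ValidationError("dataset has no outcome labels")
    ids = np.asarray(dataset.patient_ids)
    y = dataset.outcome.to_numpy()
    keep: list[str] = []
    for label in (0, 1):
        pool = ids[y == label]
        n_take = int(np.floor(fraction * len(pool) + 0.5))
        if n_take < 1:
            raise ValidationError(
                f"fraction {fraction} leaves no patients of class {label}"
            )
        keep.extend(rng.choice(pool, size=n_take, replace=False))
    return dataset.subset_patients(sorted(keep))


def subsample_experiment(
    dataset: ExpressionDataset,
    networks: Mapping[str, GeneNetwork],
    cv: CVConfig,
    sub: SubsampleConfig,
    feature_types: Sequence[str] = ("Gene", "CNF"),
) -> pd.DataFrame:
    """Learning curve: mean CV AUC per (feature type, subsample percentage).

    For each percentage, ``n_subsamples`` stratified draws without
    replacement are evaluated with the full CV protocol; the returned frame
    has one row per (feature_type, percentage, subsample) with its mean AUC.
    """
    ss = np.random.SeedSequence(sub.seed)
    rows = []
    for pct, child in zip(sub.percentages, ss.spawn(len(sub.percentages))):
        for i, sub_seed in enumerate(child.spawn(sub.n_subsamples)):
            rng = np.random.default_rng(sub_seed)
            subset = stratified_subsample(dataset, pct, rng)
            counts = np.bincount(subset.outcome.to_numpy(), minlength=2)
            if counts.min() < cv.n_folds:
                raise ValidationError(
                    f"percentage {pct} leaves class counts {counts.tolist()} "
                    f"< n_folds={cv.n_folds}"
                )
            for ftype in feature_types:
                res = evaluate_feature_type(subset, ftype, networks, cv)
                rows.append((ftype, pct, i, res.mean_auc))
                logger.info(
                    "subsample pct=%.2f draw=%d %s AUC=%.3f", pct, i, ftype, res.mean_auc
                )
    return pd.DataFrame(
        rows, columns=["feature_type", "percentage", "subsample", "mean_auc"]
    )


__all__ = [
    "CVConfig",
    "EvaluationResult",
    "SubsampleConfig",
    "auc",
    "fold_assignments",
    "fit_fold_model",
    "run_cv",
    "cnf_predict",
    "cnf_feature_matrices",
    "run_cnf_cv",
    "evaluate_feature_type",
    "stratified_subsample",
    "subsample_experiment",
]
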