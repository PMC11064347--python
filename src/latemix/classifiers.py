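"""Six-classifier bank over encoded omic subspaces.

Each encoded omic (plus age, sex, BMI) feeds six standard classifier
families — random forest, linear and RBF SVM, LDA, gradient boosting and a
one-hidden-layer MLP — tuned by stratified 5-fold cross-validation with
macro-F1 as the selection criterion. The bank's outputs are 3-class
membership probabilities for the 1-sd classes; out-of-fold probabilities on
the training sample are kept for the downstream VCDN meta-learner so that
the fusion step never sees in-sample classifier fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_predict
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .preprocess import TrainingScaler, _provenance

__all__ = ["CLASS_ORDER", "CLASSIFIER_FAMILIES", "ProbabilityMatrix",
           "make_classifier", "assemble_features", "fit_bank_cv",
           "predict_bank", "hard_labels"]

CLASS_ORDER = (-1, 0, 1)

# family -> (constructor, small tuning grid). Grids are deliberately compact;
# the harness, not the per-family search breadth, is the point.
CLASSIFIER_FAMILIES: dict[str, tuple] = {
    "random_forest": (
        lambda seed: RandomForestClassifier(n_estimators=200, random_state=seed),
        {"max_features": ["sqrt", 0.5]}),
    # SVMs expose probabilities through sigmoid calibration; grid keys
    # address the wrapped estimator
    "svm_linear": (
        lambda seed: CalibratedClassifierCV(
            SVC(kernel="linear", random_state=seed), ensemble=False),
        {"estimator__C": [0.1, 1.0, 10.0]}),
    "svm_rbf": (
        lambda seed: CalibratedClassifierCV(
            SVC(kernel="rbf", random_state=seed), ensemble=False),
        {"estimator__C": [1.0, 10.0]}),
    "lda": (lambda seed: LinearDiscriminantAnalysis(), {}),
    "gbm": (
        lambda seed: GradientBoostingClassifier(n_estimators=100, random_state=seed),
        {"max_depth": [2, 3]}),
    "mlp_1hidden": (
        lambda seed: MLPClassifier(hidden_layer_sizes=(32,), max_iter=800,
                                   random_state=seed),
        {"alpha": [1e-4, 1e-2]}),
}


def make_classifier(family: str, seed: int = 0):
    """Instantiate one of the six families with its tuning grid."""
    if family not in CLASSIFIER_FAMILIES:
        raise ValueError(f"unknown classifier family {family!r}; "
                         f"choose from {sorted(CLASSIFIER_FAMILIES)}")
    ctor, grid = CLASSIFIER_FAMILIES[family]
    return ctor(seed), grid


@dataclass
class ProbabilityMatrix:
    """Samples x 3 class-membership probabilities over classes (-1, 0, +1)."""

    probs: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        values = self.probs.to_numpy()
        if values.min() < -1e-9 or values.max() > 1 + 1e-9:
            raise ValueError("probabilities outside [0, 1]")
        row_sums = values.sum(axis=1)
        if np.abs(row_sums - 1.0).max() > 1e-8:
            raise ValueError("probability rows must sum to 1")

    def hard(self) -> np.ndarray:
        return hard_labels(self.probs.to_numpy())


def hard_labels(probs: np.ndarray) -> np.ndarray:
    """Argmax class per row; exact ties break toward the mid class 0, then
    toward -1, then +1."""
    probs = np.asarray(probs, dtype=float)
    preference = [1, 0, 2]  # column order of preference: class 0, -1, +1
    best = probs.max(axis=1, keepdims=True)
    out = np.empty(len(probs), dtype=int)
    for i, row in enumerate(probs):
        tied = np.flatnonzero(row == best[i])
        col = next(c for c in preference if c in tied)
        out[i] = CLASS_ORDER[col]
    return out


def assemble_features(subspace: pd.DataFrame, covariates: pd.DataFrame,
                      train_mask: np.ndarray,
                      scale_covariates: bool = True) -> pd.DataFrame:
    """Classifier design matrix: z-scored subspace columns + age/sex/BMI.

    Scaling statistics come from training samples only (the z-scoring of test
    rows reuses training means/sds).
    """
    if not subspace.index.equals(covariates.index):
        raise ValueError("subspace and covariates sample ids misaligned")
    train_mask = np.asarray(train_mask, dtype=bool)
    scaler = TrainingScaler("zscore").fit(subspace.loc[train_mask])
    scaler.stats_.provenance = _provenance(subspace.index, train_mask)
    scaled = scaler.transform(subspace)
    cov = covariates[["age", "sex", "bmi"]]
    if scale_covariates:
        cov_scaler = TrainingScaler("zscore").fit(cov.loc[train_mask])
        cov = cov_scaler.transform(cov)
    out = pd.concat([scaled, cov], axis=1)
    out.attrs["provenance"] = scaler.stats_.provenance
    return out


def fit_bank_cv(features: pd.DataFrame, labels: np.ndarray,
                families=None, seed: int = 0, cv_folds: int = 5) -> dict:
    """Tune and fit each family on the training sample; keep out-of-fold probs.

    Per family: a stratified ``cv_folds``-fold grid search selects the
    configuration with the best macro-F1, the winner is refit on the full
    training sample, and out-of-fold probabilities under the winning
    configuration (each sample predicted by the model that never saw it) are
    stored for the meta-learner. Fold assignments are recorded for the
    leakage audit.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if set(CLASS_ORDER) - set(classes):
        raise ValueError(f"classes missing from training labels: "
                         f"{sorted(set(CLASS_ORDER) - set(classes))}")
    if counts.min() < 2:
        raise ValueError("need at least 2 training samples of every class")
    families = list(families) if families is not None else list(CLASSIFIER_FAMILIES)
    X = features.to_numpy(dtype=float)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    fold_of = np.empty(len(labels), dtype=int)
    for f, (_, val_idx) in enumerate(cv.split(X, labels)):
        fold_of[val_idx] = f
    bank = {}
    for family in families:
        estimator, grid = make_classifier(family, seed)
        if grid:
            search = GridSearchCV(estimator, grid, scoring="f1_macro", cv=cv,
                                  refit=True, n_jobs=1)
            search.fit(X, labels)
            best = search.best_estimator_
            best_params = search.best_params_
        else:
            best = estimator.fit(X, labels)
            best_params = {}
        oof = cross_val_predict(best, X, labels, cv=cv, method="predict_proba")
        oof = _ordered(oof, best.classes_, features.index)
        bank[family] = {
            "estimator": best,
            "best_params": best_params,
            "oof": ProbabilityMatrix(oof, provenance={
                "classifier": family, "fold_origin": "out_of_fold",
                "folds": fold_of.tolist()}),
        }
    return bank


def _ordered(probs: np.ndarray, fitted_classes, index) -> pd.DataFrame:
    """Reorder probability columns to the canonical (-1, 0, +1) order and
    renormalise away floating-point drift."""
    cols = {int(c): probs[:, i] for i, c in enumerate(fitted_classes)}
    out = np.column_stack([cols[c] for c in CLASS_ORDER])
    out = np.clip(out, 0.0, None)
    out /= out.sum(axis=1, keepdims=True)
    return pd.DataFrame(out, index=index, columns=list(CLASS_ORDER))


def predict_bank(bank: dict, features_test: pd.DataFrame) -> dict[str, ProbabilityMatrix]:
    """Test-sample class probabilities from every fitted family."""
    out = {}
    for family, entry in bank.items():
        est = entry["estimator"]
        if features_test.shape[1] != est.n_features_in_:
            raise ValueError(
                f"feature width {features_test.shape[1]} != fitted width "
                f"{est.n_features_in_} for {family}")
        probs = est.predict_proba(features_test.to_numpy(dtype=float))
        out[family] = ProbabilityMatrix(
            _ordered(probs, est.classes_, features_test.index),
            provenance={"classifier": family, "fold_origin": "test"})
    return out
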