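"""Target adjustment, feature filtering, training-statistics scaling and
1-sd class construction.

Every statistic fitted here (regression coefficients, correlations, minima,
maxima, means, sds) derives from samples labelled ``train`` only — never from
validation or test samples — and each fitted artifact carries a provenance
record so that the no-leakage contract can be audited after the fact.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "AdjustedTargets", "FeatureMask", "ScalingStats", "SdClassLabels",
    "TrainingScaler", "SdClassBinner",
    "residualize_targets", "filter_transcripts", "select_features_by_list",
    "fit_scaler", "apply_scaler", "assign_sd_classes", "verify_provenance",
]


def _provenance(index: pd.Index, train_mask: np.ndarray) -> dict:
    ids = index[np.asarray(train_mask, dtype=bool)]
    digest = hashlib.sha1("\n".join(map(str, ids)).encode()).hexdigest()
    return {"source_split": "train", "n_train": int(len(ids)), "ids_hash": digest}


def verify_provenance(artifact, index: pd.Index, train_mask: np.ndarray) -> bool:
    """Check that an artifact's statistics were fitted on exactly the given
    training samples. Raises if the recorded provenance does not match."""
    expected = _provenance(index, train_mask)
    recorded = artifact.provenance
    if recorded != expected:
        raise AssertionError(
            f"provenance mismatch: fitted on {recorded}, expected {expected}")
    return True


# ---------------------------------------------------------------------------
# target residualization

@dataclass
class AdjustedTargets:
    """Residualized, z-scored targets (the supervision matrix Y).

    ``values`` holds, for every sample, the OLS residual of each target on
    intercept + age + sex + BMI — coefficients fitted on training samples
    only — standardized by the training-residual mean and sd.
    """

    values: pd.DataFrame
    coefficients: pd.DataFrame        # (intercept, age, sex, bmi) x targets
    residual_mean: pd.Series
    residual_sd: pd.Series
    provenance: dict = field(default_factory=dict)


def residualize_targets(targets: pd.DataFrame, covariates: pd.DataFrame,
                        train_mask: np.ndarray) -> AdjustedTargets:
    """Adjust each target for age, sex and BMI and z-score the residuals.

    The adjustment removes covariate-driven variation so that learned omic
    representations do not simply encode age, sex or BMI.
    """
    train_mask = np.asarray(train_mask, dtype=bool)
    if train_mask.sum() < 10:
        raise ValueError("need at least 10 training samples to residualize")
    if covariates.isna().any().any():
        raise ValueError("covariates contain missing values")
    X = np.column_stack([np.ones(len(covariates)),
                         covariates[["age", "sex", "bmi"]].to_numpy()])
    Xtr = X[train_mask]
    out = {}
    coefs = {}
    means, sds = {}, {}
    for name in targets.columns:
        y = targets[name].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(Xtr, y[train_mask], rcond=None)
        resid = y - X @ beta
        mu = resid[train_mask].mean()
        sd = resid[train_mask].std(ddof=1)
        if sd < 1e-12:
            raise ValueError(f"degenerate target {name!r}: residual sd ~ 0")
        out[name] = (resid - mu) / sd
        coefs[name] = beta
        means[name], sds[name] = mu, sd
    values = pd.DataFrame(out, index=targets.index)
    coefficients = pd.DataFrame(coefs, index=["intercept", "age", "sex", "bmi"])
    return AdjustedTargets(values, coefficients, pd.Series(means), pd.Series(sds),
                           provenance=_provenance(targets.index, train_mask))


# ---------------------------------------------------------------------------
# feature filtering

@dataclass
class FeatureMask:
    """Per-feature retention flags with a reason code per retained feature.

    Reason codes: ``bp_corr`` (correlated with an adjusted blood-pressure
    target), ``lvdd_corr_var`` (correlated with an adjusted LVDD biomarker
    and variance above threshold), ``supplied_list`` (user-supplied id list),
    ``unfiltered``; excluded features carry ``excluded`` or ``zero_variance``.
    """

    feature_ids: pd.Index
    retained: np.ndarray
    reasons: np.ndarray
    provenance: dict = field(default_factory=dict)

    def apply(self, block: pd.DataFrame) -> pd.DataFrame:
        return block.loc[:, self.retained]

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())


def _pearson_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided Pearson nullity-test p-values of every column of X vs y,
    via the t transform t = r sqrt((n-2)/(1-r^2)). Zero-variance columns
    get p = 1 (correlation undefined; caller excludes them)."""
    n = len(y)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc * yc[:, None]).sum(axis=0) / (sx * sy)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(t), 1.0, np.where(np.isinf(t), 0.0, p))
    p = np.where(sx == 0, 1.0, p)
    return p


def filter_transcripts(block: pd.DataFrame, adjusted: AdjustedTargets,
                       train_mask: np.ndarray, p_thresh: float = 0.05,
                       var_thresh: float = 0.01) -> FeatureMask:
    """Retain transcripts correlated with adjusted blood pressure, or with an
    adjusted LVDD biomarker while exceeding a raw-variance floor.

    A feature passes if (a) its Pearson correlation with adjusted SBP or DBP
    is nominally significant (two-sided p < ``p_thresh``), or (b) it is
    nominally correlated with any adjusted LVDD target (E/e', E/A, LAVI) and
    its training variance exceeds ``var_thresh``. All statistics use training
    samples only; no multiplicity correction is applied. Zero-variance
    features are excluded (correlation undefined), not an error.
    """
    train_mask = np.asarray(train_mask, dtype=bool)
    X = block.to_numpy(dtype=float)[train_mask]
    A = adjusted.values.loc[block.index[train_mask]]
    variances = X.var(axis=0, ddof=1)
    zero_var = variances == 0

    bp_p = np.minimum(_pearson_pvalues(X, A["sbp"].to_numpy()),
                      _pearson_pvalues(X, A["dbp"].to_numpy()))
    lvdd_p = np.min([_pearson_pvalues(X, A[t].to_numpy())
                     for t in ("e_over_eprime", "e_over_a", "lavi")], axis=0)

    bp_hit = (bp_p < p_thresh) & ~zero_var
    lvdd_hit = (lvdd_p < p_thresh) & (variances > var_thresh) & ~zero_var
    retained = bp_hit | lvdd_hit
    reasons = np.full(block.shape[1], "excluded", dtype=object)
    reasons[lvdd_hit] = "lvdd_corr_var"
    reasons[bp_hit] = "bp_corr"     # bp criterion takes precedence in the label
    reasons[zero_var] = "zero_variance"
    return FeatureMask(block.columns, retained, reasons,
                       provenance=_provenance(block.index, train_mask))


def select_features_by_list(block: pd.DataFrame, id_list) -> FeatureMask:
    """Retain exactly the features named in a user-supplied id list (e.g. a
    literature-replicated CpG panel); warns about ids absent from the block."""
    id_list = list(id_list)
    if not id_list:
        raise ValueError("id_list must be non-empty")
    present = set(block.columns)
    missing = [i for i in id_list if i not in present]
    if len(missing) == len(id_list):
        raise ValueError("none of the supplied feature ids are present in the block")
    if missing:
        warnings.warn(f"{len(missing)} supplied feature ids not in block: "
                      f"{missing[:10]}", stacklevel=2)
    wanted = set(id_list)
    retained = block.columns.isin(wanted)
    reasons = np.where(retained, "supplied_list", "excluded").astype(object)
    return FeatureMask(block.columns, retained, reasons,
                       provenance={"source_split": "none", "supplied_ids": len(id_list)})


# ---------------------------------------------------------------------------
# scaling

@dataclass
class ScalingStats:
    """Per-feature scaling statistics computed on training samples only."""

    method: str                      # "minmax" | "zscore"
    feature_ids: pd.Index
    stat_a: np.ndarray               # min (minmax) or mean (zscore)
    stat_b: np.ndarray               # max (minmax) or sd (zscore)
    provenance: dict = field(default_factory=dict)


class TrainingScaler(BaseEstimator, TransformerMixin):
    """Min-max or z-score scaling with statistics frozen on the fitted rows.

    Transcriptomic blocks use ``minmax`` (training columns map onto [0,1]);
    metabolomic blocks use ``zscore``. Test values may fall outside the
    training range and are deliberately not clipped. Methylation beta values
    bypass scaling entirely in the pipeline.
    """

    def __init__(self, method: str = "minmax"):
        self.method = method

    def fit(self, X: pd.DataFrame, y=None):
        if self.method not in ("minmax", "zscore"):
            raise ValueError(f"unknown scaling method {self.method!r}")
        values = np.asarray(X, dtype=float)
        if self.method == "minmax":
            a, b = values.min(axis=0), values.max(axis=0)
            bad = np.flatnonzero(b == a)
        else:
            a = values.mean(axis=0)
            b = values.std(axis=0, ddof=1)
            bad = np.flatnonzero(b == 0)
        if len(bad):
            names = (list(X.columns[bad[:5]]) if isinstance(X, pd.DataFrame)
                     else bad[:5].tolist())
            raise ValueError(f"degenerate features for {self.method}: {names}")
        self.stats_ = ScalingStats(
            self.method,
            X.columns if isinstance(X, pd.DataFrame) else pd.RangeIndex(values.shape[1]),
            a, b)
        return self

    def transform(self, X) -> pd.DataFrame | np.ndarray:
        s = self.stats_
        values = np.asarray(X, dtype=float)
        if s.method == "minmax":
            out = (values - s.stat_a) / (s.stat_b - s.stat_a)
        else:
            out = (values - s.stat_a) / s.stat_b
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out


def fit_scaler(block: pd.DataFrame, train_mask: np.ndarray,
               method: str) -> ScalingStats:
    train_mask = np.asarray(train_mask, dtype=bool)
    scaler = TrainingScaler(method).fit(block.loc[train_mask])
    stats_ = scaler.stats_
    stats_.provenance = _provenance(block.index, train_mask)
    return stats_


def apply_scaler(block: pd.DataFrame, stats_: ScalingStats) -> pd.DataFrame:
    scaler = TrainingScaler(stats_.method)
    scaler.stats_ = stats_
    return scaler.transform(block)


# ---------------------------------------------------------------------------
# 1-sd classing

@dataclass
class SdClassLabels:
    """Three-way labels per target: -1 / 0 / +1 for below, within, above one
    training sd of the training mean. Classing uses the unadjusted targets."""

    labels: pd.DataFrame
    train_mean: pd.Series
    train_sd: pd.Series
    provenance: dict = field(default_factory=dict)


class SdClassBinner(BaseEstimator, TransformerMixin):
    """Bin a continuous target into 1-sd classes around the training mean.

    Label +1 iff y > mean + sd, -1 iff y < mean - sd, else 0; values exactly
    on a boundary fall in class 0 (deviant classes require strict exceedance).
    The rule is invariant to positive affine maps of the target.
    """

    def fit(self, y, sample_weight=None):
        y = np.asarray(y, dtype=float)
        self.mean_ = y.mean()
        self.sd_ = y.std(ddof=1)
        if self.sd_ < 1e-12:
            raise ValueError("degenerate target: training sd ~ 0")
        return self

    def transform(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        labels = np.zeros(y.shape, dtype=int)
        labels[y > self.mean_ + self.sd_] = 1
        labels[y < self.mean_ - self.sd_] = -1
        return labels


def assign_sd_classes(targets: pd.DataFrame,
                      train_mask: np.ndarray) -> SdClassLabels:
    """Assign every sample to a 1-sd class per target, using the training
    mean and sd of the raw (unadjusted) target values."""
    train_mask = np.asarray(train_mask, dtype=bool)
    labels, means, sds = {}, {}, {}
    for name in targets.columns:
        binner = SdClassBinner().fit(targets[name].to_numpy()[train_mask])
        labels[name] = binner.transform(targets[name].to_numpy())
        means[name], sds[name] = binner.mean_, binner.sd_
    return SdClassLabels(pd.DataFrame(labels, index=targets.index),
                         pd.Series(means), pd.Series(sds),
                         provenance=_provenance(targets.index, train_mask))
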