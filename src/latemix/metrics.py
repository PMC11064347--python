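"""Evaluation mathematics: per-class and macro F1, the naive baseline, the
rank-based AUC, and variance-explained ladders on predicted probabilities.

Macro-F1 is the unweighted mean of the three 1-sd class F1 scores, which
rewards models for performing on the rare deviant classes (~15% each) as
much as on the dominant mid class. A prevalence-proportional random
predictor has expected per-class F1 equal to the class prevalence, so its
expected macro-F1 is 1/c — 33.3% for three classes — regardless of how
imbalanced the design is.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["f1_scores", "naive_macro_f1", "auc_binary", "prob_regression_r2"]

_CLASSES = (-1, 0, 1)


def f1_scores(true_labels, pred_labels) -> dict:
    """One-vs-rest F1 per 1-sd class plus the macro average.

    F1 = 2PR/(P+R) with precision P = TP/(TP+FP) and recall R = TP/(TP+FN);
    a class with TP = 0 and any FP or FN gets F1 = 0, and a class absent
    from both truth and prediction gets F1 = 0 with a warning.
    """
    t = np.asarray(true_labels)
    p = np.asarray(pred_labels)
    if t.shape != p.shape:
        raise ValueError("label vectors must have the same length")
    bad = set(np.unique(t)) | set(np.unique(p))
    if bad - set(_CLASSES):
        raise ValueError(f"labels outside {{-1,0,+1}}: {sorted(bad - set(_CLASSES))}")
    out = {}
    for c in _CLASSES:
        tp = int(np.sum((t == c) & (p == c)))
        fp = int(np.sum((t != c) & (p == c)))
        fn = int(np.sum((t == c) & (p != c)))
        if tp == 0 and fp == 0 and fn == 0:
            warnings.warn(f"class {c} absent from truth and prediction; F1 set to 0",
                          stacklevel=2)
            out[c] = 0.0
        elif tp == 0:
            out[c] = 0.0
        else:
            prec = tp / (tp + fp)
            rec = tp / (tp + fn)
            out[c] = 2 * prec * rec / (prec + rec)
    out["macro"] = float(np.mean([out[c] for c in _CLASSES]))
    return out


def naive_macro_f1(prevalences) -> float:
    """Expected macro-F1 of a prevalence-proportional random predictor.

    For class c with prevalence q, expected precision and recall both equal
    q, so expected F1 ~ q and the macro average is mean(q) = 1/c exactly —
    1/3 under any three-class design, including 15/70/15.
    """
    q = np.asarray(prevalences, dtype=float)
    if np.any(q <= 0):
        raise ValueError("every class prevalence must be positive")
    if abs(q.sum() - 1.0) > 1e-8:
        raise ValueError("prevalences must sum to 1")
    return float(q.mean())


def auc_binary(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC; tied scores count one half.

    Equals the probability that a random positive outranks a random
    negative. Requires both classes present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(s, method="average")
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    design = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("zero-variance outcome: R^2 undefined")
    return 1.0 - float(np.sum(resid ** 2)) / sst


def prob_regression_r2(y_continuous, predictor_sets: dict) -> pd.Series:
    """R-squared ladder of OLS fits over nested predictor sets.

    ``predictor_sets`` maps a label to a 2-D predictor array; sets are
    evaluated in insertion order, e.g. P(high) alone, then + P(low), then
    + age/sex/BMI. Along a genuinely nested ladder the R-squared values are
    non-decreasing.
    """
    y = np.asarray(y_continuous, dtype=float)
    out = {}
    for name, X in predictor_sets.items():
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        out[name] = _ols_r2(y, X)
    return pd.Series(out, name="r2")
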