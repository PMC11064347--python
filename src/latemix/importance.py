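"""Connection-Weights (Olden) variable importance for the SSAE.

The importance of input feature i for target j, RI_i(j), is the sum over all
network paths from input i to head output j of the product of the connection
weights along the path — equivalently the matrix product of the encoder and
1LP weight matrices, W1 @ W2 @ H1 @ H2. Biases are excluded and activations
ignored, as in the standard Olden formulation; with linear activations the
product is exactly the network's input-to-output Jacobian. Signs are
preserved, so a negative RI means the feature pushes the predicted target
down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .autoencoder import SemiSupervisedAutoencoder

__all__ = ["ImportanceMatrix", "connection_weights", "rank_importance"]


@dataclass
class ImportanceMatrix:
    """Raw, z-scored and percentile-ranked importance, features x targets.

    ``zscored`` standardises each target's column across features (population
    moments, so columns have mean 0 and sd 1 exactly). ``percentile`` ranks
    |RI| from the top with mid-rank ties: the single most important feature
    of a 100-feature block sits at the 1st percentile.
    """

    raw: pd.DataFrame
    zscored: pd.DataFrame
    percentile: pd.DataFrame


def _top_percentile(abs_values: np.ndarray) -> np.ndarray:
    ranks = rankdata(-abs_values, method="average")
    return 100.0 * ranks / len(abs_values)


def connection_weights(model: SemiSupervisedAutoencoder,
                       feature_ids=None, target_names=None) -> ImportanceMatrix:
    """Compute RI = W1 @ W2 @ H1 @ H2 through the encoder and grafted head."""
    if not hasattr(model, "encoder_layers_"):
        raise ValueError("model must be initialised/trained first")
    W1, W2 = (lay.W for lay in model.encoder_layers_)
    H1, H2 = (lay.W for lay in model.head_layers_)
    ri = W1 @ W2 @ H1 @ H2
    if feature_ids is None:
        feature_ids = [f"x{i}" for i in range(ri.shape[0])]
    if target_names is None:
        target_names = [f"y{j}" for j in range(ri.shape[1])]
    raw = pd.DataFrame(ri, index=pd.Index(feature_ids, name="feature"),
                       columns=target_names)
    zscored = (raw - raw.mean()) / raw.std(ddof=0)
    percentile = raw.abs().apply(lambda c: _top_percentile(c.to_numpy()))
    return ImportanceMatrix(raw, zscored, percentile)


def rank_importance(imp: ImportanceMatrix, focus_ids=None, top_k: int = 10) -> dict:
    """Ranked-importance report per target.

    Returns, per target: the ``top_k`` features by absolute z-scored RI with
    their signed values, and — when ``focus_ids`` names a feature set of
    interest (e.g. literature-replicated genes) — each focus feature's
    |RI| percentile plus the percentile at which the focus set's mean |RI|
    would sit among all features' |RI| values.
    """
    if imp.raw.empty:
        raise ValueError("empty importance matrix")
    focus_ids = list(focus_ids) if focus_ids is not None else []
    present = [f for f in focus_ids if f in imp.raw.index]
    missing = [f for f in focus_ids if f not in imp.raw.index]
    if missing:
        import warnings
        warnings.warn(f"{len(missing)} focus ids not in importance matrix",
                      stacklevel=2)
    report = {"targets": {}, "missing_focus_ids": missing}
    for target in imp.raw.columns:
        z = imp.zscored[target]
        order = z.abs().sort_values(ascending=False).index[:top_k]
        top = pd.DataFrame({
            "RI": imp.raw.loc[order, target],
            "zRI": z.loc[order],
            "percentile": imp.percentile.loc[order, target],
        })
        entry = {"top": top}
        if present:
            abs_all = imp.raw[target].abs().to_numpy()
            entry["focus_percentiles"] = imp.percentile.loc[present, target]
            mean_focus = imp.raw.loc[present, target].abs().mean()
            entry["focus_mean_percentile"] = float(
                100.0 * (np.sum(abs_all > mean_focus) + 1) / len(abs_all))
        report["targets"][target] = entry
    return report
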