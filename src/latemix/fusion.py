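"""Late integration: Cross-omics Discovery Tensor + View Correlation
Discovery Network.

For each sample, the per-omic classifiers emit c = 3 class-membership
probabilities per view. The Cross-omics Discovery Tensor (CoDT) takes every
cross-view product — entry (i, j, k) = a_i * b_j * c_k for three views —
flattened lexicographically (view 1's class index most significant) into a
vector of length c^m = 27 for three omics. Because each input row sums to 1,
the pre-rescale entries always sum to 1; entries are rescaled by c^m so a
uniform tensor has unit entries, which keeps early-training gradients
well-scaled.

The VCDN is a small fully connected net, c^m -> c^2 (LeakyReLU) -> c, whose
output is mapped onto the probability simplex by a softmax and trained with
cross-entropy under Adam. One VCDN is trained per (target, classifier
family), on out-of-fold training probabilities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from ._nn import Adam, Dense
from .classifiers import CLASS_ORDER, ProbabilityMatrix, hard_labels

__all__ = ["build_codt", "build_codt_matrix", "VCDNClassifier",
           "train_vcdn", "predict_vcdn"]


def build_codt(prob_vectors, rescale: float | None = None) -> np.ndarray:
    """CoDT for a single sample from m per-view probability vectors.

    Each vector must be nonnegative and sum to 1 (within 1e-6). The default
    rescale factor is c^m.
    """
    vectors = [np.asarray(v, dtype=float) for v in prob_vectors]
    if len(vectors) < 2:
        raise ValueError("need at least two views")
    c = len(vectors[0])
    for v in vectors:
        if v.ndim != 1 or len(v) != c:
            raise ValueError("all probability vectors must share one length")
        if np.any(v < 0):
            raise ValueError("negative probability entry")
        if abs(v.sum() - 1.0) > 1e-6:
            raise ValueError("probability vector must sum to 1")
    tensor = vectors[0]
    for v in vectors[1:]:
        tensor = np.outer(tensor, v).ravel()
    assert abs(tensor.sum() - 1.0) < 1e-6  # product-of-sums identity
    factor = float(c ** len(vectors)) if rescale is None else float(rescale)
    return tensor * factor


def build_codt_matrix(prob_matrices, rescale: float | None = None) -> np.ndarray:
    """Row-wise CoDTs for aligned (n, c) probability matrices of m views."""
    mats = [np.asarray(m.probs if isinstance(m, ProbabilityMatrix) else m,
                       dtype=float) for m in prob_matrices]
    n, c = mats[0].shape
    for m in mats:
        if m.shape != (n, c):
            raise ValueError("all probability matrices must share one shape")
    out = mats[0]
    for m in mats[1:]:
        out = (out[:, :, None] * m[:, None, :]).reshape(n, -1)
    assert np.abs(out.sum(axis=1) - 1.0).max() < 1e-6
    factor = float(c ** len(mats)) if rescale is None else float(rescale)
    return out * factor


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class VCDNClassifier(BaseEstimator, ClassifierMixin):
    """Fusion net over CoDT inputs: c^m -> c^2 (LeakyReLU) -> c -> softmax.

    ``fit`` expects CoDT rows and 1-sd class labels in {-1, 0, +1}; the
    cross-entropy between the softmax output and one-hot labels is minimised
    by mini-batch Adam. ``predict`` breaks probability ties toward class 0.
    """

    def __init__(self, n_classes: int = 3, leaky_slope: float = 0.1,
                 learning_rate: float = 1e-3, n_epochs: int = 300,
                 batch_size: int = 64, random_state: int = 0):
        self.n_classes = n_classes
        self.leaky_slope = leaky_slope
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.random_state = random_state

    def _init_layers(self, n_in: int, rng: np.random.Generator) -> None:
        c = self.n_classes
        self.layers_ = [Dense(n_in, c * c, rng, "leaky", self.leaky_slope),
                        Dense(c * c, c, rng, "linear")]

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.asarray(CLASS_ORDER)
        missing = set(CLASS_ORDER) - set(np.unique(y))
        if missing:
            raise ValueError(f"classes missing from training labels: {sorted(missing)}")
        class_index = {c: i for i, c in enumerate(CLASS_ORDER)}
        idx = np.array([class_index[v] for v in y])
        onehot = np.eye(self.n_classes)[idx]
        rng = np.random.default_rng(self.random_state)
        self._init_layers(X.shape[1], rng)
        optimizer = Adam(self.layers_, lr=self.learning_rate)
        history = []
        for epoch in range(self.n_epochs):
            order = rng.permutation(len(X))
            losses = []
            for start in range(0, len(order), self.batch_size):
                b = order[start:start + self.batch_size]
                h = X[b]
                for layer in self.layers_:
                    h = layer.forward(h, cache=True)
                probs = _softmax(h)
                loss = -np.mean(np.sum(onehot[b] * np.log(probs + 1e-12), axis=1))
                if not np.isfinite(loss):
                    raise RuntimeError(f"non-finite VCDN loss at epoch {epoch}")
                losses.append(loss)
                g = (probs - onehot[b]) / len(b)
                for layer in reversed(self.layers_):
                    g = layer.backward(g)
                optimizer.step()
            history.append(float(np.mean(losses)))
        self.history_ = history
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.layers_[0].W.shape[0]:
            raise ValueError(f"input length {X.shape[1]} != "
                             f"{self.layers_[0].W.shape[0]}")
        h = X
        for layer in self.layers_:
            h = layer.forward(h, cache=False)
        return _softmax(h)

    def predict(self, X) -> np.ndarray:
        return hard_labels(self.predict_proba(X))


def train_vcdn(codts_train: np.ndarray, labels_train, seed: int = 0,
               **kwargs) -> VCDNClassifier:
    return VCDNClassifier(random_state=seed, **kwargs).fit(codts_train, labels_train)


def predict_vcdn(model: VCDNClassifier, codts_test: np.ndarray,
                 index=None) -> ProbabilityMatrix:
    probs = model.predict_proba(codts_test)
    frame = pd.DataFrame(probs, columns=list(CLASS_ORDER),
                         index=index if index is not None
                         else pd.RangeIndex(len(probs)))
    return ProbabilityMatrix(frame, provenance={"classifier": "vcdn",
                                                "fold_origin": "test"})
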