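"""Semi-supervised denoising autoencoder (SSAE) and its unsupervised control.

The SSAE encodes a scaled omic block through one hidden layer of width ``p``
into a bottleneck of width ``l``, decodes symmetrically, and additionally
predicts the matrix of adjusted targets through a one-layer perceptron (1LP)
grafted onto the bottleneck. Training minimises the bi-output convex loss

    L = alpha * MSE(X, X') + (1 - alpha) * MSE(Y, Y')

where X' reconstructs the original data from a Gaussian-corrupted input and
Y' is the 1LP's target prediction; both MSEs are means over all matrix
elements. ``alpha = 1`` recovers a plain unsupervised denoising autoencoder
(USAE); the matched-MSE control trains a USAE until its validation
reconstruction error reaches the paired SSAE's, so that downstream
comparisons hold reconstruction quality fixed.

Hidden layers use LeakyReLU; the final decoder layer and the 1LP output are
linear. Dropout acts on the input layer during training only. Optimisation
is mini-batch Adam with per-epoch multiplicative learning-rate decay, and
training stops early once the validation loss no longer improves on its
moving average over a trailing window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._nn import Adam, Dense, Dropout

__all__ = [
    "SSAEArchitecture", "TrainConfig", "count_parameters", "corrupt",
    "ssae_loss", "SemiSupervisedAutoencoder", "build_ssae", "train_ssae",
    "train_usae_matched", "select_architecture", "encode",
]


@dataclass(frozen=True)
class SSAEArchitecture:
    """Widths and loss parameters of an SSAE.

    ``p_in``: input features; ``p``: encoder hidden width; ``l``: bottleneck;
    ``t``: supervised output width (five targets); ``r``: input dropout rate;
    ``leaky_slope``: LeakyReLU negative slope; ``alpha``: convexity weight on
    the reconstruction term.
    """

    p_in: int
    p: int
    l: int
    t: int = 5
    r: float = 0.5
    leaky_slope: float = 0.1
    alpha: float = 0.9

    def __post_init__(self):
        if not 1 <= self.l <= self.p <= self.p_in:
            raise ValueError("need 1 <= l <= p <= p_in")
        if not 0.0 <= self.r < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.t < 1:
            raise ValueError("t must be >= 1")


@dataclass
class TrainConfig:
    """Optimisation settings for SSAE/USAE training.

    ``decay`` multiplies the learning rate once per epoch. ``corruption_sd``
    is the sd of the Gaussian input corruption, redrawn every epoch; 0.01 is
    appropriate for min-max-scaled transcriptomic blocks and 0.1 for z-scored
    metabolomic blocks (about a tenth of the typical feature sd in each
    case). ``min_epochs``/``stop_window`` pair as 10/10 for transcriptomic
    and 6/6 for metabolomic training.
    """

    batch_size: int = 64
    learning_rate: float = 1e-3
    decay: float = 0.9
    min_epochs: int = 10
    stop_window: int = 10
    max_epochs: int = 100
    corruption_sd: float = 0.01
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.stop_window < 1:
            raise ValueError("stop_window must be >= 1")
        if self.corruption_sd < 0:
            raise ValueError("corruption_sd must be >= 0")


def count_parameters(p_in: int, p: int, l: int, t: int = 5) -> int:
    """Closed-form trainable-parameter count of the full SSAE (weights+biases)."""
    return ((p_in * p + p) + (p * l + l)          # encoder
            + (l * p + p) + (p * p_in + p_in)     # decoder
            + (l * l + l) + (l * t + t))          # 1LP head


def corrupt(X: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Add elementwise Gaussian noise of sd ``sigma``; fresh noise per call."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return np.array(X, copy=True)
    return X + rng.normal(0.0, sigma, size=np.shape(X))


def ssae_loss(X, X_prime, Y, Y_prime, alpha: float) -> float:
    """Bi-output loss: alpha * MSE(X, X') + (1 - alpha) * MSE(Y, Y').

    Each MSE is the mean of squared elementwise differences, making the loss
    scale-comparable across blocks of different widths.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    X, X_prime = np.asarray(X, dtype=float), np.asarray(X_prime, dtype=float)
    Y, Y_prime = np.asarray(Y, dtype=float), np.asarray(Y_prime, dtype=float)
    if X.shape != X_prime.shape or Y.shape != Y_prime.shape:
        raise ValueError("shape mismatch between originals and reconstructions")
    recon = float(np.mean((X - X_prime) ** 2))
    sup = float(np.mean((Y - Y_prime) ** 2))
    return alpha * recon + (1.0 - alpha) * sup


class SemiSupervisedAutoencoder(BaseEstimator, TransformerMixin):
    """Sklearn-style SSAE: ``fit(X, Y)`` trains, ``transform(X)`` encodes.

    Parameters
    ----------
    hidden_width, bottleneck_width : encoder widths p and l.
    alpha : convexity weight; ``alpha=1`` trains the unsupervised control
        (the head receives zero gradient).
    dropout_rate, leaky_slope : regularisation and activation parameters.
    batch_size, learning_rate, decay, min_epochs, stop_window, max_epochs,
    corruption_sd, validation_fraction : see :class:`TrainConfig`.
    random_state : seeds weight init, batching, corruption and dropout.

    Fitted attributes
    -----------------
    ``history_`` : per-epoch train/validation total loss and validation
    reconstruction MSE. ``val_recon_mse_`` : final validation reconstruction
    MSE. ``n_parameters_`` : trainable parameter count.
    """

    def __init__(self, hidden_width: int = 55, bottleneck_width: int = 6,
                 alpha: float = 0.9, dropout_rate: float = 0.5,
                 leaky_slope: float = 0.1, batch_size: int = 64,
                 learning_rate: float = 1e-3, decay: float = 0.9,
                 min_epochs: int = 6, stop_window: int = 6,
                 max_epochs: int = 100, corruption_sd: float = 0.1,
                 validation_fraction: float = 0.2, random_state: int = 0):
        self.hidden_width = hidden_width
        self.bottleneck_width = bottleneck_width
        self.alpha = alpha
        self.dropout_rate = dropout_rate
        self.leaky_slope = leaky_slope
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.decay = decay
        self.min_epochs = min_epochs
        self.stop_window = stop_window
        self.max_epochs = max_epochs
        self.corruption_sd = corruption_sd
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- construction ------------------------------------------------------

    def architecture(self, p_in: int, t: int = 5) -> SSAEArchitecture:
        return SSAEArchitecture(p_in, self.hidden_width, self.bottleneck_width,
                                t=t, r=self.dropout_rate,
                                leaky_slope=self.leaky_slope, alpha=self.alpha)

    def initialize(self, p_in: int, t: int = 5) -> "SemiSupervisedAutoencoder":
        """Build and initialise all layers without training (deterministic
        given ``random_state``)."""
        arch = self.architecture(p_in, t)
        rng = np.random.default_rng(self.random_state)
        s = arch.leaky_slope
        self.encoder_layers_ = [Dense(arch.p_in, arch.p, rng, "leaky", s),
                                Dense(arch.p, arch.l, rng, "leaky", s)]
        self.decoder_layers_ = [Dense(arch.l, arch.p, rng, "leaky", s),
                                Dense(arch.p, arch.p_in, rng, "linear")]
        self.head_layers_ = [Dense(arch.l, arch.l, rng, "leaky", s),
                             Dense(arch.l, arch.t, rng, "linear")]
        self.dropout_ = Dropout(arch.r)
        self.arch_ = arch
        self.n_parameters_ = count_parameters(arch.p_in, arch.p, arch.l, arch.t)
        assert self.n_parameters_ == sum(
            lay.n_params for lay in self._all_layers())
        self._rng = rng
        return self

    def _all_layers(self) -> list[Dense]:
        return self.encoder_layers_ + self.decoder_layers_ + self.head_layers_

    # -- forward / backward ------------------------------------------------

    def _forward(self, X: np.ndarray, training: bool):
        h = self.dropout_.forward(X, getattr(self, "_rng", None), training)
        for layer in self.encoder_layers_:
            h = layer.forward(h, cache=training)
        z = h
        d = z
        for layer in self.decoder_layers_:
            d = layer.forward(d, cache=training)
        y = z
        for layer in self.head_layers_:
            y = layer.forward(y, cache=training)
        return z, d, y

    def _backward(self, X: np.ndarray, Y: np.ndarray | None,
                  X_hat: np.ndarray, Y_hat: np.ndarray) -> None:
        alpha = self.arch_.alpha
        n = X.shape[0]
        g = (2.0 * alpha / X.size) * (X_hat - X)
        for layer in reversed(self.decoder_layers_):
            g = layer.backward(g)
        g_z = g
        if alpha < 1.0 and Y is not None:
            gy = (2.0 * (1.0 - alpha) / Y.size) * (Y_hat - Y)
            for layer in reversed(self.head_layers_):
                gy = layer.backward(gy)
            g_z = g_z + gy
        else:
            for layer in self.head_layers_:
                layer.gW[...] = 0.0
                layer.gb[...] = 0.0
        for layer in reversed(self.encoder_layers_):
            g_z = layer.backward(g_z)
        self.dropout_.backward(g_z)

    # -- training ----------------------------------------------------------

    def fit(self, X, Y=None, validation_mask=None, mse_target=None):
        """Train on the scaled block ``X`` with adjusted targets ``Y``.

        ``validation_mask`` flags the fifth of rows reserved for early
        stopping; when absent, a random fifth (per ``validation_fraction``)
        is held out. ``mse_target`` switches to matched-MSE control mode:
        training stops at the first epoch whose validation reconstruction
        MSE falls at or below the target, and raises if it is never reached.
        """
        X = np.asarray(X, dtype=float)
        if Y is not None:
            Y = np.asarray(Y, dtype=float)
            if Y.ndim == 1:
                Y = Y[:, None]
        if self.alpha < 1.0 and Y is None:
            raise ValueError("alpha < 1 requires a target matrix Y")
        t = Y.shape[1] if Y is not None else 5
        self.initialize(X.shape[1], t=t)
        rng = self._rng

        if validation_mask is None:
            order = rng.permutation(len(X))
            n_val = max(1, int(round(self.validation_fraction * len(X))))
            validation_mask = np.zeros(len(X), dtype=bool)
            validation_mask[order[:n_val]] = True
        validation_mask = np.asarray(validation_mask, dtype=bool)
        fit_idx = np.flatnonzero(~validation_mask)
        val_idx = np.flatnonzero(validation_mask)
        X_fit, X_val = X[fit_idx], X[val_idx]
        Y_fit = Y[fit_idx] if Y is not None else None
        Y_val = Y[val_idx] if Y is not None else None

        optimizer = Adam(self._all_layers(), lr=self.learning_rate)
        history = {"train_loss": [], "val_loss": [], "val_recon_mse": []}
        stopped_reason = "max_epochs"
        for epoch in range(self.max_epochs):
            lr = self.learning_rate * self.decay ** epoch
            X_delta = corrupt(X_fit, self.corruption_sd, rng)
            order = rng.permutation(len(X_fit))
            epoch_losses = []
            for start in range(0, len(order), self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, xdb = X_fit[idx], X_delta[idx]
                yb = Y_fit[idx] if Y_fit is not None else None
                _, x_hat, y_hat = self._forward(xdb, training=True)
                loss = self._loss_value(xb, x_hat, yb, y_hat)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}: {loss}")
                self._backward(xb, yb, x_hat, y_hat)
                optimizer.step(lr=lr)
                epoch_losses.append(loss)
            val_loss, val_recon = self._validation_losses(X_val, Y_val, rng)
            history["train_loss"].append(float(np.mean(epoch_losses)))
            history["val_loss"].append(val_loss)
            history["val_recon_mse"].append(val_recon)
            e = epoch + 1
            if mse_target is not None:
                if val_recon <= mse_target:
                    stopped_reason = "mse_target"
                    break
            elif e > self.min_epochs:
                window = history["val_loss"][max(0, e - 1 - self.stop_window):e - 1]
                if val_loss >= np.mean(window):
                    stopped_reason = "early_stop"
                    break
        if mse_target is not None and stopped_reason != "mse_target":
            raise RuntimeError(
                f"matched-MSE target {mse_target:.5g} not reached within "
                f"{self.max_epochs} epochs (best "
                f"{min(history['val_recon_mse']):.5g})")
        self.history_ = history
        self.stopped_reason_ = stopped_reason
        self.n_epochs_ = len(history["val_loss"])
        self.val_loss_ = history["val_loss"][-1]
        self.val_recon_mse_ = history["val_recon_mse"][-1]
        self.validation_mask_ = validation_mask
        return self

    def _loss_value(self, X, X_hat, Y, Y_hat) -> float:
        alpha = self.arch_.alpha
        recon = float(np.mean((X - X_hat) ** 2))
        if alpha == 1.0 or Y is None:
            return recon if alpha == 1.0 else alpha * recon
        return alpha * recon + (1 - alpha) * float(np.mean((Y - Y_hat) ** 2))

    def _validation_losses(self, X_val, Y_val, rng):
        """Validation total loss and reconstruction MSE, with fresh corruption
        and dropout disabled."""
        X_delta = corrupt(X_val, self.corruption_sd, rng)
        _, x_hat, y_hat = self._forward(X_delta, training=False)
        recon = float(np.mean((X_val - x_hat) ** 2))
        total = self._loss_value(X_val, x_hat, Y_val, y_hat)
        return total, recon

    # -- inference ---------------------------------------------------------

    def transform(self, X) -> np.ndarray:
        """Deterministic bottleneck activations (dropout and corruption off)."""
        index = X.index if isinstance(X, pd.DataFrame) else None
        values = np.asarray(X, dtype=float)
        if values.shape[1] != self.arch_.p_in:
            raise ValueError(
                f"input width {values.shape[1]} != model width {self.arch_.p_in}")
        h = values
        for layer in self.encoder_layers_:
            h = layer.forward(h, cache=False)
        if index is not None:
            return pd.DataFrame(h, index=index,
                                columns=[f"z{i}" for i in range(h.shape[1])])
        return h

    def reconstruct(self, X) -> np.ndarray:
        _, x_hat, _ = self._forward(np.asarray(X, dtype=float), training=False)
        return x_hat

    def predict_targets(self, X) -> np.ndarray:
        _, _, y_hat = self._forward(np.asarray(X, dtype=float), training=False)
        return y_hat


# ---------------------------------------------------------------------------
# functional wrappers

def build_ssae(arch: SSAEArchitecture, seed: int = 0) -> SemiSupervisedAutoencoder:
    """Construct and initialise an SSAE from an architecture description."""
    model = SemiSupervisedAutoencoder(
        hidden_width=arch.p, bottleneck_width=arch.l, alpha=arch.alpha,
        dropout_rate=arch.r, leaky_slope=arch.leaky_slope, random_state=seed)
    return model.initialize(arch.p_in, t=arch.t)


def _model_from(arch: SSAEArchitecture, config: TrainConfig,
                alpha: float | None = None) -> SemiSupervisedAutoencoder:
    return SemiSupervisedAutoencoder(
        hidden_width=arch.p, bottleneck_width=arch.l,
        alpha=arch.alpha if alpha is None else alpha,
        dropout_rate=arch.r, leaky_slope=arch.leaky_slope,
        batch_size=config.batch_size, learning_rate=config.learning_rate,
        decay=config.decay, min_epochs=config.min_epochs,
        stop_window=config.stop_window, max_epochs=config.max_epochs,
        corruption_sd=config.corruption_sd,
        validation_fraction=config.validation_fraction,
        random_state=config.seed)


def train_ssae(arch: SSAEArchitecture, X_train, Y_adjusted,
               config: TrainConfig,
               validation_mask=None) -> SemiSupervisedAutoencoder:
    model = _model_from(arch, config)
    return model.fit(X_train, Y_adjusted, validation_mask=validation_mask)


def train_usae_matched(arch: SSAEArchitecture, X_train, target_mse: float,
                       config: TrainConfig,
                       validation_mask=None) -> SemiSupervisedAutoencoder:
    """Train the unsupervised control until its validation reconstruction MSE
    matches the paired SSAE's (alpha pinned to 1, head detached)."""
    model = _model_from(arch, config, alpha=1.0)
    return model.fit(X_train, None, validation_mask=validation_mask,
                     mse_target=target_mse)


def bottleneck_correlation(model: SemiSupervisedAutoencoder, X_train) -> float:
    """Mean absolute off-diagonal Pearson correlation among bottleneck
    components on the training samples (0 for a width-1 bottleneck)."""
    Z = np.asarray(model.transform(X_train), dtype=float)
    if Z.shape[1] < 2:
        return 0.0
    C = np.corrcoef(Z, rowvar=False)
    C = np.nan_to_num(C, nan=0.0)
    off = np.abs(C[~np.eye(C.shape[0], dtype=bool)])
    return float(off.mean())


def select_architecture(grid, X_train, Y_adjusted, config: TrainConfig,
                        mse_cap: float, corr_cap: float,
                        validation_mask=None, alpha: float = 0.9,
                        dropout_rate: float = 0.5):
    """Pick the smallest feasible architecture from a (p, l) grid.

    A candidate is feasible when its validation reconstruction MSE is below
    ``mse_cap`` and the mean absolute pairwise correlation among bottleneck
    components on the training samples does not exceed ``corr_cap``. Among
    feasible candidates the one with the fewest trainable parameters wins;
    ties break toward smaller ``l``, then smaller ``p``. Raises with
    nearest-miss diagnostics when nothing is feasible.
    """
    X_train = np.asarray(X_train, dtype=float)
    results = []
    for p, l in grid:
        arch = SSAEArchitecture(X_train.shape[1], p, l,
                                t=np.asarray(Y_adjusted).shape[1],
                                r=dropout_rate, alpha=alpha)
        model = train_ssae(arch, X_train, Y_adjusted, config,
                           validation_mask=validation_mask)
        corr = bottleneck_correlation(
            model, X_train[~model.validation_mask_])
        results.append({"p": p, "l": l, "arch": arch, "model": model,
                        "mse": model.val_recon_mse_, "corr": corr,
                        "n_params": model.n_parameters_})
    feasible = [r for r in results
                if r["mse"] < mse_cap and r["corr"] <= corr_cap]
    if not feasible:
        diag = "; ".join(
            f"(p={r['p']}, l={r['l']}): mse={r['mse']:.4g} (cap {mse_cap}), "
            f"corr={r['corr']:.3g} (cap {corr_cap})" for r in results)
        raise RuntimeError(f"no feasible architecture in grid: {diag}")
    best = min(feasible, key=lambda r: (r["n_params"], r["l"], r["p"]))
    return best["arch"], best["model"]


def encode(model: SemiSupervisedAutoencoder, X_scaled):
    """Bottleneck representation of a scaled block (alias of transform)."""
    return model.transform(X_scaled)
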