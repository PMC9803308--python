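"""Denoising auto-encoder for 370-sample ECG beats.

A single-hidden-layer encoder/decoder: the noisy beat x is encoded as
y = phi(W x + b) and decoded as z = phi'(W' y + b'), trained with Adam to
minimise the mean squared reconstruction error (1/N) sum_i ||x_i - z_i||^2
against the clean beat. Two layouts are supported: a compressing 370-185
hidden layer ("model1") and a full-width 370-370 one ("model2"), both
ReLU encoder / sigmoid output.

Frames are min-max normalised per frame to [0, 1] before the network (the
sigmoid output range) and de-normalised on the way out, so reconstruction
SNR is reported in the original amplitude units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._nn import ACTIVATIONS, Adam, activation, activation_grad, glorot_uniform
from .synthetic import BeatFrame

__all__ = [
    "DaeParams",
    "TrainConfig",
    "DenoisingAutoencoder",
    "encode",
    "decode",
    "reconstruction_loss",
    "train_dae",
    "denoise",
    "snr_db",
    "MODEL_HIDDEN_SIZES",
]

#: hidden-layer widths of the two studied layouts
MODEL_HIDDEN_SIZES = {"model1": 185, "model2": 370}


@dataclass
class DaeParams:
    """Encoder/decoder weights: y = phi(W x + b), z = phi'(W' y + b')."""

    W: np.ndarray           # (hidden, n_in)
    b: np.ndarray           # (hidden,)
    W_prime: np.ndarray     # (n_in, hidden)
    b_prime: np.ndarray     # (n_in,)
    phi: str = "relu"
    phi_prime: str = "sigmoid"

    def __post_init__(self):
        for name in (self.phi, self.phi_prime):
            if name not in ACTIVATIONS:
                raise ValueError(f"unknown activation {name!r}")
        h, n = self.W.shape
        if self.b.shape != (h,) or self.W_prime.shape != (n, h) or \
                self.b_prime.shape != (n,):
            raise ValueError("inconsistent DAE parameter shapes")

    @property
    def hidden_size(self) -> int:
        return self.W.shape[0]

    @property
    def n_in(self) -> int:
        return self.W.shape[1]


@dataclass(frozen=True)
class TrainConfig:
    """Gradient-descent schedule (defaults: the full-scale DAE recipe)."""

    epochs: int = 400
    batch_size: int = 64
    optimizer: str = "adam"
    learning_rate: float = 0.00095
    loss: str = "mse"
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


def encode(params: DaeParams, x: np.ndarray) -> np.ndarray:
    """Hidden representation phi(W x + b); accepts a vector or a batch."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != params.n_in:
        raise ValueError(f"expected input length {params.n_in}, got {x.shape[-1]}")
    return activation(params.phi)(x @ params.W.T + params.b)


def decode(params: DaeParams, y: np.ndarray) -> np.ndarray:
    """Reconstruction phi'(W' y + b'); accepts a vector or a batch."""
    y = np.asarray(y, dtype=float)
    if y.shape[-1] != params.hidden_size:
        raise ValueError(
            f"expected hidden length {params.hidden_size}, got {y.shape[-1]}"
        )
    return activation(params.phi_prime)(y @ params.W_prime.T + params.b_prime)


def reconstruction_loss(clean_batch: np.ndarray, reconstructed_batch: np.ndarray) -> float:
    """Mean over the batch of the squared L2 residual ||x_i - z_i||^2."""
    x = np.atleast_2d(np.asarray(clean_batch, dtype=float))
    z = np.atleast_2d(np.asarray(reconstructed_batch, dtype=float))
    if x.shape != z.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {z.shape}")
    if x.shape[0] == 0:
        raise ValueError("empty batch")
    return float(np.mean(np.sum((x - z) ** 2, axis=1)))


def snr_db(reference: np.ndarray, estimate: np.ndarray) -> float:
    """Power-ratio SNR 10*log10(sum(ref^2) / sum((ref - est)^2)) in dB.

    A perfect estimate gives ``math.inf`` (distinguished value, not an error).
    """
    ref = np.asarray(reference, dtype=float)
    est = np.asarray(estimate, dtype=float)
    p_ref = float(np.sum(ref**2))
    if p_ref == 0.0:
        raise ValueError("reference is identically zero: SNR undefined")
    p_err = float(np.sum((ref - est) ** 2))
    if p_err == 0.0:
        return math.inf
    return 10.0 * math.log10(p_ref / p_err)


def _minmax(X: np.ndarray):
    lo = X.min(axis=1, keepdims=True)
    hi = X.max(axis=1, keepdims=True)
    rng = np.where(hi > lo, hi - lo, 1.0)
    return lo, rng


class DenoisingAutoencoder(TransformerMixin, BaseEstimator):
    """Single-hidden-layer denoising auto-encoder, trained noisy -> clean.

    Parameters
    ----------
    hidden_size : int, default 370
        Width of the hidden layer (185 reproduces the compressing layout).
    activation, output_activation : str
        Encoder and output nonlinearities, from {relu, sigmoid, tanh, identity}.
    epochs, batch_size, learning_rate : training schedule (Adam, MSE loss).
    normalize : bool
        Min-max scale each frame to [0, 1] using the *noisy* frame's range,
        and invert on output. Required for the sigmoid output to cover
        arbitrary amplitude units.
    seed : int
        Seeds initialisation and batch shuffling; fixed seed gives
        bit-identical training runs.

    Attributes
    ----------
    params_ : DaeParams
        Trained weights.
    loss_history_ : list of float
        Mean training loss per epoch.
    """

    def __init__(self, hidden_size: int = 370, activation: str = "relu",
                 output_activation: str = "sigmoid", epochs: int = 400,
                 batch_size: int = 64, learning_rate: float = 0.00095,
                 normalize: bool = True, seed: int = 0):
        self.hidden_size = hidden_size
        self.activation = activation
        self.output_activation = output_activation
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.normalize = normalize
        self.seed = seed

    # ------------------------------------------------------------------ fit
    def fit(self, X, y):
        """Train on noisy inputs ``X`` against clean targets ``y``.

        Both are (n_frames, 370) arrays (or lists of BeatFrame).
        """
        X = _frames_to_matrix(X)
        Y = _frames_to_matrix(y)
        if X.shape != Y.shape:
            raise ValueError(f"X and y shapes differ: {X.shape} vs {Y.shape}")
        if X.shape[0] < 1:
            raise ValueError("need at least one training pair")
        n, d = X.shape
        cfg = TrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                          learning_rate=self.learning_rate, seed=self.seed)
        rng = np.random.default_rng(self.seed)
        h = self.hidden_size
        params = {
            "W": glorot_uniform(rng, (h, d), d, h),
            "b": np.zeros(h),
            "W_prime": glorot_uniform(rng, (d, h), h, d),
            "b_prime": np.zeros(d),
        }
        opt = Adam(params, lr=cfg.learning_rate)
        phi = activation(self.activation)
        dphi = activation_grad(self.activation)
        phi_p = activation(self.output_activation)
        dphi_p = activation_grad(self.output_activation)

        if self.normalize:
            lo, rngs = _minmax(X)
            Xn = (X - lo) / rngs
            Yn = (Y - lo) / rngs
        else:
            Xn, Yn = X, Y

        self.loss_history_ = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                xb, tb = Xn[idx], Yn[idx]
                m = len(idx)
                # forward
                pre_h = xb @ params["W"].T + params["b"]
                hid = phi(pre_h)
                pre_o = hid @ params["W_prime"].T + params["b_prime"]
                zb = phi_p(pre_o)
                resid = zb - tb
                loss = float(np.mean(np.sum(resid**2, axis=1)))
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged (non-finite loss) at epoch {epoch + 1}"
                    )
                epoch_loss += loss * m
                # backward: d/dz of (1/m) sum ||z - t||^2
                d_pre_o = (2.0 / m) * resid * dphi_p(pre_o, zb)
                d_hid = d_pre_o @ params["W_prime"]
                d_pre_h = d_hid * dphi(pre_h, hid)
                grads = {
                    "W_prime": d_pre_o.T @ hid,
                    "b_prime": d_pre_o.sum(axis=0),
                    "W": d_pre_h.T @ xb,
                    "b": d_pre_h.sum(axis=0),
                }
                opt.step(params, grads)
            self.loss_history_.append(epoch_loss / n)
        self.params_ = DaeParams(
            W=params["W"], b=params["b"],
            W_prime=params["W_prime"], b_prime=params["b_prime"],
            phi=self.activation, phi_prime=self.output_activation,
        )
        self.n_features_in_ = d
        return self

    # ------------------------------------------------------------ transform
    def transform(self, X):
        """Denoise frames: encode then decode, in original amplitude units."""
        check_is_fitted(self, "params_")
        X = _frames_to_matrix(X)
        if self.normalize:
            lo, rngs = _minmax(X)
            Xn = (X - lo) / rngs
        else:
            lo, rngs = 0.0, 1.0
            Xn = X
        Z = decode(self.params_, encode(self.params_, Xn))
        return Z * rngs + lo

    def denoise_frame(self, frame: BeatFrame) -> BeatFrame:
        """Denoise one beat frame, carrying its labels through unchanged."""
        out = self.transform(frame.samples[None, :])[0]
        # PAD samples must stay exactly zero to preserve frame invariants
        out[frame.n_valid:] = 0.0
        return BeatFrame(out, frame.labels.copy(), frame.fs)

    def denoise_frames(self, frames) -> list:
        """Denoise a sequence of beat frames (labels carried through)."""
        return [self.denoise_frame(f) for f in frames]

    def save(self, path) -> None:
        """Serialize trained weights to a versioned .npz archive."""
        check_is_fitted(self, "params_")
        import json
        header = json.dumps({
            "format": "ecgwaves-dae", "version": 1,
            "hidden_size": self.params_.hidden_size,
            "phi": self.params_.phi, "phi_prime": self.params_.phi_prime,
            "normalize": self.normalize,
        })
        np.savez(path, header=np.frombuffer(header.encode(), dtype=np.uint8),
                 W=self.params_.W, b=self.params_.b,
                 W_prime=self.params_.W_prime, b_prime=self.params_.b_prime)

    @classmethod
    def load(cls, path) -> "DenoisingAutoencoder":
        import json
        with np.load(path) as npz:
            header = json.loads(bytes(npz["header"]).decode())
            if header.get("format") != "ecgwaves-dae":
                raise ValueError(f"{path}: not a DAE parameter file")
            est = cls(hidden_size=header["hidden_size"], activation=header["phi"],
                      output_activation=header["phi_prime"],
                      normalize=header["normalize"])
            est.params_ = DaeParams(W=npz["W"], b=npz["b"], W_prime=npz["W_prime"],
                                    b_prime=npz["b_prime"], phi=header["phi"],
                                    phi_prime=header["phi_prime"])
            est.n_features_in_ = est.params_.n_in
            est.loss_history_ = []
        return est


def _frames_to_matrix(X) -> np.ndarray:
    if isinstance(X, np.ndarray):
        return np.atleast_2d(np.asarray(X, dtype=float))
    if isinstance(X, BeatFrame):
        return X.samples[None, :]
    if len(X) and isinstance(X[0], BeatFrame):
        return np.stack([f.samples for f in X])
    return np.atleast_2d(np.asarray(X, dtype=float))


def train_dae(pairs, cfg: TrainConfig = TrainConfig(), arch: str = "model2",
              **overrides) -> DenoisingAutoencoder:
    """Train a DAE on (clean, noisy) frame pairs; noisy is input, clean target."""
    if arch not in MODEL_HIDDEN_SIZES:
        raise ValueError(f"arch must be one of {sorted(MODEL_HIDDEN_SIZES)}")
    clean = [c for c, _ in pairs]
    noisy = [n for _, n in pairs]
    est = DenoisingAutoencoder(
        hidden_size=MODEL_HIDDEN_SIZES[arch], epochs=cfg.epochs,
        batch_size=cfg.batch_size, learning_rate=cfg.learning_rate,
        seed=cfg.seed, **overrides,
    )
    return est.fit(noisy, clean)


def denoise(model: DenoisingAutoencoder, noisy: BeatFrame) -> BeatFrame:
    """Functional form of :meth:`DenoisingAutoencoder.denoise_frame`."""
    return model.denoise_frame(noisy)
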