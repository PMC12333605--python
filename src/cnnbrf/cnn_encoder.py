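"""1-D convolutional encoder for pair feature vectors.

A deliberately small network compresses each (nm + nd)-dimensional pair
vector to ⌊(nm + nd)/2⌋ latent features:

    conv1d (16 filters, width 16, stride 1, valid, ReLU)
    → max-pool (width 2)
    → dropout
    → dense to ⌊(nm+nd)/2⌋ units (ReLU)      ← the encoding layer
    → dropout
    → dense to 1 (sigmoid)                    ← training head only

The head is trained with binary cross-entropy under Adam on the balanced
positive/negative pair set; at encoding time dropout is inactive and the
penultimate (first dense) activations are returned, so encoding is a
deterministic row-wise map. The implementation is pure numpy — the model
is small enough that explicit forward/backward passes are both fast and
exactly reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import CnnBrfError, ConfigurationError

__all__ = [
    "EncoderConfig",
    "TrainedEncoder",
    "DivergenceError",
    "output_dim_for",
    "build_encoder",
    "train_encoder",
    "encode",
    "parameter_count",
]


class DivergenceError(CnnBrfError, FloatingPointError):
    """Training loss became NaN/Inf; usually a too-large learning rate."""


def output_dim_for(input_dim: int) -> int:
    """Latent width: half the pair-vector length, floored when odd."""
    return input_dim // 2


@dataclass(frozen=True)
class EncoderConfig:
    """Hyperparameters of the convolutional encoder.

    Defaults: 16 filters of width 16 with width-2 max-pooling; dropout 0.5
    at both dropout sites; 20 Adam epochs at learning rate 1e-3 with
    minibatches of 32. ``output_dim=None`` derives ⌊input_dim/2⌋ at build
    time.
    """

    n_filters: int = 16
    kernel_width: int = 16
    pool_width: int = 2
    dropout_rate: float = 0.5
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    output_dim: int | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ConfigurationError(f"epochs must be >= 1, got {self.epochs}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must lie in [0, 1)")
        if min(self.n_filters, self.kernel_width, self.pool_width, self.batch_size) < 1:
            raise ConfigurationError("architecture sizes must be positive")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class TrainedEncoder:
    """Encoder weights plus the config and layout they were trained under."""

    config: EncoderConfig
    input_dim: int
    params: dict[str, np.ndarray]
    training_loss_curve: list[float] = field(default_factory=list)
    feature_layout: str = "microbe_block_then_drug_block"

    # -- architecture geometry -------------------------------------------
    @property
    def n_positions(self) -> int:
        return self.input_dim - self.config.kernel_width + 1

    @property
    def n_pooled(self) -> int:
        return self.n_positions // self.config.pool_width

    @property
    def output_dim(self) -> int:
        return self.params["W1"].shape[1]

    # -- forward passes ---------------------------------------------------
    def _conv_pool(self, X: np.ndarray) -> tuple[np.ndarray, ...]:
        cfg, p = self.config, self.params
        V = sliding_window_view(X, cfg.kernel_width, axis=1)  # (B, P, K)
        Z1 = np.einsum("bpk,fk->bpf", V, p["Wc"], optimize=True) + p["bc"]
        A1 = _relu(Z1)
        P2 = self.n_pooled
        blocks = A1[:, : P2 * cfg.pool_width, :].reshape(
            X.shape[0], P2, cfg.pool_width, cfg.n_filters
        )
        arg = blocks.argmax(axis=2)
        pooled = np.take_along_axis(blocks, arg[:, :, None, :], axis=2)[:, :, 0, :]
        return V, Z1, blocks, arg, pooled

    def forward(
        self, X: np.ndarray, *, train: bool = False, rng: np.random.Generator | None = None
    ) -> dict[str, np.ndarray]:
        """Full forward pass; dropout applies only when ``train=True``."""
        cfg, p = self.config, self.params
        X = np.ascontiguousarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.input_dim:
            raise ConfigurationError(
                f"expected input of width {self.input_dim}, got shape {X.shape}"
            )
        V, Z1, blocks, arg, pooled = self._conv_pool(X)
        flat = pooled.reshape(X.shape[0], -1)
        keep = 1.0 - cfg.dropout_rate
        if train and cfg.dropout_rate > 0:
            mask1 = (rng.random(flat.shape) < keep) / keep
            flat_d = flat * mask1
        else:
            mask1, flat_d = None, flat
        Z2 = flat_d @ p["W1"] + p["b1"]
        A2 = _relu(Z2)
        if train and cfg.dropout_rate > 0:
            mask2 = (rng.random(A2.shape) < keep) / keep
            A2_d = A2 * mask2
        else:
            mask2, A2_d = None, A2
        Z3 = A2_d @ p["W2"] + p["b2"]
        prob = _sigmoid(Z3[:, 0])
        return dict(
            V=V, Z1=Z1, blocks=blocks, arg=arg, flat=flat, mask1=mask1,
            flat_d=flat_d, Z2=Z2, A2=A2, mask2=mask2, A2_d=A2_d, prob=prob,
        )

    def backward(
        self, X: np.ndarray, y: np.ndarray, cache: dict[str, np.ndarray]
    ) -> dict[str, np.ndarray]:
        """Gradients of mean binary cross-entropy w.r.t. every parameter."""
        cfg, p = self.config, self.params
        B = X.shape[0]
        dZ3 = (cache["prob"] - y)[:, None] / B  # (B, 1)
        g = {
            "W2": cache["A2_d"].T @ dZ3,
            "b2": dZ3.sum(axis=0),
        }
        dA2_d = dZ3 @ p["W2"].T
        if cache["mask2"] is not None:
            dA2_d = dA2_d * cache["mask2"]
        dZ2 = dA2_d * (cache["Z2"] > 0)
        g["W1"] = cache["flat_d"].T @ dZ2
        g["b1"] = dZ2.sum(axis=0)
        dflat = dZ2 @ p["W1"].T
        if cache["mask1"] is not None:
            dflat = dflat * cache["mask1"]
        P2, F = self.n_pooled, cfg.n_filters
        dpooled = dflat.reshape(B, P2, F)
        dblocks = np.zeros_like(cache["blocks"])
        np.put_along_axis(dblocks, cache["arg"][:, :, None, :], dpooled[:, :, None, :], axis=2)
        dA1 = np.zeros((B, self.n_positions, F))
        dA1[:, : P2 * cfg.pool_width, :] = dblocks.reshape(B, P2 * cfg.pool_width, F)
        dZ1 = dA1 * (cache["Z1"] > 0)
        g["Wc"] = np.einsum("bpf,bpk->fk", dZ1, cache["V"], optimize=True)
        g["bc"] = dZ1.sum(axis=(0, 1))
        return g

    # -- public inference -------------------------------------------------
    def encode(self, X: np.ndarray, *, block: int = 8192) -> np.ndarray:
        """Penultimate-layer activations; deterministic row-wise map."""
        X = np.ascontiguousarray(X, dtype=np.float64)
        out = np.empty((X.shape[0], self.output_dim))
        for start in range(0, X.shape[0], block):
            sl = slice(start, min(start + block, X.shape[0]))
            out[sl] = self.forward(X[sl])["A2"]
        return out

    def predict_proba(self, X: np.ndarray, *, block: int = 8192) -> np.ndarray:
        """Probability from the sigmoid head (the CNN-only baseline score)."""
        X = np.ascontiguousarray(X, dtype=np.float64)
        out = np.empty(X.shape[0])
        for start in range(0, X.shape[0], block):
            sl = slice(start, min(start + block, X.shape[0]))
            out[sl] = self.forward(X[sl])["prob"]
        return out


def build_encoder(input_dim: int, config: EncoderConfig | None = None) -> TrainedEncoder:
    """Seeded He/Xavier initialisation of the layer stack (untrained)."""
    cfg = config or EncoderConfig()
    if input_dim < cfg.kernel_width:
        raise ConfigurationError(
            f"input_dim {input_dim} is smaller than kernel width {cfg.kernel_width}"
        )
    out_dim = cfg.output_dim if cfg.output_dim is not None else output_dim_for(input_dim)
    cfg = replace(cfg, output_dim=out_dim)
    rng = np.random.default_rng(cfg.seed)
    P2 = ((input_dim - cfg.kernel_width + 1) // cfg.pool_width)
    if P2 < 1:
        raise ConfigurationError("input too short for the pooling width")
    flat_dim = P2 * cfg.n_filters
    params = {
        "Wc": rng.normal(0, np.sqrt(2.0 / cfg.kernel_width), (cfg.n_filters, cfg.kernel_width)),
        "bc": np.zeros(cfg.n_filters),
        "W1": rng.normal(0, np.sqrt(2.0 / flat_dim), (flat_dim, out_dim)),
        "b1": np.zeros(out_dim),
        "W2": rng.normal(0, np.sqrt(1.0 / out_dim), (out_dim, 1)),
        "b2": np.zeros(1),
    }
    return TrainedEncoder(cfg, input_dim, params)


def parameter_count(input_dim: int, config: EncoderConfig | None = None) -> int:
    """Closed-form trainable-parameter count; depends only on input_dim."""
    cfg = config or EncoderConfig()
    out_dim = cfg.output_dim if cfg.output_dim is not None else output_dim_for(input_dim)
    P2 = (input_dim - cfg.kernel_width + 1) // cfg.pool_width
    flat = P2 * cfg.n_filters
    return (
        cfg.n_filters * cfg.kernel_width + cfg.n_filters
        + flat * out_dim + out_dim
        + out_dim + 1
    )


def _bce(prob: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps)))


def train_encoder(
    model: TrainedEncoder,
    X: np.ndarray,
    y: np.ndarray,
    *,
    verbose: bool = False,
) -> TrainedEncoder:
    """Adam / binary cross-entropy training for ``config.epochs`` passes.

    Runs in place on *model* and returns it; the per-epoch mean minibatch
    loss is recorded on ``training_loss_curve``. All randomness (shuffling,
    dropout) comes from a generator seeded with ``config.seed``, so two runs
    with the same data and seed produce identical weights.
    """
    cfg = model.config
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64).ravel()
    if X.shape[0] != y.shape[0]:
        raise ConfigurationError("X and y row counts differ")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xC0FFEE]))
    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(p) for k, p in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    for _epoch in range(cfg.epochs):
        order = rng.permutation(X.shape[0])
        losses = []
        for start in range(0, X.shape[0], cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            cache = model.forward(X[idx], train=True, rng=rng)
            losses.append(_bce(cache["prob"], y[idx]))
            grads = model.backward(X[idx], y[idx], cache)
            step += 1
            for k, gk in grads.items():
                m[k] = beta1 * m[k] + (1 - beta1) * gk
                v[k] = beta2 * v[k] + (1 - beta2) * gk * gk
                mhat = m[k] / (1 - beta1**step)
                vhat = v[k] / (1 - beta2**step)
                model.params[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
        epoch_loss = float(np.mean(losses))
        diverged = not np.isfinite(epoch_loss) or any(
            not np.isfinite(p).all() for p in model.params.values()
        )
        if diverged:
            raise DivergenceError(
                "training diverged (non-finite loss or weights); "
                "try a lower learning rate"
            )
        model.training_loss_curve.append(epoch_loss)
        if verbose:
            print(f"epoch {_epoch + 1}/{cfg.epochs}: loss {epoch_loss:.4f}")
    return model


def encode(encoder: TrainedEncoder, X: np.ndarray) -> np.ndarray:
    """Module-level alias for :meth:`TrainedEncoder.encode`."""
    return encoder.encode(X)
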