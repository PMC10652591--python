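"""The concatenated-input autoencoder (CNC-AE).

Expression and methylation blocks enter through two input layers whose
concatenation (width ``expr_dim + meth_dim``) feeds one hidden layer and a
linear, uniformly initialized bottleneck; the decoder mirrors the encoder and
splits its final layer into two reconstruction heads matching the input
widths. The training objective is the mean squared error over both heads,
which — because the heads are a disjoint partition of one output vector — is
computed on the concatenated reconstruction.

Two presets mirror the pipeline's cohort configurations: the LGG-style
autoencoder uses relu hidden activations, the GBM-style one uses elu; both
use a linear bottleneck. The hidden width defaults to half the concatenated
width (one compression step between concatenation and bottleneck); optimizer
defaults to Adam at 1e-3 — both configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn


@dataclass(frozen=True)
class AEConfig:
    expr_dim: int
    meth_dim: int
    bottleneck_dim: int
    hidden_dim: int | None = None  # None -> round(0.5 * (expr_dim + meth_dim))
    activation: str = "relu"  # hidden layers; bottleneck is always linear
    epochs: int = 1500
    batch_size: int = 16
    seed: int = 0
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    scale_inputs: bool = False  # optional per-feature min-max scaling

    def __post_init__(self):
        if self.expr_dim < 0 or self.meth_dim < 0 or self.expr_dim + self.meth_dim == 0:
            raise ValueError("input block dimensions must be non-negative and not both zero")
        hidden = self.resolved_hidden_dim
        if not (self.bottleneck_dim < hidden <= self.expr_dim + self.meth_dim):
            raise ValueError(
                f"require bottleneck_dim < hidden_dim <= expr_dim + meth_dim "
                f"(got {self.bottleneck_dim}, {hidden}, {self.expr_dim + self.meth_dim})"
            )
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch_size must be positive")
        if self.activation not in ("relu", "elu", "linear"):
            raise ValueError(f"unsupported hidden activation: {self.activation!r}")

    @property
    def resolved_hidden_dim(self) -> int:
        if self.hidden_dim is not None:
            return self.hidden_dim
        return max(self.bottleneck_dim + 1, round(0.5 * (self.expr_dim + self.meth_dim)))

    @property
    def concat_width(self) -> int:
        return self.expr_dim + self.meth_dim


def lgg_preset(expr_dim=1110, meth_dim=3204, bottleneck_dim=400, **kw) -> AEConfig:
    """LGG-style configuration: relu hidden layers, 400-dim bottleneck."""
    return AEConfig(expr_dim=expr_dim, meth_dim=meth_dim,
                    bottleneck_dim=bottleneck_dim, activation="relu", **kw)


def gbm_preset(expr_dim=268, meth_dim=447, bottleneck_dim=100, **kw) -> AEConfig:
    """GBM-style configuration: elu hidden layers, 100-dim bottleneck."""
    return AEConfig(expr_dim=expr_dim, meth_dim=meth_dim,
                    bottleneck_dim=bottleneck_dim, activation="elu", **kw)


@dataclass
class LatentMatrix:
    sample_ids: list
    values: np.ndarray  # samples x bottleneck_dim

    def __post_init__(self):
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample count does not match latent rows")
        if not np.isfinite(self.values).all():
            raise ValueError("latent matrix contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        cols = [f"latent{i}" for i in range(self.values.shape[1])]
        return pd.DataFrame(self.values, index=self.sample_ids, columns=cols)


class CncAutoencoder:
    """Handle holding the layer stack, its config and the encoder depth."""

    def __init__(self, config: AEConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        hidden = config.resolved_hidden_dim
        width = config.concat_width
        layers = [
            nn.Dense(width, hidden, activation=config.activation, rng=rng),
            nn.Dense(hidden, config.bottleneck_dim, activation="linear",
                     init="uniform", rng=rng),
            nn.Dense(config.bottleneck_dim, hidden, activation=config.activation, rng=rng),
            nn.Dense(hidden, width, activation="linear", rng=rng),
        ]
        self._encoder_depth = 2
        self.model = nn.Sequential(
            layers, loss="mse", optimizer=config.optimizer,
            lr=config.learning_rate, rng=rng,
        )
        self._scaler = None
        self.trained = False

    @property
    def concat_width(self) -> int:
        return self.config.concat_width

    @property
    def decoder_output_widths(self) -> tuple[int, int]:
        return (self.config.expr_dim, self.config.meth_dim)

    def _concat(self, expr_block, meth_block) -> np.ndarray:
        blocks = []
        if self.config.expr_dim:
            e = np.asarray(expr_block, dtype=float)
            if e.shape[1] != self.config.expr_dim:
                raise ValueError(
                    f"expression block width {e.shape[1]} != configured {self.config.expr_dim}"
                )
            blocks.append(e)
        if self.config.meth_dim:
            mth = np.asarray(meth_block, dtype=float)
            if mth.shape[1] != self.config.meth_dim:
                raise ValueError(
                    f"methylation block width {mth.shape[1]} != configured {self.config.meth_dim}"
                )
            blocks.append(mth)
        x = np.hstack(blocks)
        if self.config.scale_inputs:
            if self._scaler is None:
                lo = x.min(axis=0)
                span = x.max(axis=0) - lo
                span[span == 0] = 1.0
                self._scaler = (lo, span)
            lo, span = self._scaler
            x = (x - lo) / span
        return x

    def encode_array(self, x: np.ndarray) -> np.ndarray:
        for layer in self.model.layers[: self._encoder_depth]:
            x = layer.forward(x, train=False)
        return x

    def weights_checksum(self) -> str:
        return self.model.weights_checksum()


def build_cnc_autoencoder(config: AEConfig) -> CncAutoencoder:
    """Construct the (untrained) concatenated autoencoder for a config."""
    return CncAutoencoder(config)


def train_autoencoder(
    ae: CncAutoencoder,
    expr_block: np.ndarray,
    meth_block: np.ndarray,
    holdout: tuple | None = None,
    lr_schedule: list[tuple[int, float]] | None = None,
) -> pd.DataFrame:
    """Train on sample-aligned blocks (samples x features each).

    Returns the loss history: per-epoch training MSE, plus final train and —
    when ``holdout=(expr, meth)`` is given — held-out MSE in ``.attrs``.
    A non-finite loss aborts with a diagnostic.

    ``lr_schedule`` — optional list of ``(epochs, learning_rate)`` phases
    replacing the single-rate run; useful when the optimizer must settle
    onto a flat optimum (e.g. the PCA floor of a linear autoencoder) where a
    constant step oscillates.
    """
    x = ae._concat(expr_block, meth_block)
    cfg = ae.config
    if lr_schedule is None:
        lr_schedule = [(cfg.epochs, cfg.learning_rate)]
    history = []
    for epochs, lr in lr_schedule:
        ae.model.optimizer.lr = lr
        history += ae.model.fit(x, x, epochs=epochs, batch_size=cfg.batch_size)
    ae.trained = True
    out = pd.DataFrame({"epoch": np.arange(1, len(history) + 1), "mse": history})
    out.attrs["lr_schedule"] = list(lr_schedule)
    out.attrs["final_train_mse"] = ae.model.evaluate(x, x)
    if holdout is not None:
        xh = ae._concat(*holdout)
        out.attrs["final_holdout_mse"] = ae.model.evaluate(xh, xh)
    return out


def encode(
    ae: CncAutoencoder,
    expr_block: np.ndarray,
    meth_block: np.ndarray,
    sample_ids=None,
) -> LatentMatrix:
    """Deterministic forward pass through the trained encoder."""
    x = ae._concat(expr_block, meth_block)
    z = ae.encode_array(x)
    if sample_ids is None:
        sample_ids = list(range(z.shape[0]))
    return LatentMatrix(sample_ids=list(sample_ids), values=z)
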