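"""Subtype classifiers over latent features: a one-hidden-layer ANN and a
deep 1-D CNN, with grid-search hyperparameter optimization and stratified
k-fold cross-validation.

The ANN is input -> dense hidden -> softmax. The CNN reshapes the latent
vector to a length-``input_dim`` single-channel sequence, applies a stack of
1-D convolutions (by default eight layers of one filter with kernel size 3 —
the unusual single-filter width is honored deliberately and can be
overridden), dropout, max pooling, then a flattened fully connected softmax
head. Both train with categorical cross-entropy.

Cross-validation retrains a fresh model per fold, with weight initialization
seeded by (seed, fold) so folds are independent but reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd
from sklearn.model_selection import ParameterGrid, StratifiedKFold

from . import nn
from .metrics import ConfusionMatrix, compute_metrics, confusion_matrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ANNConfig:
    hidden_units: int = 64
    activation: str = "relu"
    batch_size: int = 32
    epochs: int = 100
    optimizer: str = "adam"
    learning_rate: float = 1e-3

    def __post_init__(self):
        if self.hidden_units <= 0 or self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("ANN config values must be positive")
        if self.activation not in nn.ACTIVATIONS:
            raise ValueError(f"unsupported activation: {self.activation!r}")


def ann_lgg_preset() -> ANNConfig:
    return ANNConfig(activation="relu", batch_size=32, epochs=100, optimizer="adam")


def ann_gbm_preset() -> ANNConfig:
    return ANNConfig(activation="linear", batch_size=30, epochs=50, optimizer="rmsprop")


@dataclass(frozen=True)
class CNNConfig:
    n_conv_layers: int = 8
    filters: int = 1
    kernel_size: int = 3
    dropout: float = 0.2
    activation: str = "relu"
    batch_size: int = 64
    epochs: int = 2000
    optimizer: str = "rmsprop"
    learning_rate: float = 1e-3
    pool_size: int = 2

    def __post_init__(self):
        if self.kernel_size < 1 or self.filters < 1 or self.n_conv_layers < 1:
            raise ValueError("CNN config values must be positive")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        if self.activation not in nn.ACTIVATIONS:
            raise ValueError(f"unsupported activation: {self.activation!r}")


def cnn_lgg_preset() -> CNNConfig:
    return CNNConfig(activation="relu")


def cnn_gbm_preset() -> CNNConfig:
    return CNNConfig(activation="elu")


def build_ann(input_dim: int, n_classes: int, config: ANNConfig, seed: int = 0) -> nn.Sequential:
    """input -> dense hidden -> softmax(n_classes), cross-entropy loss."""
    if n_classes < 2:
        raise ValueError("need at least two classes")
    rng = np.random.default_rng(seed)
    layers = [
        nn.Dense(input_dim, config.hidden_units, activation=config.activation, rng=rng),
        nn.Dense(config.hidden_units, n_classes, activation="linear", rng=rng),
    ]
    return nn.Sequential(layers, loss="softmax_ce", optimizer=config.optimizer,
                         lr=config.learning_rate, rng=rng)


def build_cnn(input_dim: int, n_classes: int, config: CNNConfig, seed: int = 0) -> nn.Sequential:
    """Stacked valid-padding 1-D convolutions + dropout + max pooling +
    flattened softmax head over the latent sequence."""
    if n_classes < 2:
        raise ValueError("need at least two classes")
    length = input_dim
    lengths = [length]
    for _ in range(config.n_conv_layers):
        length = length - (config.kernel_size - 1)
        lengths.append(length)
    pooled = length // config.pool_size
    if length < 1 or pooled < 1:
        raise ValueError(
            f"input too short for the convolution stack: lengths {lengths}, "
            f"pooled {pooled}"
        )
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = [nn.Reshape((input_dim, 1))]
    channels = 1
    for _ in range(config.n_conv_layers):
        layers.append(
            nn.Conv1D(channels, config.filters, config.kernel_size,
                      activation=config.activation, rng=rng)
        )
        channels = config.filters
    layers.append(nn.Dropout(config.dropout, rng=rng))
    layers.append(nn.MaxPool1D(config.pool_size))
    layers.append(nn.Flatten())
    layers.append(nn.Dense(pooled * channels, n_classes, activation="linear", rng=rng))
    return nn.Sequential(layers, loss="softmax_ce", optimizer=config.optimizer,
                         lr=config.learning_rate, rng=rng)


def _one_hot(labels: np.ndarray, classes: list) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        y[i, index[lab]] = 1.0
    return y


def _fold_seed(seed: int, fold: int) -> int:
    return int(np.random.SeedSequence([seed, fold]).generate_state(1)[0] % (2**31))


@dataclass
class CVResult:
    fold: int
    cm: ConfusionMatrix
    metrics: dict
    train_idx: np.ndarray
    test_idx: np.ndarray


def stratified_cv_evaluate(
    builder,
    config,
    latent: np.ndarray,
    labels,
    k: int = 10,
    seed: int = 0,
) -> list[CVResult]:
    """Stratified k-fold cross-validation with per-fold retraining.

    ``builder(input_dim, n_classes, config, seed)`` constructs a fresh model
    per fold; each fold's confusion matrix is computed on its held-out
    samples only. k is reduced (with a warning) when the rarest class has
    fewer than k members.
    """
    latent = np.asarray(latent, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("cross-validation needs at least two classes")
    min_count = min((labels == c).sum() for c in classes)
    if min_count < k:
        logger.warning("reducing k from %d to %d (smallest class size)", k, min_count)
        k = int(min_count)
    if k < 2:
        raise ValueError("smallest class too small for cross-validation")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    results = []
    y_all = _one_hot(labels, classes)
    for fold, (train_idx, test_idx) in enumerate(skf.split(latent, labels)):
        model = builder(latent.shape[1], len(classes), config, seed=_fold_seed(seed, fold))
        model.fit(latent[train_idx], y_all[train_idx],
                  epochs=config.epochs, batch_size=config.batch_size)
        proba = model.predict_proba(latent[test_idx])
        pred = [classes[i] for i in proba.argmax(axis=1)]
        cm = confusion_matrix(labels[test_idx], pred, labels=classes)
        results.append(
            CVResult(fold=fold, cm=cm, metrics=compute_metrics(cm),
                     train_idx=train_idx, test_idx=test_idx)
        )
    return results


def grid_search(
    builder,
    base_config,
    param_grid: dict,
    latent: np.ndarray,
    labels,
    k: int = 5,
    seed: int = 0,
):
    """Exhaustive grid search scored by stratified k-fold mean accuracy.

    Ties are broken by grid order (first wins). A grid point whose training
    fails is scored 0 and logged. Returns ``(best_config, score_table)``.
    """
    if not param_grid:
        raise ValueError("empty parameter grid")
    grid = list(ParameterGrid(param_grid))
    if not grid:
        raise ValueError("empty parameter grid")
    rows = []
    best = None
    for i, params in enumerate(grid):
        config = replace(base_config, **params)
        try:
            results = stratified_cv_evaluate(builder, config, latent, labels, k=k, seed=seed)
            score = float(np.mean([r.metrics["accuracy"] for r in results]))
        except Exception as exc:  # noqa: BLE001 - a failed point must not abort the search
            logger.warning("grid point %s failed: %s", params, exc)
            score = 0.0
        rows.append({**params, "mean_accuracy": score})
        if best is None or score > best[1]:
            best = (config, score)
    return best[0], pd.DataFrame(rows)


def save_model(path, model: nn.Sequential, kind: str, config, classes: list,
               input_dim: int) -> None:
    """Persist classifier weights plus the config needed to rebuild it."""
    import json

    meta = dict(kind=kind, config=asdict(config), classes=list(classes),
                input_dim=int(input_dim))
    arrays = {f"param_{i}": p for i, p in enumerate(model.params)}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path):
    """Rebuild a saved classifier; returns ``(model, classes)``."""
    import json

    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    config_cls = {"ann": ANNConfig, "cnn": CNNConfig}[meta["kind"]]
    builder = {"ann": build_ann, "cnn": build_cnn}[meta["kind"]]
    config = config_cls(**meta["config"])
    model = builder(meta["input_dim"], len(meta["classes"]), config)
    for i, p in enumerate(model.params):
        p[...] = data[f"param_{i}"]
    return model, meta["classes"]


def predict_subtypes(model: nn.Sequential, latent, classes: list, sample_ids=None):
    """Argmax subtype call with per-class probabilities."""
    latent = np.asarray(latent, dtype=float)
    proba = model.predict_proba(latent)
    if proba.shape[1] != len(classes):
        raise ValueError("class count does not match model output width")
    labels = [classes[i] for i in proba.argmax(axis=1)]
    if sample_ids is None:
        sample_ids = list(range(len(labels)))
    out = pd.DataFrame(proba, columns=list(classes), index=sample_ids)
    out.insert(0, "predicted", labels)
    return out
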