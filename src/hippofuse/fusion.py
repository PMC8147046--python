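"""Late-fusion head: z-scored deep + shape features into a softmax classifier.

Deep visual features and spectral shape features live on very different
scales, so both are z-scored with statistics learned from the training rows
only, then concatenated (deep first, shape second) and fed to a small fully
connected network trained with the same optimizer family as the CNN
(SGD + momentum, cross-entropy, L2, dropout).  The feature extractors are
frozen during fusion training by default; an end-to-end fine-tuning path is
intentionally out of the default pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .densecnn import TrainConfig

_STD_FLOOR = 1e-8


@dataclass
class Normalizer:
    """Per-feature z-score statistics (population std, floored)."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, rows: np.ndarray) -> "Normalizer":
        rows = np.asarray(rows, dtype=np.float64)
        if rows.ndim != 2 or rows.shape[0] < 1:
            raise ValueError("need a nonempty 2D array of training rows")
        std = rows.std(axis=0)  # population (divide-by-n) convention
        return cls(mean=rows.mean(axis=0), std=np.maximum(std, _STD_FLOOR))

    def transform(self, rows: np.ndarray) -> np.ndarray:
        rows = np.asarray(rows, dtype=np.float64)
        return (rows - self.mean) / self.std


def fit_apply_zscore(train_rows: np.ndarray, other_rows: np.ndarray | None = None):
    """Fit a z-score on training rows and apply it to all given rows.

    Returns ``(normalizer, train_transformed, other_transformed)``;
    constant features map to 0 (std floor), and no test row influences the
    statistics.
    """
    train_rows = np.asarray(train_rows, dtype=np.float64)
    if train_rows.shape[0] < 2:
        raise ValueError("need at least 2 training rows to fit a z-score")
    norm = Normalizer.fit(train_rows)
    other = None if other_rows is None else norm.transform(other_rows)
    return norm, norm.transform(train_rows), other


@dataclass
class FusionConfig:
    hidden_layers: tuple[int, ...] = (32,)
    dropout_rate: float = 0.5
    l2_weight: float = 0.02
    train: TrainConfig = field(default_factory=lambda: TrainConfig(epochs=200, batch_size=16))

    def __post_init__(self):
        self.hidden_layers = tuple(int(h) for h in self.hidden_layers)
        if any(h <= 0 for h in self.hidden_layers):
            raise ValueError("hidden layer widths must be positive")


class FusionModel:
    """Fully connected softmax head; logistic regression when no hidden layer."""

    def __init__(self, in_dim: int, cfg: FusionConfig, rng_seed: int):
        self.cfg = cfg
        self.in_dim = in_dim
        rng = np.random.default_rng(rng_seed)
        drop_rng = np.random.default_rng(rng.integers(2 ** 31))
        layers: list[nn.Layer] = []
        prev = in_dim
        for width in cfg.hidden_layers:
            layers += [nn.Dense(prev, width, rng), nn.ReLU(),
                       nn.Dropout(cfg.dropout_rate, drop_rng)]
            prev = width
        layers.append(nn.Dense(prev, 2, rng))
        self.net = nn.Sequential(layers)
        self.fitted = False

    def forward(self, x, training=False):
        return self.net.forward(np.asarray(x, dtype=np.float32), training=training)

    def backward(self, dlogits):
        return self.net.backward(dlogits)

    def all_layers(self):
        yield from self.net.iter_layers()

    def param_items(self):
        return [(lay, name) for lay in self.all_layers() for name in lay.params]

    def parameter_vector(self) -> np.ndarray:
        return np.concatenate([lay.params[n].ravel() for lay, n in self.param_items()])


def _rows_to_array(features) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(features, np.ndarray):
        return np.asarray(features, dtype=np.float64), None
    vals = [np.asarray(f.values, dtype=np.float64) for f in features]
    dims = {v.shape for v in vals}
    if len(dims) > 1:
        raise ValueError(f"feature rows have mismatched dimensions: {sorted(dims)}")
    ids = [getattr(f, "subject_id", None) for f in features]
    return np.vstack(vals), ids


def train_fusion(features, labels, cfg: FusionConfig) -> tuple[FusionModel, nn.History]:
    """Train the fusion head on (already normalized) feature rows."""
    x, _ = _rows_to_array(features)
    y = np.asarray(labels, dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to train the fusion head")
    if x.shape[0] != y.shape[0]:
        raise ValueError(f"{x.shape[0]} feature rows but {y.shape[0]} labels")
    model = FusionModel(x.shape[1], cfg, rng_seed=cfg.train.seed)
    hist = nn.fit_classifier(
        model, x.astype(np.float32), y, epochs=cfg.train.epochs,
        batch_size=cfg.train.batch_size, lr=cfg.train.learning_rate,
        momentum=cfg.train.momentum, l2=cfg.l2_weight,
        seed=cfg.train.seed + 1)
    model.fitted = True
    return model, hist


def predict_scores(model: FusionModel, rows) -> np.ndarray:
    """AD-class softmax probability per row (CN probability = 1 - score)."""
    if not getattr(model, "fitted", False):
        raise ValueError("fusion model has not been trained")
    x, _ = _rows_to_array(rows)
    if x.shape[1] != model.in_dim:
        raise ValueError(f"feature dimension {x.shape[1]} does not match "
                         f"model input dimension {model.in_dim}")
    logits = model.forward(x, training=False)
    return nn.softmax(logits)[:, 1]
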