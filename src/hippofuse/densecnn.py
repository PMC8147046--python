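"""Two-stream lightweight 3D dense convolutional network for AD vs CN.

One stream per hippocampus (left, right).  Each stream: an initial 3x3x3
convolution with batch norm and ReLU, a 2x max pool, then dense blocks
(DenseNet-style concatenative connectivity) each followed by a transition
layer (1x1x1 conv, batch norm, ReLU, 2x max pool), ending in global average
pooling.  The two GAP vectors are concatenated, passed through dropout and
a fully connected layer to a 2-way softmax.  The concatenated GAP output is
the "deep visual feature" vector used downstream for fusion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

from . import nn

#: label encoding used throughout: AD is the positive class.
LABEL_CODES = {"CN": 0, "AD": 1}


@dataclass
class ArchConfig:
    """Architecture hyperparameters.

    Defaults follow the two-dense-block design with 8 and 16 filters,
    dropout 0.5 and L2 weight decay 0.02.
    """
    input_grid: tuple[int, int, int] = (32, 32, 32)
    initial_filters: int = 8
    dense_block_filters: tuple[int, ...] = (8, 16)
    convs_per_block: int = 2
    kernel_size: int = 3
    dropout_rate: float = 0.5
    l2_weight: float = 0.02

    def __post_init__(self):
        self.input_grid = tuple(int(g) for g in self.input_grid)
        self.dense_block_filters = tuple(int(f) for f in self.dense_block_filters)
        if self.initial_filters <= 0 or any(f <= 0 for f in self.dense_block_filters):
            raise ValueError("filter counts must be positive")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        factor = self.pool_factor
        bad = [g for g in self.input_grid if g % factor]
        if bad:
            raise ValueError(
                f"input_grid {self.input_grid} must be divisible by the "
                f"cumulative pooling factor {factor}")

    @property
    def pool_factor(self) -> int:
        return 2 ** (1 + len(self.dense_block_filters))

    @property
    def stream_channels(self) -> int:
        """Channels after the last transition layer (= GAP length per stream)."""
        ch = self.initial_filters
        for g in self.dense_block_filters:
            ch += g * self.convs_per_block
        return ch

    @property
    def feature_dim(self) -> int:
        """Length of the concatenated left+right GAP feature vector."""
        return 2 * self.stream_channels

    def to_dict(self):
        return {"input_grid": list(self.input_grid),
                "initial_filters": self.initial_filters,
                "dense_block_filters": list(self.dense_block_filters),
                "convs_per_block": self.convs_per_block,
                "kernel_size": self.kernel_size,
                "dropout_rate": self.dropout_rate,
                "l2_weight": self.l2_weight}

    @classmethod
    def from_dict(cls, d):
        return cls(**d)


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    momentum: float = 0.9
    epochs: int = 60
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or not (0 <= self.momentum < 1):
            raise ValueError("learning_rate must be > 0 and momentum in [0,1)")
        if self.epochs < 0 or self.batch_size <= 0:
            raise ValueError("epochs must be >= 0 and batch_size > 0")


@dataclass
class DeepFeatureVector:
    values: np.ndarray
    subject_id: str


def _build_stream(cfg: ArchConfig, rng: np.random.Generator) -> nn.Sequential:
    layers = [nn.Conv3d(1, cfg.initial_filters, cfg.kernel_size, rng,
                        input_grad=False),
              nn.BatchNorm(cfg.initial_filters), nn.ReLU(), nn.MaxPool3d()]
    ch = cfg.initial_filters
    for growth in cfg.dense_block_filters:
        block = nn.DenseBlock(ch, growth, cfg.convs_per_block, cfg.kernel_size, rng)
        ch = block.out_ch
        # transition: 1x1x1 channel-preserving conv, then downsample
        layers += [block, nn.Conv3d(ch, ch, 1, rng), nn.BatchNorm(ch),
                   nn.ReLU(), nn.MaxPool3d()]
    layers.append(nn.GlobalAvgPool())
    return nn.Sequential(layers)


class VisualModel:
    """The two-stream network; built via :func:`build_visual_model`."""

    def __init__(self, cfg: ArchConfig, rng_seed: int):
        self.cfg = cfg
        rng = np.random.default_rng(rng_seed)
        self.left = _build_stream(cfg, rng)
        self.right = _build_stream(cfg, rng)
        self.dropout = nn.Dropout(cfg.dropout_rate,
                                  np.random.default_rng(rng.integers(2 ** 31)))
        self.fc = nn.Dense(cfg.feature_dim, 2, rng)
        self._half = cfg.stream_channels

    # -- forward/backward -------------------------------------------------
    def forward(self, x, training=False):
        xl, xr = x
        fl = self.left.forward(xl, training=training)
        fr = self.right.forward(xr, training=training)
        f = np.concatenate([fl, fr], axis=1)
        f = self.dropout.forward(f, training=training)
        return self.fc.forward(f, training=training)

    def backward(self, dlogits):
        df = self.fc.backward(dlogits)
        df = self.dropout.backward(df)
        self.left.backward(np.ascontiguousarray(df[:, :self._half]))
        self.right.backward(np.ascontiguousarray(df[:, self._half:]))

    def features(self, x) -> np.ndarray:
        """Concatenated L/R GAP activations in inference mode."""
        xl, xr = x
        return np.concatenate([self.left.forward(xl, training=False),
                               self.right.forward(xr, training=False)], axis=1)

    def predict_proba(self, x, batch_size: int = 32) -> np.ndarray:
        """AD-class softmax probability per row, inference mode."""
        n = x[0].shape[0]
        out = np.empty(n)
        for s in range(0, n, batch_size):
            sl = slice(s, min(s + batch_size, n))
            logits = self.forward((x[0][sl], x[1][sl]), training=False)
            out[sl] = nn.softmax(logits)[:, LABEL_CODES["AD"]]
        return out

    # -- parameter plumbing ----------------------------------------------
    def all_layers(self):
        yield from self.left.iter_layers()
        yield from self.right.iter_layers()
        yield self.dropout
        yield self.fc

    def param_items(self):
        items = []
        for lay in self.all_layers():
            for name in lay.params:
                items.append((lay, name))
        return items

    def parameter_vector(self) -> np.ndarray:
        return np.concatenate([lay.params[n].ravel() for lay, n in self.param_items()])

    @property
    def n_parameters(self) -> int:
        return int(sum(lay.params[n].size for lay, n in self.param_items()))

    # -- checkpointing ----------------------------------------------------
    def save(self, run_dir: str | Path) -> None:
        run_dir = Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        (run_dir / "arch.json").write_text(json.dumps(self.cfg.to_dict(), indent=2))
        arrays = {f"p{i}": lay.params[n] for i, (lay, n) in enumerate(self.param_items())}
        for i, lay in enumerate(self.all_layers()):
            if isinstance(lay, nn.BatchNorm):
                arrays[f"rm{i}"] = lay.running_mean
                arrays[f"rv{i}"] = lay.running_var
        np.savez(run_dir / "weights.npz", **arrays)

    @classmethod
    def load(cls, run_dir: str | Path) -> "VisualModel":
        run_dir = Path(run_dir)
        cfg = ArchConfig.from_dict(json.loads((run_dir / "arch.json").read_text()))
        model = cls(cfg, rng_seed=0)
        with np.load(run_dir / "weights.npz") as z:
            for i, (lay, n) in enumerate(model.param_items()):
                lay.params[n] = z[f"p{i}"].copy()
            for i, lay in enumerate(model.all_layers()):
                if isinstance(lay, nn.BatchNorm):
                    lay.running_mean = z[f"rm{i}"].copy()
                    lay.running_var = z[f"rv{i}"].copy()
        return model


def build_visual_model(config: ArchConfig, rng_seed: int = 0) -> VisualModel:
    """Construct the two-stream network with seeded weight initialization."""
    return VisualModel(config, rng_seed)


@dataclass
class TrainedVisualModel:
    model: VisualModel
    history: nn.History = field(default_factory=nn.History)


def encode_labels(labels) -> np.ndarray:
    return np.asarray([LABEL_CODES[str(l)] for l in labels], dtype=np.int64)


def pairs_to_arrays(pairs) -> tuple[tuple[np.ndarray, np.ndarray], np.ndarray]:
    """Stack a list of labeled volume pairs into network-ready arrays."""
    xl = np.stack([np.asarray(p.left.data, dtype=np.float32) for p in pairs])[..., None]
    xr = np.stack([np.asarray(p.right.data, dtype=np.float32) for p in pairs])[..., None]
    y = encode_labels([p.label for p in pairs])
    return (xl, xr), y


def train_visual_model(model: VisualModel, dataset, train_cfg: TrainConfig,
                       val_fraction: float = 0.1) -> TrainedVisualModel:
    """Train on labeled volume pairs with a stratified validation split.

    The validation split is carved from the given data; the parameters with
    the best validation loss are restored.  ``epochs=0`` returns the model
    untouched with an empty history.
    """
    x, y = pairs_to_arrays(dataset)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    if train_cfg.epochs == 0:
        return TrainedVisualModel(model, nn.History())
    rng = np.random.default_rng(train_cfg.seed)
    idx_tr, idx_va = train_test_split(
        np.arange(len(y)), test_size=val_fraction, stratify=y,
        random_state=int(rng.integers(2 ** 31)))
    ytr = y[idx_tr]
    if min(np.bincount(ytr, minlength=2)) < 2:
        raise ValueError("need at least 2 subjects per class in the training portion")
    hist = nn.fit_classifier(
        model, (x[0][idx_tr], x[1][idx_tr]), ytr,
        epochs=train_cfg.epochs, batch_size=train_cfg.batch_size,
        lr=train_cfg.learning_rate, momentum=train_cfg.momentum,
        l2=model.cfg.l2_weight, seed=int(rng.integers(2 ** 31)),
        val=((x[0][idx_va], x[1][idx_va]), y[idx_va]))
    return TrainedVisualModel(model, hist)


def extract_deep_features(trained, pair) -> DeepFeatureVector:
    """Deterministic inference-mode GAP features for one subject."""
    model = trained.model if isinstance(trained, TrainedVisualModel) else trained
    shape = tuple(pair.left.data.shape)
    if shape != model.cfg.input_grid:
        raise ValueError(f"volume grid {shape} does not match model input grid "
                         f"{model.cfg.input_grid}")
    xl = np.asarray(pair.left.data, dtype=np.float32)[None, ..., None]
    xr = np.asarray(pair.right.data, dtype=np.float32)[None, ..., None]
    return DeepFeatureVector(values=model.features((xl, xr))[0], subject_id=pair.subject_id)
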