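"""Transfer-learning feature extraction.

A convolutional backbone (the classic 16-layer five-block topology, or a
``tiny`` three-block variant sized for CPU experiments) is topped with a new
head — flatten, a dense feature layer (default 256 units) and a two-class
softmax.  During fine-tuning the first ``frozen_blocks``
convolution blocks keep their initial weights bit-exactly; later blocks and
the head are trained with RMSProp on the slice-level dataset, and the
checkpoint with minimum validation loss is returned.  Each slice yields a
1x256 feature vector at the penultimate layer; the 32 slice vectors of one
subject are concatenated, in ascending slice-index order, into a single
1x8192 subject representation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _nn
from .io_fusion import FusedSlice, SliceDataset

#: conv channels per block, one tuple per block
TOPOLOGIES: dict[str, tuple[tuple[int, ...], ...]] = {
    "vgg16": ((64, 64), (128, 128), (256, 256, 256), (512, 512, 512), (512, 512, 512)),
    "tiny": ((8,), (16,), (32,)),
}
_DEFAULT_FROZEN = {"vgg16": 4, "tiny": 2}


@dataclass(frozen=True)
class BackboneConfig:
    topology: str = "vgg16"
    frozen_blocks: int | None = None  # None -> topology default (vgg16: 4, tiny: 2)
    feature_dim: int = 256
    n_classes: int = 2
    input_size: tuple[int, int, int] = (110, 110, 3)
    pretrained_weights: str | None = None

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}; expected one of {tuple(TOPOLOGIES)}")
        if self.feature_dim <= 0:
            raise ValueError("feature_dim must be positive")
        n_blocks = len(TOPOLOGIES[self.topology])
        if self.frozen_blocks is not None and not (0 <= self.frozen_blocks < n_blocks):
            raise ValueError(
                f"frozen_blocks must lie in [0, {n_blocks}) for {self.topology}, got {self.frozen_blocks}"
            )

    @property
    def n_conv_blocks(self) -> int:
        return len(TOPOLOGIES[self.topology])

    @property
    def n_frozen(self) -> int:
        return _DEFAULT_FROZEN[self.topology] if self.frozen_blocks is None else self.frozen_blocks


@dataclass(frozen=True)
class TrainConfig:
    """Fine-tuning hyperparameters; defaults follow the original training recipe."""

    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 50
    rho: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be nonnegative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class SliceFeature:
    vector: np.ndarray
    subject_id: str
    slice_index: int


@dataclass(frozen=True)
class SubjectFeature:
    vector: np.ndarray
    subject_id: str
    label: int


class Backbone:
    """Convolutional feature extractor with its two-class softmax head."""

    def __init__(self, config: BackboneConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence((seed, 0xBAC)))
        blocks = TOPOLOGIES[config.topology]
        layers: list[_nn.Layer] = []
        self._block_slices: list[slice] = []
        in_ch = config.input_size[2]
        for channels in blocks:
            start = len(layers)
            for out_ch in channels:
                layers.append(_nn.Conv2d(in_ch, out_ch, rng=rng))
                layers.append(_nn.ReLU())
                in_ch = out_ch
            layers.append(_nn.MaxPool2d())
            self._block_slices.append(slice(start, len(layers)))
        # head: flatten (keeps spatial layout, as in the classic FC head) ->
        # dense feature layer -> softmax
        h, w = config.input_size[:2]
        for _ in blocks:
            h, w = h // 2, w // 2
        if h < 1 or w < 1:
            raise ValueError(f"input size {config.input_size[:2]} too small for {len(blocks)} pooling stages")
        layers.append(_nn.Flatten())
        layers.append(_nn.Dense(in_ch * h * w, config.feature_dim, rng=rng))
        layers.append(_nn.ReLU())
        layers.append(_nn.Dense(config.feature_dim, config.n_classes, rng=rng))
        self.net = _nn.Sequential(layers)
        self._feature_upto = len(layers) - 1  # penultimate: through the feature ReLU
        if config.pretrained_weights is not None:
            self.load_weights(config.pretrained_weights)
        for b in range(config.n_frozen):
            for layer in self.net.layers[self._block_slices[b]]:
                layer.trainable = False

    # -- weight i/o -------------------------------------------------------
    def load_weights(self, path: str | Path) -> None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(
                f"pretrained weights not found at {path}; supply a local .npz exported "
                "from a matching topology"
            )
        archive = np.load(path)
        for i, layer in enumerate(self.net.layers):
            for name in layer.params:
                key = f"layer{i}_{name}"
                if key not in archive:
                    raise ValueError(f"weights at {path} do not match topology (missing {key})")
                if archive[key].shape != layer.params[name].shape:
                    raise ValueError(
                        f"weights/topology mismatch at {key}: file {archive[key].shape} "
                        f"vs model {layer.params[name].shape}"
                    )
                layer.params[name] = archive[key].astype(np.float32)

    def save_weights(self, path: str | Path) -> None:
        arrays = {
            f"layer{i}_{name}": layer.params[name]
            for i, layer in enumerate(self.net.layers)
            for name in layer.params
        }
        np.savez(path, **arrays)

    def save_checkpoint(self, path: str | Path, train_config: TrainConfig | None = None) -> None:
        """Weights as .npz plus a JSON sidecar recording the configuration."""
        path = Path(path)
        self.save_weights(path)
        sidecar = {
            "backbone": {
                "topology": self.config.topology,
                "frozen_blocks": self.config.n_frozen,
                "feature_dim": self.config.feature_dim,
                "n_classes": self.config.n_classes,
                "input_size": list(self.config.input_size),
            },
        }
        if train_config is not None:
            sidecar["train"] = {
                "learning_rate": train_config.learning_rate,
                "batch_size": train_config.batch_size,
                "epochs": train_config.epochs,
                "seed": train_config.seed,
            }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))

    # -- inference --------------------------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        h, w, c = self.config.input_size
        if x.shape[1:] != (c, h, w):
            raise ValueError(f"input batch shape {x.shape[1:]} does not match model input {(c, h, w)}")

    def features(self, x: np.ndarray) -> np.ndarray:
        """Penultimate-layer features for a (N, 3, H, W) float batch in [0, 1]."""
        self._check_input(x)
        return self.net.forward(x, train=False, upto=self._feature_upto)

    def logits(self, x: np.ndarray) -> np.ndarray:
        self._check_input(x)
        return self.net.forward(x, train=False)

    def frozen_state(self) -> list[dict[str, np.ndarray]]:
        state = []
        for b in range(self.config.n_frozen):
            for layer in self.net.layers[self._block_slices[b]]:
                state.append({k: v.copy() for k, v in layer.params.items()})
        return state


def build_model(config: BackboneConfig, seed: int = 0) -> Backbone:
    """Instantiate the backbone; blocks ``1..n_frozen`` are non-trainable."""
    return Backbone(config, seed=seed)


def feature_map_shapes(
    config: BackboneConfig, input_size: tuple[int, int] | None = None
) -> list[tuple[str, int, int, int]]:
    """Analytic (name, channels, height, width) for every conv/pool layer.

    Same-padded 3x3 convolutions preserve spatial size; each 2x2 stride-2
    pooling floors it to half.  E.g. the vgg16 topology on a 110x110 input
    emits 64 maps of 55x55 at the first pooling layer and 256 maps of 27x27
    at the seventh convolution.
    """
    if input_size is None:
        input_size = config.input_size[:2]
    h, w = input_size
    if h <= 0 or w <= 0:
        raise ValueError("input size must be positive")
    shapes = []
    for bi, channels in enumerate(TOPOLOGIES[config.topology], start=1):
        for ci, out_ch in enumerate(channels, start=1):
            shapes.append((f"block{bi}_conv{ci}", out_ch, h, w))
        h, w = h // 2, w // 2
        shapes.append((f"block{bi}_pool", channels[-1], h, w))
    return shapes


def _slices_to_batch(slices: Sequence[FusedSlice]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.pixels for s in slices]).astype(np.float32) / 255.0
    x = x.transpose(0, 3, 1, 2)  # channels-first
    y = np.array([1 if s.label > 0 else 0 for s in slices], dtype=np.int64)
    return x, y


def _dataset_loss(model: Backbone, slices: Sequence[FusedSlice], batch_size: int = 64) -> float:
    losses, weights = [], []
    for start in range(0, len(slices), batch_size):
        x, y = _slices_to_batch(slices[start : start + batch_size])
        loss, _ = _nn.softmax_cross_entropy(model.logits(x), y)
        losses.append(loss)
        weights.append(len(y))
    return float(np.average(losses, weights=weights))


def fine_tune(
    model: Backbone, dataset: SliceDataset, train_config: TrainConfig
) -> tuple[Backbone, dict[str, list[float]]]:
    """Train the unfrozen blocks and head; return the min-validation-loss checkpoint.

    History holds one train and one validation loss per epoch.  If the dataset
    has no validation items the training loss doubles as the checkpoint
    criterion.  ``epochs=0`` returns the model unchanged with empty history.
    """
    train_slices = dataset.train_items
    if not dataset.items:
        raise ValueError("cannot fine-tune on an empty dataset")
    if not train_slices:
        raise ValueError("dataset has no training partition")
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    if train_config.epochs == 0:
        return model, history
    val_slices = dataset.val_items
    rng = np.random.default_rng(np.random.SeedSequence((train_config.seed, 0xF1)))
    optimizer = _nn.RMSProp(lr=train_config.learning_rate, rho=train_config.rho)
    best_state, best_loss = None, np.inf
    for _epoch in range(train_config.epochs):
        order = rng.permutation(len(train_slices))
        epoch_losses, epoch_weights = [], []
        for start in range(0, len(order), train_config.batch_size):
            batch = [train_slices[i] for i in order[start : start + train_config.batch_size]]
            x, y = _slices_to_batch(batch)
            logits = model.net.forward(x, train=True)
            loss, dlogits = _nn.softmax_cross_entropy(logits, y)
            model.net.backward(dlogits)
            optimizer.step(model.net)
            epoch_losses.append(loss)
            epoch_weights.append(len(y))
        train_loss = float(np.average(epoch_losses, weights=epoch_weights))
        val_loss = _dataset_loss(model, val_slices) if val_slices else train_loss
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.net.get_state()
    if best_state is not None:
        model.net.set_state(best_state)
    return model, history


def extract_slice_features(model: Backbone, fused: FusedSlice) -> SliceFeature:
    """Deterministic 1 x feature_dim representation of one fused slice."""
    x, _ = _slices_to_batch([fused])
    vec = model.features(x)[0].astype(np.float32)
    return SliceFeature(vector=vec, subject_id=fused.subject_id, slice_index=fused.slice_index)


def extract_features(
    model: Backbone, slices: Sequence[FusedSlice], batch_size: int = 64
) -> list[SliceFeature]:
    """Batched feature extraction, order-preserving."""
    out: list[SliceFeature] = []
    for start in range(0, len(slices), batch_size):
        chunk = slices[start : start + batch_size]
        x, _ = _slices_to_batch(chunk)
        vecs = model.features(x)
        out.extend(
            SliceFeature(vector=v.astype(np.float32), subject_id=s.subject_id, slice_index=s.slice_index)
            for v, s in zip(vecs, chunk)
        )
    return out


def aggregate_subject(
    features: Sequence[SliceFeature], label: int, expected_indices: Sequence[int] | None = None
) -> SubjectFeature:
    """Concatenate one subject's slice features in ascending slice-index order.

    With the default 32-slice window and 256-dimensional slice features the
    result is the 1 x 8192 subject representation; block k of the output
    corresponds to the k-th slice index of the window.
    """
    if not features:
        raise ValueError("no slice features to aggregate")
    subject_ids = {f.subject_id for f in features}
    if len(subject_ids) != 1:
        raise ValueError(f"features mix subjects: {sorted(subject_ids)}")
    indices = [f.slice_index for f in features]
    if len(set(indices)) != len(indices):
        raise ValueError("duplicate slice indices in aggregation")
    if expected_indices is not None and set(indices) != set(expected_indices):
        missing = sorted(set(expected_indices) - set(indices))
        extra = sorted(set(indices) - set(expected_indices))
        raise ValueError(f"slice indices do not cover the window: missing {missing}, extra {extra}")
    ordered = sorted(features, key=lambda f: f.slice_index)
    dims = {f.vector.shape for f in ordered}
    if len(dims) != 1:
        raise ValueError(f"slice features disagree in dimension: {dims}")
    vector = np.concatenate([f.vector for f in ordered])
    return SubjectFeature(vector=vector, subject_id=subject_ids.pop(), label=label)
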