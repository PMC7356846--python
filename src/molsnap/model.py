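"""Image-classifier training harness.

The training protocol is fixed-epoch minibatch SGD with one validation pass
per epoch: defaults of 30 epochs, learning rate 0.006, batch size 108, one
random seed. Per-epoch parameter checkpoints are retained and the deployed
model is the checkpoint with the lowest validation cross-entropy
(``select_best_epoch``), which is then used to score Test images.

The classifier itself is pluggable. The default ``tiny_cnn`` backbone is a
small convolutional network implemented in NumPy: a 1x1 convolution over RGB
(a per-pixel color-feature bank), ReLU, global average pooling, a fixed
whitening layer calibrated on the training set at initialization, and a
linear softmax head. It is deliberately minimal — enough capacity to learn
color/shape composition cues in ball-and-stick snapshots at desk scale —
and deterministic under a fixed seed. Heavier backbones register through
:func:`register_backbone`.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

LABEL_TO_INDEX = {"inactive": 0, "active": 1}


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    learning_rate: float = 0.006
    batch_size: int = 108
    solver: str = "sgd"
    momentum: float = 0.9
    seed: int = 1
    backbone: str = "tiny_cnn"
    backbone_options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.solver != "sgd":
            raise ValueError(f"unsupported solver {self.solver!r}")


@dataclass
class EpochRecord:
    epoch: int  # 1-based
    loss_val: float  # cross-entropy on Val
    acc_val: float  # percent correct on Val, 0-100
    loss_tra: float = float("nan")


def _default_color_bank() -> np.ndarray:
    """Depiction-palette color centers (unit RGB) for the frozen conv bank."""
    from .elements import element_table
    bank_elements = ("H", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I")
    table = element_table()
    colors = []
    for el in bank_elements:
        rgb = np.asarray(table[el].cpk_color, dtype=float) / 255.0
        if not any(np.allclose(rgb, c) for c in colors):
            colors.append(rgb)
    return np.array(colors)


class TinyCNN:
    """Small convolutional color-composition network (NumPy).

    The feature extractor is a frozen 1x1 convolution selective for the
    depiction palette: channel k responds relu(1 - ||pixel - c_k||^2 / tau^2)
    to its reference color c_k (a quadratic color expansion makes this a
    linear operation per pixel). Global average pooling turns the per-pixel
    responses into per-image soft color fractions and global max pooling
    into color-presence indicators; a calibrated standardization layer
    brings both to unit scale and a trainable linear softmax head sits on
    top. Freezing the feature bank and training only the head
    mirrors the fixed-pretrained-backbone fine-tuning protocol and keeps the
    optimization convex, stable and seeded-deterministic.
    """

    def __init__(self, rng: np.random.Generator,
                 color_bank: Optional[np.ndarray] = None, tau: float = 0.35):
        self.colors = (_default_color_bank() if color_bank is None
                       else np.asarray(color_bank, dtype=float))
        self.tau = float(tau)
        self.n_hidden = 2 * len(self.colors)  # mean-pool + max-pool channels
        self.W2 = np.zeros((self.n_hidden, 2))
        self.b2 = np.zeros(2)
        self.mu = np.zeros(self.n_hidden)
        self.sigma = np.ones(self.n_hidden)

    # -- parameter plumbing -------------------------------------------------
    def get_params(self) -> dict:
        return {k: getattr(self, k).copy() for k in
                ("W2", "b2", "mu", "sigma")}

    def set_params(self, params: dict) -> None:
        for k, v in params.items():
            setattr(self, k, v.copy())

    def trainable(self) -> list[str]:
        return ["W2", "b2"]

    # -- computation --------------------------------------------------------
    def _pooled(self, x: np.ndarray) -> np.ndarray:
        # (N, H, W, 3) in [0,1] -> (N, 2K): soft color fractions (mean pool)
        # then color-presence responses (max pool)
        n = x.shape[0]
        p = x.reshape(n, -1, 3)
        d2 = (np.sum(p ** 2, axis=-1)[:, :, None]
              + np.sum(self.colors ** 2, axis=-1)[None, None, :]
              - 2.0 * p @ self.colors.T)
        h = np.maximum(1.0 - d2 / self.tau ** 2, 0.0)
        return np.concatenate([h.mean(axis=1), h.max(axis=1)], axis=1)

    def calibrate(self, x: np.ndarray) -> None:
        """Fix the standardization layer from a sample of training images.

        Colored structure covers a small fraction of each frame, so raw
        pooled fractions live at a tiny scale; standardizing them to unit
        variance puts the head's gradients on the scale the default
        learning rate expects. The statistics are frozen afterwards — they
        are architecture, not trained parameters.
        """
        pooled = self._pooled(x)
        std = pooled.std(axis=0)
        floor = max(1e-8, 0.01 * float(std.max()))
        self.mu = pooled.mean(axis=0)
        self.sigma = np.maximum(std, floor)

    def forward(self, x: np.ndarray):
        pooled = self._pooled(x)
        z = (pooled - self.mu) / self.sigma
        logits = z @ self.W2 + self.b2
        return logits, (z,)

    def backward(self, cache, grad_logits: np.ndarray) -> dict:
        (z,) = cache
        return {"W2": z.T @ grad_logits, "b2": grad_logits.sum(axis=0)}


BACKBONES: dict[str, Callable[..., TinyCNN]] = {"tiny_cnn": TinyCNN}


def register_backbone(name: str, factory: Callable) -> None:
    """Extension point for heavier architectures (name 'custom' or other)."""
    BACKBONES[name] = factory


@dataclass
class ModelHandle:
    """A trained classifier: backbone plus per-epoch checkpoints."""

    backbone: object
    checkpoints: list[dict]  # params after each epoch, index = epoch - 1
    records: list[EpochRecord]
    config: TrainConfig
    best_epoch: int = 0  # 1-based, set after selection

    def use_epoch(self, epoch: int) -> None:
        self.backbone.set_params(self.checkpoints[epoch - 1])
        self.best_epoch = epoch


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def _cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    return float(-np.mean(np.log(np.clip(probs[np.arange(len(y)), y],
                                         1e-12, None))))


def load_images(manifest: pd.DataFrame, root: str | Path) -> np.ndarray:
    """Load manifest rows into a float32 (N, H, W, 3) array scaled to [0,1]."""
    root = Path(root)
    arrays = []
    for path in manifest["image_path"]:
        full = root / path
        if not full.exists():
            raise FileNotFoundError(f"image file missing: {full}")
        with Image.open(full) as im:
            arrays.append(np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0)
    return np.stack(arrays)


def replicate_view(manifest: pd.DataFrame, replicate_id: str) -> pd.DataFrame:
    return manifest[manifest["replicate"] == replicate_id].reset_index(drop=True)


def train(manifest: pd.DataFrame, config: TrainConfig,
          root: str | Path) -> tuple[ModelHandle, list[EpochRecord]]:
    """Train on the manifest's Tra partition, validating each epoch on Val.

    Deterministic for a fixed config seed. Raises before training if the
    training partition does not contain both classes.
    """
    tra = manifest[manifest["partition"] == "Tra"]
    val = manifest[manifest["partition"] == "Val"]
    if len(tra) == 0 or len(val) == 0:
        raise ValueError("manifest must contain non-empty Tra and Val partitions")
    if tra["label"].nunique() < 2:
        raise ValueError("training partition contains a single class")

    x_tra = load_images(tra, root)
    y_tra = tra["label"].map(LABEL_TO_INDEX).to_numpy()
    x_val = load_images(val, root)
    y_val = val["label"].map(LABEL_TO_INDEX).to_numpy()

    rng = np.random.default_rng(config.seed)
    factory = BACKBONES[config.backbone]
    net = factory(rng, **config.backbone_options)
    if hasattr(net, "calibrate"):
        net.calibrate(x_tra)

    velocity = {k: np.zeros_like(getattr(net, k)) for k in net.trainable()}
    checkpoints: list[dict] = []
    records: list[EpochRecord] = []
    n = len(x_tra)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x_tra[idx], y_tra[idx]
            logits, cache = net.forward(xb)
            probs = _softmax(logits)
            epoch_loss += _cross_entropy(probs, yb) * len(idx)
            grad_logits = probs.copy()
            grad_logits[np.arange(len(yb)), yb] -= 1.0
            grad_logits /= len(yb)
            grads = net.backward(cache, grad_logits)
            for k in net.trainable():
                velocity[k] = config.momentum * velocity[k] \
                    - config.learning_rate * grads[k]
                setattr(net, k, getattr(net, k) + velocity[k])
        val_logits, _ = net.forward(x_val)
        val_probs = _softmax(val_logits)
        records.append(EpochRecord(
            epoch=epoch,
            loss_val=_cross_entropy(val_probs, y_val),
            acc_val=float(np.mean(val_probs.argmax(axis=1) == y_val)) * 100.0,
            loss_tra=epoch_loss / n,
        ))
        checkpoints.append(net.get_params())

    handle = ModelHandle(backbone=net, checkpoints=checkpoints,
                         records=records, config=config)
    handle.use_epoch(select_best_epoch(records))
    return handle, records


def select_best_epoch(records: Sequence[EpochRecord]) -> int:
    """Epoch (1-based) with the lowest validation loss; earliest wins ties."""
    if not records:
        raise ValueError("no epoch records")
    best = min(records, key=lambda r: (r.loss_val, r.epoch))
    return best.epoch


def predict_images(handle: ModelHandle, rows: pd.DataFrame,
                   root: str | Path) -> pd.DataFrame:
    """Probability-of-active for each manifest row, as a prediction table."""
    x = load_images(rows, root)
    logits, _ = handle.backbone.forward(x)
    probs = _softmax(logits)[:, LABEL_TO_INDEX["active"]]
    out = rows[["compound_id", "theta_x", "theta_y", "theta_z", "label"]].copy()
    out["probability_active"] = probs
    return out.reset_index(drop=True)


def write_epoch_log(records: Sequence[EpochRecord], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, index=False)
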