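"""Whole-image classifier (P2): frozen convolutional backbone + trainable head.

The production configuration mirrors transfer learning with a densenet169
trunk frozen through its convolutional blocks; since pretrained weights are
an external asset, a first-class ``small-test-backbone`` is provided: a
seeded, frozen random convolutional feature extractor over 64x64 inputs
whose global-average-pooled features feed a trainable softmax head.  The
head is trained with stochastic gradient descent (learning rate 1e-4),
cross-entropy loss and batch size 32; the frozen trunk is never touched by
the optimizer, so the freeze contract holds bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from . import nnet
from .types import EbusImage, UnavailableBackboneError

__all__ = ["TransferConfig", "SingleImageModel", "build_model"]

BACKBONES = ("densenet169-pretrained", "small-test-backbone")


@dataclass
class TransferConfig:
    backbone: str = "small-test-backbone"
    input_px: int = 64
    learning_rate: float = 0.0001
    batch_size: int = 32
    epochs: int = 50
    rng_seed: int = 0

    def __post_init__(self):
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def _to_input(image: EbusImage | np.ndarray, px: int) -> np.ndarray:
    """Bilinear resize to (3, px, px) floats in [0, 1]; grayscale replicated."""
    arr = image.pixels if isinstance(image, EbusImage) else np.asarray(image)
    arr = arr.astype(float) / 255.0
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    out = resize(arr, (px, px, 3), order=1, anti_aliasing=True, mode="reflect")
    return out.transpose(2, 0, 1)


class SingleImageModel:
    """Frozen random conv trunk, global average pooling, softmax head."""

    def __init__(self, config: TransferConfig):
        if config.backbone == "densenet169-pretrained":
            raise UnavailableBackboneError(
                "densenet169-pretrained requires an external weights file; "
                "use the small-test-backbone configuration")
        self.config = config
        rng = np.random.default_rng(config.rng_seed)
        # frozen trunk: 4 conv/pool stages, 64 -> 4 spatial, 64 channels
        self._trunk = nnet.Sequential([
            nnet.Conv2D(3, 8, rng=rng), nnet.ReLU(), nnet.MaxPool2x2(),
            nnet.Conv2D(8, 16, rng=rng), nnet.ReLU(), nnet.MaxPool2x2(),
            nnet.Conv2D(16, 32, rng=rng), nnet.ReLU(), nnet.MaxPool2x2(),
            nnet.Conv2D(32, 64, rng=rng), nnet.ReLU(), nnet.MaxPool2x2(),
        ])
        self._head = nnet.Sequential([nnet.Dense(64, 2, rng=rng)])
        self._feat_mean: np.ndarray | None = None
        self._feat_std: np.ndarray | None = None
        self.training_log: list[dict] = []

    # -- feature extraction (frozen path) ---------------------------------
    def frozen_params(self) -> list[np.ndarray]:
        return [p.copy() for p in self._trunk.params]

    def features(self, images: list[EbusImage] | np.ndarray, batch: int = 16) -> np.ndarray:
        px = self.config.input_px
        x = np.stack([_to_input(im, px) for im in images])
        feats = []
        for i in range(0, len(x), batch):
            f = self._trunk.forward(x[i:i + batch], train=False)
            feats.append(f.mean(axis=(2, 3)))  # global average pooling
        return np.vstack(feats)

    # -- training ---------------------------------------------------------
    def fit(self, images: list[EbusImage], labels: np.ndarray,
            epochs: int | None = None) -> "SingleImageModel":
        labels = np.asarray(labels, dtype=int)
        feats = self.features(images)
        self._feat_mean = feats.mean(axis=0)
        self._feat_std = feats.std(axis=0) + 1e-8
        z = (feats - self._feat_mean) / self._feat_std
        rng = np.random.default_rng(self.config.rng_seed + 1)
        self._head.fit(z, labels,
                       optimizer=nnet.SGD(self.config.learning_rate),
                       epochs=self.config.epochs if epochs is None else epochs,
                       batch_size=self.config.batch_size, rng=rng,
                       log=self.training_log)
        return self

    def predict_p2(self, images: list[EbusImage]) -> np.ndarray:
        """Malignancy probability per image."""
        if self._feat_mean is None:
            raise RuntimeError("model is not trained")
        feats = self.features(images)
        z = (feats - self._feat_mean) / self._feat_std
        return self._head.predict_proba(z)[:, 1]


def build_model(cfg: TransferConfig) -> SingleImageModel:
    return SingleImageModel(cfg)
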