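"""Patch-level CNN and the ratio-threshold aggregation (P3).

Each 3x32x32 patch from the 2–5 mm annulus is classified independently by a
four-stage CNN (8/16/32/64 kernels of 3x3, each stage conv + batch-norm +
ReLU + 2x2 max pooling + dropout, then dense 256 and dense 2 with softmax).
The per-image statistic is the malignant-patch ratio

    P3 = nM / (nM + nB)

and the image is called malignant iff P3 > T (default T = 0.63; equality is
benign).  Patch labels are hard argmax verdicts — the ratio counts patches,
not probabilities — with ties broken toward benign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nnet
from .preprocess import PatchSet
from .types import EmptyPatchSetError

__all__ = ["PatchCnnConfig", "PatchDecision", "build_patch_cnn", "PatchModel",
           "aggregate_p3", "patch_array"]


@dataclass
class PatchCnnConfig:
    conv_channels: tuple[int, ...] = (8, 16, 32, 64)
    kernel: int = 3
    fc_width: int = 256
    dropout: float = 0.25
    learning_rate: float = 0.001
    batch_size: int = 128
    epochs: int = 12
    threshold: float = 0.63          # decision threshold T on the patch ratio
    rng_seed: int = 0


@dataclass
class PatchDecision:
    n_malignant: int
    n_benign: int
    threshold: float

    @property
    def p3(self) -> float:
        return self.n_malignant / (self.n_malignant + self.n_benign)

    @property
    def label(self) -> int:
        return 1 if self.p3 > self.threshold else 0


def aggregate_p3(labels: np.ndarray | list[int], threshold: float = 0.63) -> PatchDecision:
    """Patch-count ratio and class for one image's patch verdicts.

    Raises :class:`EmptyPatchSetError` on zero patches so the ensemble can
    drop the patch model for that image.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise EmptyPatchSetError("no patches: P3 is undefined for this image")
    n_mal = int((labels == 1).sum())
    n_ben = int((labels == 0).sum())
    return PatchDecision(n_malignant=n_mal, n_benign=n_ben, threshold=threshold)


def patch_array(patchset: PatchSet) -> np.ndarray:
    """(N, 3, 32, 32) float input tensor from a PatchSet (RGB replicated)."""
    out = []
    for p in patchset.patches:
        px = p.pixels.astype(float) / 255.0
        if px.ndim == 2:
            px = np.stack([px] * 3, axis=0)
        else:
            px = px.transpose(2, 0, 1)
        out.append(px)
    return np.stack(out) if out else np.zeros((0, 3, 32, 32))


def build_patch_cnn(cfg: PatchCnnConfig) -> nnet.Sequential:
    """The patch CNN: spatial path 32 -> 16 -> 8 -> 4 -> 2, flatten to 256."""
    rng = np.random.default_rng(cfg.rng_seed)
    layers: list[nnet.Layer] = []
    c_in = 3
    for c_out in cfg.conv_channels:
        layers += [
            nnet.Conv2D(c_in, c_out, k=cfg.kernel, rng=rng),
            nnet.BatchNorm2D(c_out),
            nnet.ReLU(),
            nnet.MaxPool2x2(),
            nnet.Dropout(cfg.dropout, rng=np.random.default_rng(cfg.rng_seed + 7)),
        ]
        c_in = c_out
    layers += [
        nnet.Flatten(),
        nnet.Dense(cfg.conv_channels[-1] * 2 * 2, cfg.fc_width, rng=rng),
        nnet.ReLU(),
        nnet.Dense(cfg.fc_width, 2, rng=rng),
    ]
    return nnet.Sequential(layers)


def _instance_norm(x: np.ndarray) -> np.ndarray:
    """Standardize each patch to zero mean / unit variance so the classifier
    sees echotexture rather than absolute brightness."""
    mu = x.mean(axis=(1, 2, 3), keepdims=True)
    sd = x.std(axis=(1, 2, 3), keepdims=True) + 1e-8
    return (x - mu) / sd


class PatchModel:
    """Trainable patch CNN with the per-image ratio aggregation."""

    def __init__(self, config: PatchCnnConfig | None = None):
        self.config = config or PatchCnnConfig()
        self.net = build_patch_cnn(self.config)
        self.training_log: list[dict] = []

    def fit(self, patches: np.ndarray, labels: np.ndarray,
            epochs: int | None = None) -> "PatchModel":
        rng = np.random.default_rng(self.config.rng_seed + 1)
        self.net.fit(_instance_norm(patches), np.asarray(labels, dtype=int),
                     optimizer=nnet.Adam(self.config.learning_rate),
                     epochs=self.config.epochs if epochs is None else epochs,
                     batch_size=self.config.batch_size, rng=rng,
                     log=self.training_log)
        return self

    def classify_patches(self, patchset: PatchSet | np.ndarray) -> np.ndarray:
        """Hard per-patch verdicts (argmax, ties toward benign)."""
        x = patch_array(patchset) if isinstance(patchset, PatchSet) else patchset
        if len(x) == 0:
            raise EmptyPatchSetError("empty patch set")
        proba = self.net.predict_proba(_instance_norm(x))
        return (proba[:, 1] > proba[:, 0]).astype(int)

    def predict_image(self, patchset: PatchSet | np.ndarray) -> PatchDecision:
        labels = self.classify_patches(patchset)
        return aggregate_p3(labels, threshold=self.config.threshold)
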