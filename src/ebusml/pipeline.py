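"""End-to-end orchestration: preprocessing, the three models, fusion.

``EnsemblePipeline.fit`` runs the full training recipe on a cohort:

1. every image is contrast-stretched (1st/99th percentile thresholds) and a
   lesion mask is ray-cast from the probe center (or ground-truth masks are
   used when provided and trusted);
2. the 89-entry feature vectors of the *non-augmented* training lesions
   train the MI-selected random forest (P1);
3. the training split is augmented class-asymmetrically (malignant x3,
   benign x5) and feeds the whole-image model (P2) and, after annulus patch
   tiling, the patch CNN (P3);
4. per-image (P1, P2, P3) on the training originals drive the exhaustive
   weight/cutoff grid search (or the published operating point is kept).

One global seed fans out to per-module seeds through fixed offsets so each
model stays reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble import EnsembleConfig, EvalReport, fuse_batch, metrics, optimize
from .multi_patch import PatchCnnConfig, PatchModel, aggregate_p3, patch_array
from .preprocess import (ContrastParams, RingSpec, augment, contrast_stretch,
                         detect_boundary, percentile_thresholds, select_patches)
from .radiomics import QuantizationSpec, assemble_vector
from .single_image import SingleImageModel, TransferConfig
from .tabular import ForestConfig, RadiomicsForest
from .types import Cohort, EbusImage, EmptyPatchSetError, LesionMask

__all__ = ["PipelineConfig", "EnsemblePipeline"]

# fixed offsets of the per-module seeds derived from the global seed
_SEED_FOREST, _SEED_SINGLE, _SEED_PATCH = 11, 23, 37


@dataclass
class PipelineConfig:
    seed: int = 0
    gamma: float = 1.0
    n_rays: int = 180
    use_true_masks: bool = False      # trust cohort masks instead of ray casting
    probe_radius_mm: float = 2.0
    ring: RingSpec = field(default_factory=RingSpec)
    quant: QuantizationSpec = field(default_factory=QuantizationSpec)
    forest: ForestConfig | None = None
    transfer: TransferConfig | None = None
    patch_cnn: PatchCnnConfig | None = None
    optimize_weights: bool = True

    def __post_init__(self):
        if self.forest is None:
            self.forest = ForestConfig(rng_seed=self.seed + _SEED_FOREST)
        if self.transfer is None:
            self.transfer = TransferConfig(rng_seed=self.seed + _SEED_SINGLE)
        if self.patch_cnn is None:
            self.patch_cnn = PatchCnnConfig(rng_seed=self.seed + _SEED_PATCH)


class EnsemblePipeline:
    def __init__(self, config: PipelineConfig | None = None):
        self.config = config or PipelineConfig()
        self.forest: RadiomicsForest | None = None
        self.single: SingleImageModel | None = None
        self.patch_model: PatchModel | None = None
        self.ensemble_cfg: EnsembleConfig | None = None
        self._masks: dict[str, LesionMask] = {}
        self._features: dict[str, np.ndarray] = {}

    # -- per-image preprocessing (cached by image id) ---------------------
    def enhance(self, image: EbusImage) -> EbusImage:
        params = percentile_thresholds(image)
        params.gamma = self.config.gamma
        return contrast_stretch(image, params)

    def mask_for(self, image: EbusImage, true_mask: LesionMask | None = None) -> LesionMask:
        if self.config.use_true_masks and true_mask is not None:
            return true_mask
        if image.id not in self._masks:
            self._masks[image.id] = detect_boundary(self.enhance(image),
                                                    self.config.n_rays)
        return self._masks[image.id]

    def feature_row(self, image: EbusImage, mask: LesionMask, record) -> np.ndarray:
        if image.id not in self._features:
            vec = assemble_vector(self.enhance(image), mask, record,
                                  q=self.config.quant)
            self._features[image.id] = vec.values
        return self._features[image.id]

    def _feature_frame(self, cohort: Cohort, idx: list[int]) -> pd.DataFrame:
        from .radiomics import FEATURE_NAMES
        rows = []
        for i in idx:
            mask = self.mask_for(cohort.images[i], cohort.masks[i])
            rows.append(self.feature_row(cohort.images[i], mask, cohort.records[i]))
        return pd.DataFrame(rows, columns=FEATURE_NAMES,
                            index=[cohort.images[i].id for i in idx])

    # -- training ---------------------------------------------------------
    def fit(self, cohort: Cohort) -> "EnsemblePipeline":
        cfg = self.config
        train_idx = cohort.indices("train")
        if not train_idx:
            raise ValueError("cohort has no training split")

        # P1: MI-selected random forest on non-augmented training lesions
        x_train = self._feature_frame(cohort, train_idx)
        y_train = cohort.labels[train_idx]
        self.forest = RadiomicsForest(cfg.forest).fit(x_train, y_train)

        # class-asymmetric augmentation of the training split only
        masks = [self.mask_for(cohort.images[i], cohort.masks[i])
                 for i in range(len(cohort))]
        work = Cohort(images=cohort.images, masks=masks,
                      records=cohort.records, split=cohort.split)
        aug = augment(work.subset(train_idx))

        # P2: frozen-trunk whole-image model on the augmented set
        self.single = SingleImageModel(cfg.transfer)
        self.single.fit(aug.images, aug.labels)

        # P3: patch CNN on annulus patches of the augmented set
        xs, ys = [], []
        for i in range(len(aug)):
            ps = select_patches(aug.images[i], aug.masks[i], cfg.ring,
                                probe_radius_mm=cfg.probe_radius_mm)
            if len(ps):
                xs.append(patch_array(ps))
                ys.append(np.full(len(ps), aug.records[i].label, dtype=int))
        self.patch_model = PatchModel(cfg.patch_cnn)
        if xs:
            self.patch_model.fit(np.concatenate(xs), np.concatenate(ys))

        # ensemble operating point from the training originals
        p1, p2, p3 = self.predict_proba(cohort, train_idx)
        if cfg.optimize_weights:
            p3_filled = np.where(np.isnan(p3), 0.5, p3)
            self.ensemble_cfg = optimize(p1, p2, p3_filled, y_train)
        else:
            self.ensemble_cfg = EnsembleConfig()
        return self

    # -- inference --------------------------------------------------------
    def predict_proba(self, cohort: Cohort, idx: list[int]
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(P1, P2, P3) per image; P3 is NaN where no patch qualifies."""
        if self.forest is None or self.single is None or self.patch_model is None:
            raise RuntimeError("pipeline is not trained")
        x = self._feature_frame(cohort, idx)
        p1 = self.forest.predict_p1(x)
        images = [cohort.images[i] for i in idx]
        p2 = self.single.predict_p2(images)
        p3 = np.full(len(idx), np.nan)
        for k, i in enumerate(idx):
            mask = self.mask_for(cohort.images[i], cohort.masks[i])
            ps = select_patches(cohort.images[i], mask, self.config.ring,
                                probe_radius_mm=self.config.probe_radius_mm)
            try:
                labels = self.patch_model.classify_patches(ps)
                p3[k] = aggregate_p3(labels, self.config.patch_cnn.threshold).p3
            except EmptyPatchSetError:
                pass
        return p1, p2, p3

    def evaluate(self, cohort: Cohort, part: str = "test") -> dict:
        """Fused and per-model reports on one split."""
        idx = cohort.indices(part)
        labels = cohort.labels[idx]
        p1, p2, p3 = self.predict_proba(cohort, idx)
        fused, pred = fuse_batch(p1, p2, p3, self.ensemble_cfg)
        t = self.config.patch_cnn.threshold
        p3_class = np.where(np.isnan(p3), 0, (p3 > t)).astype(int)
        return {
            "fused": metrics(pred, labels, scores=fused),
            "model1": metrics((p1 > 0.5).astype(int), labels, scores=p1),
            "model2": metrics((p2 > 0.5).astype(int), labels, scores=p2),
            "model3": metrics(p3_class, labels,
                              scores=np.where(np.isnan(p3), 0.5, p3)),
            "p": {"p1": p1, "p2": p2, "p3": p3, "fused": fused,
                  "labels": labels, "pred": pred},
            "config": self.ensemble_cfg,
        }
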