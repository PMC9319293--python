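"""Serializable run configuration: one YAML reconstructs any run."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .multi_patch import PatchCnnConfig
from .pipeline import PipelineConfig
from .preprocess import RingSpec
from .radiomics import QuantizationSpec
from .single_image import TransferConfig
from .tabular import ForestConfig

__all__ = ["load_run_config", "dump_run_config"]


def dump_run_config(cfg: PipelineConfig, path: Path | str) -> None:
    doc = {
        "seed": cfg.seed,
        "gamma": cfg.gamma,
        "n_rays": cfg.n_rays,
        "use_true_masks": cfg.use_true_masks,
        "probe_radius_mm": cfg.probe_radius_mm,
        "optimize_weights": cfg.optimize_weights,
        "ring": asdict(cfg.ring),
        "quant": asdict(cfg.quant),
        "forest": asdict(cfg.forest),
        "transfer": asdict(cfg.transfer),
        "patch_cnn": asdict(cfg.patch_cnn),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_run_config(path: Path | str) -> PipelineConfig:
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as e:
        raise ValueError(f"invalid YAML config: {e}") from e
    if not isinstance(doc, dict):
        raise ValueError("invalid config: expected a mapping")
    kwargs = {k: doc[k] for k in ("seed", "gamma", "n_rays", "use_true_masks",
                                  "probe_radius_mm", "optimize_weights")
              if k in doc}
    if "ring" in doc:
        kwargs["ring"] = RingSpec(**doc["ring"])
    if "quant" in doc:
        kwargs["quant"] = QuantizationSpec(**doc["quant"])
    if "forest" in doc:
        kwargs["forest"] = ForestConfig(**doc["forest"])
    if "transfer" in doc:
        kwargs["transfer"] = TransferConfig(**doc["transfer"])
    if "patch_cnn" in doc:
        doc_pc = dict(doc["patch_cnn"])
        if "conv_channels" in doc_pc:
            doc_pc["conv_channels"] = tuple(doc_pc["conv_channels"])
        kwargs["patch_cnn"] = PatchCnnConfig(**doc_pc)
    return PipelineConfig(**kwargs)
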