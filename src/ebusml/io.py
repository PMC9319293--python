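"""File interfaces: 8-bit PNG images/masks, CSV metadata, JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .types import Cohort, EbusImage, LesionMask, PatientRecord

__all__ = ["save_png", "load_png", "save_cohort", "load_cohort",
           "save_patchset", "METADATA_COLUMNS"]

METADATA_COLUMNS = ["id", "gender", "smoking", "age", "lesion_size", "label", "split"]


def save_png(path: Path | str, pixels: np.ndarray) -> None:
    arr = np.asarray(pixels)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    Image.fromarray(arr.astype(np.uint8)).save(path)


def load_png(path: Path | str) -> np.ndarray:
    return np.asarray(Image.open(path))


def save_cohort(cohort: Cohort, directory: Path | str, *,
                probe_radius_mm: float | None = None) -> None:
    """Write images/ and masks/ PNGs, metadata.csv and a calibration sidecar."""
    d = Path(directory)
    (d / "images").mkdir(parents=True, exist_ok=True)
    (d / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for img, mask, rec, split in zip(cohort.images, cohort.masks,
                                     cohort.records, cohort.split):
        save_png(d / "images" / f"{img.id}.png", img.pixels)
        save_png(d / "masks" / f"{img.id}.png", mask.mask)
        rows.append({"id": img.id, "gender": rec.gender, "smoking": rec.smoking,
                     "age": rec.age, "lesion_size": rec.lesion_size,
                     "label": rec.label, "split": split})
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(d / "metadata.csv", index=False)
    if cohort.images:
        img0 = cohort.images[0]
        sidecar = {"mm_per_px": img0.mm_per_px,
                   "probe_center": list(img0.probe_center)}
        if probe_radius_mm is not None:
            sidecar["probe_radius_mm"] = probe_radius_mm
        (d / "calibration.json").write_text(json.dumps(sidecar, indent=2))


def load_cohort(directory: Path | str) -> Cohort:
    d = Path(directory)
    meta = pd.read_csv(d / "metadata.csv")
    cal = json.loads((d / "calibration.json").read_text())
    images, masks, records, split = [], [], [], []
    for _, row in meta.iterrows():
        px = load_png(d / "images" / f"{row['id']}.png")
        m = load_png(d / "masks" / f"{row['id']}.png") > 127
        images.append(EbusImage(pixels=px, probe_center=tuple(cal["probe_center"]),
                                mm_per_px=cal["mm_per_px"], id=str(row["id"])))
        masks.append(LesionMask(m))
        records.append(PatientRecord(gender=row["gender"], smoking=row["smoking"],
                                     age=float(row["age"]),
                                     lesion_size=row["lesion_size"],
                                     label=int(row["label"]), id=str(row["id"])))
        split.append(str(row["split"]))
    return Cohort(images=images, masks=masks, records=records, split=split)


def save_patchset(patchset, directory: Path | str) -> None:
    """Patches as 32x32 PNGs plus a manifest CSV `image_id,row,col`."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, p in enumerate(patchset.patches):
        save_png(d / f"{patchset.image_id}-patch{k:02d}.png", p.pixels)
        rows.append({"image_id": patchset.image_id, "row": p.row, "col": p.col})
    pd.DataFrame(rows, columns=["image_id", "row", "col"]).to_csv(
        d / "manifest.csv", index=False)
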