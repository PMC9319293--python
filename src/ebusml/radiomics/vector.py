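"""Assembly of the 89-entry feature vector (85 radiomics + 4 clinical)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..types import EbusImage, LesionMask, PatientRecord
from .features import aws_feature, texture_features
from .matrices import GLCM_ANGLES, glcm
from .quantization import QuantizationSpec, quantize
from .shape import shape2d_features

__all__ = ["FeatureVector", "FEATURE_NAMES", "CLINICAL_NAMES",
           "encode_clinical", "radiomics_features", "assemble_vector"]

SHAPE_NAMES = [
    "shape_area", "shape_perimeter", "shape_perimeter_area_ratio",
    "shape_major_axis_length", "shape_minor_axis_length", "shape_elongation",
    "shape_sphericity", "shape_maximum_diameter", "shape_equivalent_diameter",
]

CLINICAL_NAMES = ["clinical_gender", "clinical_smoking", "clinical_age",
                  "clinical_lesion_size"]

_SMOKING_ORDINAL = {"non-smoker": 0.0, "ex-smoker": 1.0, "smoker": 2.0}


def encode_clinical(record: PatientRecord) -> dict[str, float]:
    """Encode the 4 clinical fields: gender and lesion size binary, smoking
    ordinal (non/ex/current = 0/1/2), age in years."""
    return {
        "clinical_gender": 1.0 if record.gender == "male" else 0.0,
        "clinical_smoking": _SMOKING_ORDINAL[record.smoking],
        "clinical_age": float(record.age),
        "clinical_lesion_size": 1.0 if record.lesion_size == ">=3cm" else 0.0,
    }


def radiomics_features(roi: EbusImage | np.ndarray, mask: LesionMask | np.ndarray,
                       q: QuantizationSpec = QuantizationSpec()) -> dict[str, float]:
    """The 85 radiomics values (shape + texture banks + AWS) of one lesion."""
    gray = roi.gray if isinstance(roi, EbusImage) else np.asarray(roi, float)
    m = mask.mask if isinstance(mask, LesionMask) else np.asarray(mask, bool)
    # crop to the mask bounding box: texture matrices only see in-mask pixels
    rows = np.any(m, axis=1)
    cols = np.any(m, axis=0)
    r0, r1 = np.nonzero(rows)[0][[0, -1]]
    c0, c1 = np.nonzero(cols)[0][[0, -1]]
    sub_g = gray[r0:r1 + 1, c0:c1 + 1]
    sub_m = m[r0:r1 + 1, c0:c1 + 1]

    quant = quantize(sub_g, sub_m, q)
    out = shape2d_features(m)
    out.update(texture_features(quant, n_levels=q.n_gray_levels))
    aws = np.mean([aws_feature(glcm(quant, off, n_levels=q.n_gray_levels,
                                    symmetric=False))
                   for off in GLCM_ANGLES.values()])
    out["glcm_aws"] = float(aws)
    return out


def _radiomics_names() -> list[str]:
    # frozen canonical order: shape, glcm (incl. aws), gldm, glrlm, glszm, ngtdm
    tiny = np.array([[1, 2], [2, 1]])
    tex = texture_features(tiny, n_levels=2)
    glcm_names = sorted(k for k in tex if k.startswith("glcm_")) + ["glcm_aws"]
    gldm_names = sorted(k for k in tex if k.startswith("gldm_"))
    glrlm_names = sorted(k for k in tex if k.startswith("glrlm_"))
    glszm_names = sorted(k for k in tex if k.startswith("glszm_"))
    ngtdm_names = sorted(k for k in tex if k.startswith("ngtdm_"))
    return SHAPE_NAMES + glcm_names + gldm_names + glrlm_names + glszm_names + ngtdm_names


RADIOMICS_NAMES: list[str] = _radiomics_names()
FEATURE_NAMES: list[str] = RADIOMICS_NAMES + CLINICAL_NAMES


@dataclass
class FeatureVector:
    """89 named values for one lesion, in the frozen canonical order."""

    values: np.ndarray
    names: tuple[str, ...] = tuple(FEATURE_NAMES)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.names):
            raise ValueError("value/name length mismatch")
        if np.isnan(self.values).any():
            raise ValueError("feature vector contains NaN")

    def __len__(self) -> int:
        return len(self.values)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def assemble_vector(roi: EbusImage | np.ndarray, mask: LesionMask | np.ndarray,
                    record: PatientRecord,
                    q: QuantizationSpec = QuantizationSpec()) -> FeatureVector:
    """Concatenate the 85 radiomics values with the 4 encoded clinical values."""
    feats = radiomics_features(roi, mask, q)
    feats.update(encode_clinical(record))
    missing = [n for n in FEATURE_NAMES if n not in feats]
    if missing:
        raise ValueError(f"missing features: {missing}")
    return FeatureVector(np.array([feats[n] for n in FEATURE_NAMES]))
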