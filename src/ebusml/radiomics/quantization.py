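"""Gray-level quantization of the in-mask intensities."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["QuantizationSpec", "quantize"]


@dataclass
class QuantizationSpec:
    """Fixed-bin-count quantization over the in-mask intensity range."""

    n_gray_levels: int = 32

    def __post_init__(self):
        if self.n_gray_levels < 2:
            raise ValueError("need at least 2 gray levels")


def quantize(roi: np.ndarray, mask: np.ndarray,
             q: QuantizationSpec = QuantizationSpec()) -> np.ndarray:
    """Map in-mask intensities to integer levels 1..n via equal-width bins.

    Bins span [min, max] of the in-mask values; a constant region maps
    everything to level 1.  Out-of-mask pixels are 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = np.asarray(roi, dtype=float)
    lo = vals[mask].min()
    hi = vals[mask].max()
    out = np.zeros(mask.shape, dtype=np.int32)
    if hi <= lo:
        out[mask] = 1
        return out
    n = q.n_gray_levels
    lev = np.floor((vals[mask] - lo) / (hi - lo) * n).astype(np.int32) + 1
    out[mask] = np.clip(lev, 1, n)
    return out
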