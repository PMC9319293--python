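"""Weighted soft-voting fusion of the three model probabilities and the
evaluation metrics.

The fused malignancy probability is P = w1*P1 + w2*P2 + w3*P3 with
non-negative weights summing to 1; the image is malignant iff P > cutoff
(equality is benign).  The published operating point is w = (0.41, 0.08,
0.51) with cutoff 0.53.  Weights and cutoff are chosen by exhaustive grid
search (step 0.01 on the weight simplex and on the cutoff) maximizing
training accuracy, with ties broken toward the smallest cutoff and then the
lexicographically smallest weight triple.  When P3 is undefined for an image
(no patches), (w1, w2) are renormalized to sum to 1 for that image.

Metrics: accuracy, sensitivity (malignant recall), specificity (benign
recall), PPV and NPV from the confusion counts, plus the trapezoidal AUC of
the ROC over the continuous fused probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve

__all__ = ["EnsembleConfig", "EvalReport", "fuse", "fuse_batch", "optimize",
           "metrics", "PAPER_WEIGHTS", "PAPER_CUTOFF"]

PAPER_WEIGHTS = (0.41, 0.08, 0.51)
PAPER_CUTOFF = 0.53


@dataclass
class EnsembleConfig:
    weights: tuple[float, float, float] = PAPER_WEIGHTS
    cutoff: float = PAPER_CUTOFF

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")
        if not (0.0 < self.cutoff < 1.0):
            raise ValueError("cutoff must lie in (0, 1)")


def fuse(p1: float, p2: float, p3: float | None,
         cfg: EnsembleConfig = EnsembleConfig()) -> tuple[float, int]:
    """Fused probability and class for one image.

    ``p3=None`` marks an image whose patch model is undefined; (w1, w2) are
    then renormalized to sum to 1.
    """
    w1, w2, w3 = cfg.weights
    for name, p in (("P1", p1), ("P2", p2)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    if p3 is None:
        s = w1 + w2
        if s <= 0:
            raise ValueError("cannot renormalize: w1 + w2 = 0")
        p = (w1 * p1 + w2 * p2) / s
    else:
        if not (0.0 <= p3 <= 1.0):
            raise ValueError("P3 must lie in [0, 1]")
        p = w1 * p1 + w2 * p2 + w3 * p3
    return float(p), int(p > cfg.cutoff)


def fuse_batch(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
               cfg: EnsembleConfig = EnsembleConfig()) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized fuse; NaN entries of p3 mark undefined patch models."""
    out = np.empty(len(p1))
    for i in range(len(p1)):
        pi3 = None if np.isnan(p3[i]) else float(p3[i])
        out[i], _ = fuse(float(p1[i]), float(p2[i]), pi3, cfg)
    return out, (out > cfg.cutoff).astype(int)


def optimize(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
             labels: np.ndarray, step: float = 0.01) -> EnsembleConfig:
    """Exhaustive accuracy-maximizing grid search over weights and cutoff.

    The simplex grid contains the vertices (1,0,0), (0,1,0), (0,0,1), so the
    optimized training accuracy can never fall below any single model's.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes in the calibration set")
    n = int(round(1.0 / step))
    combos = []
    for a in range(n + 1):
        for b in range(n + 1 - a):
            combos.append((a / n, b / n, (n - a - b) / n))
    W = np.array(combos)                               # (m, 3) lexicographic
    P = np.stack([p1, p2, p3])                         # (3, N)
    fused = W @ P                                      # (m, N)
    cutoffs = np.round(np.arange(step, 1.0, step), 10)
    best_acc = -1.0
    best_cfg: EnsembleConfig | None = None
    for c in cutoffs:                                  # ascending: ties keep smallest cutoff
        acc = ((fused > c).astype(int) == labels).mean(axis=1)
        m = int(np.argmax(acc))                        # first max = lex smallest weights
        if acc[m] > best_acc + 1e-12:
            best_acc = float(acc[m])
            best_cfg = EnsembleConfig(tuple(float(w) for w in np.round(W[m], 10)),
                                      float(c))
    return best_cfg


@dataclass
class EvalReport:
    tp: int
    fn: int
    fp: int
    tn: int
    auc: float | None = None
    roc: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float | None:
        pos = self.tp + self.fn
        return self.tp / pos if pos else None

    @property
    def specificity(self) -> float | None:
        neg = self.fp + self.tn
        return self.tn / neg if neg else None

    @property
    def ppv(self) -> float | None:
        det = self.tp + self.fp
        return self.tp / det if det else None

    @property
    def npv(self) -> float | None:
        det = self.tn + self.fn
        return self.tn / det if det else None

    def as_percent(self, ndigits: int = 2) -> dict[str, float | None]:
        """Rates on the 0–100 scale, rounded only here at report time."""
        def pct(v):
            return None if v is None else round(100.0 * v, ndigits)
        return {
            "accuracy": pct(self.accuracy),
            "sensitivity": pct(self.sensitivity),
            "specificity": pct(self.specificity),
            "ppv": pct(self.ppv),
            "npv": pct(self.npv),
            "auc": None if self.auc is None else round(self.auc, 4),
        }

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn,
                **self.as_percent()}


def metrics(predictions: np.ndarray, labels: np.ndarray,
            scores: np.ndarray | None = None) -> EvalReport:
    """Confusion counts and rates; AUC from continuous scores when given."""
    predictions = np.asarray(predictions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must align")
    tp = int(((predictions == 1) & (labels == 1)).sum())
    fn = int(((predictions == 0) & (labels == 1)).sum())
    fp = int(((predictions == 1) & (labels == 0)).sum())
    tn = int(((predictions == 0) & (labels == 0)).sum())
    auc = None
    roc = None
    if scores is not None and len(np.unique(labels)) == 2:
        fpr, tpr, thr = roc_curve(labels, scores)
        auc = float(np.trapezoid(tpr, fpr))
        roc = (fpr, tpr, thr)
    return EvalReport(tp=tp, fn=fn, fp=fp, tn=tn, auc=auc, roc=roc)
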