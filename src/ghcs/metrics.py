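"""Classification and segmentation evaluation.

Classification metrics follow the usual confusion-matrix definitions
(abnormal = positive class):

    Rec = TP/(TP+FN)   Spe = TN/(TN+FP)   Acc = (TP+TN)/total
    Pre = TP/(TP+FP)   F1  = 2·Pre·Rec/(Pre+Rec)

The per-class report additionally reproduces the column convention used
in published gastric-histology confusion-matrix breakdowns, where the
normal-class row reads its "recall" down the predicted-normal column:
normal recall = TN/(TN+FN), normal specificity = TP/(TP+FP), normal
precision = TN/(TN+FP), and the abnormal row mirrors it (swap TP↔TN,
FP↔FN).  Overall accuracy is identical under either convention.

Segmentation overlap uses the Dice coefficient DC = 2|A∩B|/(|A|+|B|)
and Jaccard index JI = |A∩B|/|A∪B|, which satisfy DC = 2·JI/(1+JI)
identically.  Display values are percentages rounded half-up to two
decimals; full precision is always retained alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Optional

import numpy as np

#: Marker used when a metric's denominator is zero.
UNDEFINED = "undefined"


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN with abnormal as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion counts are all zero")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def round2(fraction: float) -> float:
    """Percentage display value: half-up rounding at two decimals."""
    return float(
        Decimal(repr(fraction * 100.0)).quantize(Decimal("0.01"), ROUND_HALF_UP)
    )


def _ratio(num: int, den: int):
    return num / den if den > 0 else None


def classification_metrics(counts: ConfusionCounts) -> Dict[str, Optional[float]]:
    """Recall, specificity, accuracy, precision and F1 as fractions.

    Metrics with a zero denominator are ``None`` (displayed as
    ``undefined``), never silently zero.
    """
    rec = _ratio(counts.tp, counts.tp + counts.fn)
    spe = _ratio(counts.tn, counts.tn + counts.fp)
    acc = counts.tp + counts.tn
    pre = _ratio(counts.tp, counts.tp + counts.fp)
    f1 = (
        2 * pre * rec / (pre + rec)
        if pre is not None and rec is not None and (pre + rec) > 0
        else None
    )
    return {
        "recall": rec,
        "specificity": spe,
        "accuracy": acc / counts.total,
        "precision": pre,
        "f1": f1,
    }


def _row(rec, spe, pre):
    f1 = (
        2 * pre * rec / (pre + rec)
        if pre is not None and rec is not None and (pre + rec) > 0
        else None
    )
    return {"recall": rec, "specificity": spe, "precision": pre, "f1": f1}


def per_class_report(counts: ConfusionCounts) -> Dict[str, Dict]:
    """Two-row report (normal / abnormal) in the published convention.

    The returned dict carries fractions under ``normal``/``abnormal``/
    ``accuracy`` and two-decimal percentage strings under ``display``.
    """
    normal = _row(
        rec=_ratio(counts.tn, counts.tn + counts.fn),
        spe=_ratio(counts.tp, counts.tp + counts.fp),
        pre=_ratio(counts.tn, counts.tn + counts.fp),
    )
    abnormal = _row(
        rec=_ratio(counts.tp, counts.tp + counts.fp),
        spe=_ratio(counts.tn, counts.tn + counts.fn),
        pre=_ratio(counts.tp, counts.tp + counts.fn),
    )
    accuracy = (counts.tp + counts.tn) / counts.total

    def disp(row):
        return {
            k: (f"{round2(v):.2f}" if v is not None else UNDEFINED)
            for k, v in row.items()
        }

    return {
        "normal": normal,
        "abnormal": abnormal,
        "accuracy": accuracy,
        "display": {
            "normal": disp(normal),
            "abnormal": disp(abnormal),
            "accuracy": f"{round2(accuracy):.2f}",
        },
    }


def _as_binary(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask) > 0


def _check_pair(pred: np.ndarray, truth: np.ndarray):
    a, b = _as_binary(pred), _as_binary(truth)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice coefficient 2|A∩B|/(|A|+|B|); 1.0 when both masks are empty."""
    a, b = _check_pair(pred, truth)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def jaccard(pred: np.ndarray, truth: np.ndarray) -> float:
    """Jaccard index |A∩B|/|A∪B|; 1.0 when both masks are empty."""
    a, b = _check_pair(pred, truth)
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


# Fixed overlay colors: TP green, FP blue, FN red.
_GREEN = np.array([0, 200, 0], dtype=np.uint8)
_BLUE = np.array([0, 0, 220], dtype=np.uint8)
_RED = np.array([220, 0, 0], dtype=np.uint8)


def pixel_outcome_map(
    pred: np.ndarray,
    truth: np.ndarray,
    background: np.ndarray | None = None,
    alpha: float = 0.6,
) -> np.ndarray:
    """RGB overlay of per-pixel outcomes: TP green, FP blue, FN red.

    Elsewhere the background image shows through (black when no
    background is given); with a background the outcome colors are
    alpha-blended onto it.
    """
    a, b = _check_pair(pred, truth)
    h, w = a.shape
    if background is None:
        base = np.zeros((h, w, 3), dtype=np.float64)
        blend = 1.0
    else:
        background = np.asarray(background)
        if background.ndim == 2:
            background = np.stack([background] * 3, axis=-1)
        if background.shape[:2] != (h, w):
            raise ValueError("background shape does not match masks")
        base = background.astype(np.float64)
        blend = alpha
    out = base.copy()
    for region, color in (((a & b), _GREEN), ((a & ~b), _BLUE), ((~a & b), _RED)):
        out[region] = (1.0 - blend) * base[region] + blend * color
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def posterior_heatmap(
    tile_posteriors: np.ndarray, upscale: int = 1
) -> np.ndarray:
    """Expand a grid of tile-level abnormal posteriors into a heat raster.

    Posteriors in [0, 1] are upsampled by pixel replication and mapped
    through a monotone blue-low / red-high colormap (R = 255·p,
    B = 255·(1−p)), so heat rank order equals posterior rank order.
    """
    p = np.asarray(tile_posteriors, dtype=np.float64)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("posteriors must lie in [0, 1]")
    big = np.kron(p, np.ones((upscale, upscale)))
    heat = np.zeros(big.shape + (3,), dtype=np.uint8)
    heat[..., 0] = np.rint(255.0 * big)
    heat[..., 2] = np.rint(255.0 * (1.0 - big))
    return heat


def confusion_from_labels(pred, truth, positive: str = "abnormal") -> ConfusionCounts:
    """Build counts from parallel label sequences."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    p = pred == positive
    t = truth == positive
    return ConfusionCounts(
        tp=int((p & t).sum()),
        tn=int((~p & ~t).sum()),
        fp=int((p & ~t).sum()),
        fn=int((~p & t).sum()),
    )
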