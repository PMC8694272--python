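"""Segmentation evaluation: overlap metrics and the Hausdorff distance.

All overlap metrics are derived from the pixel confusion counts with
foreground label 1: Dice = 2TP/(2TP+FP+FN), Jaccard = TP/(TP+FP+FN),
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP). The Hausdorff
distance is the plain (non-percentile) max over both directions of the
farthest nearest-point Euclidean distance between the two nonzero-pixel
sets.

Conventions for degenerate cases, stated because they matter when a
model predicts (or the truth is) an empty mask: Dice and Jaccard of two
empty masks are 1.0; a metric whose denominator is zero is reported as
NaN (an explicit "undefined" marker, never a silent 0); the Hausdorff
distance of an empty mask raises ``EmptyMaskError`` and is reported as
NaN in batch summaries. Batch summaries use the sample standard
deviation (ddof=1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import directed_hausdorff

from .data_io import BinaryMask, PairedDataset
from .exceptions import DataError, EmptyMaskError

__all__ = [
    "ConfusionCounts", "confusion_counts", "dice_coefficient", "jaccard_index",
    "sensitivity", "specificity", "hausdorff_distance",
    "MetricReport", "evaluate_pairs", "evaluate_dataset",
]

METRIC_COLUMNS = ("dice", "jaccard", "sensitivity", "specificity", "hausdorff")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _as_binary(arr) -> np.ndarray:
    a = arr.pixels if isinstance(arr, BinaryMask) else np.asarray(arr)
    if not np.isin(a, (0, 1)).all():
        raise DataError("metric inputs must be binary {0,1} masks")
    return a.astype(bool)


def confusion_counts(prediction, truth) -> ConfusionCounts:
    p = _as_binary(prediction)
    t = _as_binary(truth)
    if p.shape != t.shape:
        raise DataError(f"shape mismatch: {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    tn = int(np.count_nonzero(~p & ~t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def dice_coefficient(c: ConfusionCounts) -> float:
    den = 2 * c.tp + c.fp + c.fn
    if den == 0:  # both masks empty: identical, so perfect overlap
        return 1.0
    return 2.0 * c.tp / den


def jaccard_index(c: ConfusionCounts) -> float:
    den = c.tp + c.fp + c.fn
    if den == 0:
        return 1.0
    return c.tp / den


def sensitivity(c: ConfusionCounts) -> float:
    den = c.tp + c.fn
    return c.tp / den if den else math.nan


def specificity(c: ConfusionCounts) -> float:
    den = c.tn + c.fp
    return c.tn / den if den else math.nan


def hausdorff_distance(a, b) -> float:
    """Symmetric Hausdorff distance (pixels) between nonzero-pixel sets."""
    pa = np.argwhere(_as_binary(a))
    pb = np.argwhere(_as_binary(b))
    if len(pa) == 0 or len(pb) == 0:
        raise EmptyMaskError(
            "Hausdorff distance is undefined for an empty mask "
            f"(|A|={len(pa)}, |B|={len(pb)})")
    return max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0])


@dataclass
class MetricReport:
    """Per-case metric table plus mean ± sample-std summary."""

    per_case: pd.DataFrame  # columns METRIC_COLUMNS, one row per case

    def mean(self) -> pd.Series:
        return self.per_case[list(METRIC_COLUMNS)].mean()

    def std(self) -> pd.Series:
        return self.per_case[list(METRIC_COLUMNS)].std(ddof=1)

    def summary(self, label: str = "") -> str:
        m, s = self.mean(), self.std()
        parts = []
        for col in METRIC_COLUMNS:
            scale = 100.0 if col != "hausdorff" else 1.0
            mv, sv = m[col] * scale, s[col] * scale
            mtxt = "undef" if math.isnan(mv) else f"{mv:.2f}"
            stxt = "n/a" if math.isnan(sv) else f"{sv:.2f}"
            parts.append(f"{col}: {mtxt} ± {stxt}")
        head = f"[{label}] " if label else ""
        return head + " | ".join(parts)

    def to_csv(self, path: str) -> None:
        self.per_case.to_csv(path, index=False)

    def to_json(self, path: str) -> None:
        import json
        payload = {
            "per_case": self.per_case.to_dict(orient="records"),
            "mean": {k: _none_if_nan(v) for k, v in self.mean().items()},
            "std": {k: _none_if_nan(v) for k, v in self.std().items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _none_if_nan(v: float):
    return None if (isinstance(v, float) and math.isnan(v)) else float(v)


def case_metrics(prediction, truth) -> dict:
    c = confusion_counts(prediction, truth)
    try:
        hd = hausdorff_distance(prediction, truth)
    except EmptyMaskError:
        hd = math.nan
    return {
        "dice": dice_coefficient(c),
        "jaccard": jaccard_index(c),
        "sensitivity": sensitivity(c),
        "specificity": specificity(c),
        "hausdorff": hd,
    }


def evaluate_pairs(predictions: list, truths: list) -> MetricReport:
    if len(predictions) == 0 or len(predictions) != len(truths):
        raise ValueError("need equal, nonzero numbers of predictions and truths")
    rows = [case_metrics(p, t) for p, t in zip(predictions, truths)]
    return MetricReport(pd.DataFrame(rows, columns=list(METRIC_COLUMNS)))


def evaluate_dataset(model, data: PairedDataset, threshold: float = 0.5
                     ) -> MetricReport:
    """Run a generator over a paired dataset and score its binarized masks.

    ``model`` is anything with ``predict_mask(image_batch, threshold)``
    returning an (n, 1, H, W) binary array — in practice a trained
    ``GeneratorModel``.
    """
    if len(data) == 0:
        raise ValueError("cannot evaluate an empty dataset")
    preds = model.predict_mask(data.images(), threshold=threshold)
    truths = [m.pixels for _, m in data.pairs]
    return evaluate_pairs([p[0] for p in preds.astype(np.uint8)], truths)
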