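"""Segmentation scoring: confusion counts, completeness/correctness/quality,
Pearson correlation, and grouped batch evaluation.

The positive class is the dense tissue (glandular, optionally mass) binarized
from a label map.  With pixel counts TP/FP/FN/TN against a ground-truth mask:

    completeness = TP / (TP + FN)      (how much truth was recovered)
    correctness  = TP / (TP + FP)      (how much of the prediction is right)
    quality      = TP / (TP + FP + FN) (a single combined overlap score)

All three reach their optimum, 1, exactly when prediction equals truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import labels as L


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class MetricsReport:
    completeness: float
    correctness: float
    quality: float


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixel-wise 2x2 contingency of binary prediction vs binary truth."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    return ConfusionCounts(
        TP=int(np.count_nonzero(pred & truth)),
        FP=int(np.count_nonzero(pred & ~truth)),
        FN=int(np.count_nonzero(~pred & truth)),
        TN=int(np.count_nonzero(~pred & ~truth)),
    )


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Completeness, correctness and quality from confusion counts.

    Degenerate conventions: if both TP+FN and TP+FP are zero (prediction and
    truth both empty) all three metrics are 1; if exactly one of the two
    denominators is zero, the affected metric is 0.
    """
    tp, fp, fn = counts.TP, counts.FP, counts.FN
    if min(tp, fp, fn, counts.TN) < 0:
        raise ValueError("confusion counts must be non-negative")
    den_cm, den_cr = tp + fn, tp + fp
    if den_cm == 0 and den_cr == 0:
        return MetricsReport(1.0, 1.0, 1.0)
    cm = tp / den_cm if den_cm else 0.0
    cr = tp / den_cr if den_cr else 0.0
    rho = tp / (tp + fp + fn)
    return MetricsReport(completeness=cm, correctness=cr, quality=rho)


def dense_mask(label_map: np.ndarray, include_mass: bool = True) -> np.ndarray:
    """Binarize the dense (glandular/mass) positive class from a label map."""
    label_map = np.asarray(label_map)
    out = label_map == L.GLANDULAR
    if include_mass:
        out |= label_map == L.MASS
    return out


def pearson_r(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient of two equal-length sequences."""
    xs = np.asarray(xs, dtype=np.float64)
    ys = np.asarray(ys, dtype=np.float64)
    if xs.ndim != 1 or ys.ndim != 1 or xs.size != ys.size:
        raise ValueError("inputs must be 1-D sequences of equal length")
    if xs.size < 2:
        raise ValueError("need at least two observations")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(xs, ys).statistic)


def batch_evaluate(
    cases: Iterable[tuple[str, np.ndarray, np.ndarray, str]],
    include_mass: bool = True,
) -> pd.DataFrame:
    """Per-image metrics plus per-group and overall mean rows.

    ``cases`` yields ``(image_id, predicted label map, truth dense mask,
    group tag)`` — groups are e.g. breast types fatty / fatty-glandular /
    dense-glandular.  Returns a table with columns image, group, TP, FP, FN,
    TN, completeness, correctness, quality; summary rows carry image =
    "mean" and the group name (or "overall").
    """
    rows = []
    for image_id, pred_labels, truth, group in cases:
        c = confusion(dense_mask(pred_labels, include_mass), truth)
        m = metrics(c)
        rows.append(
            dict(image=image_id, group=group, TP=c.TP, FP=c.FP, FN=c.FN, TN=c.TN,
                 completeness=m.completeness, correctness=m.correctness,
                 quality=m.quality)
        )
    if not rows:
        raise ValueError("no cases to evaluate")
    df = pd.DataFrame(rows)
    summaries = []
    metric_cols = ["completeness", "correctness", "quality"]
    for group, sub in df.groupby("group", sort=True):
        summaries.append(dict(image="mean", group=group,
                              TP=np.nan, FP=np.nan, FN=np.nan, TN=np.nan,
                              **{c: sub[c].mean() for c in metric_cols}))
    summaries.append(dict(image="mean", group="overall",
                          TP=np.nan, FP=np.nan, FN=np.nan, TN=np.nan,
                          **{c: df[c].mean() for c in metric_cols}))
    return pd.concat([df, pd.DataFrame(summaries)], ignore_index=True)
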