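"""Breast-density quantification and BIRADS categorization.

Density is the percentage of the breast area occupied by radiographically
dense (glandular, optionally mass) tissue:

    density = 100 * glandular_pixels / breast_pixels

The breast area counts every non-background label — the skin-air interface
and both fat layers are deliberately kept inside the denominator, while the
pectoral muscle was blanked to background upstream and is therefore
excluded.  The BIRADS category follows the four-bin fibroglandular-content
table (<=25 / <=50 / <=75 / >75 percent), and a linear model

    y = 1.327 + 0.040 * x

estimates a continuous BIRADS score from the density percentage x, which
compensates for the denominator being enlarged by the skin-air band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import labels as L

#: Coefficients of the linear BIRADS-estimation model.
BIRADS_MODEL_INTERCEPT = 1.327
BIRADS_MODEL_SLOPE = 0.040

#: Upper category edges of the fibroglandular-percentage table.
BIRADS_THRESHOLDS = (25.0, 50.0, 75.0)


@dataclass(frozen=True)
class DensityReport:
    glandular_pixels: int
    breast_pixels: int
    percentage: float
    birads_category: int
    birads_estimate: float

    def to_dict(self) -> dict:
        return {
            "glandular_pixels": self.glandular_pixels,
            "breast_pixels": self.breast_pixels,
            "percentage": self.percentage,
            "birads_category": self.birads_category,
            "birads_estimate": self.birads_estimate,
            "birads_estimate_rounded": round_birads(self.birads_estimate),
        }


def density_percentage(
    labels: np.ndarray, include_mass: bool = True
) -> DensityReport:
    """Density report for a segmentation label map (anatomical scheme, ids 0..5).

    ``include_mass`` counts mass pixels as dense tissue (a mass is a
    hyperdense structure embedded in the glandular region).
    """
    labels = np.asarray(labels)
    breast = labels != L.BACKGROUND
    breast_pixels = int(breast.sum())
    if breast_pixels == 0:
        raise ValueError("zero breast pixels: cannot compute density")
    dense = labels == L.GLANDULAR
    if include_mass:
        dense |= labels == L.MASS
    glandular_pixels = int(dense.sum())
    pct = 100.0 * glandular_pixels / breast_pixels
    return DensityReport(
        glandular_pixels=glandular_pixels,
        breast_pixels=breast_pixels,
        percentage=pct,
        birads_category=birads_category(pct),
        birads_estimate=estimate_birads(pct),
    )


def birads_category(percentage: float) -> int:
    """Four-bin BIRADS category from fibroglandular percentage.

    <=25 -> 1 (predominantly fat); (25, 50] -> 2; (50, 75] -> 3; >75 -> 4
    (extremely dense).  The printed table leaves the 25/26 etc. boundaries
    ambiguous; bins here are half-open upward.
    """
    p = float(percentage)
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"percentage must lie in [0, 100], got {p}")
    for cat, edge in enumerate(BIRADS_THRESHOLDS, start=1):
        if p <= edge:
            return cat
    return 4


def estimate_birads(percentage: float) -> float:
    """Linear BIRADS estimate y = 1.327 + 0.040 x (raw, unclipped)."""
    p = float(percentage)
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"percentage must lie in [0, 100], got {p}")
    return BIRADS_MODEL_INTERCEPT + BIRADS_MODEL_SLOPE * p


def round_birads(estimate: float) -> int:
    """Convenience rounding of the linear estimate to a category in [1, 4]."""
    return int(np.clip(np.rint(estimate), 1, 4))
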