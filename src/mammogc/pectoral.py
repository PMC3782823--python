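"""Pectoral-muscle handling: orientation, seeded region growing, removal.

MLO mammograms show the pectoral muscle as a bright triangle in the image
corner on the chest-wall side.  All images are normalized so the chest wall
(and hence the pectoral) sits at the upper-LEFT; a horizontal flip is applied
when the chest wall is on the right, and the flip is recorded so results can
be mapped back.  The muscle is then extracted by breadth-first region growing
from a corner seed and blanked to background so it is excluded both from the
graph-cut labels and from the breast-area denominator of the density stage.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class OrientedImage:
    image: np.ndarray
    flipped: bool  # true iff a horizontal flip was applied
    side: str  # chest-wall side of the ORIGINAL image: "left" or "right"


def detect_side(mask: np.ndarray, border: int = 2) -> str:
    """Chest-wall side of a breast mask: the vertical border with more foreground.

    Counts foreground pixels in the ``border`` outermost columns on each side;
    ties break to "left".
    """
    mask = np.asarray(mask)
    if mask.size == 0 or not mask.any():
        raise ValueError("empty mask")
    border = max(1, min(int(border), mask.shape[1]))
    left = int(np.count_nonzero(mask[:, :border]))
    right = int(np.count_nonzero(mask[:, -border:]))
    return "right" if right > left else "left"


def orient_mlo(image: np.ndarray, side: str) -> OrientedImage:
    """Normalize chest wall to the left border; flipping is exact column reversal."""
    image = np.asarray(image)
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    if side == "right":
        return OrientedImage(image=image[:, ::-1].copy(), flipped=True, side=side)
    return OrientedImage(image=image.copy(), flipped=False, side=side)


def default_pectoral_seed(
    mask: np.ndarray, inset: int = 3
) -> tuple[int, int]:
    """Seed for pectoral growing: foreground pixel nearest the upper-left corner,
    nudged ``inset`` pixels inward (diagonally) while it stays on foreground."""
    mask = np.asarray(mask)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty mask")
    d2 = rows.astype(np.int64) ** 2 + cols.astype(np.int64) ** 2
    order = np.lexsort((cols, rows, d2))
    r, c = int(rows[order[0]]), int(cols[order[0]])
    for _ in range(int(inset)):
        rn = min(r + 1, mask.shape[0] - 1)
        cn = min(c + 1, mask.shape[1] - 1)
        if mask[rn, cn]:
            r, c = rn, cn
        else:
            break
    return (r, c)


def grow_pectoral(
    image: np.ndarray, seed: tuple[int, int], tolerance: float = 16.0
) -> np.ndarray:
    """Breadth-first 4-connected region growing with a running-mean criterion.

    A pixel is admitted iff |intensity - current region mean| <= tolerance,
    with the mean updated incrementally as pixels are admitted in BFS order
    (neighbors visited up, down, left, right).  Returns a uint8 mask that is
    4-connected and contains the seed.
    """
    image = np.asarray(image)
    h, w = image.shape
    r0, c0 = int(seed[0]), int(seed[1])
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ValueError(f"seed {seed} out of bounds for image {image.shape}")
    if image[r0, c0] == 0:
        raise ValueError("seed lies on a removed (zero) background pixel")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    mask = np.zeros((h, w), dtype=np.uint8)
    mask[r0, c0] = 1
    total = float(image[r0, c0])
    count = 1
    queue = deque([(r0, c0)])
    img = image.astype(np.float64)
    while queue:
        r, c = queue.popleft()
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rn, cn = r + dr, c + dc
            if 0 <= rn < h and 0 <= cn < w and not mask[rn, cn]:
                if abs(img[rn, cn] - total / count) <= tolerance:
                    mask[rn, cn] = 1
                    total += img[rn, cn]
                    count += 1
                    queue.append((rn, cn))
    return mask


def remove_pectoral(image: np.ndarray, pect: np.ndarray) -> np.ndarray:
    """Blank the pectoral mask to 0 so it joins the excluded background."""
    image = np.asarray(image)
    pect = np.asarray(pect)
    if image.shape != pect.shape:
        raise ValueError(f"shape mismatch: image {image.shape} vs mask {pect.shape}")
    out = image.copy()
    out[pect != 0] = 0
    return out
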