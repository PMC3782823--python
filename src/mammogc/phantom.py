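"""Synthetic MLO-view mammogram phantoms with pixel-exact truth.

The phantom emulates the gross geometry of a mediolateral-oblique mammogram:
a half-elliptical breast attached to one vertical border (the chest wall),
wrapped in a thin skin-air band and an uncompressed-fat band, with a central
glandular blob inside the compressed fat, an optional hyperdense mass disk
inside the glandular region, a pectoral-muscle triangle at the top chest-wall
corner, and an optional bright rectangular label artifact in the background.
Each region is rendered at its mean intensity; additive Gaussian noise
(clipped to [0, 255], rounded to integers) models digitization noise.

Every phantom carries a truth label map, so each downstream stage —
binarization, pectoral growing, graph-cut segmentation, density — can be
scored against exact per-pixel ground truth without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import labels as L

#: Default region mean intensities (gray levels), strictly ordered in density.
DEFAULT_MEANS: dict[str, int] = {
    "background": 5,
    "skin_air": 30,
    "uncompressed_fat": 60,
    "compressed_fat": 110,
    "glandular": 180,
    "mass": 220,
    "pectoral": 200,
    "artifact": 230,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and noise parameters of one synthetic mammogram."""

    height: int = 96
    width: int = 80
    side: str = "left"  # vertical border the chest wall touches
    mean_intensity: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_MEANS))
    noise_sd: float = 0.0
    has_mass: bool = False
    mass_center: tuple[float, float] | None = None  # (row, col); default = glandular center
    mass_radius: float | None = None  # pixels; default = height/16
    has_artifact: bool = False
    rng_seed: int = 0

    def validate(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ValueError("phantom dimensions must be at least 32x32")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        m = self.mean_intensity
        order = ["background", "skin_air", "uncompressed_fat", "compressed_fat", "glandular"]
        missing = [k for k in order + ["pectoral"] if k not in m]
        if self.has_mass and "mass" not in m:
            missing.append("mass")
        if missing:
            raise ValueError(f"mean_intensity missing regions: {missing}")
        seq = [m[k] for k in order] + ([m["mass"]] if self.has_mass else [])
        if any(not 0 <= v <= 255 for v in m.values()):
            raise ValueError("mean intensities must lie in [0, 255]")
        if any(a >= b for a, b in zip(seq, seq[1:])):
            raise ValueError(
                "mean intensities must be strictly ordered "
                "background < skin_air < uncompressed_fat < compressed_fat "
                "< glandular (< mass)"
            )
        if m["pectoral"] < m["glandular"]:
            raise ValueError("pectoral mean intensity must be >= glandular mean")


@dataclass(frozen=True)
class Phantom:
    """A rendered phantom: 8-bit image, truth label map and the generating spec."""

    image: np.ndarray  # uint8, (H, W)
    truth: np.ndarray  # int labels, (H, W)
    spec: PhantomSpec

    @property
    def breast_mask(self) -> np.ndarray:
        """Breast region proper: everything but background, pectoral and artifact."""
        return np.isin(self.truth, (L.SKIN_AIR, L.UNCOMPRESSED_FAT,
                                    L.COMPRESSED_FAT, L.GLANDULAR, L.MASS))

    @property
    def foreground_mask(self) -> np.ndarray:
        """Breast plus pectoral — what breast-profile binarization should find."""
        return self.breast_mask | (self.truth == L.PECTORAL)

    def truth_density_percentage(self, include_mass: bool = True) -> float:
        dense = self.truth == L.GLANDULAR
        if include_mass:
            dense |= self.truth == L.MASS
        return 100.0 * dense.sum() / self.breast_mask.sum()


def _geometry(spec: PhantomSpec) -> dict[str, float]:
    h, w = spec.height, spec.width
    skin = float(min(5, max(2, round(0.016 * h))))
    fat = float(max(3, round(0.04 * h)))
    return {
        "cy": 0.5 * h,                 # breast ellipse center row (on chest wall)
        "a_r": 0.42 * h,               # breast vertical semi-axis
        "a_c": 0.67 * w,               # breast horizontal semi-axis
        "skin_px": skin,               # skin-air band thickness
        "fat_px": fat,                 # uncompressed-fat band thickness
        "g_cy": 0.5 * h,               # glandular blob center
        "g_cx": 0.26 * w,
        "g_ar": 0.175 * h,             # glandular semi-axes
        "g_ac": 0.20 * w,
        "pect_r": 0.35 * h,            # pectoral triangle leg lengths
        "pect_c": 0.29 * w,
        "mass_r": h / 16.0,            # default mass radius
    }


def _inside_half_ellipse(rr, cc, cy, a_r, a_c):
    # chest wall at column 0; pixel centers
    return ((rr - cy) / a_r) ** 2 + (cc / a_c) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Render ``spec`` into a noisy 8-bit image plus its exact truth label map.

    Regions are painted outside-in (background, skin-air band, fat bands,
    glandular, mass) with the pectoral triangle and the optional artifact
    rectangle drawn last; a pixel belongs to a region when its center lies
    inside the region's analytic shape, later-drawn regions winning ties.
    """
    spec.validate()
    g = _geometry(spec)
    h, w = spec.height, spec.width
    # rendered chest-wall-left; mirrored at the end for side="right", so the
    # two lateralities are exact column-reversals of each other (noise included)
    rr, cc = np.mgrid[0:h, 0:w].astype(float)

    truth = np.full((h, w), L.BACKGROUND, dtype=np.int64)
    cy, a_r, a_c = g["cy"], g["a_r"], g["a_c"]
    breast = _inside_half_ellipse(rr, cc, cy, a_r, a_c)
    truth[breast] = L.SKIN_AIR
    s, f = g["skin_px"], g["fat_px"]
    inner1 = _inside_half_ellipse(rr, cc, cy, a_r - s, a_c - s)
    truth[inner1] = L.UNCOMPRESSED_FAT
    inner2 = _inside_half_ellipse(rr, cc, cy, a_r - s - f, a_c - s - f)
    truth[inner2] = L.COMPRESSED_FAT

    gland = ((rr - g["g_cy"]) / g["g_ar"]) ** 2 + ((cc - g["g_cx"]) / g["g_ac"]) ** 2 <= 1.0
    if not (inner2 | gland).sum() == inner2.sum():  # gland must sit inside compressed fat
        raise ValueError("glandular blob exceeds the compressed-fat region for this geometry")
    truth[gland] = L.GLANDULAR

    if spec.has_mass:
        mc = spec.mass_center if spec.mass_center is not None else (g["g_cy"], g["g_cx"])
        mr = spec.mass_radius if spec.mass_radius is not None else g["mass_r"]
        if mr <= 0:
            raise ValueError("mass_radius must be positive")
        mass = (rr - mc[0]) ** 2 + (cc - mc[1]) ** 2 <= mr**2
        if not mass.any():
            raise ValueError("mass disk rasterizes to zero pixels")
        if (mass & ~gland).any():
            raise ValueError("mass disk must lie entirely inside the glandular region")
        truth[mass] = L.MASS

    pect = (rr / g["pect_r"] + cc / g["pect_c"]) <= 1.0
    truth[pect] = L.PECTORAL

    if spec.has_artifact:
        # bright rectangle in the far background corner, away from the breast
        r0, r1 = int(0.05 * h), int(0.15 * h)
        c0, c1 = int(0.82 * w), int(0.95 * w)
        art = (rr >= r0) & (rr < r1) & (cc >= c0) & (cc < c1)
        if (art & (truth != L.BACKGROUND)).any():
            raise ValueError("artifact rectangle overlaps non-background regions")
        truth[art] = L.ARTIFACT

    means = np.zeros(8)
    for name, lid in L.REGION_IDS.items():
        means[lid] = spec.mean_intensity.get(name, 0)
    image = means[truth]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    if spec.side == "right":
        image = image[:, ::-1].copy()
        truth = truth[:, ::-1].copy()
    return Phantom(image=image, truth=truth, spec=spec)


def mirrored(spec: PhantomSpec) -> PhantomSpec:
    """The same phantom on the opposite laterality."""
    return replace(spec, side="right" if spec.side == "left" else "left")


def sample_truth_seeds(
    phantom: Phantom,
    per_region: int = 3,
    rng: np.random.Generator | int | None = 0,
    include_labels: tuple[int, ...] | None = None,
) -> list[tuple[int, int, int]]:
    """Sample seed pixels uniformly from each truth region.

    Pectoral and artifact truth pixels are never sampled (they are handled
    by dedicated pipeline stages, not by the segmentation seeds).  Returns
    ``(row, col, label)`` entries in the phantom's native coordinates.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if include_labels is None:
        include_labels = tuple(
            int(l) for l in np.unique(phantom.truth) if l in L.SEGMENTATION_LABELS
        )
    entries: list[tuple[int, int, int]] = []
    for lab in include_labels:
        rows, cols = np.nonzero(phantom.truth == lab)
        if rows.size == 0:
            raise ValueError(f"truth has no pixels of label {L.REGION_NAMES[lab]}")
        k = min(per_region, rows.size)
        idx = rng.choice(rows.size, size=k, replace=False)
        entries += [(int(rows[i]), int(cols[i]), lab) for i in idx]
    return entries
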