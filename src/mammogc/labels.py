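"""Anatomical region labels shared across the pipeline.

The segmentation scheme uses up to six labels (ids 0..5).  The synthetic
phantom additionally distinguishes the pectoral muscle and any background
artifact (radio-opaque marker) in its truth map; those two are never
segmentation targets — the pectoral is removed before the graph cut and
artifacts are erased during preprocessing.
"""

from __future__ import annotations

# Segmentation labels, ordered from least to most radiographically dense.
BACKGROUND = 0
SKIN_AIR = 1
UNCOMPRESSED_FAT = 2
COMPRESSED_FAT = 3
GLANDULAR = 4
MASS = 5

# Phantom-truth-only labels.
PECTORAL = 6
ARTIFACT = 7

REGION_NAMES: dict[int, str] = {
    BACKGROUND: "background",
    SKIN_AIR: "skin_air",
    UNCOMPRESSED_FAT: "uncompressed_fat",
    COMPRESSED_FAT: "compressed_fat",
    GLANDULAR: "glandular",
    MASS: "mass",
    PECTORAL: "pectoral",
    ARTIFACT: "artifact",
}
REGION_IDS: dict[str, int] = {v: k for k, v in REGION_NAMES.items()}

#: Labels a graph-cut segmentation may use (3 to 6 of these).
SEGMENTATION_LABELS = (
    BACKGROUND,
    SKIN_AIR,
    UNCOMPRESSED_FAT,
    COMPRESSED_FAT,
    GLANDULAR,
    MASS,
)

# Fixed RGB palette for color label renderings (one row per label id 0..7).
PALETTE = (
    (0, 0, 0),        # background: black
    (70, 130, 180),   # skin_air: steel blue
    (255, 215, 0),    # uncompressed_fat: gold
    (255, 140, 0),    # compressed_fat: dark orange
    (220, 20, 60),    # glandular: crimson
    (255, 255, 255),  # mass: white
    (34, 139, 34),    # pectoral: forest green
    (148, 0, 211),    # artifact: violet
)


def label_name(label_id: int) -> str:
    try:
        return REGION_NAMES[int(label_id)]
    except KeyError:
        raise ValueError(f"unknown region label id {label_id!r}") from None


def label_id(name: str) -> int:
    try:
        return REGION_IDS[name]
    except KeyError:
        raise ValueError(f"unknown region name {name!r}") from None
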