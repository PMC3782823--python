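"""Reading and writing images, label maps and seed files.

Grayscale images travel as 8-bit PGM (binary P5 or ASCII P2) or PNG.  Label
maps are written as PGM rasters of small integer ids accompanied by a JSON
legend mapping each id to its region name, plus an optional color PNG using
the fixed palette.  Seed files are CSV with a ``row,col,label`` header (label
given by region name) or the JSON equivalent.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .labels import PALETTE, REGION_NAMES, label_id


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale image (PGM P2/P5 or PNG) as a 2-D uint8 array."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:  # collapse RGB(A) readbacks of grayscale PNGs
        arr = arr[..., :3].mean(axis=2)
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D grayscale image, got shape {arr.shape}")
    return arr


def write_image(path: str | Path, image: np.ndarray, ascii_pgm: bool = False) -> None:
    """Write a 2-D uint8 array as PGM (P5, or P2 if ``ascii_pgm``) or PNG by suffix."""
    path = Path(path)
    image = np.ascontiguousarray(image, dtype=np.uint8)
    if image.ndim != 2:
        raise ValueError("write_image expects a 2-D array")
    if path.suffix.lower() == ".pgm" and ascii_pgm:
        h, w = image.shape
        lines = [f"P2\n{w} {h}\n255"]
        lines += [" ".join(str(int(v)) for v in row) for row in image]
        path.write_text("\n".join(lines) + "\n")
    else:
        iio.imwrite(path, image)


def write_label_map(
    prefix: str | Path, labels: np.ndarray, legend: dict[int, str] | None = None
) -> dict[str, Path]:
    """Write ``<prefix>.pgm`` (ids), ``<prefix>.json`` (legend) and ``<prefix>.png`` (color).

    Returns the mapping of artifact kind to path.
    """
    prefix = Path(prefix)
    labels = np.asarray(labels)
    if legend is None:
        legend = {int(i): REGION_NAMES[int(i)] for i in np.unique(labels)}
    pgm = prefix.with_suffix(".pgm")
    write_image(pgm, labels.astype(np.uint8))
    legend_path = prefix.with_suffix(".json")
    legend_path.write_text(
        json.dumps({str(k): v for k, v in sorted(legend.items())}, indent=2) + "\n"
    )
    palette = np.asarray(PALETTE, dtype=np.uint8)
    color = palette[np.clip(labels, 0, len(palette) - 1)]
    png = prefix.with_suffix(".png")
    iio.imwrite(png, color)
    return {"labels": pgm, "legend": legend_path, "color": png}


def read_label_map(path: str | Path, legend_path: str | Path | None = None):
    """Read a label-map PGM and its JSON legend; returns (labels, legend)."""
    path = Path(path)
    labels = iio.imread(path)
    if labels.ndim != 2:
        raise ValueError(f"{path}: label map must be 2-D")
    labels = labels.astype(np.int64)
    if legend_path is None:
        legend_path = path.with_suffix(".json")
    legend_path = Path(legend_path)
    if legend_path.exists():
        legend = {int(k): v for k, v in json.loads(legend_path.read_text()).items()}
    else:
        legend = {int(i): REGION_NAMES.get(int(i), str(int(i))) for i in np.unique(labels)}
    return labels, legend


def read_seeds(path: str | Path) -> list[tuple[int, int, int]]:
    """Read seeds from CSV (``row,col,label`` header, label = region name) or JSON."""
    path = Path(path)
    entries: list[tuple[int, int, int]] = []
    if path.suffix.lower() == ".json":
        for rec in json.loads(path.read_text()):
            entries.append((int(rec["row"]), int(rec["col"]), label_id(str(rec["label"]))))
        return entries
    import csv

    with path.open(newline="") as fh:
        for rec in csv.DictReader(fh):
            entries.append((int(rec["row"]), int(rec["col"]), label_id(rec["label"].strip())))
    return entries


def write_seeds(path: str | Path, entries: list[tuple[int, int, int]]) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        recs = [
            {"row": int(r), "col": int(c), "label": REGION_NAMES[int(l)]}
            for r, c, l in entries
        ]
        path.write_text(json.dumps(recs, indent=2) + "\n")
        return
    lines = ["row,col,label"]
    lines += [f"{int(r)},{int(c)},{REGION_NAMES[int(l)]}" for r, c, l in entries]
    path.write_text("\n".join(lines) + "\n")
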