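"""End-to-end pipeline: preprocess -> pectoral removal -> graph cut -> density.

``run_pipeline`` drives the whole chain on one mammogram given user seeds in
ORIGINAL image coordinates, handling all coordinate bookkeeping (crop offset,
downsampling, orientation flip) so that seeds and results can be mapped
between the source image and the processed grid.  Pixels blanked by pectoral
removal are pre-assigned background seeds, which both pins their label and
keeps them out of the breast-area denominator.  Runs are deterministic:
identical inputs and config produce byte-identical artifacts, recorded in a
MANIFEST with content hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as mio
from . import labels as L
from .density import DensityReport, density_percentage
from .graphcut import EnergyBreakdown, GCParams, SeedSet, segment
from .pectoral import (
    default_pectoral_seed,
    detect_side,
    grow_pectoral,
    orient_mlo,
    remove_pectoral,
)
from .preprocess import (
    binarize_breast,
    crop_to_breast,
    downsample,
    median_enhance,
    remove_background_artifacts,
)

log = logging.getLogger("mammogc")


@dataclass(frozen=True)
class PipelineConfig:
    """Every stage parameter of the pipeline, serializable to a JSON file."""

    threshold: float | None = None  # None -> automatic (threshold_method)
    threshold_method: str = "triangle"  # "triangle" | "otsu"
    opening_radius: int = 2
    crop_margin: int = 2
    downsample_factor: int = 4
    median_kernel: int = 3
    side: str = "auto"  # "auto" | "left" | "right"
    pectoral_tolerance: float = 16.0
    gc: GCParams = field(default_factory=lambda: GCParams(model_sigma=4.0))
    include_mass: bool = True
    rng_seed: int = 0

    def validate(self) -> None:
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd and positive")
        if self.side not in ("auto", "left", "right"):
            raise ValueError("side must be auto, left or right")
        if self.threshold_method not in ("triangle", "otsu"):
            raise ValueError("threshold_method must be 'triangle' or 'otsu'")
        if self.pectoral_tolerance < 0:
            raise ValueError("pectoral_tolerance must be >= 0")
        if self.crop_margin < 0 or self.opening_radius < 0:
            raise ValueError("crop_margin and opening_radius must be >= 0")
        self.gc.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "gc" in d and isinstance(d["gc"], dict):
            d["gc"] = GCParams(**d["gc"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class PipelineResult:
    label_map: np.ndarray  # on the processed (cropped/downsampled/oriented) grid
    density: DensityReport
    energy: EnergyBreakdown
    pectoral_mask: np.ndarray
    processed_image: np.ndarray
    geometry: dict  # crop bbox/offset, factor, flipped, shapes
    artifacts: dict[str, Path]

    def to_processed(self, row: float, col: float) -> tuple[float, float]:
        """Map a point from original-image to processed-grid coordinates."""
        g = self.geometry
        r = (row - g["offset"][0]) / g["factor"]
        c = (col - g["offset"][1]) / g["factor"]
        if g["flipped"]:
            c = (g["processed_shape"][1] - 1) - c
        return r, c


def _map_seeds(
    entries, offset, factor, flipped, shape
) -> list[tuple[int, int, int]]:
    """User seeds (original coords) -> processed-grid coords; off-grid dropped."""
    out = []
    for r, c, lab in entries:
        rr = (int(r) - offset[0]) // factor
        cc = (int(c) - offset[1]) // factor
        if flipped:
            cc = (shape[1] - 1) - cc
        if 0 <= rr < shape[0] and 0 <= cc < shape[1]:
            out.append((rr, cc, int(lab)))
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    image: np.ndarray,
    seeds,
    config: PipelineConfig = PipelineConfig(),
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full chain on one 8-bit grayscale mammogram.

    ``seeds`` is a SeedSet or list of ``(row, col, label)`` in ORIGINAL image
    coordinates.  When ``outdir`` is given, every intermediate image, the
    final label maps (grayscale id raster + JSON legend + color PNG), the
    density report and a MANIFEST of content hashes are written there.  A
    stage failure aborts with the stage name; partial outputs are kept and
    the MANIFEST marks the run incomplete.
    """
    config.validate()
    image = np.asarray(image)
    if isinstance(seeds, SeedSet):
        entries = list(seeds.entries)
    else:
        entries = [(int(r), int(c), int(l)) for r, c, l in seeds]
    outdir = Path(outdir) if outdir is not None else None
    artifacts: dict[str, Path] = {}

    def emit(name: str, arr: np.ndarray) -> None:
        if outdir is not None:
            path = outdir / f"{name}.pgm"
            mio.write_image(path, arr.astype(np.uint8))
            artifacts[name] = path

    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        cfg_path = outdir / "config.json"
        cfg_path.write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n")
        artifacts["config"] = cfg_path

    stage = "start"
    try:
        t0 = time.perf_counter()
        stage = "binarize"
        mask = binarize_breast(image, threshold=config.threshold,
                               method=config.threshold_method,
                               opening_radius=config.opening_radius)
        emit("breast_mask", mask * 255)

        stage = "artifact_removal"
        cleaned = remove_background_artifacts(image, mask)
        emit("cleaned", cleaned)

        stage = "crop"
        crop = crop_to_breast(cleaned, mask, margin=config.crop_margin)
        mask_c = mask[crop.bbox[0]:crop.bbox[2], crop.bbox[1]:crop.bbox[3]]

        stage = "downsample"
        small = downsample(crop.image, config.downsample_factor)

        stage = "median"
        enhanced = median_enhance(small, config.median_kernel)
        emit("preprocessed", enhanced)

        stage = "orient"
        side = detect_side(mask_c) if config.side == "auto" else config.side
        oriented = orient_mlo(enhanced, side)
        work = oriented.image
        emit("oriented", work)

        stage = "pectoral"
        fg = work > 0
        seed_px = default_pectoral_seed(fg)
        pect = grow_pectoral(work, seed_px, tolerance=config.pectoral_tolerance)
        work = remove_pectoral(work, pect)
        emit("pectoral_mask", pect * 255)
        emit("no_pectoral", work)

        stage = "seeds"
        mapped = _map_seeds(entries, crop.offset, config.downsample_factor,
                            oriented.flipped, work.shape)
        seed_map = np.full(work.shape, -1, dtype=np.int64)
        # pectoral-removed pixels are hard background seeds
        seed_map[pect != 0] = L.BACKGROUND
        dropped = 0
        for r, c, lab in mapped:
            if seed_map[r, c] == -1:
                seed_map[r, c] = lab
            elif seed_map[r, c] != lab:
                dropped += 1  # collision after mapping: first assignment wins
        if dropped:
            log.warning("dropped %d conflicting seeds after coordinate mapping", dropped)
        rr, cc = np.nonzero(seed_map >= 0)
        seedset = SeedSet([(int(r), int(c), int(seed_map[r, c])) for r, c in zip(rr, cc)])

        stage = "segment"
        label_map, energy = segment(work, seedset, config.gc)
        if outdir is not None:
            paths = mio.write_label_map(outdir / "labels", label_map)
            artifacts.update({f"labels_{k}": v for k, v in paths.items()})

        stage = "density"
        report = density_percentage(label_map, include_mass=config.include_mass)

        geometry = {
            "offset": list(crop.offset),
            "bbox": list(crop.bbox),
            "factor": config.downsample_factor,
            "flipped": oriented.flipped,
            "side": side,
            "source_shape": list(image.shape),
            "processed_shape": list(work.shape),
        }
        if outdir is not None:
            rep_path = outdir / "report.json"
            rep_path.write_text(json.dumps(
                {"density": report.to_dict(),
                 "energy": dataclasses.asdict(energy),
                 "geometry": geometry}, indent=2, sort_keys=True) + "\n")
            artifacts["report"] = rep_path
            manifest = {
                "complete": True,
                "files": {k: _sha256(p) for k, p in sorted(artifacts.items())},
            }
            (outdir / "MANIFEST.json").write_text(
                json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        log.info("pipeline finished in %.2fs (side=%s, %d seeds)",
                 time.perf_counter() - t0, side, len(seedset.entries))
        return PipelineResult(
            label_map=label_map, density=report, energy=energy,
            pectoral_mask=pect, processed_image=work,
            geometry=geometry, artifacts=artifacts,
        )
    except Exception as exc:
        if outdir is not None:
            manifest = {
                "complete": False,
                "failed_stage": stage,
                "error": str(exc),
                "files": {k: _sha256(p) for k, p in sorted(artifacts.items())
                          if p.exists()},
            }
            (outdir / "MANIFEST.json").write_text(
                json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
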