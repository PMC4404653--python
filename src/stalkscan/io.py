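"""Scan loading, physical calibration, and trait-table output.

Flatbed scans arrive as 8-bit RGB TIFF or PNG rasters with a known
resolution (dots per inch).  All downstream measurements are made in
pixels and converted to centimeters through a single calibration factor
``px_per_cm = dpi / 2.54``; at the 800 dpi used for stalk scans this is
314.96 px/cm (commonly quoted rounded to 315).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

CM_PER_INCH = 2.54

#: Column order of the trait CSV.  Fixed so downstream consumers can rely on it.
TRAIT_COLUMNS = (
    "source_id",
    "transection_index",
    "area_cm2",
    "mean_diameter_cm",
    "perimeter_cm",
    "rind_thickness_cm",
    "pith_area_cm2",
    "bundle_count",
    "bundle_density_per_cm2",
    "mean_bundle_area_cm2",
    "n_manual_bundles",
)


class CalibrationError(ValueError):
    """No usable physical scale (dpi) for a scan."""


@dataclass
class ScanImage:
    """An 8-bit RGB scan plus its physical resolution.

    ``pixels`` is always (rows, cols, 3) uint8; grayscale sources are
    replicated across channels so channel-specific steps (the rind
    segmentation uses green) degrade gracefully.
    """

    pixels: np.ndarray
    dpi: float
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected (rows, cols, 3) raster, got {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("empty raster")
        if px.dtype != np.uint8:
            raise ValueError("ScanImage pixels must be uint8")
        if not self.dpi > 0:
            raise CalibrationError(f"dpi must be positive, got {self.dpi}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def green(self) -> np.ndarray:
        return self.pixels[:, :, 1]


@dataclass(frozen=True)
class Calibration:
    """Pixels-per-centimeter scale factor of a scan."""

    px_per_cm: float

    def __post_init__(self) -> None:
        if not self.px_per_cm > 0:
            raise ValueError("px_per_cm must be positive")

    def px_to_cm(self, px: float) -> float:
        return px / self.px_per_cm

    def px2_to_cm2(self, px2: float) -> float:
        return px2 / self.px_per_cm**2


@dataclass
class TraitRecord:
    """Per-transection morphometric traits, in physical units."""

    source_id: str
    transection_index: int
    area_cm2: float = np.nan
    mean_diameter_cm: float = np.nan
    perimeter_cm: float = np.nan
    rind_thickness_cm: float = np.nan
    pith_area_cm2: float = np.nan
    bundle_count: int = 0
    bundle_density_per_cm2: float = np.nan
    mean_bundle_area_cm2: float = np.nan
    n_manual_bundles: int = 0


def calibration_from_dpi(dpi: float) -> Calibration:
    """Convert a scan resolution in dots per inch to pixels per cm.

    Uses exactly 2.54 cm/inch and keeps the full-precision value
    (800 dpi -> 314.96..., never rounded internally).
    """
    if not np.isfinite(dpi) or dpi <= 0:
        raise ValueError(f"dpi must be a positive real, got {dpi}")
    return Calibration(px_per_cm=dpi / CM_PER_INCH)


def _normalize_raster(arr: np.ndarray) -> np.ndarray:
    """Coerce a decoded raster to (rows, cols, 3) uint8."""
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.dtype == np.uint16:
        # 16-bit scanners: 65535/255 = 257 maps full scale onto 8 bits
        arr = (arr // 257).astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = np.clip(np.round(arr), 0, 255).astype(np.uint8)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"cannot interpret raster of shape {arr.shape}")
    return np.ascontiguousarray(arr)


def _dpi_from_tiff(path: Path) -> float | None:
    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if xres is None:
                return None
            num, den = xres.value if isinstance(xres.value, tuple) else (xres.value, 1)
            if den == 0 or num == 0:
                return None
            res = num / den
            unit_val = getattr(unit, "value", 2)
            unit_val = int(getattr(unit_val, "value", unit_val))
            if unit_val == 3:  # centimeters
                res *= CM_PER_INCH
            return float(res)
    except Exception:
        return None


def _dpi_from_png(path: Path) -> float | None:
    try:
        from PIL import Image

        with Image.open(path) as im:
            info = im.info
            if "dpi" in info:
                d = info["dpi"][0]
                return float(d) if d else None
            if "pHYs" in info or im.info.get("aspect"):
                return None
    except Exception:
        return None
    return None


def load_scan(path: str | Path, dpi_override: float | None = None) -> ScanImage:
    """Read a TIFF or PNG scan as an 8-bit RGB :class:`ScanImage`.

    dpi comes from the file's resolution metadata when present, else from
    ``dpi_override``.  A scan with neither raises :class:`CalibrationError`
    because no physical measurement is possible without a scale.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    try:
        if suffix in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
            meta_dpi = _dpi_from_tiff(path)
        else:
            import imageio.v3 as iio

            arr = iio.imread(path)
            meta_dpi = _dpi_from_png(path)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise IOError(f"cannot decode image {path}: {exc}") from exc

    if arr.ndim == 4:  # multi-page TIFF: caller should use load_scan_pages
        arr = arr[0]
    dpi = meta_dpi if meta_dpi else dpi_override
    if dpi is None or dpi <= 0:
        raise CalibrationError(
            f"{path}: no dpi in file metadata and no dpi_override given"
        )
    return ScanImage(pixels=_normalize_raster(arr), dpi=float(dpi), source_id=path.name)


def load_scan_pages(path: str | Path, dpi_override: float | None = None) -> list[ScanImage]:
    """Load every page of a (possibly multi-page) TIFF as separate scans."""
    path = Path(path)
    if path.suffix.lower() not in {".tif", ".tiff"}:
        return [load_scan(path, dpi_override)]
    arr = tifffile.imread(path)
    meta_dpi = _dpi_from_tiff(path)
    dpi = meta_dpi if meta_dpi else dpi_override
    if dpi is None or dpi <= 0:
        raise CalibrationError(f"{path}: no dpi available")
    if arr.ndim in (2, 3) and (arr.ndim == 2 or arr.shape[2] in (3, 4)):
        pages = [arr]
    else:
        pages = list(arr)
    out = []
    for i, page in enumerate(pages):
        sid = path.name if len(pages) == 1 else f"{path.name}#page{i}"
        out.append(ScanImage(pixels=_normalize_raster(page), dpi=float(dpi), source_id=sid))
    return out


def save_scan(scan: ScanImage, path: str | Path) -> None:
    """Write a scan as TIFF with resolution metadata."""
    path = Path(path)
    tifffile.imwrite(
        path,
        scan.pixels,
        resolution=(scan.dpi, scan.dpi),
        resolutionunit="INCH",
    )


def records_to_frame(records: Sequence[TraitRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in TRAIT_COLUMNS}
        if (not np.isfinite(row["bundle_density_per_cm2"])) and row["bundle_count"] == 0:
            # degenerate pith (area 0): write density 0, not NaN
            if not (row["pith_area_cm2"] > 0):
                logger.warning(
                    "%s[%d]: zero pith area, writing bundle density 0",
                    r.source_id,
                    r.transection_index,
                )
                row["bundle_density_per_cm2"] = 0.0
        rows.append(row)
    return pd.DataFrame(rows, columns=list(TRAIT_COLUMNS))


def write_traits(records: Sequence[TraitRecord], path: str | Path) -> None:
    """Write the trait table as CSV, one row per transection.

    Column order follows :data:`TRAIT_COLUMNS`; floats carry 6 significant
    digits, which round-trips every measured quantity at well below
    measurement precision.
    """
    frame = records_to_frame(records)
    frame.to_csv(path, index=False, float_format="%.6g")


def read_traits(path: str | Path) -> pd.DataFrame:
    """Re-read a trait CSV written by :func:`write_traits`."""
    return pd.read_csv(path)


@dataclass
class Sidecar:
    """Per-scan provenance and user overrides.

    Replaces the interactive steps of the original workflow: crop-box
    adjustments and manually added bundle coordinates are edited in this
    JSON file and the scan re-run.  All coordinates are 0-based (row, col)
    in the cropped object frame; crop boxes are half-open pixel index
    ranges in the full scan frame.
    """

    crop_boxes: list[list[int]] = field(default_factory=list)
    manual_bundles: dict[str, list[list[int]]] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    @classmethod
    def load(cls, path: str | Path) -> "Sidecar":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            crop_boxes=data.get("crop_boxes", []),
            manual_bundles={
                str(k): v for k, v in data.get("manual_bundles", {}).items()
            },
            parameters=data.get("parameters", {}),
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "crop_boxes": self.crop_boxes,
                    "manual_bundles": self.manual_bundles,
                    "parameters": self.parameters,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
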