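"""Core raster/ROI data model, calibration and file I/O.

Conventions
-----------
* Coordinates are 0-based ``(row, col)``; rectangles are half-open on the
  far side, so a rect of height ``h`` covers rows ``row0 .. row0+h-1``.
* Intensities are never silently rescaled on load; :func:`normalize_unit`
  is the explicit, logged normalization step.  The sharpness metric is
  linear in intensity, so cross-image comparisons require a declared
  common scale.
* RGB inputs are reduced to luma with the Rec.709 weights
  (0.2126, 0.7152, 0.0722).
"""

from __future__ import annotations

import csv
import json
import logging
import math
import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml
from skimage.draw import polygon2mask

logger = logging.getLogger(__name__)

_LUMA_WEIGHTS = np.array([0.2126, 0.7152, 0.0722])


class FormatError(ValueError):
    """Raised for malformed rasters or annotation files."""


class BoundsError(ValueError):
    """Raised when an ROI does not lie fully inside its image."""


class DegenerateInputError(ValueError):
    """Raised for degenerate numerical input (e.g. all-zero raster)."""


@dataclass(frozen=True)
class CalibratedImage:
    """A 2-D intensity raster with physical pixel pitch.

    Parameters
    ----------
    pixels
        Non-negative float raster, shape ``(rows, cols)``.
    pitch_um
        Micrometres per pixel (> 0).  Device pixel pitch is not inferable
        from the raster, so it must always be supplied by the caller.
    bit_depth
        Source integer depth (8 or 16) or ``"float"``.
    origin_label
        Free-text provenance: file path or generator spec string.
    """

    pixels: np.ndarray
    pitch_um: float
    bit_depth: int | str = "float"
    origin_label: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise FormatError(f"raster must be 2-D and non-empty, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise FormatError("raster contains non-finite intensities")
        if px.min() < 0:
            raise FormatError("raster contains negative intensities")
        if not (self.pitch_um > 0):
            raise ValueError(f"pitch_um must be > 0, got {self.pitch_um}")
        if self.bit_depth not in (8, 16, "float"):
            raise ValueError(f"bit_depth must be 8, 16 or 'float', got {self.bit_depth!r}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def field_um(self) -> tuple[float, float]:
        """Physical extent (rows, cols) of the raster in micrometres."""
        return (self.shape[0] * self.pitch_um, self.shape[1] * self.pitch_um)


@dataclass(frozen=True)
class RoiRect:
    """Axis-aligned rectangle, 0-based, half-open on the far side."""

    name: str
    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("RoiRect height and width must be >= 1")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("RoiRect origin must be non-negative")

    def bounds_ok(self, shape: tuple[int, int]) -> bool:
        return (self.row0 + self.height <= shape[0]
                and self.col0 + self.width <= shape[1])

    def compose(self, inner: "RoiRect") -> "RoiRect":
        """Rectangle addressing ``inner`` of the crop of ``self``."""
        if inner.row0 + inner.height > self.height or inner.col0 + inner.width > self.width:
            raise BoundsError("inner rectangle exceeds outer rectangle")
        return RoiRect(inner.name, self.row0 + inner.row0, self.col0 + inner.col0,
                       inner.height, inner.width)


@dataclass(frozen=True)
class RoiMask:
    """Named binary mask congruent with its parent raster."""

    name: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2 or m.size == 0:
            raise FormatError("mask must be a non-empty 2-D raster")
        object.__setattr__(self, "mask", m)

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    def require_nonempty(self) -> "RoiMask":
        if self.area_px == 0:
            raise DegenerateInputError(f"mask {self.name!r} has no true pixels")
        return self


@dataclass(frozen=True)
class Landmarks:
    """Ordered sub-pixel ``(row, col)`` points for manual measurements.

    Used for annotation-based distances such as the apical diameter of a
    capillary loop or the perivascular-zone width; no detection algorithm
    is provided for these, only measurement of supplied points.
    """

    points: tuple[tuple[float, float], ...]
    label: str = ""

    def __post_init__(self) -> None:
        pts = tuple((float(r), float(c)) for r, c in self.points)
        if len(pts) < 2:
            raise ValueError("Landmarks require >= 2 points")
        object.__setattr__(self, "points", pts)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def load_image(path: str | os.PathLike, pitch_um: float) -> CalibratedImage:
    """Read a single-channel (or RGB) TIFF/PNG into a CalibratedImage.

    Relative intensity scale is preserved exactly: an 8-bit value of 128
    loads as 128.0.  RGB rasters are reduced by fixed luma weighting and
    the reduction is logged.
    """
    path = os.fspath(path)
    try:
        if path.lower().endswith((".tif", ".tiff")):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise IOError(f"cannot read image {path!r}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.size == 0:
        raise FormatError(f"zero-size raster in {path!r}")

    if arr.dtype == np.uint8:
        bit_depth: int | str = 8
    elif arr.dtype == np.uint16:
        bit_depth = 16
    else:
        bit_depth = "float"

    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] != 3:
            raise FormatError(f"unsupported channel count {arr.shape[2]} in {path!r}")
        logger.info("reducing RGB %s to luma with Rec.709 weights", path)
        arr = arr.astype(float) @ _LUMA_WEIGHTS
    elif arr.ndim != 2:
        raise FormatError(f"unsupported raster dimensionality {arr.ndim} in {path!r}")

    return CalibratedImage(arr.astype(float), pitch_um, bit_depth, origin_label=path)


def save_image(image: CalibratedImage, path: str | os.PathLike) -> None:
    """Write the raster as 8/16-bit TIFF (or PNG), matching ``bit_depth``.

    Integer-depth images round-trip bit-exactly; float rasters are stored
    as 32-bit float TIFF.
    """
    path = os.fspath(path)
    px = image.pixels
    if image.bit_depth == 8:
        out = np.clip(np.rint(px), 0, 255).astype(np.uint8)
    elif image.bit_depth == 16:
        out = np.clip(np.rint(px), 0, 65535).astype(np.uint16)
    else:
        out = px.astype(np.float32)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, out)
    else:
        if out.dtype == np.float32:
            raise FormatError("float rasters must be saved as TIFF")
        iio.imwrite(path, out)


def normalize_unit(image: CalibratedImage) -> CalibratedImage:
    """Map intensities to [0, 1] by the nominal full scale of ``bit_depth``.

    8-bit → /255, 16-bit → /65535; float rasters are divided by their own
    maximum.  Raises on all-zero rasters.
    """
    px = image.pixels
    mx = px.max()
    if mx <= 0:
        raise DegenerateInputError("cannot normalize an all-zero raster")
    if image.bit_depth == 8:
        scale = 255.0
    elif image.bit_depth == 16:
        scale = 65535.0
    else:
        scale = mx
    logger.info("normalizing %s by full-scale %g", image.origin_label or "<raster>", scale)
    return replace(image, pixels=px / scale, bit_depth="float")


def crop(image: CalibratedImage, roi: RoiRect) -> CalibratedImage:
    """Extract the rectangle ``roi``; out-of-bounds ROIs are rejected."""
    if not roi.bounds_ok(image.shape):
        raise BoundsError(
            f"roi {roi.name!r} ({roi.row0},{roi.col0},{roi.height},{roi.width}) "
            f"exceeds image shape {image.shape}")
    sub = image.pixels[roi.row0:roi.row0 + roi.height, roi.col0:roi.col0 + roi.width]
    label = f"{image.origin_label}[{roi.name}]" if image.origin_label else roi.name
    return replace(image, pixels=sub.copy(), origin_label=label)


def measure_distance(landmarks: Landmarks, pitch_um: float) -> float:
    """Euclidean distance between exactly two landmark points, in μm."""
    if len(landmarks.points) != 2:
        raise ValueError(f"measure_distance needs exactly 2 points, got {len(landmarks.points)}")
    (r0, c0), (r1, c1) = landmarks.points
    return math.hypot(r1 - r0, c1 - c0) * pitch_um


# ---------------------------------------------------------------------------
# ROI and config files
# ---------------------------------------------------------------------------

def load_rois(path: str | os.PathLike,
              image_shape: tuple[int, int] | None = None,
              ) -> list[RoiRect | RoiMask]:
    """Read an ROI file: JSON rect/polygon entries or a CSV rectangle list.

    JSON schema: ``[{"name":.., "type":"rect", "row0":.., "col0":..,
    "height":.., "width":..}, ...]`` with ``"type":"polygon"`` entries
    carrying ``"vertices": [[row, col], ...]`` instead; polygons are
    rasterized to masks (``image_shape`` required).
    """
    path = os.fspath(path)
    out: list[RoiRect | RoiMask] = []
    if path.lower().endswith(".json"):
        with open(path) as fh:
            entries = json.load(fh)
        for e in entries:
            kind = e.get("type", "rect")
            if kind == "rect":
                out.append(RoiRect(e["name"], int(e["row0"]), int(e["col0"]),
                                   int(e["height"]), int(e["width"])))
            elif kind == "polygon":
                if image_shape is None:
                    raise FormatError("polygon ROIs require image_shape for rasterization")
                verts = np.asarray(e["vertices"], dtype=float)
                mask = polygon2mask(image_shape, verts)
                out.append(RoiMask(e["name"], mask).require_nonempty())
            else:
                raise FormatError(f"unknown ROI type {kind!r} in {path}")
    else:
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                out.append(RoiRect(row["name"], int(row["row0"]), int(row["col0"]),
                                   int(row["height"]), int(row["width"])))
    if not out:
        raise FormatError(f"no ROIs found in {path}")
    return out


def save_rois(rois: Sequence[RoiRect], path: str | os.PathLike) -> None:
    path = os.fspath(path)
    if path.lower().endswith(".json"):
        entries = [dict(name=r.name, type="rect", row0=r.row0, col0=r.col0,
                        height=r.height, width=r.width) for r in rois]
        with open(path, "w") as fh:
            json.dump(entries, fh, indent=1)
    else:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["name", "row0", "col0", "height", "width"])
            for r in rois:
                w.writerow([r.name, r.row0, r.col0, r.height, r.width])


DEFAULT_CONFIG: dict = {
    "pitch_um": 1.0,
    "normalize": True,
    "sigma_low": 0.5,
    "sigma_high": 8.0,
    "smooth_sigma": 15.0,
    "threshold_frac": 0.20,
}


def load_config(path: str | os.PathLike | None) -> dict:
    """Merge a YAML config over the package defaults."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(os.fspath(path)) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg
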