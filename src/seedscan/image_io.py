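"""Scanner image I/O and physical-unit conversion.

Seed scans are 8-bit grayscale rasters acquired at a known resolution
(dots per inch); all downstream measurements are made in pixels and
converted to millimetres using that resolution. Resolution is read from
the file (TIFF resolution tags, PNG pHYs chunk) unless overridden by the
caller, who typically knows the scanner setting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

__all__ = [
    "RasterImage",
    "load_image",
    "save_image",
    "px_to_mm",
    "px_area_to_mm2",
    "MM_PER_INCH",
]

logger = logging.getLogger(__name__)

MM_PER_INCH = 25.4


@dataclass(frozen=True)
class RasterImage:
    """An 8-bit grayscale image with its acquisition resolution.

    Parameters
    ----------
    pixels
        2-D ``uint8`` array of intensities in [0, 255], row-major.
    dpi
        Acquisition resolution in dots per inch; must be positive.
        Square pixels are assumed.
    image_id
        Identifier for provenance, usually the source file stem.
    """

    pixels: np.ndarray
    dpi: float
    image_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        if not self.dpi > 0:
            raise ValueError(f"dpi must be positive, got {self.dpi}")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "dpi", float(self.dpi))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def load_image(path: str | Path, dpi_override: float | None = None) -> RasterImage:
    """Load a TIFF/PNG scan as a grayscale :class:`RasterImage`.

    Color inputs are converted to grayscale by standard luminance
    weighting (ITU-R 601) with a logged warning; 16-bit inputs are
    rescaled to 8-bit with a warning. The resolution is taken from
    ``dpi_override`` if given, else from file metadata; if neither is
    available a :class:`ValueError` is raised.
    """
    path = Path(path)
    if dpi_override is not None and not dpi_override > 0:
        raise ValueError(f"dpi_override must be positive, got {dpi_override}")
    try:
        with Image.open(path) as im:
            im.load()
            file_dpi = _metadata_dpi(im)
            arr = _to_uint8_gray(im, path)
    except FileNotFoundError as exc:
        raise IOError(f"image file not found: {path}") from exc
    except UnidentifiedImageError as exc:
        raise IOError(f"cannot decode image file: {path}") from exc

    if dpi_override is not None:
        dpi = float(dpi_override)
    elif file_dpi is not None:
        dpi = file_dpi
    else:
        raise ValueError(
            f"no resolution metadata in {path} and no dpi_override given; "
            "pass the scanner dpi explicitly"
        )
    return RasterImage(pixels=arr, dpi=dpi, image_id=path.stem)


def _metadata_dpi(im: Image.Image) -> float | None:
    dpi = im.info.get("dpi")
    if dpi is None:
        return None
    x, y = float(dpi[0]), float(dpi[1])
    if x <= 0:
        return None
    if abs(x - y) > 1e-6 * max(x, y):
        logger.warning("non-square resolution (%g x %g dpi); using x", x, y)
    # PNG stores resolution in dots per meter; undo the quantization for
    # the integral dpi values scanners actually use
    if abs(x - round(x)) < 0.05:
        x = float(round(x))
    return x


def _to_uint8_gray(im: Image.Image, path: Path) -> np.ndarray:
    if im.mode in ("RGB", "RGBA", "P"):
        logger.warning("color image %s converted to grayscale by luminance", path)
        im = im.convert("L")
    elif im.mode in ("I", "I;16", "I;16B", "I;16L"):
        logger.warning("16-bit image %s rescaled to 8-bit", path)
        arr = np.asarray(im, dtype=np.float64)
        arr = arr / 257.0 if arr.max() > 255 else arr
        return np.clip(np.round(arr), 0, 255).astype(np.uint8)
    elif im.mode != "L":
        im = im.convert("L")
    return np.asarray(im, dtype=np.uint8)


def save_image(image: RasterImage, path: str | Path) -> None:
    """Write a :class:`RasterImage` to PNG or TIFF with dpi metadata."""
    path = Path(path)
    pil = Image.fromarray(image.pixels, mode="L")
    pil.save(path, dpi=(image.dpi, image.dpi))


def px_to_mm(length_px: float, dpi: float) -> float:
    """Convert a pixel length to millimetres at the given resolution."""
    if not dpi > 0:
        raise ValueError(f"dpi must be positive, got {dpi}")
    return float(length_px) * MM_PER_INCH / float(dpi)


def px_area_to_mm2(area_px: float, dpi: float) -> float:
    """Convert a pixel area to square millimetres at the given resolution."""
    if not dpi > 0:
        raise ValueError(f"dpi must be positive, got {dpi}")
    return float(area_px) * (MM_PER_INCH / float(dpi)) ** 2
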