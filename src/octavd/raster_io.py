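"""Reading, writing and masking of 8-bit en-face angiogram rasters.

The analysis works on single-channel 8-bit images (intensities 0-255).
Regions that are not conjunctiva (cornea, eyelids, lashes) are excluded
up front: excluded pixels are zeroed *and* flagged invalid, so that
filters may run over the full raster while every statistic downstream
(vessel density, confusion counts) is taken over valid pixels only.

Masks are exchanged as 8-bit PNG holding exactly {0, 255}; any other
pixel value is rejected rather than silently thresholded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "GrayImage",
    "BinaryMask",
    "read_gray_image",
    "write_gray_image",
    "read_mask",
    "write_mask",
    "apply_exclusion_roi",
]


@dataclass
class GrayImage:
    """A 2-D 8-bit grayscale image with a validity mask.

    Attributes
    ----------
    pixels : (H, W) uint8 array of intensities in [0, 255].
    valid : (H, W) bool array; True marks pixels inside the analysis
        region (conjunctiva).  Statistics are computed over valid
        pixels only.
    """

    pixels: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {px.shape}")
        if px.dtype != np.uint8:
            arr = np.asarray(px)
            if np.issubdtype(arr.dtype, np.floating):
                if np.any(arr < 0) or np.any(arr > 255):
                    raise ValueError("intensities outside [0, 255]")
                px = np.floor(arr + 0.5).astype(np.uint8)
            else:
                if np.any(arr < 0) or np.any(arr > 255):
                    raise ValueError("intensities outside [0, 255]")
                px = arr.astype(np.uint8)
        self.pixels = px
        if self.valid is None:
            self.valid = np.ones(px.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != px.shape:
                raise ValueError("pixels and valid mask shapes differ")
        if not self.valid.any():
            raise ValueError("image has no valid pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def valid_values(self) -> np.ndarray:
        """Intensities of the valid pixels, flattened."""
        return self.pixels[self.valid]

    def with_pixels(self, pixels: np.ndarray) -> "GrayImage":
        """New image with the same validity mask and replaced pixels."""
        return GrayImage(pixels, self.valid.copy())


@dataclass
class BinaryMask:
    """A 2-D boolean mask; True = pixel classified as vascular flow."""

    flow: np.ndarray

    def __post_init__(self) -> None:
        self.flow = np.asarray(self.flow, dtype=bool)
        if self.flow.ndim != 2:
            raise ValueError(f"expected a 2-D mask, got shape {self.flow.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.flow.shape


def _to_grayscale(arr: np.ndarray, path: Path) -> np.ndarray:
    if arr.ndim == 3:
        if arr.shape[2] in (3, 4):
            # ITU-R BT.601 luminance on RGB(A); alpha ignored
            rgb = arr[..., :3].astype(np.float64)
            arr = np.floor(
                0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2] + 0.5
            )
        elif arr.shape[2] == 1:
            arr = arr[..., 0]
        else:
            raise ValueError(f"{path}: unsupported channel count {arr.shape[2]}")
    if arr.ndim != 2:
        raise ValueError(f"{path}: not a 2-D raster (shape {arr.shape})")
    return arr


def read_gray_image(path: str | Path) -> GrayImage:
    """Read a single-channel 8-bit TIFF/PNG as a fully valid GrayImage.

    RGB inputs are converted by the BT.601 luminance rule; images whose
    samples do not fit 8 bits are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"could not read {path}: {exc}") from exc
    arr = _to_grayscale(np.asarray(arr), path)
    if arr.dtype != np.uint8:
        if np.any(arr < 0) or np.any(arr > 255):
            raise ValueError(f"{path}: intensities outside 8-bit range")
        arr = arr.astype(np.uint8)
    return GrayImage(arr)


def write_gray_image(path: str | Path, img: GrayImage) -> None:
    """Write the pixel raster as 8-bit TIFF or PNG (by extension)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, img.pixels)
    else:
        iio.imwrite(path, img.pixels)


def read_mask(path: str | Path) -> BinaryMask:
    """Read a 0/255 8-bit PNG as a BinaryMask.

    Any pixel value other than 0 or 255 raises ValueError.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    arr = np.asarray(iio.imread(path))
    arr = _to_grayscale(arr, path)
    values = np.unique(arr)
    if not np.isin(values, (0, 255)).all():
        bad = [int(v) for v in values if v not in (0, 255)]
        raise ValueError(f"{path}: mask holds non-binary values {bad}")
    return BinaryMask(arr == 255)


def write_mask(path: str | Path, mask: BinaryMask) -> None:
    """Write a BinaryMask as 8-bit PNG with foreground = 255."""
    iio.imwrite(Path(path), np.where(mask.flow, 255, 0).astype(np.uint8))


def apply_exclusion_roi(img: GrayImage, roi: BinaryMask) -> GrayImage:
    """Remove a region (cornea / eyelids) from the analysis.

    ``roi.flow`` True marks pixels to EXCLUDE.  Excluded pixels are set
    to intensity 0 and flagged invalid; everything else is untouched.
    Raises ValueError on shape mismatch or if nothing would remain.
    """
    if roi.shape != img.shape:
        raise ValueError(f"ROI shape {roi.shape} != image shape {img.shape}")
    keep = img.valid & ~roi.flow
    if not keep.any():
        raise ValueError("exclusion ROI removes every valid pixel")
    pixels = img.pixels.copy()
    pixels[roi.flow] = 0
    return GrayImage(pixels, keep)
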