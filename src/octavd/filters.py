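"""Pre-threshold image processing stages.

Every operator maps a GrayImage to a GrayImage of identical shape and
leaves the validity mask untouched.  Filters are computed in floating
point and quantized back to 8 bits (round half up) only at the module
boundary; grayscale morphology uses a discrete Euclidean disk with
reflect padding at the borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import frangi as _skimage_frangi
from skimage.morphology import disk as _disk

from .raster_io import GrayImage

__all__ = [
    "FilterParams",
    "gaussian_blur",
    "close_morphology",
    "tophat_filter",
    "bandpass_filter",
    "bandpass_response",
    "frangi_vesselness",
    "cornea_global_suppress",
]


@dataclass
class FilterParams:
    """Default parameters of the filtering stages.

    gaussian_sigma : smoothing radius in pixels.
    close_radius : disk radius of the grayscale closing (1 or 2 px for
        the registry methods).
    bandpass_small, bandpass_large : structure sizes in pixels; the
        bandpass suppresses structures at or below the small size and
        at or above the large size.
    tophat_radius : disk radius of the white top-hat opening.
    frangi_scales : Hessian scales (px) of the vesselness filter.
    frangi_beta : blob/ridge discrimination sensitivity.
    frangi_c : structureness normalization; None = half the maximum
        Hessian norm at each scale.
    """

    gaussian_sigma: float = 4.0
    close_radius: int = 1
    bandpass_small: float = 2.0
    bandpass_large: float = 50.0
    tophat_radius: int = 15
    frangi_scales: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    frangi_beta: float = 0.5
    frangi_c: float | None = None

    def __post_init__(self) -> None:
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be > 0")
        if self.close_radius <= 0 or self.tophat_radius <= 0:
            raise ValueError("morphology radii must be > 0")
        if not 0 < self.bandpass_small < self.bandpass_large:
            raise ValueError("need 0 < bandpass_small < bandpass_large")
        if len(self.frangi_scales) == 0 or min(self.frangi_scales) <= 0:
            raise ValueError("frangi_scales must be positive and nonempty")


def _quantize(arr: np.ndarray) -> np.ndarray:
    """Clip to [0, 255] and round half up to uint8."""
    return np.floor(np.clip(arr, 0.0, 255.0) + 0.5).astype(np.uint8)


def gaussian_blur(img: GrayImage, sigma: float = 4.0) -> GrayImage:
    """Gaussian smoothing with the given sigma radius (pixels)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    out = ndimage.gaussian_filter(img.pixels.astype(np.float64), sigma, mode="reflect")
    return img.with_pixels(_quantize(out))


def close_morphology(img: GrayImage, radius: int = 1) -> GrayImage:
    """Grayscale closing (dilation then erosion) with a disk element.

    Fills dark gaps between noncontiguous bright pixels within the
    given radius; extensive and idempotent.
    """
    if radius <= 0:
        raise ValueError("radius must be >= 1")
    out = ndimage.grey_closing(img.pixels, footprint=_disk(radius), mode="reflect")
    return img.with_pixels(out)


def tophat_filter(img: GrayImage, radius: int = 15) -> GrayImage:
    """White top-hat: image minus its opening with a disk element.

    Keeps bright structures smaller than the structuring element and
    removes slowly varying background; output is in [0, input].
    """
    if radius <= 0:
        raise ValueError("radius must be >= 1")
    opened = ndimage.grey_opening(img.pixels, footprint=_disk(radius), mode="reflect")
    return img.with_pixels(img.pixels - opened)


def bandpass_response(pixels: np.ndarray, small: float, large: float) -> np.ndarray:
    """Raw (unscaled) frequency-domain bandpass response.

    The transfer function is a difference of two Gaussians in the
    Fourier domain, parameterized by structure size: a structure of
    diameter d is associated with a spatial Gaussian of sigma = d / 3,
    so the band keeps structures between `small` and `large` pixels and
    removes the DC component.  The image is mirror-extended before the
    transform to avoid wrap-around artifacts.
    """
    if not 0 < small < large:
        raise ValueError("need 0 < small < large")
    arr = np.asarray(pixels, dtype=np.float64)
    h, w = arr.shape
    padded = np.pad(arr, ((0, h), (0, w)), mode="symmetric")
    spectrum = np.fft.rfft2(padded)
    fy = np.fft.fftfreq(2 * h)[:, None]
    fx = np.fft.rfftfreq(2 * w)[None, :]
    f2 = fy * fy + fx * fx
    sigma_small = small / 3.0
    sigma_large = large / 3.0
    transfer = np.exp(-2 * np.pi**2 * sigma_small**2 * f2) - np.exp(
        -2 * np.pi**2 * sigma_large**2 * f2
    )
    out = np.fft.irfft2(spectrum * transfer, s=padded.shape)
    return out[:h, :w]


def bandpass_filter(img: GrayImage, small: float = 2.0, large: float = 50.0) -> GrayImage:
    """Bandpass removing structures <= `small` px and >= `large` px.

    The float response (see :func:`bandpass_response`) is min-max
    rescaled to [0, 255]; a zero-variance response maps to all zeros.
    """
    out = bandpass_response(img.pixels, small, large)
    lo, hi = out.min(), out.max()
    if hi - lo < 1e-12:
        return img.with_pixels(np.zeros(img.shape, dtype=np.uint8))
    return img.with_pixels(_quantize((out - lo) * (255.0 / (hi - lo))))


def frangi_vesselness(
    img: GrayImage,
    scales: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0),
    beta: float = 0.5,
    c: float | None = None,
) -> GrayImage:
    """Multiscale Hessian vesselness for bright ridges on dark ground.

    Takes the per-pixel maximum response over the given scales and
    rescales it so the strongest response maps to 255.  `c` is the
    structureness normalization; None uses half the maximum Hessian
    norm per scale.
    """
    if len(scales) == 0:
        raise ValueError("scales must be nonempty")
    if beta <= 0 or (c is not None and c <= 0):
        raise ValueError("beta and c must be > 0")
    resp = _skimage_frangi(
        img.pixels.astype(np.float64),
        sigmas=list(scales),
        beta=beta,
        gamma=c,
        black_ridges=False,
        mode="reflect",
    )
    peak = resp.max()
    if peak <= 0:
        return img.with_pixels(np.zeros(img.shape, dtype=np.uint8))
    return img.with_pixels(_quantize(resp * (255.0 / peak)))


def cornea_global_suppress(
    img: GrayImage, roi_means: tuple[float, float, float]
) -> GrayImage:
    """Zero out pixels dimmer than the mean of three avascular measures.

    `roi_means` are three mean gray values sampled from an avascular
    region (the cornea); pixels strictly below their average are set to
    0, all others pass through unchanged.
    """
    means = tuple(roi_means)
    if len(means) != 3:
        raise ValueError("exactly three ROI mean intensities required")
    if any(m < 0 for m in means):
        raise ValueError("ROI means must be nonnegative")
    cutoff = float(np.mean(means))
    pixels = img.pixels.copy()
    pixels[pixels < cutoff] = 0
    return img.with_pixels(pixels)
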