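"""Binarization operators: fixed, global and local (adaptive) thresholds.

All operators share two conventions:

* comparison is strict — a pixel is flow only if its intensity exceeds
  the threshold, so constant regions binarize to background;
* pixels flagged invalid (outside the conjunctival analysis region)
  are never foreground.

Local statistics are taken over a discrete disk neighborhood.  Mean,
standard deviation (Phansalkar) and their thresholds are computed by
FFT convolution with reflect padding; the rank-based local median and
local Otsu operators crop the neighborhood at the image border.  A
small epsilon guards the strict comparison against floating-point noise
from the FFT path; it is far below the granularity of any statistic of
8-bit data, so results equal exact arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.signal import fftconvolve
from skimage.filters import rank as _rank
from skimage.morphology import disk as _disk

from .raster_io import BinaryMask, GrayImage

__all__ = [
    "PhansalkarParams",
    "LocalWindow",
    "OtsuResult",
    "threshold_fixed",
    "threshold_global_mean",
    "threshold_global_otsu",
    "otsu_threshold",
    "threshold_local",
    "threshold_phansalkar",
]

_EPS = 1e-6


@dataclass
class PhansalkarParams:
    """Constants of the Phansalkar local threshold.

    t = mu * (1 + p*exp(-q*mu) + k*((sigma/r) - 1)) on intensities
    normalized to [0, 1]; mu and sigma are the local mean and SD over a
    disk of `radius` pixels.  The defaults are the constants of the
    original low-contrast formulation.
    """

    radius: int = 15
    k: float = 0.25
    r: float = 0.5
    p: float = 2.0
    q: float = 10.0

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.r <= 0:
            raise ValueError("r must be > 0")


@dataclass
class LocalWindow:
    """A local-threshold configuration: disk radius, statistic, offset."""

    radius: int = 15
    statistic: str = "mean"
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.statistic not in {"mean", "median", "otsu", "phansalkar"}:
            raise ValueError(f"unknown statistic {self.statistic!r}")


class OtsuResult(NamedTuple):
    threshold: int
    degenerate: bool


def _masked(img: GrayImage, fg: np.ndarray) -> BinaryMask:
    return BinaryMask(fg & img.valid)


def threshold_fixed(img: GrayImage, t: float) -> BinaryMask:
    """Foreground = valid pixels with intensity strictly above ``t``."""
    if not 0 <= t <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    return _masked(img, img.pixels > t)


def threshold_global_mean(img: GrayImage) -> BinaryMask:
    """Global threshold at the mean intensity of the valid pixels."""
    t = float(img.valid_values().mean())
    return _masked(img, img.pixels > t)


def otsu_threshold(hist: np.ndarray) -> OtsuResult:
    """Exhaustive Otsu cutoff for a 256-bin intensity histogram.

    Scans every cutoff t, splitting levels into {<= t} and {> t}, and
    returns the smallest t maximizing the between-class variance.  A
    histogram with all mass in one bin is degenerate: that bin's level
    is returned with the flag set.
    """
    hist = np.asarray(hist, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError("expected a 256-bin histogram")
    total = hist.sum()
    if total <= 0:
        raise ValueError("histogram is empty")
    occupied = np.nonzero(hist)[0]
    if occupied.size == 1:
        return OtsuResult(int(occupied[0]), True)
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)
    m0 = np.cumsum(levels * hist)
    w1 = total - w0
    m_total = m0[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (m_total * w0 - total * m0) ** 2 / (w0 * w1)
    between[(w0 == 0) | (w1 == 0)] = -np.inf
    return OtsuResult(int(np.argmax(between)), False)


def threshold_global_otsu(img: GrayImage) -> BinaryMask:
    """Global Otsu threshold over the valid-pixel histogram."""
    hist = np.bincount(img.valid_values(), minlength=256)
    t, _ = otsu_threshold(hist)
    return _masked(img, img.pixels > t)


def _disk_local_moments(pixels: np.ndarray, radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Local mean and mean-of-squares over a disk, reflect padding."""
    kernel = _disk(radius).astype(np.float64)
    kernel /= kernel.sum()
    arr = np.asarray(pixels, dtype=np.float64)
    padded = np.pad(arr, radius, mode="symmetric")
    mean = fftconvolve(padded, kernel, mode="valid")
    sqmean = fftconvolve(padded * padded, kernel, mode="valid")
    return mean, sqmean


def threshold_local(img: GrayImage, window: LocalWindow) -> BinaryMask:
    """Adaptive threshold from disk-neighborhood statistics.

    mean / median: t = local statistic - offset; otsu: t = Otsu cutoff
    of the local histogram.  Foreground iff intensity > t (strict), so
    flat neighborhoods binarize to background.
    """
    if window.statistic == "phansalkar":
        return threshold_phansalkar(img, PhansalkarParams(radius=window.radius))
    if window.statistic == "mean":
        mean, _ = _disk_local_moments(img.pixels, window.radius)
        fg = img.pixels > mean - window.offset + _EPS
    elif window.statistic == "median":
        med = _rank.median(img.pixels, _disk(window.radius))
        fg = img.pixels > med.astype(np.float64) - window.offset
    else:  # otsu
        fp = _disk(window.radius)
        t = _rank.otsu(img.pixels, fp)
        # single-level neighborhoods have no two-class split: background
        spread = _rank.maximum(img.pixels, fp) > _rank.minimum(img.pixels, fp)
        fg = (img.pixels > t) & spread
    return _masked(img, fg)


def threshold_phansalkar(img: GrayImage, params: PhansalkarParams | None = None) -> BinaryMask:
    """Phansalkar low-contrast local threshold.

    Intensities are normalized to [0, 1]; the per-pixel threshold is
    mu * (1 + p*exp(-q*mu) + k*((sigma/r) - 1)) with mu, sigma the disk
    neighborhood mean and SD.
    """
    params = params or PhansalkarParams()
    norm = img.pixels.astype(np.float64) / 255.0
    mean, sqmean = _disk_local_moments(norm, params.radius)
    var = np.maximum(sqmean - mean * mean, 0.0)
    sigma = np.sqrt(var)
    t = mean * (1.0 + params.p * np.exp(-params.q * mean) + params.k * (sigma / params.r - 1.0))
    return _masked(img, norm > t + _EPS)
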