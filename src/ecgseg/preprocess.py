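"""Page preprocessing: cropping, Gaussian smoothing and Otsu binarization.

A page image is a 2-D array of intensities, (row, col) indexed with row 0 at
the top, either 8-bit integers in [0, 255] or reals in [0, 1].  Ink (the ECG
trace) is dark on a light paper background, so the binary foreground is the
set of pixels *below* the Otsu threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import BoxOutOfBounds, DegenerateImage, InvalidSigma

__all__ = [
    "CropBox",
    "PreprocessParams",
    "DEFAULT_CROP",
    "as_grayscale",
    "crop_roi",
    "gaussian_blur",
    "otsu_threshold",
    "otsu_binarize",
    "binarize_page",
]

# Rec. 601 luminance weights used for color -> grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class CropBox:
    """Half-open pixel box [row_start, row_end) x [col_start, col_end)."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.row_start < self.row_end):
            raise BoxOutOfBounds(f"bad row range [{self.row_start}, {self.row_end})")
        if not (0 <= self.col_start < self.col_end):
            raise BoxOutOfBounds(f"bad col range [{self.col_start}, {self.col_end})")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_end - self.row_start, self.col_end - self.col_start)


#: Default plotting-region box for the 2213x1572-class scans this layout
#: ships on; disable cropping for images that are already trimmed.
DEFAULT_CROP = CropBox(280, 1520, 150, 2150)


@dataclass(frozen=True)
class PreprocessParams:
    """Cropping and smoothing settings applied before binarization."""

    crop: CropBox = DEFAULT_CROP
    sigma: float = 0.7
    apply_crop: bool = True

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise InvalidSigma(f"sigma must be > 0, got {self.sigma}")


def as_grayscale(image: np.ndarray) -> np.ndarray:
    """Reduce an (H, W[, 3|4]) array to a single-channel (H, W) image."""
    image = np.asarray(image)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] in (3, 4):
        return image[..., :3].astype(np.float64) @ _LUMA
    raise ValueError(f"cannot interpret shape {image.shape} as an image")


def crop_roi(image: np.ndarray, box: CropBox) -> np.ndarray:
    """Return a copy of the sub-image selected by ``box``."""
    image = np.asarray(image)
    h, w = image.shape[:2]
    if box.row_end > h or box.col_end > w:
        raise BoxOutOfBounds(f"box {box} exceeds image extent {h}x{w}")
    return image[box.row_start : box.row_end, box.col_start : box.col_end].copy()


def gaussian_blur(image: np.ndarray, sigma: float) -> np.ndarray:
    """Smooth with a normalized 2-D Gaussian, truncated at radius ceil(3σ).

    Borders are reflect-padded (half-sample symmetric), which preserves the
    global mean intensity of the page.  Output is float64, same shape.
    """
    if sigma <= 0:
        raise InvalidSigma(f"sigma must be > 0, got {sigma}")
    radius = math.ceil(3 * sigma)
    return ndimage.gaussian_filter(
        np.asarray(image, dtype=np.float64), sigma=sigma, mode="reflect", radius=radius
    )


def otsu_threshold(image: np.ndarray) -> float:
    """Otsu threshold over the exact-value intensity histogram.

    Candidate thresholds are the distinct intensities present; a threshold t
    splits the pixels into {x < t} and {x >= t}, and the value maximizing the
    between-class variance is returned (ties broken toward the lowest t).
    """
    values, counts = np.unique(np.asarray(image).ravel(), return_counts=True)
    if values.size < 2:
        raise DegenerateImage("image has a single intensity; no threshold exists")
    values = values.astype(np.float64)
    counts = counts.astype(np.float64)
    n = counts.sum()
    # Cumulative count/sum of the class below each candidate values[1:].
    n0 = np.cumsum(counts)[:-1]
    s0 = np.cumsum(values * counts)[:-1]
    n1 = n - n0
    mu0 = s0 / n0
    mu1 = (values @ counts - s0) / n1
    between = n0 * n1 * (mu0 - mu1) ** 2
    return float(values[1:][int(np.argmax(between))])


def otsu_binarize(image: np.ndarray) -> tuple[float, np.ndarray]:
    """Binarize a grayscale page; foreground (1) = intensity below threshold."""
    t = otsu_threshold(image)
    mask = (np.asarray(image) < t).astype(np.uint8)
    return t, mask


def binarize_page(image: np.ndarray, params: PreprocessParams | None = None) -> tuple[float, np.ndarray]:
    """Full preprocessing chain: grayscale -> crop -> blur -> Otsu mask."""
    if params is None:
        params = PreprocessParams()
    gray = as_grayscale(image)
    if params.apply_crop:
        gray = crop_roi(gray, params.crop)
    blurred = gaussian_blur(gray, params.sigma)
    return otsu_binarize(blurred)
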