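"""Canny edge detection: the contour half of the hybrid segmentation pipeline.

The detector is the classic four-stage chain — Gaussian smoothing, 3x3 Sobel
gradients, interpolation-free non-maximum suppression with the gradient
direction quantized to four bins, and two-threshold hysteresis linking.
Thresholds are specified as fractions of the maximum gradient magnitude so a
single pair of defaults works across images of very different contrast.

Borders are handled by reflection during smoothing and differentiation, so a
step that runs into the image border is still detected there; during
non-maximum suppression, neighbours outside the image are treated as zero
magnitude.
"""

from __future__ import annotations

import numpy as np
import scipy.ndimage as ndi
from skimage.measure import label as _cc_label

__all__ = ["canny", "gradient_field", "nonmax_suppress", "hysteresis"]


def gradient_field(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sobel gradient magnitude and direction of a grayscale image.

    Returns ``(magnitude, direction)`` with the direction angle folded into
    [0, pi). Pixels of zero magnitude get direction 0 by convention.
    """
    img = np.asarray(img, dtype=float)
    gy = ndi.sobel(img, axis=0, mode="reflect")
    gx = ndi.sobel(img, axis=1, mode="reflect")
    mag = np.hypot(gx, gy)
    direction = np.mod(np.arctan2(gy, gx), np.pi)
    direction[mag == 0] = 0.0
    return mag, direction


# neighbour offsets (row, col) along the +gradient direction, per NMS bin
_BIN_OFFSETS = {
    0: (0, 1),    # ~horizontal gradient -> compare left/right
    1: (1, 1),    # ~45 degrees
    2: (1, 0),    # ~vertical gradient -> compare up/down
    3: (1, -1),   # ~135 degrees
}


def _shifted(mag: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Magnitude of the neighbour at offset (dr, dc); 0 outside the image."""
    out = np.zeros_like(mag)
    h, w = mag.shape
    rs = slice(max(dr, 0), h + min(dr, 0))
    cs = slice(max(dc, 0), w + min(dc, 0))
    rd = slice(max(-dr, 0), h + min(-dr, 0))
    cd = slice(max(-dc, 0), w + min(-dc, 0))
    out[rd, cd] = mag[rs, cs]
    return out


def nonmax_suppress(mag: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Thin the gradient magnitude to local ridge maxima.

    The direction is quantized to {0, 45, 90, 135} degrees and each pixel is
    compared against its two neighbours along that axis.  Plateau ties are
    broken toward the pixel that comes first along the positive direction
    (kept iff strictly greater than the negative neighbour and >= the
    positive one), so an exactly symmetric smoothed step yields a
    single-pixel-wide edge.
    """
    bins = np.floor((direction + np.pi / 8) / (np.pi / 4)).astype(int) % 4
    keep = np.zeros(mag.shape, dtype=bool)
    for b, (dr, dc) in _BIN_OFFSETS.items():
        pos = _shifted(mag, dr, dc)
        neg = _shifted(mag, -dr, -dc)
        keep |= (bins == b) & (mag > neg) & (mag >= pos) & (mag > 0)
    out = np.zeros_like(mag)
    out[keep] = mag[keep]
    return out


def hysteresis(mag_nms: np.ndarray, low: float, high: float) -> np.ndarray:
    """Two-threshold edge linking.

    Pixels with magnitude >= ``high`` seed edges; pixels >= ``low`` become
    edges when 8-connected to a seed.  Returns a boolean edge map.
    """
    if not (0 <= low <= high):
        raise ValueError(f"need 0 <= low <= high, got low={low}, high={high}")
    mag_nms = np.asarray(mag_nms, dtype=float)
    strong = mag_nms >= high
    weak = mag_nms >= low
    if not strong.any():
        return np.zeros_like(weak)
    lab = _cc_label(weak, connectivity=2)
    keep = np.unique(lab[strong])
    return np.isin(lab, keep[keep > 0])


def canny(
    img: np.ndarray,
    sigma: float = 1.4,
    low_frac: float = 0.10,
    high_frac: float = 0.20,
) -> np.ndarray:
    """Canny edge map of a grayscale image.

    Parameters
    ----------
    img : (H, W) array
        Grayscale intensities (any real range).
    sigma : float
        Scale of the Gaussian smoothing, in pixels.
    low_frac, high_frac : float
        Hysteresis thresholds as fractions of the maximum gradient
        magnitude after suppression; require 0 < low_frac < high_frac <= 1.

    Returns
    -------
    (H, W) bool array, True at edge pixels.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("canny expects a 2-D grayscale image")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if not (0 < low_frac < high_frac <= 1):
        raise ValueError("need 0 < low_frac < high_frac <= 1")
    radius = int(np.ceil(3 * sigma))
    if min(img.shape) < 2 * radius + 1:
        raise ValueError(
            f"image {img.shape} smaller than the {2 * radius + 1}-pixel "
            f"smoothing kernel (sigma={sigma})"
        )
    smoothed = ndi.gaussian_filter(img, sigma, mode="reflect", truncate=3.0)
    mag, direction = gradient_field(smoothed)
    thin = nonmax_suppress(mag, direction)
    peak = thin.max()
    if peak == 0:
        return np.zeros(img.shape, dtype=bool)
    return hysteresis(thin, low_frac * peak, high_frac * peak)
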