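"""Gabor filter-bank texture features for region centers.

A Gabor filter is a sinusoid under a Gaussian envelope — a band-pass filter
selective for one spatial wavelength and one orientation.  The bank spans
8 orientations x 5 wavelengths (40 kernels); convolving the grayscale image
with each kernel and taking the smoothed response magnitude yields a 40-long
texture descriptor per pixel, which is sampled at each center position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from scipy.signal import fftconvolve

from .region_seeding import CenterSet

__all__ = [
    "DEFAULT_WAVELENGTHS",
    "DEFAULT_ORIENTATIONS",
    "GaborBank",
    "gabor_kernel",
    "build_bank",
    "texture_features",
    "center_features",
]

DEFAULT_WAVELENGTHS: tuple[float, ...] = (4.0, 8.0, 16.0, 32.0, 64.0)
DEFAULT_ORIENTATIONS: tuple[float, ...] = tuple(k * np.pi / 8 for k in range(8))

# sigma/lambda ratio for ~one-octave frequency bandwidth
SIGMA_PER_WAVELENGTH = 0.56


def gabor_kernel(
    wavelength: float,
    theta: float,
    sigma: float,
    gamma: float = 0.5,
    psi: float = 0.0,
) -> np.ndarray:
    """Even (cosine) Gabor kernel, DC-corrected so its entries sum to zero.

    ``k(x, y) = exp(-(x'^2 + gamma^2 y'^2) / (2 sigma^2)) cos(2 pi x'/lambda + psi)``
    with ``x' = x cos(theta) + y sin(theta)`` and
    ``y' = -x sin(theta) + y cos(theta)``, sampled on a square grid of
    half-width ceil(3 sigma).  The mean is subtracted so a constant image
    produces zero response.
    """
    if wavelength <= 0 or sigma <= 0 or gamma <= 0:
        raise ValueError("wavelength, sigma and gamma must all be > 0")
    r = int(np.ceil(3 * sigma))
    y, x = np.mgrid[-r : r + 1, -r : r + 1].astype(float)
    xp = x * np.cos(theta) + y * np.sin(theta)
    yp = -x * np.sin(theta) + y * np.cos(theta)
    k = np.exp(-(xp**2 + gamma**2 * yp**2) / (2 * sigma**2)) * np.cos(
        2 * np.pi * xp / wavelength + psi
    )
    return k - k.mean()


@dataclass
class GaborBank:
    """A fixed grid of Gabor kernels in wavelength-major, orientation-minor order."""

    kernels: list[np.ndarray]
    wavelengths: np.ndarray   # (F,) wavelength of each kernel, in pixels
    orientations: np.ndarray  # (F,) orientation of each kernel, radians
    gamma: float = 0.5        # envelope aspect ratio, shared by the bank

    def __len__(self) -> int:
        return len(self.kernels)


def build_bank(
    wavelengths: tuple[float, ...] = DEFAULT_WAVELENGTHS,
    orientations: tuple[float, ...] = DEFAULT_ORIENTATIONS,
    gamma: float = 0.5,
    psi: float = 0.0,
) -> GaborBank:
    """Build the default 5-wavelength x 8-orientation bank (40 kernels)."""
    kernels, lams, thetas = [], [], []
    for lam in wavelengths:
        for theta in orientations:
            kernels.append(gabor_kernel(lam, theta, SIGMA_PER_WAVELENGTH * lam, gamma, psi))
            lams.append(lam)
            thetas.append(theta)
    return GaborBank(kernels, np.array(lams), np.array(thetas), gamma=gamma)


def texture_features(
    img: np.ndarray, bank: GaborBank, quadrature: bool = False
) -> np.ndarray:
    """Per-pixel response magnitudes of the image under every bank kernel.

    Each response is |convolution| with reflect padding, then Gaussian
    smoothed at scale 0.5 x wavelength.  With ``quadrature`` the magnitude
    of the even/odd (cosine/sine) filter pair is taken instead of the even
    response alone; the pair's energy is translation invariant for periodic
    textures, where the even projection is phase-sensitive.  Kernels whose
    wavelength is >= min(H, W)/2 do not fit usefully in the image and
    contribute an all-zero plane, keeping the feature length constant.

    Returns an (H, W, F) stack, F = len(bank).
    """
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    lam_max = min(h, w) / 2
    usable = [lam for lam in np.unique(bank.wavelengths) if lam < lam_max]
    if not usable:
        raise ValueError(
            f"image {img.shape} too small for any bank wavelength; "
            f"wavelengths must be < {lam_max:g} px"
        )
    stack = np.zeros((h, w, len(bank)))
    for i, (kernel, lam, theta) in enumerate(
        zip(bank.kernels, bank.wavelengths, bank.orientations)
    ):
        if lam >= lam_max:
            continue
        r = kernel.shape[0] // 2
        pad = min(r, h - 1, w - 1)
        padded = np.pad(img, pad, mode="reflect")

        def conv(k):
            out = fftconvolve(padded, k, mode="same")
            return out[pad : pad + h, pad : pad + w]

        if quadrature:
            odd = gabor_kernel(lam, theta, SIGMA_PER_WAVELENGTH * lam,
                               gamma=bank.gamma, psi=-np.pi / 2)
            resp = np.hypot(conv(kernel), conv(odd))
        else:
            resp = np.abs(conv(kernel))
        stack[..., i] = ndi.gaussian_filter(resp, 0.5 * lam, mode="reflect")
    return stack


def center_features(
    feature_stack: np.ndarray, centers: CenterSet, normalize: bool = True
) -> CenterSet:
    """Attach to each center the feature vector of its nearest pixel.

    With ``normalize`` on, every feature coordinate is divided by its maximum
    across the centers, so each coordinate lies in [0, 1]; this makes the
    spatial-distance x feature-distance merge criterion unit-free.
    """
    h, w, _ = feature_stack.shape
    pos = centers.positions
    if (pos[:, 0] < -0.5).any() or (pos[:, 0] > h - 0.5).any() or (
        pos[:, 1] < -0.5
    ).any() or (pos[:, 1] > w - 0.5).any():
        raise ValueError("center position outside image bounds")
    rows = np.clip(np.rint(pos[:, 0]).astype(int), 0, h - 1)
    cols = np.clip(np.rint(pos[:, 1]).astype(int), 0, w - 1)
    feats = feature_stack[rows, cols, :].astype(float)
    if normalize:
        peak = feats.max(axis=0)
        nz = peak > 0
        feats[:, nz] = feats[:, nz] / peak[nz]
    return CenterSet(
        positions=centers.positions.copy(),
        colors=centers.colors.copy(),
        areas=centers.areas.copy(),
        features=feats,
        source_region_ids=[list(s) for s in centers.source_region_ids],
    )
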