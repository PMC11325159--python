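"""Gabor kernels, filter-bank responses, center feature sampling."""

import numpy as np
import pytest

from hybriseg import build_bank, gabor_kernel, texture_features, center_features
from hybriseg.region_seeding import CenterSet
from hybriseg.texture_gabor import DEFAULT_WAVELENGTHS, SIGMA_PER_WAVELENGTH


def grating(h, w, wavelength, horizontal_normal=True, amplitude=60.0, mean=128.0):
    """Sinusoid varying along columns (normal horizontal) or rows."""
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    axis = cols if horizontal_normal else rows
    return mean + amplitude * np.sin(2 * np.pi * axis / wavelength)


def test_kernel_matches_closed_form_up_to_dc_shift():
    lam, theta, sigma, gamma = 8.0, 0.3, 4.0, 0.5
    k = gabor_kernel(lam, theta, sigma, gamma)
    r = k.shape[0] // 2
    # uncorrected value at the origin is exp(0) * cos(0) = 1, so the DC
    # shift removed by the correction is 1 - k[center]
    dc = 1.0 - k[r, r]
    # spot-check a second grid point against the closed form
    x, y = 2.0, -1.0
    xp = x * np.cos(theta) + y * np.sin(theta)
    yp = -x * np.sin(theta) + y * np.cos(theta)
    expected = np.exp(-(xp**2 + gamma**2 * yp**2) / (2 * sigma**2)) * np.cos(
        2 * np.pi * xp / lam
    )
    assert k[r - 1, r + 2] + dc == pytest.approx(expected, abs=1e-12)


def test_kernel_entries_sum_to_zero():
    for lam in (4.0, 16.0):
        k = gabor_kernel(lam, 1.1, SIGMA_PER_WAVELENGTH * lam)
        assert abs(k.sum()) < 1e-10


def test_kernel_theta_periodicity():
    a = gabor_kernel(8.0, 0.7, 4.0)
    b = gabor_kernel(8.0, 0.7 + np.pi, 4.0)
    assert np.allclose(a, b)


def test_kernel_rejects_nonpositive_parameters():
    with pytest.raises(ValueError):
        gabor_kernel(-1.0, 0.0, 2.0)
    with pytest.raises(ValueError):
        gabor_kernel(4.0, 0.0, 0.0)


def test_default_bank_has_40_kernels():
    bank = build_bank()
    assert len(bank) == 40
    assert len(np.unique(bank.wavelengths)) == 5
    assert len(np.unique(bank.orientations)) == 8


def test_constant_image_gives_zero_responses():
    bank = build_bank()
    stack = texture_features(np.full((64, 64), 200.0), bank)
    assert stack.shape == (64, 64, 40)
    assert stack.max() <= 1e-9 * 255


def test_grating_argmax_selects_matching_wavelength_and_orientation():
    bank = build_bank()
    img = grating(96, 96, 8.0, horizontal_normal=True)
    stack = texture_features(img, bank)
    # mean response over the central window, per kernel
    means = stack[24:72, 24:72, :].mean(axis=(0, 1))
    best = int(np.argmax(means))
    assert bank.wavelengths[best] == 8.0
    assert bank.orientations[best] == 0.0  # gradient normal along x


def test_rotated_grating_moves_argmax_to_orthogonal_orientation():
    bank = build_bank()
    img = grating(96, 96, 8.0, horizontal_normal=False)
    means = texture_features(img, bank)[24:72, 24:72, :].mean(axis=(0, 1))
    best = int(np.argmax(means))
    assert bank.wavelengths[best] == 8.0
    assert bank.orientations[best] == pytest.approx(np.pi / 2)


def test_shifted_grating_has_same_quadrature_energy():
    # the even projection alone is phase-sensitive; the quadrature pair's
    # energy is the translation-invariant quantity
    bank = build_bank()
    a = texture_features(grating(160, 160, 8.0), bank, quadrature=True)
    rows, cols = np.mgrid[0:160, 0:160].astype(float)
    shifted = 128 + 60 * np.sin(2 * np.pi * (cols + 3) / 8.0)
    b = texture_features(shifted, bank, quadrature=True)
    # compare deep in the interior, and only for kernels whose combined
    # kernel + smoothing reach fits between the window and the border
    # (lambda <= 16 here): larger kernels see the reflected boundary
    # everywhere on any practical canvas, so no border-free value exists
    win = (slice(64, 96), slice(64, 96))
    ma, mb = a[win].mean(axis=(0, 1)), b[win].mean(axis=(0, 1))
    interior = bank.wavelengths <= 16
    scale = max(ma[interior].max(), 1e-12)
    assert np.all(np.abs(ma[interior] - mb[interior]) <= 0.01 * scale + 1e-9)


def test_even_response_argmax_kernel_is_shift_stable():
    bank = build_bank()
    a = texture_features(grating(64, 64, 8.0), bank)
    rows, cols = np.mgrid[0:64, 0:64].astype(float)
    b = texture_features(128 + 60 * np.sin(2 * np.pi * (cols + 3) / 8.0), bank)
    win = (slice(16, 48), slice(16, 48))
    assert np.argmax(a[win].mean(axis=(0, 1))) == np.argmax(b[win].mean(axis=(0, 1)))


def test_too_small_image_raises():
    bank = build_bank()
    with pytest.raises(ValueError, match="too small"):
        texture_features(np.zeros((4, 4)), bank)


def _centers(points):
    pts = np.asarray(points, float)
    return CenterSet(
        positions=pts,
        colors=np.zeros((len(pts), 3)),
        areas=np.ones(len(pts)),
        source_region_ids=[[i] for i in range(len(pts))],
    )


def test_center_features_length_and_normalization():
    bank = build_bank()
    stack = texture_features(grating(64, 64, 8.0), bank)
    cs = center_features(stack, _centers([(32.0, 32.0)]), normalize=True)
    assert cs.features.shape == (1, 40)
    assert cs.features.max() == pytest.approx(1.0)
    assert (cs.features <= 1.0 + 1e-12).all()


def test_center_features_out_of_bounds_raises():
    bank = build_bank()
    stack = texture_features(np.zeros((32, 32)), bank)
    with pytest.raises(ValueError, match="bounds"):
        center_features(stack, _centers([(40.0, 2.0)]))


def test_within_texture_distance_below_cross_texture_distance():
    bank = build_bank()
    img = np.where(
        np.arange(96)[None, :] < 48,
        grating(96, 96, 8.0, horizontal_normal=True),
        grating(96, 96, 16.0, horizontal_normal=False),
    )
    stack = texture_features(img, bank)
    cs = center_features(
        stack, _centers([(30.0, 16.0), (60.0, 30.0), (30.0, 70.0), (60.0, 80.0)])
    )
    f = cs.features
    within = max(np.linalg.norm(f[0] - f[1]), np.linalg.norm(f[2] - f[3]))
    cross = min(
        np.linalg.norm(f[i] - f[j]) for i in (0, 1) for j in (2, 3)
    )
    assert cross > within
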