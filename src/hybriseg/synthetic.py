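"""Deterministic synthetic test images with exact ground-truth labels.

The generator emulates the regime the segmentation method targets: images
composed of piecewise-constant coloured regions, optionally carrying an
oriented sinusoidal texture (added to all channels so the mean colour is
untouched), plus additive Gaussian pixel noise.  Because the ground truth
is known by construction, every pipeline stage is testable without any
external dataset.

The fixed palette places every channel value at the centre of a broad
intensity band ({32, 96, 160, 224}) and spreads the colours in luma, so
the dominant colours of a fixture are unambiguous — distinct both to a
colour-frequency tally and to a gradient-based edge detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Texture", "Shape", "FixtureSpec", "render", "preset", "shapes_spec", "PALETTE"]

# background first; shape colours follow
PALETTE: tuple[tuple[int, int, int], ...] = (
    (32, 32, 32),     # dark grey background, luma 32
    (224, 32, 32),    # red,        luma ~89
    (32, 160, 224),   # azure,      luma ~129
    (224, 224, 32),   # yellow,     luma ~202
    (160, 32, 224),   # violet,     luma ~92
    (32, 224, 96),    # green,      luma ~152
)


@dataclass
class Texture:
    """Sinusoidal luma grating: amplitude * sin(2 pi (x cos t + y sin t) / wavelength)."""

    wavelength: float
    orientation: float
    amplitude: float


@dataclass
class Shape:
    """One flat-coloured shape.

    kind 'rect':  geometry = (min_row, min_col, max_row, max_col), inclusive
    kind 'disk':  geometry = (center_row, center_col, radius)
    kind 'stripe': geometry = (min_col, max_col), full image height
    """

    kind: str
    geometry: tuple
    color: tuple[int, int, int]
    texture: Texture | None = None


@dataclass
class FixtureSpec:
    """Full description of a synthetic fixture; rendering is deterministic."""

    height: int
    width: int
    background: tuple[int, int, int] = PALETTE[0]
    background_texture: Texture | None = None
    shapes: list[Shape] = field(default_factory=list)
    noise_sigma: float = 0.0
    seed: int = 0


def _mask(shape: Shape, h: int, w: int) -> np.ndarray:
    rows, cols = np.mgrid[0:h, 0:w]
    if shape.kind == "rect":
        r0, c0, r1, c1 = shape.geometry
        if not (0 <= r0 <= r1 < h and 0 <= c0 <= c1 < w):
            raise ValueError(f"rect {shape.geometry} outside {h}x{w} canvas")
        return (rows >= r0) & (rows <= r1) & (cols >= c0) & (cols <= c1)
    if shape.kind == "disk":
        cr, cc, rad = shape.geometry
        if not (rad <= cr <= h - 1 - rad and rad <= cc <= w - 1 - rad):
            raise ValueError(f"disk {shape.geometry} outside {h}x{w} canvas")
        return (rows - cr) ** 2 + (cols - cc) ** 2 <= rad**2
    if shape.kind == "stripe":
        c0, c1 = shape.geometry
        if not (0 <= c0 <= c1 < w):
            raise ValueError(f"stripe {shape.geometry} outside {h}x{w} canvas")
        return (cols >= c0) & (cols <= c1)
    raise ValueError(f"unknown shape kind {shape.kind!r}")


def _grating(tex: Texture, h: int, w: int) -> np.ndarray:
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    phase = 2 * np.pi * (
        cols * np.cos(tex.orientation) + rows * np.sin(tex.orientation)
    ) / tex.wavelength
    return tex.amplitude * np.sin(phase)


def render(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render a spec into ``(rgb_image, ground_truth_labels)``.

    Label 0 is the background; shape i gets label i+1; later shapes occlude
    earlier ones.  Textures modulate luma (all channels equally) before
    noise; noise is sampled per channel from the spec seed and the result
    is clipped to [0, 255] and rounded to 8 bits.
    """
    h, w = spec.height, spec.width
    if h < 1 or w < 1:
        raise ValueError("canvas must be at least 1x1")
    img = np.empty((h, w, 3), dtype=float)
    img[:] = spec.background
    gt = np.zeros((h, w), dtype=np.int32)
    if spec.background_texture is not None:
        img += _grating(spec.background_texture, h, w)[..., None]
    for i, shape in enumerate(spec.shapes):
        m = _mask(shape, h, w)
        img[m] = shape.color
        if shape.texture is not None:
            img[m] += _grating(shape.texture, h, w)[m, None]
        gt[m] = i + 1
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img += rng.normal(0.0, spec.noise_sigma, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, gt


# anchor slots on a 96x96 canvas, spaced so jittered shapes never overlap
_SLOTS = ((24, 20), (24, 48), (24, 76), (72, 20), (72, 48), (72, 76))


def shapes_spec(
    n_colors: int,
    seed: int,
    size: int = 96,
    noise_sigma: float = 0.0,
) -> FixtureSpec:
    """A fixture with exactly ``n_colors`` distinct flat colours.

    ``n_colors`` counts the background plus n_colors - 1 shapes, each placed
    in its own slot with seed-jittered position and extent, alternating
    rectangles and disks.  Slot spacing, jitter (+-3 px) and shape extents
    (half-width 8-10 px) are sized so shapes never overlap or touch the
    canvas border.  Supports 2..6 colours (the palette size).
    """
    if not 2 <= n_colors <= len(PALETTE):
        raise ValueError(f"n_colors must be in [2, {len(PALETTE)}]")
    rng = np.random.default_rng(seed)
    scale = size / 96.0
    shapes: list[Shape] = []
    for i in range(n_colors - 1):
        sr, sc = _SLOTS[i]
        cr = int(round(sr * scale)) + int(rng.integers(-3, 4))
        cc = int(round(sc * scale)) + int(rng.integers(-3, 4))
        half = int(rng.integers(8, 11))
        color = PALETTE[i + 1]
        if i % 2 == 0:
            shapes.append(Shape("rect", (cr - half, cc - half, cr + half, cc + half), color))
        else:
            shapes.append(Shape("disk", (cr, cc, half), color))
    return FixtureSpec(
        height=size, width=size, background=PALETTE[0],
        shapes=shapes, noise_sigma=noise_sigma, seed=seed,
    )


def preset(name: str, seed: int) -> FixtureSpec:
    """Named fixture presets.

    - ``shapes``   3-5 flat-coloured shapes on a dark background
    - ``textures`` two flat regions of identical mean colour carrying
      orthogonal gratings (wavelengths 8 px and 16 px) — only texture can
      separate them
    - ``noisy``    the shapes preset plus Gaussian noise, sigma = 10
    """
    rng = np.random.default_rng(seed)
    if name == "shapes":
        return shapes_spec(int(rng.integers(4, 7)), seed)
    if name == "noisy":
        return shapes_spec(int(rng.integers(4, 7)), seed, noise_sigma=10.0)
    if name == "textures":
        grey = (128, 128, 128)
        return FixtureSpec(
            height=96,
            width=96,
            background=grey,
            background_texture=Texture(wavelength=8.0, orientation=0.0, amplitude=50.0),
            shapes=[
                Shape(
                    "stripe", (48, 95), grey,
                    texture=Texture(wavelength=16.0, orientation=np.pi / 2, amplitude=50.0),
                )
            ],
            noise_sigma=0.0,
            seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}; choose from: shapes, textures, noisy")
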