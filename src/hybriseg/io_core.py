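"""Core raster I/O, configuration, and the top-level segmentation pipeline.

The pipeline chains three stages:

I.   Contour seeding — Canny edges, connected components of the non-edge
     pixels, region properties, joining of similar adjacent regions, one
     seed center per region.
II.  Center reduction — Gabor texture features at each center; centers that
     are spatially close and texturally similar (distance product below a
     threshold) are merged.
III. Colour clustering — the cluster count K is estimated from the image's
     colour frequencies, fuzzy c-means clusters the reduced centers' RGB
     values, and every pixel is labelled by its nearest colour centre.

Images are plain numpy arrays: RGB images are (H, W, 3) uint8, grayscale
images (H, W) float, label maps (H, W) int.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from . import center_merging, color_fcm, edge_contour, region_seeding, texture_gabor
from .color_fcm import FCMResult

__all__ = [
    "PipelineConfig",
    "SegmentationResult",
    "read_image",
    "to_grayscale",
    "write_label_map",
    "read_label_map",
    "segment",
]

logger = logging.getLogger("hybriseg")

LUMA_WEIGHTS = (0.299, 0.587, 0.114)  # ITU-R BT.601


@dataclass
class PipelineConfig:
    """Every knob of the pipeline, with working defaults.

    ``merge_threshold`` of None means the default
    ``merge_threshold_frac`` x image diagonal (texture features normalized
    to [0, 1] make the product criterion unit-free).
    """

    # step I — edges and region seeding
    canny_sigma: float = 1.4
    canny_low_frac: float = 0.10
    canny_high_frac: float = 0.20
    connectivity: int = 4
    cc_target: str = "regions"      # "regions" (edge complement) | "edges"
    tau_color: float = 25.0         # RGB units
    min_area: int = 20              # pixels
    # step II — texture features and center merging
    n_orientations: int = 8
    n_wavelengths: int = 5
    base_wavelength: float = 4.0    # wavelengths are base * 2^i
    gabor_gamma: float = 0.5
    gabor_quadrature: bool = False  # even response only by default
    normalize_features: bool = True
    merge_threshold: float | None = None
    merge_threshold_frac: float = 0.05
    # step III — cluster count, FCM, labelling
    quant_levels: int = 4           # Q levels per channel
    f_min: float = 0.01             # minimum main-colour frequency
    fcm_m: float = 2.0
    fcm_tol: float = 1e-5
    fcm_max_iter: int = 300
    fcm_on: str = "centers"         # "centers" | "pixels"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.canny_sigma <= 0 or self.tau_color < 0 or self.min_area < 1:
            raise ValueError("invalid step-I parameters")
        if not (0 < self.canny_low_frac < self.canny_high_frac <= 1):
            raise ValueError("need 0 < canny_low_frac < canny_high_frac <= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.cc_target not in ("regions", "edges"):
            raise ValueError("cc_target must be 'regions' or 'edges'")
        if self.n_orientations < 1 or self.n_wavelengths < 1:
            raise ValueError("orientation and wavelength counts must be >= 1")
        if self.merge_threshold is not None and self.merge_threshold < 0:
            raise ValueError("merge_threshold must be >= 0")
        if self.merge_threshold_frac <= 0:
            raise ValueError("merge_threshold_frac must be > 0")
        if self.quant_levels < 2 or not (0 < self.f_min < 1):
            raise ValueError("invalid colour-frequency parameters")
        if self.fcm_m <= 1 or self.fcm_tol <= 0 or self.fcm_max_iter < 1:
            raise ValueError("invalid FCM parameters")
        if self.fcm_on not in ("centers", "pixels"):
            raise ValueError("fcm_on must be 'centers' or 'pixels'")

    def wavelengths(self) -> tuple[float, ...]:
        return tuple(self.base_wavelength * 2**i for i in range(self.n_wavelengths))

    def orientations(self) -> tuple[float, ...]:
        return tuple(k * np.pi / self.n_orientations for k in range(self.n_orientations))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


@dataclass
class SegmentationResult:
    """Pipeline output: the label map plus everything needed to audit it."""

    label_map: np.ndarray            # (H, W) int32
    rgb_centers: np.ndarray          # (K, 3) float cluster colours
    n_initial: int                   # centers after step I
    n_reduced: int                   # centers after step II
    k: int                           # clusters used by FCM
    fcm: FCMResult | None
    edge_map: np.ndarray | None
    config: PipelineConfig
    timings: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_labels(self) -> int:
        return len(np.unique(self.label_map))


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as an (H, W, 3) uint8 RGB array.

    Single-channel files are replicated to three channels.  Palette images,
    alpha channels and bit depths other than 8 are rejected with an error
    naming the offending property.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with Image.open(path) as im:
        if im.mode == "L":
            arr = np.asarray(im, dtype=np.uint8)
            return np.repeat(arr[..., None], 3, axis=2)
        if im.mode == "RGB":
            return np.asarray(im, dtype=np.uint8)
        raise ValueError(
            f"unsupported image mode {im.mode!r} in {path.name}: "
            "need 8-bit grayscale (L) or 8-bit RGB"
        )


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Luma conversion 0.299 R + 0.587 G + 0.114 B, kept real-valued."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    return img @ np.asarray(LUMA_WEIGHTS)


def write_label_map(
    label_map: np.ndarray,
    path: str | Path,
    rgb_centers: np.ndarray | None = None,
) -> None:
    """Write a label map as a 16-bit single-channel PNG.

    A companion JSON sidecar (``<path>.json``) maps label id to its cluster
    RGB triplet when ``rgb_centers`` is given.
    """
    labels = np.asarray(label_map)
    if labels.min() < 0 or labels.max() > 65535:
        raise ValueError("labels must fit in uint16 (0..65535)")
    path = Path(path)
    Image.fromarray(labels.astype(np.uint16)).save(path, format="PNG")
    if rgb_centers is not None:
        sidecar = {
            str(i): [float(v) for v in c] for i, c in enumerate(np.asarray(rgb_centers))
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_label_map(path: str | Path) -> np.ndarray:
    """Read back a label map written by :func:`write_label_map`."""
    with Image.open(path) as im:
        return np.asarray(im).astype(np.int32)


def _single_color_result(
    img: np.ndarray, cfg: PipelineConfig, timings: dict
) -> SegmentationResult:
    color = np.asarray(img, dtype=float).reshape(-1, 3)[0]
    msg = "degenerate single-colour image: returning a single-label result"
    logger.warning(msg)
    return SegmentationResult(
        label_map=np.zeros(img.shape[:2], dtype=np.int32),
        rgb_centers=color[None, :],
        n_initial=1,
        n_reduced=1,
        k=1,
        fcm=None,
        edge_map=np.zeros(img.shape[:2], dtype=bool),
        config=cfg,
        timings=timings,
        warnings=[msg],
    )


def segment(img: np.ndarray, cfg: PipelineConfig | None = None) -> SegmentationResult:
    """Run the full three-stage pipeline on an RGB image.

    Deterministic for a fixed (image, config) pair: the only randomness is
    the FCM initialisation, driven by ``cfg.seed``.
    """
    cfg = cfg or PipelineConfig()
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if min(img.shape[:2]) < 16:
        raise ValueError("image must be at least 16x16 for the filter bank")
    notes: list[str] = []
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    if len(np.unique(img.reshape(-1, 3), axis=0)) == 1:
        return _single_color_result(img, cfg, timings)

    # ---- step I: contour-seeded regions -------------------------------
    gray = to_grayscale(img)
    edges = edge_contour.canny(
        gray, cfg.canny_sigma, cfg.canny_low_frac, cfg.canny_high_frac
    )
    binary = ~edges if cfg.cc_target == "regions" else edges
    comp = region_seeding.connected_components(binary, cfg.connectivity)
    table = region_seeding.region_properties(comp, img)
    if len(table) > 0:
        table = region_seeding.join_similar_regions(
            table, region_seeding.region_adjacency(comp), cfg.tau_color, cfg.min_area
        )
    timings["step1_s"] = time.perf_counter() - t0

    if len(table) < 2:
        msg = "fewer than 2 initial centers: falling back to K=2 FCM on pixel colours"
        logger.warning(msg)
        notes.append(msg)
        result = color_fcm.fcm(
            img.reshape(-1, 3).astype(float), 2, cfg.fcm_m, cfg.fcm_tol,
            cfg.fcm_max_iter, cfg.seed,
        )
        labels = color_fcm.assign_labels(img, result.centers)
        timings["total_s"] = time.perf_counter() - t0
        return SegmentationResult(
            label_map=labels, rgb_centers=result.centers,
            n_initial=len(table), n_reduced=len(table), k=len(result.centers),
            fcm=result, edge_map=edges, config=cfg, timings=timings, warnings=notes,
        )

    centers = region_seeding.initial_centers(table)
    n_initial = len(centers)
    logger.info("step I: %d initial centers", n_initial)

    # ---- step II: texture features + center merging -------------------
    t1 = time.perf_counter()
    bank = texture_gabor.build_bank(
        cfg.wavelengths(), cfg.orientations(), gamma=cfg.gabor_gamma
    )
    stack = texture_gabor.texture_features(gray, bank, quadrature=cfg.gabor_quadrature)
    centers = texture_gabor.center_features(stack, centers, cfg.normalize_features)
    diag = float(np.hypot(*img.shape[:2]))
    threshold = (
        cfg.merge_threshold
        if cfg.merge_threshold is not None
        else cfg.merge_threshold_frac * diag
    )
    reduced = center_merging.merge_centers(centers, threshold)
    n_reduced = len(reduced)
    logger.info("step II: centers reduced %d -> %d", n_initial, n_reduced)
    timings["step2_s"] = time.perf_counter() - t1

    # ---- step III: colour-frequency K, FCM, per-pixel labelling --------
    t2 = time.perf_counter()
    k_est = color_fcm.color_frequency_index(img, cfg.quant_levels, cfg.f_min)
    if cfg.fcm_on == "pixels":
        points = img.reshape(-1, 3).astype(float)
    else:
        points = reduced.colors
    k_used = min(k_est, len(points))
    if k_used < k_est:
        notes.append(f"K lowered from {k_est} to {k_used}: only {len(points)} FCM points")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        result = color_fcm.fcm(
            points, k_used, cfg.fcm_m, cfg.fcm_tol, cfg.fcm_max_iter, cfg.seed
        )
    notes.extend(str(w.message) for w in caught)
    labels = color_fcm.assign_labels(img, result.centers)
    k_final = len(result.centers)
    logger.info(
        "step III: K=%d (estimated %d), %d output labels",
        k_final, k_est, len(np.unique(labels)),
    )
    timings["step3_s"] = time.perf_counter() - t2
    timings["total_s"] = time.perf_counter() - t0
    return SegmentationResult(
        label_map=labels, rgb_centers=result.centers,
        n_initial=n_initial, n_reduced=n_reduced, k=k_final,
        fcm=result, edge_map=edges, config=cfg, timings=timings, warnings=notes,
    )
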