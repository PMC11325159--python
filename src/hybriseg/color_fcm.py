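"""Cluster-count estimation from colour frequencies, fuzzy c-means, labelling.

The number of clusters K is read off the image itself: all distinct colours
are tallied, shades are collapsed by quantizing each channel into Q uniform
levels, and K is the number of quantized colour bins whose pixel share
reaches a minimum frequency — the count of the image's "main colours".

Fuzzy c-means (FCM) then clusters the RGB values of the reduced region
centers.  FCM assigns every point a graded membership u_ik in [0, 1] to each
cluster and alternates

    u_ik = 1 / sum_j (||x_k - v_i|| / ||x_k - v_j||)^(2/(m-1))
    v_i  = sum_k u_ik^m x_k / sum_k u_ik^m

which monotonically decreases the fuzzified objective
J_m = sum_ik u_ik^m ||x_k - v_i||^2.  Finally every pixel is labelled with
its nearest cluster centre in RGB space.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ColorFrequencyTable",
    "FCMResult",
    "color_frequency_table",
    "color_frequency_index",
    "fcm",
    "assign_labels",
    "reconstruct",
]

logger = logging.getLogger(__name__)


@dataclass
class ColorFrequencyTable:
    """Quantized colour bins with pixel counts and frequency fractions."""

    colors: np.ndarray       # (B, 3) representative RGB per occupied bin
    counts: np.ndarray       # (B,) pixel counts, >= 1
    fractions: np.ndarray    # (B,) counts / total, sums to 1


@dataclass
class FCMResult:
    """Fuzzy c-means output: centres, memberships, convergence trace."""

    centers: np.ndarray          # (K, 3) real-valued RGB cluster centres
    memberships: np.ndarray      # (N, K), each row sums to 1
    objective: np.ndarray = field(default_factory=lambda: np.zeros(0))
    iterations: int = 0
    converged: bool = False


def color_frequency_table(img: np.ndarray, q_levels: int = 4) -> ColorFrequencyTable:
    """Tally distinct colours, then collapse shades into Q^3 quantized bins.

    The representative colour of a bin is its centre on the [0, 255] scale.
    """
    if q_levels < 2:
        raise ValueError("q_levels must be >= 2")
    px = np.asarray(img).reshape(-1, 3).astype(np.int64)
    # distinct colours with their counts ("unique frequencies are kept")
    colors, counts = np.unique(px, axis=0, return_counts=True)
    # collapse shades: quantize each channel into q_levels uniform bins
    binned = np.minimum(colors * q_levels // 256, q_levels - 1)
    codes = binned[:, 0] * q_levels * q_levels + binned[:, 1] * q_levels + binned[:, 2]
    occupied, inverse = np.unique(codes, return_inverse=True)
    bin_counts = np.bincount(inverse, weights=counts).astype(np.int64)
    b = np.stack(
        [occupied // (q_levels * q_levels), (occupied // q_levels) % q_levels,
         occupied % q_levels],
        axis=1,
    )
    reps = (b + 0.5) * (256.0 / q_levels)
    return ColorFrequencyTable(
        colors=reps, counts=bin_counts, fractions=bin_counts / bin_counts.sum()
    )


def color_frequency_index(img: np.ndarray, q_levels: int = 4, f_min: float = 0.01) -> int:
    """Estimate the cluster count K as the number of main colours.

    K = number of quantized colour bins with frequency >= ``f_min``,
    clipped to [2, 64].
    """
    if not (0 < f_min < 1):
        raise ValueError("f_min must be in (0, 1)")
    table = color_frequency_table(img, q_levels)
    k = int(np.count_nonzero(table.fractions >= f_min))
    return int(np.clip(k, 2, 64))


def _farthest_point_init(points: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Seed K centres from the points: random first pick, then greedy
    farthest-point selection (ties to the lowest index)."""
    rng = np.random.default_rng(seed)
    first = int(rng.integers(len(points)))
    chosen = [first]
    dmin = np.linalg.norm(points - points[first], axis=1)
    while len(chosen) < k:
        nxt = int(np.argmax(dmin))
        chosen.append(nxt)
        dmin = np.minimum(dmin, np.linalg.norm(points - points[nxt], axis=1))
    return points[chosen].astype(float).copy()


def fcm(
    points: np.ndarray,
    k: int,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int = 0,
) -> FCMResult:
    """Fuzzy c-means clustering of RGB points.

    Parameters
    ----------
    points : (N, 3) array
        Input colours.
    k : int
        Number of clusters; lowered (with a warning) to the number of
        distinct points if fewer are available.
    m : float
        Fuzzifier, > 1.  m -> 1 approaches hard k-means; larger m is fuzzier.
    tol : float
        Convergence threshold on the maximum membership change.
    max_iter : int
        Iteration cap.
    seed : int
        Seed for the farthest-point initialisation.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or len(points) == 0:
        raise ValueError("points must be a non-empty (N, D) array")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if k < 1:
        raise ValueError("k must be >= 1")
    n_distinct = len(np.unique(points, axis=0))
    if k > n_distinct:
        warnings.warn(
            f"k={k} exceeds the {n_distinct} distinct points; lowering k",
            stacklevel=2,
        )
        k = n_distinct

    centers = _farthest_point_init(points, k, seed)
    u = _memberships(points, centers, m)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        um = u**m
        centers = (um.T @ points) / um.sum(axis=0)[:, None]
        u_new = _memberships(points, centers, m)
        trace.append(_objective(points, centers, u_new, m))
        delta = float(np.abs(u_new - u).max())
        u = u_new
        if delta < tol:
            converged = True
            break
    return FCMResult(
        centers=centers,
        memberships=u,
        objective=np.array(trace),
        iterations=it,
        converged=converged,
    )


def _memberships(points: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    d = np.linalg.norm(points[:, None, :] - centers[None, :, :], axis=2)
    coincident = d < 1e-12
    hit = coincident.any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d ** (-2.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
    if hit.any():
        # a point sitting on one or more centres: crisp membership split
        # equally among the coincident centres
        u[hit] = coincident[hit] / coincident[hit].sum(axis=1, keepdims=True)
    return u


def _objective(points, centers, u, m) -> float:
    d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return float((u**m * d2).sum())


def assign_labels(img: np.ndarray, rgb_centers: np.ndarray) -> np.ndarray:
    """Label every pixel with the index of its nearest RGB cluster centre.

    Ties break toward the lowest centre index.
    """
    centers = np.asarray(rgb_centers, dtype=float)
    if centers.ndim != 2 or len(centers) == 0:
        raise ValueError("rgb_centers must be a non-empty (K, 3) array")
    px = np.asarray(img, dtype=float).reshape(-1, 3)
    d2 = ((px[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)  # argmin takes the first minimum: lowest index
    return labels.reshape(np.asarray(img).shape[:2]).astype(np.int32)


def reconstruct(label_map: np.ndarray, rgb_centers: np.ndarray) -> np.ndarray:
    """Paint every pixel with the rounded RGB of its cluster centre."""
    labels = np.asarray(label_map)
    centers = np.asarray(rgb_centers, dtype=float)
    if labels.size and labels.max() >= len(centers):
        raise ValueError(
            f"label {int(labels.max())} out of range for {len(centers)} centres"
        )
    if labels.min() < 0:
        raise ValueError("labels must be non-negative")
    rounded = np.clip(np.floor(centers + 0.5), 0, 255).astype(np.uint8)  # half-up
    return rounded[labels]
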