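"""Reduce the center set by merging nearby, texturally similar centers.

Two centers merge when the product of their spatial (pixel) distance and
their texture feature distance falls strictly below a threshold: centers
that are both close together and belong to approximately the same texture
almost certainly seed the same region.  Qualifying pairs are linked and
their connected groups collapse in a single transitive-closure pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .region_seeding import CenterSet, _UnionFind

__all__ = ["MergeDecision", "spatial_distance", "feature_distance", "merge_centers"]

# default merge threshold as a fraction of the image diagonal (features normalized)
DEFAULT_THRESHOLD_FRAC = 0.05


@dataclass
class MergeDecision:
    """One pairwise evaluation of the merge criterion."""

    i: int
    j: int
    spatial: float
    feature: float
    product: float
    merged: bool


def spatial_distance(p1, p2) -> float:
    """Euclidean distance between two center positions, in pixels."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    return float(np.linalg.norm(p1 - p2))


def feature_distance(f1, f2) -> float:
    """Euclidean norm of the difference of two texture feature vectors."""
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    if f1.shape != f2.shape:
        raise ValueError("feature vectors must have equal length")
    return float(np.linalg.norm(f1 - f2))


def merge_centers(
    centers: CenterSet, threshold: float, decisions: list[MergeDecision] | None = None
) -> CenterSet:
    """Collapse groups of centers linked by the product criterion.

    All pairs are evaluated; pairs with
    ``spatial_distance * feature_distance < threshold`` are linked, and each
    connected group (union-find transitive closure) collapses to a single
    center at the area-weighted mean position with area-weighted mean colour
    and unweighted mean feature.  Pass a list as ``decisions`` to record
    every pairwise evaluation.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if centers.features is None:
        raise ValueError("centers carry no texture features; run center_features first")
    n = len(centers)
    if n <= 1:
        return centers

    pos = centers.positions
    feats = centers.features
    sd = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    fd = np.linalg.norm(feats[:, None, :] - feats[None, :, :], axis=2)
    prod = sd * fd

    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            merged = bool(prod[i, j] < threshold)
            if merged:
                uf.union(i, j)
            if decisions is not None:
                decisions.append(
                    MergeDecision(i, j, float(sd[i, j]), float(fd[i, j]),
                                  float(prod[i, j]), merged)
                )

    groups: dict[int, list[int]] = {}
    for k in range(n):
        groups.setdefault(uf.find(k), []).append(k)
    ordered = sorted(groups.values(), key=lambda g: min(g))

    new_pos, new_col, new_area, new_feat, new_src = [], [], [], [], []
    for g in ordered:
        a = centers.areas[g]
        w = a / a.sum() if a.sum() > 0 else np.full(len(g), 1.0 / len(g))
        new_pos.append(w @ pos[g])
        new_col.append(w @ centers.colors[g])
        new_area.append(float(a.sum()))
        new_feat.append(feats[g].mean(axis=0))
        src: list[int] = []
        for k in g:
            src.extend(centers.source_region_ids[k] if centers.source_region_ids else [])
        new_src.append(src)

    return CenterSet(
        positions=np.array(new_pos),
        colors=np.array(new_col),
        areas=np.array(new_area),
        features=np.array(new_feat),
        source_region_ids=new_src,
    )
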