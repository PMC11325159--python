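"""Turn an edge map into an initial set of region centers.

Connected components of the non-edge pixels (regions bounded by contours)
are measured, similar adjacent regions are joined, and each surviving region
contributes one seed center at its centroid carrying its mean colour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage.measure import label as _cc_label

__all__ = [
    "RegionTable",
    "CenterSet",
    "connected_components",
    "region_adjacency",
    "region_properties",
    "join_similar_regions",
    "initial_centers",
]


@dataclass
class RegionTable:
    """Per-region properties: id, pixel area, centroid, mean colour, bbox.

    Rows are aligned across all arrays. Centroids are (row, col) in pixel
    coordinates; bounding boxes are (min_row, min_col, max_row, max_col),
    inclusive.
    """

    ids: np.ndarray          # (R,) int
    areas: np.ndarray        # (R,) int
    centroids: np.ndarray    # (R, 2) float
    mean_colors: np.ndarray  # (R, 3) float
    bboxes: np.ndarray       # (R, 4) int

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class CenterSet:
    """Region centers: positions, mean colours, areas, texture features.

    ``features`` is None until populated by the Gabor stage; afterwards it is
    an (N, F) array with F = orientation count x wavelength count.
    """

    positions: np.ndarray            # (N, 2) float, (row, col)
    colors: np.ndarray               # (N, 3) float
    areas: np.ndarray                # (N,) float
    features: np.ndarray | None = None
    source_region_ids: list[list[int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.positions)


def connected_components(binary: np.ndarray, connectivity: int = 4) -> np.ndarray:
    """Label the True pixels of a binary image into connected components.

    Foreground components get labels 1..C (contiguous); the False background
    keeps the separate label 0.  ``connectivity`` is 4 or 8.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    binary = np.asarray(binary, dtype=bool)
    return _cc_label(binary, background=0, connectivity=1 if connectivity == 4 else 2)


def region_properties(label_map: np.ndarray, img: np.ndarray) -> RegionTable:
    """Measure area, centroid, mean RGB and bounding box per labelled region.

    Label 0 is treated as background (e.g. the edge pixels) and excluded.
    """
    label_map = np.asarray(label_map)
    img = np.asarray(img, dtype=float)
    if label_map.shape != img.shape[:2]:
        raise ValueError(
            f"label map shape {label_map.shape} != image shape {img.shape[:2]}"
        )
    ids = np.unique(label_map)
    ids = ids[ids > 0]
    if ids.size == 0:
        return RegionTable(
            ids=ids,
            areas=np.zeros(0, dtype=int),
            centroids=np.zeros((0, 2)),
            mean_colors=np.zeros((0, 3)),
            bboxes=np.zeros((0, 4), dtype=int),
        )
    areas = ndi.sum_labels(np.ones_like(label_map), label_map, ids).astype(int)
    rows, cols = np.indices(label_map.shape)
    cr = ndi.mean(rows, label_map, ids)
    cc = ndi.mean(cols, label_map, ids)
    mean_colors = np.stack(
        [ndi.mean(img[..., ch], label_map, ids) for ch in range(img.shape[2])], axis=1
    )
    objs = ndi.find_objects(label_map)
    bboxes = np.array(
        [
            (sl[0].start, sl[1].start, sl[0].stop - 1, sl[1].stop - 1)
            for sl in (objs[i - 1] for i in ids)
        ],
        dtype=int,
    )
    return RegionTable(
        ids=ids,
        areas=areas,
        centroids=np.stack([cr, cc], axis=1),
        mean_colors=mean_colors,
        bboxes=bboxes,
    )


def region_adjacency(label_map: np.ndarray) -> set[tuple[int, int]]:
    """Pairs of region ids that share a 4-neighbour pixel pair.

    Pairs involving label 0 (background/edges) are excluded; pairs are
    returned as (small_id, large_id).
    """
    lm = np.asarray(label_map)
    pairs: set[tuple[int, int]] = set()
    for a, b in ((lm[:-1, :], lm[1:, :]), (lm[:, :-1], lm[:, 1:])):
        diff = (a != b) & (a > 0) & (b > 0)
        if diff.any():
            lo = np.minimum(a[diff], b[diff])
            hi = np.maximum(a[diff], b[diff])
            pairs.update(zip(lo.tolist(), hi.tolist()))
    return pairs


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _aggregate(rt: RegionTable, groups: list[list[int]]) -> RegionTable:
    """Collapse row groups of a RegionTable into area-weighted aggregates."""
    ids, areas, cents, colors, bboxes = [], [], [], [], []
    for g in groups:
        a = rt.areas[g].astype(float)
        w = a / a.sum()
        ids.append(int(rt.ids[g].min()))
        areas.append(int(a.sum()))
        cents.append(w @ rt.centroids[g])
        colors.append(w @ rt.mean_colors[g])
        bb = rt.bboxes[g]
        bboxes.append(
            (bb[:, 0].min(), bb[:, 1].min(), bb[:, 2].max(), bb[:, 3].max())
        )
    return RegionTable(
        ids=np.array(ids, dtype=int),
        areas=np.array(areas, dtype=int),
        centroids=np.array(cents, dtype=float),
        mean_colors=np.array(colors, dtype=float),
        bboxes=np.array(bboxes, dtype=int),
    )


def join_similar_regions(
    rt: RegionTable,
    adjacency: set[tuple[int, int]],
    tau_color: float = 25.0,
    min_area: int = 20,
) -> RegionTable:
    """Merge adjacent regions of similar mean colour; absorb tiny regions.

    Two adjacent regions merge when the Euclidean distance between their
    mean RGB colours is strictly below ``tau_color`` (transitively, via
    union-find).  Afterwards every region with area below ``min_area`` is
    absorbed into its adjacent region of closest mean colour.  Merged
    properties are recomputed as area-weighted aggregates.
    """
    if tau_color < 0:
        raise ValueError("tau_color must be >= 0")
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    if len(rt) <= 1:
        return rt

    index = {int(i): k for k, i in enumerate(rt.ids)}
    uf = _UnionFind(len(rt))
    for a, b in adjacency:
        if a in index and b in index:
            ia, ib = index[a], index[b]
            d = float(np.linalg.norm(rt.mean_colors[ia] - rt.mean_colors[ib]))
            if d < tau_color:
                uf.union(ia, ib)

    def group_rows() -> dict[int, list[int]]:
        g: dict[int, list[int]] = {}
        for k in range(len(rt)):
            g.setdefault(uf.find(k), []).append(k)
        return g

    # absorb small groups into the adjacent group of closest mean colour;
    # iterate because absorbing can change group areas
    root_adj: set[tuple[int, int]] = set()
    for a, b in adjacency:
        if a in index and b in index:
            ra, rb = uf.find(index[a]), uf.find(index[b])
            if ra != rb:
                root_adj.add((min(ra, rb), max(ra, rb)))
    changed = True
    while changed:
        changed = False
        groups = group_rows()
        areas = {r: int(rt.areas[rows].sum()) for r, rows in groups.items()}
        colors = {
            r: np.average(rt.mean_colors[rows], axis=0, weights=rt.areas[rows])
            for r, rows in groups.items()
        }
        for r in sorted(groups, key=lambda r: areas[r]):
            if areas[r] >= min_area:
                continue
            neigh = {
                (b if a == uf.find(r) else a)
                for a, b in {
                    (uf.find(x), uf.find(y)) for x, y in root_adj
                }
                if uf.find(r) in (a, b) and a != b
            }
            neigh.discard(uf.find(r))
            if not neigh:
                continue
            best = min(
                neigh, key=lambda n: float(np.linalg.norm(colors[r] - colors[n]))
            )
            uf.union(r, best)
            changed = True
            break

    groups = sorted(group_rows().values(), key=lambda g: min(g))
    return _aggregate(rt, groups)


def initial_centers(rt: RegionTable) -> CenterSet:
    """One seed center per region, at its centroid, carrying its mean colour."""
    if len(rt) == 0:
        raise ValueError("empty region table: no centers can be seeded")
    return CenterSet(
        positions=rt.centroids.copy(),
        colors=rt.mean_colors.copy(),
        areas=rt.areas.astype(float).copy(),
        features=None,
        source_region_ids=[[int(i)] for i in rt.ids],
    )
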