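"""Density-based clustering (DBSCAN) of positive pixels on a binary grid.

A positive pixel p is a *core* pixel when its Eps-neighborhood
NEps(p) = {q positive | dist(p, q) ≤ eps} (Euclidean pixel distance,
p included) holds at least ``min_pxl`` positive pixels.  Clusters are
the maximal sets of pixels density-reachable from a core pixel through
chains of core-pixel neighborhoods; positive pixels reachable from no
core pixel are noise.  Negative (background) pixels are never cluster
members and keep their own reserved label.

The scan runs row-major from the top-left, so labels — including the
cluster that wins a border pixel reachable from two clusters — are
fully deterministic.  Defaults ``eps=5`` / ``min_pxl=60`` are the
operating point used for dermoscopy lesions.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import BinaryMask

__all__ = [
    "BACKGROUND",
    "UNCLASSIFIED",
    "NOISE",
    "DbscanParams",
    "LabelMap",
    "disc_offsets",
    "eps_neighborhood",
    "expand_cluster",
    "dbscan",
    "select_lesion_mask",
]

# Reserved label values.  Cluster IDs are consecutive positive integers
# in first-assignment (scan) order.
BACKGROUND = -2  # negative pixel, never clustered
UNCLASSIFIED = -1  # positive pixel not yet visited
NOISE = 0  # positive pixel reachable from no core pixel


@dataclass(frozen=True)
class DbscanParams:
    """Neighborhood radius (pixels, Euclidean) and core density threshold."""

    eps: float = 5.0
    min_pxl: int = 60

    def __post_init__(self) -> None:
        if self.eps < 0:
            raise ValueError("eps must be >= 0")
        if self.min_pxl < 1:
            raise ValueError("min_pxl must be >= 1")


@dataclass(frozen=True)
class LabelMap:
    """Per-pixel cluster IDs plus the reserved BACKGROUND/NOISE values."""

    labels: np.ndarray
    n_clusters: int

    def cluster_sizes(self) -> np.ndarray:
        """Pixel count per cluster ID (index 0 unused)."""
        pos = self.labels[self.labels > 0]
        return np.bincount(pos, minlength=self.n_clusters + 1)


def disc_offsets(eps: float) -> np.ndarray:
    """Integer (drow, dcol) offsets with drow² + dcol² ≤ eps², row-major."""
    r = int(np.floor(eps))
    d = np.arange(-r, r + 1)
    dr, dc = np.meshgrid(d, d, indexing="ij")
    keep = dr**2 + dc**2 <= eps**2
    return np.stack([dr[keep], dc[keep]], axis=1)


def eps_neighborhood(
    mask: BinaryMask, p: tuple[int, int], eps: float
) -> set[tuple[int, int]]:
    """All in-bounds positive pixels within Euclidean distance eps of p.

    Includes p itself when p is positive; the image border simply
    truncates the disc.
    """
    h, w = mask.shape
    r, c = p
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"pixel {p} outside {h}×{w} grid")
    pts = np.array([r, c]) + disc_offsets(eps)
    ok = (pts[:, 0] >= 0) & (pts[:, 0] < h) & (pts[:, 1] >= 0) & (pts[:, 1] < w)
    pts = pts[ok]
    pos = mask.values[pts[:, 0], pts[:, 1]]
    return {(int(a), int(b)) for a, b in pts[pos]}


def _neighbor_counts(values: np.ndarray, eps: float) -> np.ndarray:
    """|NEps(p)| for every pixel, via disc-stencil convolution."""
    r = int(np.floor(eps))
    size = 2 * r + 1
    kernel = np.zeros((size, size), dtype=np.int64)
    offs = disc_offsets(eps)
    kernel[offs[:, 0] + r, offs[:, 1] + r] = 1
    return ndimage.convolve(values.astype(np.int64), kernel, mode="constant", cval=0)


def expand_cluster(
    mask: BinaryMask,
    labels: np.ndarray,
    seed: tuple[int, int],
    cluster_id: int,
    params: DbscanParams,
    _counts: np.ndarray | None = None,
    _offsets: np.ndarray | None = None,
) -> bool:
    """Grow ``cluster_id`` from ``seed`` by density-reachability.

    Returns False — marking the seed as provisional NOISE — when the
    seed fails the core test.  Otherwise labels the seed and every
    density-reachable positive pixel with ``cluster_id`` using a FIFO
    work-queue of core pixels: each queued core pixel's positive
    neighbors join the cluster; neighbors that are themselves core are
    enqueued; NOISE pixels encountered are absorbed as border pixels.
    """
    values = mask.values
    h, w = values.shape
    if not values[seed]:
        raise ValueError(f"seed {seed} is not a positive pixel")
    if labels[seed] != UNCLASSIFIED:
        raise ValueError(f"seed {seed} is already labeled")
    counts = _counts if _counts is not None else _neighbor_counts(values, params.eps)
    offsets = _offsets if _offsets is not None else disc_offsets(params.eps)

    if counts[seed] < params.min_pxl:
        labels[seed] = NOISE
        return False

    labels[seed] = cluster_id
    queue: deque[tuple[int, int]] = deque([seed])
    while queue:
        r, c = queue.popleft()
        pts = offsets + (r, c)
        ok = (pts[:, 0] >= 0) & (pts[:, 0] < h) & (pts[:, 1] >= 0) & (pts[:, 1] < w)
        pts = pts[ok]
        rows, cols = pts[:, 0], pts[:, 1]
        claim = values[rows, cols] & (
            (labels[rows, cols] == UNCLASSIFIED) | (labels[rows, cols] == NOISE)
        )
        rows, cols = rows[claim], cols[claim]
        was_unclassified = labels[rows, cols] == UNCLASSIFIED
        labels[rows, cols] = cluster_id
        # only previously-unvisited core pixels need expansion; a NOISE
        # pixel was already found non-core and stays a border member
        core = was_unclassified & (counts[rows, cols] >= params.min_pxl)
        for rr, cc in zip(rows[core], cols[core]):
            queue.append((int(rr), int(cc)))
    return True


def dbscan(mask: BinaryMask, params: DbscanParams | None = None) -> LabelMap:
    """Cluster the positive pixels of a binary mask.

    Row-major scan from (0, 0); each unclassified positive pixel passing
    the core test seeds a new cluster grown by :func:`expand_cluster`.
    Fully deterministic given mask and parameters.
    """
    params = params or DbscanParams()
    values = mask.values
    labels = np.where(values, UNCLASSIFIED, BACKGROUND).astype(np.int64)
    counts = _neighbor_counts(values, params.eps)
    offsets = disc_offsets(params.eps)

    cluster_id = 0
    for r, c in zip(*np.nonzero(values)):
        if labels[r, c] != UNCLASSIFIED:
            continue
        if expand_cluster(
            mask, labels, (int(r), int(c)), cluster_id + 1, params,
            _counts=counts, _offsets=offsets,
        ):
            cluster_id += 1
    return LabelMap(labels=labels, n_clusters=cluster_id)


def select_lesion_mask(
    label_map: LabelMap,
    policy: str = "largest",
    fill_holes: bool = True,
) -> BinaryMask:
    """Pick the lesion region out of a clustering.

    ``policy='largest'`` keeps the cluster with the most pixels;
    ``'all'`` keeps the union of all clusters.  Interior holes are
    filled by default (the lesion is a solid region).  An empty
    clustering yields an empty mask and a warning.
    """
    labels = label_map.labels
    if label_map.n_clusters == 0:
        warnings.warn("no clusters found; returning empty lesion mask", stacklevel=2)
        return BinaryMask(np.zeros(labels.shape, dtype=bool))
    if policy == "largest":
        sizes = label_map.cluster_sizes()
        sizes[0] = 0
        region = labels == int(np.argmax(sizes))
    elif policy == "all":
        region = labels > 0
    else:
        raise ValueError(f"unknown selection policy {policy!r}")
    if fill_holes:
        region = ndimage.binary_fill_holes(region)
    return BinaryMask(region)
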