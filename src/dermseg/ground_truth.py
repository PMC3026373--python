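"""Manual-border ground truth: filled closed quadratic B-spline masks.

A dermatologist-style border is given as an ordered list of control
points on the lesion boundary.  The points are used as de Boor control
points of a closed (periodic) degree-2 B-spline with uniform knots; the
curve is sampled densely, rasterized as a one-pixel-wide closed
polyline, and the enclosed region is obtained by flood-filling the
background from the image border and complementing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.interpolate import BSpline
from skimage.draw import line as draw_line

from .core_io import BinaryMask

__all__ = [
    "ControlPolygon",
    "read_control_points",
    "write_control_points",
    "sample_closed_bspline",
    "bspline_closed_mask",
]


@dataclass(frozen=True)
class ControlPolygon:
    """Ordered (row, col) control points inside an (H, W) image."""

    points: np.ndarray
    image_shape: tuple[int, int]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of (row, col)")
        if pts.shape[0] < 3:
            raise ValueError("a closed border needs at least 3 control points")
        h, w = self.image_shape
        if (
            pts[:, 0].min() < 0
            or pts[:, 1].min() < 0
            or pts[:, 0].max() > h - 1
            or pts[:, 1].max() > w - 1
        ):
            raise ValueError("control points must lie inside the image")
        object.__setattr__(self, "points", pts)


def read_control_points(path: str | Path, image_shape: tuple[int, int]) -> ControlPolygon:
    """Read a two-column plain-text point file (row col; '#' comments)."""
    pts = []
    for raw in Path(path).read_text().splitlines():
        text = raw.split("#", 1)[0].strip()
        if not text:
            continue
        r, c = text.split()
        pts.append((float(r), float(c)))
    return ControlPolygon(np.asarray(pts), image_shape)


def write_control_points(poly: ControlPolygon, path: str | Path) -> None:
    lines = [f"{r:g} {c:g}" for r, c in poly.points]
    Path(path).write_text("\n".join(lines) + "\n")


def sample_closed_bspline(points: np.ndarray, samples_per_segment: int) -> np.ndarray:
    """Densely sample the periodic uniform quadratic B-spline of the points.

    The n control points are wrapped (first two repeated) so that the
    spline closes; the returned polyline has n·samples_per_segment
    vertices covering the full period, endpoint excluded.
    """
    pts = np.asarray(points, dtype=np.float64)
    n = pts.shape[0]
    k = 2
    coeffs = np.vstack([pts, pts[:k]])
    knots = np.arange(n + 2 * k + 1, dtype=np.float64)
    spline = BSpline(knots, coeffs, k, axis=0)
    t = np.linspace(k, n + k, n * samples_per_segment, endpoint=False)
    return spline(t)


def _segments_intersect(curve: np.ndarray) -> tuple[int, int] | None:
    """First properly-intersecting non-adjacent segment pair, or None."""
    n = curve.shape[0]
    a = curve
    b = np.roll(curve, -1, axis=0)
    d = b - a
    for i in range(n - 2):
        # candidate partners: j > i+1, and skip the closing adjacency (0, n-1)
        j0 = i + 2
        j1 = n - 1 if i == 0 else n
        if j0 >= j1:
            continue
        aj = a[j0:j1]
        dj = d[j0:j1]
        denom = d[i, 0] * dj[:, 1] - d[i, 1] * dj[:, 0]
        rel = aj - a[i]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (rel[:, 0] * dj[:, 1] - rel[:, 1] * dj[:, 0]) / denom
            s = (rel[:, 0] * d[i, 1] - rel[:, 1] * d[i, 0]) / denom
        # endpoint touches between non-adjacent segments count: a simple
        # closed polyline never revisits a point away from its neighbors
        tol = 1e-9
        hit = (
            (np.abs(denom) > 1e-12)
            & (t >= -tol) & (t <= 1 + tol)
            & (s >= -tol) & (s <= 1 + tol)
        )
        if hit.any():
            return i, int(j0 + np.argmax(hit))
    return None


def bspline_closed_mask(
    poly: ControlPolygon, samples_per_segment: int = 32
) -> BinaryMask:
    """Rasterize and fill the closed quadratic B-spline of a control polygon.

    The filled region (curve pixels included) is returned as a mask of
    the polygon's image shape.  A self-intersecting sampled curve makes
    the fill undefined and raises ``ValueError`` naming the first
    intersecting segment pair.
    """
    if samples_per_segment < 2:
        raise ValueError("samples_per_segment must be >= 2")
    curve = sample_closed_bspline(poly.points, samples_per_segment)
    bad = _segments_intersect(curve)
    if bad is not None:
        raise ValueError(
            f"sampled curve self-intersects (segments {bad[0]} and {bad[1]}); "
            "fill is undefined"
        )
    h, w = poly.image_shape
    grid = np.zeros((h, w), dtype=bool)
    ij = np.rint(curve).astype(int)
    ij[:, 0] = np.clip(ij[:, 0], 0, h - 1)
    ij[:, 1] = np.clip(ij[:, 1], 0, w - 1)
    nxt = np.roll(ij, -1, axis=0)
    for (r0, c0), (r1, c1) in zip(ij, nxt):
        rr, cc = draw_line(r0, c0, r1, c1)
        grid[rr, cc] = True
    # flood the outside from the border; everything unreached is lesion
    outside = _flood_outside(grid)
    return BinaryMask(~outside)


def _flood_outside(curve: np.ndarray) -> np.ndarray:
    h, w = curve.shape
    free = ~curve
    comp, _ = ndimage.label(free, structure=ndimage.generate_binary_structure(2, 1))
    border_ids = np.unique(
        np.concatenate([comp[0, :], comp[-1, :], comp[:, 0], comp[:, -1]])
    )
    border_ids = border_ids[border_ids > 0]
    return np.isin(comp, border_ids)
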