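"""Fuzzy c-means segmentation of images over pixel colors.

FCM minimizes the objective

    F_m(u, c) = Σ_i Σ_j u_ij^m ||x_i − c_j||²

over membership degrees u_ij ∈ [0, 1] (rows summing to 1) and cluster
centers c_j, by alternating the two stationarity updates

    c_j  = Σ_i u_ij^m x_i / Σ_i u_ij^m
    u_ij = 1 / Σ_k ( d(x_i, c_j) / d(x_i, c_k) )^(2/(m−1))

until the membership matrix stops changing.  For image segmentation the
data are the n = H·W pixel RGB triples; a pixel whose maximum
membership falls below the percent threshold T stays unclassified, the
rest take their argmax cluster, and the lesion is the cluster with the
darkest (minimum-luminance) center, kept as its largest connected
component with holes filled.

Operating point: c=5 clusters, fuzzifier m=2, threshold T=30.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .core_io import BinaryMask, RasterImage
from .dbscan_seg import NOISE, LabelMap

__all__ = [
    "FcmParams",
    "MembershipMatrix",
    "membership_update",
    "centers_update",
    "fcm_objective",
    "fcm_fit",
    "fcm_segment_image",
]

_LUM = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class FcmParams:
    c: int = 5
    m: float = 2.0
    tol: float = 1e-5
    max_iter: int = 300
    seed: int = 0
    T: float = 30.0  # defuzzification threshold, percent

    def __post_init__(self) -> None:
        if self.c < 1:
            raise ValueError("c must be >= 1")
        if self.m <= 1:
            raise ValueError("fuzzification factor m must be > 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0 < self.T < 100:
            raise ValueError("T must lie in (0, 100)")


@dataclass
class MembershipMatrix:
    """Fit result: memberships, centers and the objective trace."""

    u: np.ndarray  # n × c, rows sum to 1
    centers: np.ndarray  # c × d
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True
    n_iter: int = 0


def membership_update(data: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    """Membership degrees of each point in each cluster.

    A point coinciding with one or more centers gets its mass split
    equally among the coinciding centers (the d=0 singularity rule).
    """
    if m <= 1:
        raise ValueError("fuzzification factor m must be > 1")
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    centers = np.atleast_2d(np.asarray(centers, dtype=np.float64))
    d2 = cdist(data, centers, metric="sqeuclidean")
    zero = d2 <= 0.0
    with np.errstate(divide="ignore"):
        w = d2 ** (-1.0 / (m - 1.0))
    u = np.where(zero, 0.0, w)
    singular = zero.any(axis=1)
    u[singular] = zero[singular].astype(np.float64)
    u /= u.sum(axis=1, keepdims=True)
    return u


def centers_update(data: np.ndarray, u: np.ndarray, m: float) -> np.ndarray:
    """u^m-weighted mean of the data per cluster."""
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    um = np.asarray(u, dtype=np.float64) ** m
    mass = um.sum(axis=0)
    if np.any(mass <= 0):
        raise ValueError("degenerate cluster: a membership column has zero total mass")
    return (um.T @ data) / mass[:, None]


def fcm_objective(
    data: np.ndarray, u: np.ndarray, centers: np.ndarray, m: float
) -> float:
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    centers = np.atleast_2d(np.asarray(centers, dtype=np.float64))
    d2 = cdist(data, centers, metric="sqeuclidean")
    return float(np.sum(np.asarray(u, dtype=np.float64) ** m * d2))


def fcm_fit(data: np.ndarray, params: FcmParams) -> MembershipMatrix:
    """Alternate center and membership updates from a seeded random start.

    The initial membership matrix is uniform-random with normalized
    rows; iteration stops when max |U^(k+1) − U^(k)| < tol or at
    ``max_iter`` (then ``converged`` is False).  Bitwise reproducible
    for a fixed seed.
    """
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    n = data.shape[0]
    if n < params.c:
        warnings.warn(
            f"fewer points ({n}) than clusters ({params.c})", stacklevel=2
        )
    rng = np.random.default_rng(params.seed)
    u = rng.random((n, params.c))
    u /= u.sum(axis=1, keepdims=True)

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        centers = centers_update(data, u, params.m)
        u_new = membership_update(data, centers, params.m)
        trace.append(fcm_objective(data, u_new, centers, params.m))
        delta = float(np.max(np.abs(u_new - u)))
        u = u_new
        if delta < params.tol:
            converged = True
            break
    return MembershipMatrix(
        u=u,
        centers=centers,
        objective_trace=np.asarray(trace),
        converged=converged,
        n_iter=it,
    )


def fcm_segment_image(
    image: RasterImage,
    params: FcmParams | None = None,
    lesion_cluster: int | str = "auto",
) -> tuple[BinaryMask, LabelMap, MembershipMatrix]:
    """Segment an image by FCM over its pixel RGB triples.

    Pixels whose maximum membership is below T/100 stay unclassified
    (NOISE in the label map); the rest take their argmax cluster (ties
    to the lowest index).  The lesion cluster is the one with the
    minimum-luminance center unless an explicit index is given; its
    mask is reduced to the largest 8-connected component, hole-filled.
    """
    params = params or FcmParams()
    h, w = image.shape
    data = image.pixels.reshape(-1, 3).astype(np.float64)
    fit = fcm_fit(data, params)

    max_u = fit.u.max(axis=1)
    assigned = fit.u.argmax(axis=1)  # argmax ties go to the lowest index
    classified = max_u >= params.T / 100.0

    labels = np.where(classified, assigned + 1, NOISE).reshape(h, w).astype(np.int64)
    label_map = LabelMap(labels=labels, n_clusters=params.c)

    if lesion_cluster == "auto":
        lesion = int(np.argmin(fit.centers @ _LUM))
    else:
        lesion = int(lesion_cluster)
        if not 0 <= lesion < params.c:
            raise ValueError(f"lesion cluster index {lesion} out of range")

    region = (labels == lesion + 1)
    if not region.any():
        warnings.warn("no pixel assigned to the lesion cluster; empty mask", stacklevel=2)
        return BinaryMask(region), label_map, fit

    comp, n_comp = ndimage.label(region, structure=np.ones((3, 3), dtype=int))
    if n_comp > 1:
        sizes = np.bincount(comp.ravel())
        sizes[0] = 0
        region = comp == int(np.argmax(sizes))
    region = ndimage.binary_fill_holes(region)
    return BinaryMask(region), label_map, fit
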