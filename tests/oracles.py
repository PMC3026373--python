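"""Independent reference implementations used only to check the package.

These are deliberately brute-force (quadratic pairwise distances,
exhaustive threshold scans, shoelace areas) and share no code with the
implementation under test.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


def brute_force_density_closure(values: np.ndarray, eps: float, min_pxl: int):
    """O(n²) density-reachability closure over the positive pixels.

    Returns (points, core, comp_of_core, reachable) where ``points`` is
    the (n, 2) array of positive pixel coordinates in row-major order,
    ``core`` a boolean core flag per point, ``comp_of_core`` the
    component id per point (-1 for non-core), and ``reachable`` a list
    per point of the component ids whose cores lie within eps (empty ⇒
    noise for non-core points).
    """
    pts = np.argwhere(values)
    n = len(pts)
    if n == 0:
        return pts, np.zeros(0, bool), np.full(0, -1), []
    diff = pts[:, None, :] - pts[None, :, :]
    adj = (diff[..., 0] ** 2 + diff[..., 1] ** 2) <= eps * eps
    core = adj.sum(axis=1) >= min_pxl

    comp_of_core = np.full(n, -1)
    core_idx = np.nonzero(core)[0]
    if len(core_idx):
        sub = adj[np.ix_(core_idx, core_idx)]
        _, comp = connected_components(csr_matrix(sub), directed=False)
        comp_of_core[core_idx] = comp

    reachable = []
    for i in range(n):
        comps = set(comp_of_core[j] for j in np.nonzero(adj[i] & core)[0])
        comps.discard(-1)
        reachable.append(comps)
    return pts, core, comp_of_core, reachable


def assert_dbscan_matches_closure(label_map, values, eps, min_pxl):
    """Check a clustering against the brute-force closure.

    Equivalence up to cluster-ID renaming: identical noise set,
    identical core partition, and every border pixel attached to a
    cluster whose cores can reach it.
    """
    from dermseg.dbscan_seg import BACKGROUND, NOISE, UNCLASSIFIED

    labels = label_map.labels
    assert not np.any(labels == UNCLASSIFIED)
    assert np.array_equal(labels == BACKGROUND, ~values)

    pts, core, comp_of_core, reachable = brute_force_density_closure(
        values, eps, min_pxl
    )
    impl = labels[pts[:, 0], pts[:, 1]]

    # noise ⇔ no core pixel within eps
    expect_noise = np.array([len(r) == 0 for r in reachable])
    assert np.array_equal(impl == NOISE, expect_noise)

    # core partition identical up to renaming (bijective id map)
    fwd: dict[int, int] = {}
    bwd: dict[int, int] = {}
    for lab, comp in zip(impl[core], comp_of_core[core]):
        assert lab > 0
        assert fwd.setdefault(int(lab), int(comp)) == comp
        assert bwd.setdefault(int(comp), int(lab)) == lab
    n_clusters = len(set(comp_of_core[core]))
    assert label_map.n_clusters == n_clusters

    # border pixels: must belong to a cluster that density-reaches them
    border = ~core & ~expect_noise
    for lab, comps in zip(impl[border], np.array(reachable, dtype=object)[border]):
        assert fwd[int(lab)] in comps


def otsu_variance_scan(intensity: np.ndarray) -> np.ndarray:
    """Between-class variance (up to a constant factor) for t = 0..254.

    Entries where one class is empty are -inf.  The Otsu threshold is
    the smallest argmax of this vector.
    """
    flat = np.asarray(intensity).ravel().astype(np.float64)
    out = np.full(255, -np.inf)
    for t in range(255):
        lo = flat[flat <= t]
        hi = flat[flat > t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        out[t] = len(lo) * len(hi) * (lo.mean() - hi.mean()) ** 2
    return out


def exhaustive_otsu(intensity: np.ndarray) -> int:
    """Smallest threshold maximizing between-class variance, by full scan."""
    scan = otsu_variance_scan(intensity)
    assert np.isfinite(scan).any(), "constant image"
    return int(np.argmax(scan))


def shoelace_area(curve: np.ndarray) -> float:
    """Exact polygon area of a closed sampled curve ((row, col) vertices)."""
    y, x = curve[:, 0], curve[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def disc_lattice_count(eps: float) -> int:
    """Number of integer offsets with dx² + dy² ≤ eps², by enumeration."""
    r = int(np.ceil(eps)) + 1
    count = 0
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            if dx * dx + dy * dy <= eps * eps:
                count += 1
    return count
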