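"""Independent reference implementations used only by the tests.

These deliberately use brute force / exact enumeration rather than the
package's own algorithms, so they can serve as oracles.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_min_energy(
    cost_fg: np.ndarray,
    cost_bg: np.ndarray,
    edges: np.ndarray,
    weights: np.ndarray,
    hard_fg: np.ndarray | None = None,
    hard_bg: np.ndarray | None = None,
) -> float:
    """Exhaustive minimum of the binary MRF energy over all labelings."""
    n = len(cost_fg)
    best = np.inf
    for bits in itertools.product([False, True], repeat=n):
        x = np.array(bits)
        if hard_fg is not None and not np.all(x[hard_fg]):
            continue
        if hard_bg is not None and np.any(x[hard_bg]):
            continue
        e = float(np.sum(np.where(x, cost_fg, cost_bg)))
        if len(edges):
            i, j = edges[:, 0], edges[:, 1]
            e += float(np.sum(weights[x[i] != x[j]]))
        best = min(best, e)
    return best


def exact_kmeans_1d_sse(values: np.ndarray, k: int) -> float:
    """Exact optimal within-cluster SSE for 1-D k-means.

    The optimal 1-D clustering partitions the sorted values into k
    contiguous runs; dynamic programming over split points finds the global
    optimum.
    """
    x = np.sort(np.asarray(values, dtype=np.float64))
    n = len(x)
    ps = np.concatenate([[0.0], np.cumsum(x)])
    ps2 = np.concatenate([[0.0], np.cumsum(x**2)])

    def seg_cost(i: int, j: int) -> float:
        # SSE of x[i:j]
        s, s2, m = ps[j] - ps[i], ps2[j] - ps2[i], j - i
        return s2 - s * s / m

    INF = float("inf")
    dp = np.full((k + 1, n + 1), INF)
    dp[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            dp[c, j] = min(
                dp[c - 1, i] + seg_cost(i, j) for i in range(c - 1, j)
            )
    return float(dp[k, n])


def oversampled_cylinder_volume(
    shape: tuple[int, int, int],
    spacing: float,
    center_xy: tuple[float, float],
    radius: float,
    z0: float,
    z1: float,
    factor: int = 5,
) -> tuple[float, int]:
    """Cylinder volume estimated by subdividing each voxel ``factor``^3 times.

    Returns (volume mm^3, number of partially covered voxels).
    """
    nx, ny, nz = shape
    sub = (np.arange(factor) + 0.5) / factor - 0.5  # sub-offsets in voxel units
    ox, oy, oz = np.meshgrid(sub, sub, sub, indexing="ij")
    offsets = np.stack([ox, oy, oz], axis=-1).reshape(-1, 3) * spacing

    vol = 0.0
    n_partial = 0
    vox_vol = spacing**3
    xs = np.arange(nx) * spacing
    ys = np.arange(ny) * spacing
    zs = np.arange(nz) * spacing
    # only voxels near the cylinder matter
    for ix, x in enumerate(xs):
        if abs(x - center_xy[0]) > radius + spacing:
            continue
        for iy, y in enumerate(ys):
            if np.hypot(x - center_xy[0], y - center_xy[1]) > radius + spacing:
                continue
            for iz, z in enumerate(zs):
                if z < z0 - spacing or z > z1 + spacing:
                    continue
                pts = np.array([x, y, z]) + offsets
                inside = (
                    (np.hypot(pts[:, 0] - center_xy[0], pts[:, 1] - center_xy[1]) <= radius)
                    & (pts[:, 2] >= z0)
                    & (pts[:, 2] <= z1)
                )
                frac = inside.mean()
                vol += frac * vox_vol
                if 0.0 < frac < 1.0:
                    n_partial += 1
    return vol, n_partial
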