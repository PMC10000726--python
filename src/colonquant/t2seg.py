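"""Quasi-automatic colon segmentation in T2 images from anatomical markers.

Stages
------
1. **Medial path**: minimum-cost voxel paths between consecutive markers on
   the 26-neighborhood graph, with edge cost = step length x (eps +
   robustly normalized intensity of the target voxel). Because the colonic
   lumen is dark in T2, the cheapest route between markers runs through the
   lumen. The concatenated path is smoothed and resampled.
2. **Tissue probability**: P(colon | intensity, distance-to-path) factored
   as a kernel-density intensity likelihood (fit on voxels near the path,
   mode rescaled to 1) times a sigmoid distance prior with scale r0.
3. **Graph cut**: binary MRF with -log probability unaries, contrast-
   modulated 6-neighborhood pairwise weights, path voxels as hard
   foreground and everything beyond 3 r0 as hard background; solved
   coarse-to-fine (multigrid) with a narrow-band full-resolution re-solve.
4. **Refinement**: include/exclude markers trigger a local re-solve inside
   a ball around each marker, with the marker voxel as a hard seed.
5. **Segment labels**: each colon voxel takes the segment of its nearest
   medial-path point (ascending/transverse/descending/pelvic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree
from scipy.stats import gaussian_kde
from skimage.measure import block_reduce

from . import graphcut
from .core_io import LabelVolume, MarkerSet, Modality, MRIVolume, ValidationError
from .paths import MedialPath, resample_polyline, smooth_polyline

__all__ = [
    "T2SegConfig",
    "TissueProbability",
    "PathError",
    "ModelError",
    "ConstraintError",
    "estimate_medial_path",
    "build_probability_model",
    "segment_t2",
    "apply_refinement",
    "assign_segments",
]


class PathError(RuntimeError):
    """Medial-path estimation failed."""


class ModelError(RuntimeError):
    """Probability model could not be fit."""


class ConstraintError(RuntimeError):
    """Hard segmentation constraints are infeasible."""


@dataclass
class T2SegConfig:
    r0: float = 15.0  # mm, scale of the distance-to-path prior
    lam: float = 2.0  # pairwise weight
    eps: float = 0.05  # floor of the path-cost intensity term
    resample_step_mm: float = 2.0
    smooth_window: int = 5
    path_pad_mm: float = 25.0  # search-box padding around each marker pair
    multigrid: bool = True
    coarse_factor: int = 4
    band_voxels: int = 3
    progressive_passes: int = 2  # 1 = single pass, 2 = re-center path once
    recenter_radius_mm: float = 6.0
    unary_clamp: tuple[float, float] = (1e-6, 1e6)
    kde_grid_size: int = 256
    kde_max_samples: int = 20000
    refine_radius_mm: float = 20.0


@dataclass
class TissueProbability:
    """P(colon | intensity, distance to medial path) on the T2 grid."""

    prob: np.ndarray
    params: dict = field(default_factory=dict)
    distance_mm: np.ndarray | None = None  # distance-to-path, reused for seeds


def _normalize_robust(data: np.ndarray) -> np.ndarray:
    p1, p99 = np.percentile(data, [1, 99])
    if p99 <= p1:
        return np.zeros_like(data)
    return np.clip((data - p1) / (p99 - p1), 0.0, 1.0)


_NEIGHBOR_OFFSETS = np.array(
    [(dx, dy, dz)
     for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
     if (dx, dy, dz) != (0, 0, 0)]
)


def _min_cost_voxel_path(
    norm: np.ndarray,
    spacing: np.ndarray,
    start: np.ndarray,
    goal: np.ndarray,
    eps: float,
    pad_vox: np.ndarray,
) -> np.ndarray:
    """Dijkstra shortest path between two voxels inside a padded box."""
    shape = np.array(norm.shape)
    lo = np.clip(np.minimum(start, goal) - pad_vox, 0, shape - 1)
    hi = np.clip(np.maximum(start, goal) + pad_vox + 1, 1, shape)
    box = norm[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    bshape = np.array(box.shape)
    n = int(np.prod(bshape))
    flat = box.reshape(-1)

    rows, cols, w = [], [], []
    idx3 = np.arange(n).reshape(tuple(bshape))
    for off in _NEIGHBOR_OFFSETS:
        src_sl, dst_sl = [], []
        for a in range(3):
            if off[a] >= 0:
                src_sl.append(slice(0, bshape[a] - off[a]))
                dst_sl.append(slice(off[a], bshape[a]))
            else:
                src_sl.append(slice(-off[a], bshape[a]))
                dst_sl.append(slice(0, bshape[a] + off[a]))
        s = idx3[tuple(src_sl)].reshape(-1)
        d = idx3[tuple(dst_sl)].reshape(-1)
        step = float(np.linalg.norm(off * spacing))
        rows.append(s)
        cols.append(d)
        w.append(step * (eps + flat[d]))
    graph = csr_matrix(
        (np.concatenate(w), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )
    src_flat = int(np.ravel_multi_index(start - lo, tuple(bshape)))
    dst_flat = int(np.ravel_multi_index(goal - lo, tuple(bshape)))
    dist, pred = dijkstra(
        graph, directed=True, indices=src_flat, return_predecessors=True
    )
    if not np.isfinite(dist[dst_flat]):
        raise PathError(f"no finite-cost path between voxels {start} and {goal}")
    chain = [dst_flat]
    while chain[-1] != src_flat:
        chain.append(int(pred[chain[-1]]))
    chain.reverse()
    vox = np.array(np.unravel_index(chain, tuple(bshape))).T + lo
    return vox


def estimate_medial_path(
    t2: MRIVolume,
    markers: MarkerSet | np.ndarray,
    config: T2SegConfig | None = None,
) -> MedialPath:
    """Colon centerline through the anatomical markers, in order.

    ``markers`` may be a full :class:`MarkerSet` (boundary indices are then
    recorded on the path) or a bare (n, 3) array of ordered world points
    with n >= 2.
    """
    cfg = config or T2SegConfig()
    if isinstance(markers, MarkerSet):
        pts = markers.points
        tags = [m.tag for m in markers.anatomical]
    else:
        pts = np.atleast_2d(np.asarray(markers, dtype=np.float64))
        tags = None
    if len(pts) < 2:
        raise PathError(f"need at least 2 markers, got {len(pts)}")
    inb = t2.in_bounds(pts)
    if not np.all(inb):
        raise PathError(f"markers outside the volume: indices {np.where(~inb)[0].tolist()}")

    norm = _normalize_robust(t2.data)
    vox = np.rint(t2.world_to_voxel(pts)).astype(int)
    pad_vox = np.maximum(np.rint(cfg.path_pad_mm / t2.spacing).astype(int), 2)

    pieces = []
    for k in range(len(vox) - 1):
        try:
            piece = _min_cost_voxel_path(norm, t2.spacing, vox[k], vox[k + 1], cfg.eps, pad_vox)
        except PathError as e:
            raise PathError(f"marker pair {k}->{k + 1}: {e}") from e
        world = t2.voxel_to_world(piece.astype(np.float64))
        world[0], world[-1] = pts[k], pts[k + 1]
        pieces.append(world if k == 0 else world[1:])
    poly = np.vstack(pieces)

    # de-duplicate consecutive identical points (marker snapping can collide)
    keep = np.ones(len(poly), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(poly, axis=0), axis=1) > 1e-9
    poly = poly[keep]

    # pin the marker vertices during smoothing so the path keeps passing
    # through every specialist-provided point
    marker_tree = cKDTree(poly)
    _, pin_idx = marker_tree.query(pts)
    poly = smooth_polyline(poly, cfg.smooth_window, pinned=pin_idx)
    poly = resample_polyline(poly, cfg.resample_step_mm)

    boundary_indices = np.array([], dtype=int)
    if tags is not None:
        tree = cKDTree(poly)
        b_idx = [int(tree.query(p)[1]) for p, t in zip(pts, tags) if t != "intermediate"]
        b_idx[0], b_idx[-1] = 0, len(poly) - 1
        for k in range(1, len(b_idx)):
            if b_idx[k] <= b_idx[k - 1]:
                b_idx[k] = b_idx[k - 1] + 1
        boundary_indices = np.array(b_idx)
    return MedialPath(points=poly, boundary_indices=boundary_indices)


def build_probability_model(
    t2: MRIVolume, path: MedialPath, r0: float, config: T2SegConfig | None = None
) -> TissueProbability:
    """KDE intensity likelihood x sigmoid distance prior.

    prob(v) = L(I(v)) * D(d(v)) with L a kernel-density estimate over
    intensities sampled within r0/2 of the path (rescaled so its mode is 1)
    and D(d) = 1 / (1 + exp((d - r0) / (r0 / 4))).
    """
    cfg = config or T2SegConfig()
    if r0 <= 0:
        raise ModelError(f"r0 must be positive, got {r0}")
    if len(path.points) == 0:
        raise ModelError("empty medial path")
    dense = resample_polyline(path.points, 1.0)
    tree = cKDTree(dense)
    grid = MRIVolume(
        np.zeros(t2.shape), t2.spacing, t2.origin, Modality.T2
    ).grid_points().reshape(-1, 3)
    dist, _ = tree.query(grid)
    dist = dist.reshape(t2.shape)

    core = dist <= r0 / 2.0
    samples = t2.data[core]
    if samples.size == 0:
        raise ModelError(f"no voxels within r0/2 = {r0 / 2} mm of the path")
    if samples.size > cfg.kde_max_samples:
        rng = np.random.default_rng(0)  # fixed: the model must be deterministic
        samples = rng.choice(samples, size=cfg.kde_max_samples, replace=False)
    if np.ptp(samples) == 0:
        # constant core intensity: likelihood is flat, prior does all the work
        likelihood = np.ones(t2.shape)
        igrid, lgrid = np.array([samples[0]]), np.array([1.0])
    else:
        kde = gaussian_kde(samples, bw_method="silverman")
        igrid = np.linspace(float(t2.data.min()), float(t2.data.max()), cfg.kde_grid_size)
        lgrid = kde(igrid)
        lgrid = lgrid / lgrid.max()
        likelihood = np.interp(t2.data, igrid, lgrid)

    prior = 1.0 / (1.0 + np.exp(np.clip((dist - r0) / (r0 / 4.0), -60, 60)))
    prob = np.clip(likelihood * prior, 0.0, 1.0)
    return TissueProbability(
        prob=prob,
        params={"r0": r0, "intensity_grid": igrid, "likelihood_grid": lgrid},
        distance_mm=dist,
    )


def _pairwise_edges(
    shape: tuple[int, int, int], intensity: np.ndarray, spacing: np.ndarray, lam: float
) -> tuple[np.ndarray, np.ndarray]:
    """6-neighborhood contrast-weighted edges over a full grid."""
    idx3 = np.arange(int(np.prod(shape))).reshape(shape)
    flat = intensity.reshape(-1)
    all_e, all_di, all_len = [], [], []
    for a in range(3):
        sl_s = [slice(None)] * 3
        sl_d = [slice(None)] * 3
        sl_s[a] = slice(0, shape[a] - 1)
        sl_d[a] = slice(1, shape[a])
        s = idx3[tuple(sl_s)].reshape(-1)
        d = idx3[tuple(sl_d)].reshape(-1)
        all_e.append(np.stack([s, d], axis=1))
        all_di.append(np.abs(flat[s] - flat[d]))
        all_len.append(np.full(len(s), float(spacing[a])))
    edges = np.vstack(all_e)
    di = np.concatenate(all_di)
    elen = np.concatenate(all_len)
    sigma_c = float(np.median(di))
    if sigma_c <= 0:
        sigma_c = max(float(di.mean()), 1e-6)
    weights = lam * np.exp(-(di**2) / (2 * sigma_c**2)) / elen
    return edges, weights


def _unaries(prob_flat: np.ndarray, clamp: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    # probabilities are clipped away from {0, 1} so the -log terms stay
    # ~20 rather than saturating the clamp; beyond that point the unary is
    # effectively infinite relative to any pairwise sum anyway
    p = np.clip(prob_flat, 1e-9, 1.0 - 1e-9)
    lo, hi = clamp
    c_fg = np.clip(-np.log(p), lo, hi)
    c_bg = np.clip(-np.log(1.0 - p), lo, hi)
    return c_fg, c_bg


def _solve_level(
    prob: np.ndarray,
    intensity: np.ndarray,
    spacing: np.ndarray,
    hard_fg: np.ndarray,
    hard_bg: np.ndarray,
    cfg: T2SegConfig,
    restrict: np.ndarray | None = None,
    frozen_labels: np.ndarray | None = None,
) -> np.ndarray:
    """One graph-cut solve; optionally restricted to a band of free voxels.

    Outside ``restrict`` (when given) the voxels keep ``frozen_labels`` and
    act as contracted seeds for their in-band neighbors.
    """
    shape = prob.shape
    edges, weights = _pairwise_edges(shape, intensity, spacing, cfg.lam)
    c_fg, c_bg = _unaries(prob.reshape(-1), cfg.unary_clamp)
    efg = hard_fg.reshape(-1)
    ebg = hard_bg.reshape(-1)
    if np.any(efg & ebg):
        raise ConstraintError("conflicting hard constraints (marker in a hard-background region)")
    hf, hb = efg.copy(), ebg.copy()
    if restrict is not None:
        # frozen labels outside the band act as seeds, but explicit
        # constraints take precedence over them
        frozen = ~restrict.reshape(-1)
        fl = frozen_labels.reshape(-1)
        hf |= frozen & fl & ~ebg
        hb |= frozen & ~fl & ~efg
    labels = graphcut.min_cut(c_fg, c_bg, edges, weights, hard_fg=hf, hard_bg=hb)
    return labels.reshape(shape)


def _segment_once(
    t2: MRIVolume, path: MedialPath, cfg: T2SegConfig
) -> np.ndarray:
    """One probability-model + graph-cut pass for a given medial path."""
    tp = build_probability_model(t2, path, cfg.r0, cfg)
    prob = tp.prob
    dist = tp.distance_mm

    hard_fg = np.zeros(t2.shape, dtype=bool)
    path_vox = np.rint(t2.world_to_voxel(path.points)).astype(int)
    inb = np.all((path_vox >= 0) & (path_vox < np.array(t2.shape)), axis=1)
    pv = path_vox[inb]
    hard_fg[pv[:, 0], pv[:, 1], pv[:, 2]] = True
    hard_bg = dist > 3.0 * cfg.r0
    hard_bg &= ~hard_fg

    if cfg.multigrid:
        f = cfg.coarse_factor
        block = (f, f, f)
        prob_c = block_reduce(prob, block, np.mean)
        int_c = block_reduce(t2.data, block, np.mean)
        fg_c = block_reduce(hard_fg, block, np.max)
        bg_c = block_reduce(hard_bg, block, np.min) & ~fg_c
        coarse = _solve_level(prob_c, int_c, t2.spacing * f, fg_c, bg_c, cfg)
        up = np.repeat(np.repeat(np.repeat(coarse, f, 0), f, 1), f, 2)
        up = up[: t2.shape[0], : t2.shape[1], : t2.shape[2]]
        b = cfg.band_voxels
        band = ndimage.binary_dilation(up, iterations=b) & ~ndimage.binary_erosion(
            up, iterations=b, border_value=0
        )
        mask = _solve_level(
            prob, t2.data, t2.spacing, hard_fg, hard_bg, cfg,
            restrict=band, frozen_labels=up,
        )
    else:
        mask = _solve_level(prob, t2.data, t2.spacing, hard_fg, hard_bg, cfg)
    return mask


def recenter_path(
    path: MedialPath,
    mask: np.ndarray,
    spacing: np.ndarray,
    origin: np.ndarray,
    cfg: T2SegConfig | None = None,
) -> MedialPath:
    """Pull each path vertex to the deepest mask interior nearby.

    A minimum-cost path through a dark lumen hugs the inner wall of bends;
    snapping each vertex to the local maximum of the mask's Euclidean
    distance transform (within ``recenter_radius_mm``) recovers a true
    centerline, which sharpens the distance prior on the next pass.
    """
    cfg = cfg or T2SegConfig()
    if not np.any(mask):
        return path
    edt = ndimage.distance_transform_edt(mask, sampling=spacing)
    shape = np.array(mask.shape)
    rad_vox = np.maximum(np.rint(cfg.recenter_radius_mm / np.asarray(spacing)).astype(int), 1)
    offsets = np.stack(
        np.meshgrid(*[np.arange(-r, r + 1) for r in rad_vox], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    keep_mm = np.linalg.norm(offsets * spacing, axis=1) <= cfg.recenter_radius_mm
    offsets = offsets[keep_mm]
    new_pts = path.points.copy()
    vox = np.rint((path.points - origin) / spacing).astype(int)
    for i, v in enumerate(vox):
        cand = v + offsets
        ok = np.all((cand >= 0) & (cand < shape), axis=1)
        cand = cand[ok]
        vals = edt[cand[:, 0], cand[:, 1], cand[:, 2]]
        j = int(np.argmax(vals))
        if vals[j] > 0:
            new_pts[i] = cand[j] * spacing + origin
    keep = np.ones(len(new_pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(new_pts, axis=0), axis=1) > 1e-9
    new_pts = new_pts[keep]
    old_b = path.points[path.boundary_indices] if len(path.boundary_indices) else None
    new_pts = smooth_polyline(new_pts, cfg.smooth_window)
    new_pts = resample_polyline(new_pts, cfg.resample_step_mm)
    boundary_indices = np.array([], dtype=int)
    if old_b is not None:
        tree = cKDTree(new_pts)
        b_idx = [int(tree.query(p)[1]) for p in old_b]
        b_idx[0], b_idx[-1] = 0, len(new_pts) - 1
        for k in range(1, len(b_idx)):
            if b_idx[k] <= b_idx[k - 1]:
                b_idx[k] = b_idx[k - 1] + 1
        boundary_indices = np.array(b_idx)
    return MedialPath(points=new_pts, boundary_indices=boundary_indices)


def segment_t2(
    t2: MRIVolume,
    markers: MarkerSet,
    config: T2SegConfig | None = None,
    path: MedialPath | None = None,
) -> LabelVolume:
    """Marker-guided colon segmentation of a T2 volume.

    Returns segment labels (1 ascending .. 4 pelvic) on the T2 grid. The
    binary mask is the globally optimal graph cut at the coarse level,
    refined at full resolution inside a narrow band around the coarse
    boundary. The progressive mode (default) re-centers the medial path on
    the provisional mask and re-solves, which corrects the corner-cutting
    of the initial marker-to-marker path. The largest 26-connected
    component containing the most markers is kept.
    """
    cfg = config or T2SegConfig()
    markers.validate_against(t2)
    if path is None:
        path = estimate_medial_path(t2, markers, cfg)
    mask = _segment_once(t2, path, cfg)
    for _ in range(max(cfg.progressive_passes - 1, 0)):
        path = recenter_path(path, mask, t2.spacing, t2.origin, cfg)
        mask = _segment_once(t2, path, cfg)

    mask = _keep_marker_component(mask, t2, markers)
    return assign_segments(mask, path, spacing=t2.spacing, origin=t2.origin)


def _keep_marker_component(mask: np.ndarray, t2: MRIVolume, markers: MarkerSet) -> np.ndarray:
    """Largest 26-connected component containing the most anatomical markers."""
    structure = np.ones((3, 3, 3), dtype=bool)
    comp, n = ndimage.label(mask, structure=structure)
    if n <= 1:
        return mask
    mvox = np.rint(t2.world_to_voxel(markers.points)).astype(int)
    mvox = np.clip(mvox, 0, np.array(t2.shape) - 1)
    marker_comp = comp[mvox[:, 0], mvox[:, 1], mvox[:, 2]]
    counts = np.bincount(marker_comp[marker_comp > 0], minlength=n + 1)
    if counts.max() == 0:
        sizes = np.bincount(comp.reshape(-1), minlength=n + 1)
        best = int(np.argmax(sizes[1:]) + 1)
    else:
        candidates = np.where(counts == counts.max())[0]
        sizes = np.bincount(comp.reshape(-1), minlength=n + 1)
        best = int(candidates[np.argmax(sizes[candidates])])
    if counts[best] < len(mvox):
        warnings.warn(
            f"{len(mvox) - counts[best]} anatomical marker(s) fall outside the kept component",
            stacklevel=2,
        )
    return comp == best


def assign_segments(
    mask: np.ndarray | LabelVolume,
    path: MedialPath,
    spacing: np.ndarray | None = None,
    origin: np.ndarray | None = None,
) -> LabelVolume:
    """Label each colon voxel by the segment of its nearest path point.

    Equidistant voxels go to the lower segment index.
    """
    if isinstance(mask, LabelVolume):
        spacing, origin = mask.spacing, mask.origin
        mask_arr = mask.mask()
    else:
        mask_arr = np.asarray(mask, dtype=bool)
        if spacing is None or origin is None:
            raise ValueError("spacing and origin required for a bare mask array")
    if not np.any(mask_arr):
        raise ValidationError("empty mask")
    if len(path.boundary_indices) != 5:
        raise ValidationError("path must carry the 5 boundary tags")
    vox = np.argwhere(mask_arr)
    world = vox * np.asarray(spacing) + np.asarray(origin)
    b = path.boundary_indices
    dists = np.empty((4, len(world)))
    for k in range(1, 5):
        seg_pts = path.points[b[k - 1]: b[k] + 1]
        d, _ = cKDTree(seg_pts).query(world)
        dists[k - 1] = d
    # round to break near-ties deterministically in favor of the lower label
    seg = np.argmin(np.round(dists, 9), axis=0) + 1
    labels = np.zeros(mask_arr.shape, dtype=np.int16)
    labels[vox[:, 0], vox[:, 1], vox[:, 2]] = seg
    return LabelVolume(labels, np.asarray(spacing), np.asarray(origin), Modality.T2)


def apply_refinement(
    t2: MRIVolume,
    seg: LabelVolume,
    markers: MarkerSet,
    config: T2SegConfig | None = None,
    path: MedialPath | None = None,
) -> LabelVolume:
    """Correct a segmentation with include/exclude refinement markers.

    Re-solves the full-resolution graph cut inside a ball (default radius
    20 mm) around each refinement marker, with the marker voxel as a hard
    seed of its polarity; labels outside the balls are frozen.
    """
    cfg = config or T2SegConfig()
    if not markers.refinement:
        return LabelVolume(seg.labels.copy(), seg.spacing, seg.origin, seg.space)
    markers.validate_against(t2)
    if path is None:
        path = estimate_medial_path(t2, markers, cfg)
    tp = build_probability_model(t2, path, cfg.r0, cfg)

    grid = MRIVolume(
        np.zeros(t2.shape), t2.spacing, t2.origin, Modality.T2
    ).grid_points().reshape(-1, 3)
    region = np.zeros(int(np.prod(t2.shape)), dtype=bool)
    hard_fg = np.zeros(t2.shape, dtype=bool)
    hard_bg = np.zeros(t2.shape, dtype=bool)
    for p, pol in markers.refinement:
        region |= np.linalg.norm(grid - p, axis=1) <= cfg.refine_radius_mm
        v = tuple(np.rint(t2.world_to_voxel(p)).astype(int))
        if pol == "include":
            hard_fg[v] = True
        else:
            hard_bg[v] = True
    region = region.reshape(t2.shape)
    prev = seg.mask()
    mask = _solve_level(
        tp.prob, t2.data, t2.spacing, hard_fg, hard_bg, cfg,
        restrict=region, frozen_labels=prev,
    )
    return assign_segments(mask, path, spacing=t2.spacing, origin=t2.origin)
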