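"""Colonic content classification and morphology quantification.

Content: in-mask T1-FS intensities are clustered by 1-D k-means (default
k = 3). Clusters are ordered by centroid; the darkest is gas, the brightest
solid (feces), and intermediate clusters carry a solid fraction that
interpolates linearly in centroid intensity between those extremes. Volumes
are reported per colon segment in mL, together with a fraction-weighted
"solid-equivalent" volume.

Morphology: segment lengths come from the medial-path arc length; at regular
arc-length stations the mask is resampled on a plane orthogonal to the path
tangent, and the cross-section containing the path point yields a perimeter
(sub-pixel marching-squares contour) and a mean radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage import measure
from sklearn.cluster import KMeans

from .core_io import SEGMENT_NAMES, ContentReport, LabelVolume, MRIVolume
from .paths import MedialPath

__all__ = [
    "ContentClassMap",
    "DegenerateInputError",
    "MorphologyError",
    "classify_content",
    "quantify_content",
    "compute_morphology",
    "class_names",
]


class DegenerateInputError(ValueError):
    pass


class MorphologyError(RuntimeError):
    pass


def class_names(k: int) -> list[str]:
    """gas, mixed(...), solid — ordered from darkest to brightest cluster."""
    if k == 2:
        return ["gas", "solid"]
    if k == 3:
        return ["gas", "mixed", "solid"]
    return ["gas"] + [f"mixed_{i}" for i in range(1, k - 1)] + ["solid"]


@dataclass
class ContentClassMap:
    """Per-voxel content class inside the colon mask.

    ``classes`` holds the cluster rank (0 = gas .. k-1 = solid) inside the
    mask and -1 outside; ``solid_fraction`` maps each voxel's cluster to its
    solid percentage: 0 for gas, 1 for solid, linear in centroid intensity
    in between.
    """

    classes: np.ndarray
    solid_fraction: np.ndarray
    centroids: np.ndarray
    k: int
    names: list[str] = field(default_factory=list)


def _exact_kmeans_1d(values: np.ndarray, weights: np.ndarray, k: int) -> np.ndarray:
    """Optimal contiguous partition of sorted weighted values into k runs.

    Returns the k-1 boundary indices b such that cluster r covers unique-
    value indices (b[r-1], b[r]] (with b[-1] = -1 implied).
    """
    u = values.size
    pw = np.concatenate([[0.0], np.cumsum(weights)])
    pwx = np.concatenate([[0.0], np.cumsum(weights * values)])
    pwx2 = np.concatenate([[0.0], np.cumsum(weights * values**2)])

    def seg(i: int, j: int) -> float:  # SSE of values[i:j]
        w, s, s2 = pw[j] - pw[i], pwx[j] - pwx[i], pwx2[j] - pwx2[i]
        return s2 - s * s / w

    INF = float("inf")
    dp = np.full((k + 1, u + 1), INF)
    choice = np.zeros((k + 1, u + 1), dtype=int)
    dp[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, u + 1):
            best, arg = INF, c - 1
            for i in range(c - 1, j):
                cand = dp[c - 1, i] + seg(i, j)
                if cand < best:
                    best, arg = cand, i
            dp[c, j] = best
            choice[c, j] = arg
    bounds = []
    j = u
    for c in range(k, 0, -1):
        i = choice[c, j]
        bounds.append(i - 1)
        j = i
    return np.array(sorted(bounds[:-1]))  # k-1 inner boundaries (end indices)


def classify_content(
    t1fs: MRIVolume, seg: LabelVolume, k: int = 3, seed: int = 0
) -> ContentClassMap:
    """1-D k-means over in-mask intensities.

    When the number of distinct intensities is small the exact global
    optimum is computed by dynamic programming over the sorted values
    (1-D k-means clusters are contiguous runs); otherwise Lloyd's
    algorithm with k-means++ initialization and 20 seeded restarts is
    used. ``seed`` only affects the Lloyd path.
    """
    if t1fs.shape != seg.shape:
        raise ValueError(f"grid mismatch: {t1fs.shape} vs {seg.shape}")
    mask = seg.mask()
    vals = t1fs.data[mask]
    if vals.size == 0:
        raise DegenerateInputError("empty segmentation")
    n_distinct = np.unique(vals).size
    if n_distinct < k:
        raise DegenerateInputError(
            f"only {n_distinct} distinct in-mask intensities; cannot form k={k} clusters"
        )
    uniq, inv, counts = np.unique(vals, return_inverse=True, return_counts=True)
    if uniq.size <= 1024:
        # 1-D k-means is exactly solvable: optimal clusters are contiguous
        # runs of the sorted values, found by dynamic programming over the
        # weighted unique values
        boundaries = _exact_kmeans_1d(uniq, counts.astype(np.float64), k)
        rank_of_uniq = np.searchsorted(boundaries, np.arange(uniq.size), side="left")
        assign = rank_of_uniq[inv]
        centroids = np.array([
            np.average(uniq[assign_range], weights=counts[assign_range])
            for assign_range in (rank_of_uniq == r for r in range(k))
        ])
    else:
        km = KMeans(n_clusters=k, init="k-means++", n_init=20, max_iter=500, tol=1e-12,
                    random_state=seed)
        assign = km.fit_predict(vals.reshape(-1, 1))
        centroids = km.cluster_centers_.reshape(-1)
    order = np.argsort(centroids)
    rank_of = np.empty(k, dtype=int)
    rank_of[order] = np.arange(k)
    ranks = rank_of[assign]
    centroids_sorted = centroids[order]

    c_gas, c_solid = centroids_sorted[0], centroids_sorted[-1]
    span = c_solid - c_gas
    frac_of_rank = (centroids_sorted - c_gas) / span if span > 0 else np.zeros(k)

    classes = np.full(seg.shape, -1, dtype=np.int16)
    classes[mask] = ranks
    solid_fraction = np.zeros(seg.shape, dtype=np.float64)
    solid_fraction[mask] = frac_of_rank[ranks]
    return ContentClassMap(
        classes=classes,
        solid_fraction=solid_fraction,
        centroids=centroids_sorted,
        k=k,
        names=class_names(k),
    )


def quantify_content(
    cmap: ContentClassMap, seg: LabelVolume, spacing: np.ndarray | None = None
) -> ContentReport:
    """Per-segment and total class volumes (mL) plus solid-equivalent volume."""
    if cmap.classes.shape != seg.shape:
        raise ValueError(f"grid mismatch: {cmap.classes.shape} vs {seg.shape}")
    sp = np.asarray(spacing if spacing is not None else seg.spacing, dtype=np.float64)
    vox_ml = float(np.prod(sp)) / 1000.0
    names = cmap.names
    volumes: dict[str, dict[str, float]] = {}
    totals = {name: 0.0 for name in names}
    for seg_id, seg_name in SEGMENT_NAMES.items():
        in_seg = seg.labels == seg_id
        row = {}
        for rank, name in enumerate(names):
            count = int(np.count_nonzero(in_seg & (cmap.classes == rank)))
            row[name] = count * vox_ml
            totals[name] += row[name]
        volumes[seg_name] = row
    totals["total"] = float(sum(v for kk, v in totals.items() if kk != "total"))
    solid_equiv = float(np.sum(cmap.solid_fraction[seg.mask()])) * vox_ml
    return ContentReport(
        volumes_ml=volumes, totals_ml=totals, solid_equivalent_ml=solid_equiv
    )


def _plane_basis(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = tangent / np.linalg.norm(tangent)
    a = np.zeros(3)
    a[np.argmin(np.abs(t))] = 1.0
    u = np.cross(t, a)
    u /= np.linalg.norm(u)
    v = np.cross(t, u)
    return u, v


def compute_morphology(
    seg: LabelVolume,
    path: MedialPath,
    step: float = 10.0,
    pitch: float = 0.5,
    extent: float = 80.0,
) -> dict[str, dict[str, float]]:
    """Per-segment length, mean cross-section perimeter and mean radius (mm).

    Cross-sections are sampled every ``step`` mm of arc length on a 2D grid
    (``pitch`` mm, ``extent`` mm across) in the plane orthogonal to the path
    tangent; the sub-pixel 0.5-level contour of the component containing the
    path point gives the perimeter, and the mean contour distance to the
    path point gives the radius. Stations where the path point lies outside
    the mask are skipped (with a warning count); if every station is
    skipped the morphology is undefined.
    """
    if len(path.points) < 2:
        raise MorphologyError("path has no arc; morphology is undefined")
    if len(path.boundary_indices) != 5:
        raise MorphologyError("path must carry the 5 segment boundaries")
    mask = np.asarray(seg.mask(), dtype=np.float64)
    tangents = path.tangents()
    seg_lengths = path.segment_lengths()

    half = extent / 2.0
    coords_1d = np.arange(-half, half + pitch / 2, pitch)
    uu, vv = np.meshgrid(coords_1d, coords_1d, indexing="ij")
    npix = len(coords_1d)
    center_px = np.array([half / pitch, half / pitch])

    stations = np.arange(0.0, path.total_length + step / 2, step)
    per_seg: dict[int, list[tuple[float, float]]] = {s: [] for s in range(1, 5)}
    skipped = 0
    for s in stations:
        i = int(np.argmin(np.abs(path.arc_length - s)))
        center = path.points[i]
        seg_id = int(path.segment_of_index(np.array([i]))[0])
        u, v = _plane_basis(tangents[i])
        pts = center + uu[..., None] * u + vv[..., None] * v
        idx = ((pts.reshape(-1, 3) - seg.origin) / seg.spacing).T
        section = map_coordinates(mask, idx, order=1, mode="constant", cval=0.0)
        section = section.reshape(npix, npix)
        # soften the voxelization staircase before contouring; the blur
        # radius is about one source voxel, so the 0.5 level stays put
        # while the contour length stops overcounting the steps
        blur_px = float(np.mean(seg.spacing)) / pitch / 2.0
        section = gaussian_filter(section, sigma=blur_px)
        ci = int(round(center_px[0]))
        if section[ci, ci] < 0.5:
            skipped += 1
            continue
        binary = section >= 0.5
        comp = measure.label(binary, connectivity=2)
        comp_id = comp[ci, ci]
        # sub-pixel contour of the continuous field, restricted to the
        # component containing the path point
        level_img = np.where((comp == comp_id) | ~binary, section, 0.0)
        contours = measure.find_contours(level_img, 0.5)
        chosen = None
        for contour in contours:
            if measure.points_in_poly(center_px.reshape(1, 2), contour)[0]:
                chosen = contour
                break
        if chosen is None:
            skipped += 1
            continue
        d = np.diff(chosen, axis=0)
        perimeter = float(np.sum(np.linalg.norm(d, axis=1))) * pitch
        radius = float(np.mean(np.linalg.norm(chosen - center_px, axis=1))) * pitch
        per_seg[seg_id].append((perimeter, radius))

    if all(len(v) == 0 for v in per_seg.values()):
        raise MorphologyError("every morphology station was skipped; mask/path mismatch")
    if skipped:
        warnings.warn(f"{skipped} morphology station(s) skipped", stacklevel=2)

    out: dict[str, dict[str, float]] = {}
    for seg_id, rows in per_seg.items():
        name = SEGMENT_NAMES[seg_id]
        entry = {"length_mm": seg_lengths[seg_id]}
        if rows:
            arr = np.asarray(rows)
            entry["mean_perimeter_mm"] = float(arr[:, 0].mean())
            entry["mean_radius_mm"] = float(arr[:, 1].mean())
        else:
            entry["mean_perimeter_mm"] = float("nan")
            entry["mean_radius_mm"] = float("nan")
        out[name] = entry
    return out
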