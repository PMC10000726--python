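"""Automatic colon segmentation in T1-FS images.

The T1-FS colon boundary is invisible wherever no feces is present (gas and
fat are both dark), so the segmentation is not computed from the T1-FS
image alone. Instead:

1. A non-rigid transformation from T2 to T1-FS space is estimated by
   multiresolution free-form (B-spline) registration with a mutual-
   information similarity metric, composed with an initial translation-only
   alignment.
2. The validated T2 colon segmentation is pushed through that field into
   T1-FS space (inverse-mapped nearest-label resampling — labels are never
   linearly interpolated).
3. A closed triangle surface of the transferred mask is then adapted
   iteratively: vertices move along their outward normals toward adjacent
   fecal content (bright voxels under a two-component intensity mixture
   model), with Laplacian smoothing and a displacement corridor that
   preserves the transferred T2 shape. Where the image carries no content
   evidence — gas, fat, tissue — the surface stays where the T2 shape put
   it, because nothing in a fat-saturated image marks the true wall there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from scipy.ndimage import map_coordinates
from scipy.sparse import csr_matrix
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes
from sklearn.isotonic import IsotonicRegression
from sklearn.mixture import GaussianMixture

from .core_io import LabelVolume, Modality, MRIVolume
from .syncnav import DeformationField

__all__ = [
    "RegistrationConfig",
    "AdaptationConfig",
    "ContentProbability",
    "RegistrationError",
    "ModelError",
    "AdaptationError",
    "register_t2_to_t1fs",
    "build_content_probability",
    "transfer_labels",
    "adapt_colon_to_t1fs",
]


class RegistrationError(RuntimeError):
    pass


class ModelError(RuntimeError):
    pass


class AdaptationError(RuntimeError):
    pass


@dataclass
class RegistrationConfig:
    shrink_factors: tuple[int, ...] = (8, 4, 2)
    smoothing_sigmas: tuple[float, ...] = (4.0, 2.0, 1.0)
    control_spacing_mm: float = 32.0  # B-spline control-point spacing
    iterations: int = 30
    sampling_fraction: float = 0.05
    histogram_bins: int = 32
    translation_iterations: int = 30
    seed: int = 12345  # metric-sampling seed: keeps registration deterministic


@dataclass
class AdaptationConfig:
    delta_mm: float = 0.5  # per-iteration normal step
    corridor_mm: float = 8.0  # max displacement from the transferred surface
    n_max: int = 100
    stop_disp_mm: float = 0.05
    smooth_weight: float = 0.5
    probe_offsets_mm: tuple[float, ...] = (2.0, 4.0)
    expand_threshold: float = 0.8  # probe probability at which expansion engages
    allow_contraction: bool = False
    content_snap: bool = True  # conditional dilation into adjacent content
    snap_threshold: float = 0.5  # smoothed posterior level for the snap


@dataclass
class ContentProbability:
    """P(fecal content | intensity) on the T1-FS grid, monotone in intensity."""

    prob: np.ndarray
    model: dict = field(default_factory=dict)


def _to_sitk(vol: MRIVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    return img


def register_t2_to_t1fs(
    t2: MRIVolume, t1fs: MRIVolume, config: RegistrationConfig | None = None
) -> DeformationField:
    """Estimate the dense T2 -> T1-FS displacement field.

    Multiresolution B-spline free-form deformation with Mattes mutual
    information, preceded by a translation-only alignment. Returns the
    displacement sampled on the T2 grid, in mm. Optimizer non-convergence
    produces a warning, not an exception: the best field found is returned.
    """
    cfg = config or RegistrationConfig()
    for name, vol in (("T2", t2), ("T1-FS", t1fs)):
        if np.ptp(vol.data) == 0:
            raise RegistrationError(f"{name} volume is constant; registration is undefined")
    fixed = sitk.Cast(_to_sitk(t2), sitk.sitkFloat32)
    moving = sitk.Cast(_to_sitk(t1fs), sitk.sitkFloat32)

    # -- stage 1: translation-only alignment
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=cfg.histogram_bins)
    reg.SetMetricSamplingStrategy(reg.RANDOM)
    reg.SetMetricSamplingPercentage(cfg.sampling_fraction, cfg.seed)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=2.0, minStep=1e-3, numberOfIterations=cfg.translation_iterations
    )
    reg.SetInitialTransform(sitk.TranslationTransform(3), inPlace=True)
    translation = reg.Execute(fixed, moving)

    # -- stage 2: multiresolution B-spline on top of the translation.
    # The control mesh is laid out at the requested spacing and optimized
    # with LBFGSB over a coarse-to-fine image pyramid; the finest pyramid
    # level stays below full resolution, which is accurate enough for the
    # smooth inter-acquisition motion while keeping runtime modest.
    mesh_size = [
        max(1, int(round(sz * sp / cfg.control_spacing_mm)))
        for sz, sp in zip(fixed.GetSize(), fixed.GetSpacing())
    ]
    bspline = sitk.BSplineTransformInitializer(fixed, mesh_size, order=3)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=cfg.histogram_bins)
    reg.SetMetricSamplingStrategy(reg.RANDOM)
    reg.SetMetricSamplingPercentage(cfg.sampling_fraction, cfg.seed)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsLBFGSB(
        gradientConvergenceTolerance=1e-7, numberOfIterations=cfg.iterations
    )
    reg.SetMovingInitialTransform(translation)
    reg.SetInitialTransform(bspline, inPlace=True)
    reg.SetShrinkFactorsPerLevel(list(cfg.shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(cfg.smoothing_sigmas))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    out = reg.Execute(fixed, moving)
    stop = reg.GetOptimizerStopConditionDescription()
    if "Maximum number of iterations" in stop or "failure" in stop.lower():
        warnings.warn(f"registration stopped without convergence: {stop}", stacklevel=2)

    total = sitk.CompositeTransform(3)
    total.AddTransform(translation)
    total.AddTransform(out)  # applied first: p -> translation(bspline(p))

    to_field = sitk.TransformToDisplacementFieldFilter()
    to_field.SetReferenceImage(fixed)
    disp_img = to_field.Execute(total)
    disp = sitk.GetArrayFromImage(disp_img)  # (z, y, x, 3), components in (x, y, z)
    disp = np.ascontiguousarray(np.transpose(disp, (2, 1, 0, 3)))
    return DeformationField(disp, t2.spacing, t2.origin)


def build_content_probability(
    t1fs: MRIVolume, mask_init: np.ndarray, min_voxels: int = 50
) -> ContentProbability:
    """Two-component Gaussian mixture over in-mask T1-FS intensities.

    The bright component is fecal content; ``prob`` is the posterior of
    that component evaluated everywhere, forced non-decreasing in intensity
    by isotonic correction (unequal component variances can otherwise make
    the posterior dip at the extremes).
    """
    mask = np.asarray(mask_init, dtype=bool)
    vals = t1fs.data[mask]
    if vals.size < min_voxels:
        raise ModelError(f"only {vals.size} voxels in the initial mask (need >= {min_voxels})")
    sample = vals
    if sample.size > 50000:
        sample = np.random.default_rng(0).choice(sample, 50000, replace=False)
    gmm = GaussianMixture(n_components=2, random_state=0, n_init=3)
    gmm.fit(sample.reshape(-1, 1))
    means = gmm.means_.reshape(-1)
    span = float(np.ptp(t1fs.data))
    if span == 0 or abs(means[0] - means[1]) < 0.01 * span:
        raise ModelError(
            f"mixture collapse: component means {means} within 1% of the intensity range"
        )
    hi = int(np.argmax(means))
    grid = np.linspace(float(t1fs.data.min()), float(t1fs.data.max()), 512)
    post = gmm.predict_proba(grid.reshape(-1, 1))[:, hi]
    post = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True).fit_transform(grid, post)
    prob = np.interp(t1fs.data, grid, post)
    return ContentProbability(
        prob=prob,
        model={
            "means": means,
            "sds": np.sqrt(gmm.covariances_.reshape(-1)),
            "weights": gmm.weights_.reshape(-1),
            "intensity_grid": grid,
            "posterior_grid": post,
        },
    )


def transfer_labels(
    seg_t2: LabelVolume, field: DeformationField, t1fs: MRIVolume
) -> LabelVolume:
    """Push a T2-space label volume through the field onto the T1-FS grid.

    Uses inverse mapping with nearest-label sampling: for every T1-FS voxel
    center q, solve p + d(p) = q and take the label at the T2 voxel nearest
    to p. Raises :class:`AdaptationError` if the inversion fails to
    converge at voxels that carry labels.
    """
    if not np.any(seg_t2.labels):
        raise AdaptationError("empty T2 segmentation")
    grid = MRIVolume(
        np.zeros(t1fs.shape), t1fs.spacing, t1fs.origin, Modality.T1FS
    ).grid_points().reshape(-1, 3)
    src = field.map_inverse(grid, raise_on_failure=False)
    vox = np.rint((src - seg_t2.origin) / seg_t2.spacing).astype(int)
    inside = np.all((vox >= 0) & (vox < np.array(seg_t2.shape)), axis=1)
    out = np.zeros(len(grid), dtype=np.int16)
    out[inside] = seg_t2.labels[vox[inside, 0], vox[inside, 1], vox[inside, 2]]
    # the inversion contract only needs to hold where labels land
    labeled = out > 0
    if np.any(labeled):
        residual = np.linalg.norm(src[labeled] + field(src[labeled]) - grid[labeled], axis=1)
        if float(np.max(residual)) > 1.0:
            raise AdaptationError(
                f"deformation field is not invertible at mask voxels "
                f"(max residual {residual.max():.2f} mm)"
            )
    return LabelVolume(
        out.reshape(t1fs.shape), t1fs.spacing, t1fs.origin, Modality.T1FS
    )


def _vertex_normals(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    fn = np.cross(
        verts[faces[:, 1]] - verts[faces[:, 0]], verts[faces[:, 2]] - verts[faces[:, 0]]
    )
    vn = np.zeros_like(verts)
    np.add.at(vn, faces[:, 0], fn)
    np.add.at(vn, faces[:, 1], fn)
    np.add.at(vn, faces[:, 2], fn)
    norms = np.linalg.norm(vn, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return vn / norms


def _adjacency(n: int, faces: np.ndarray) -> csr_matrix:
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e = np.vstack([e, e[:, ::-1]])
    data = np.ones(len(e))
    adj = csr_matrix((data, (e[:, 0], e[:, 1])), shape=(n, n))
    adj.sum_duplicates()
    adj.data[:] = 1.0  # collapse duplicate edges
    deg = np.asarray(adj.sum(axis=1)).reshape(-1)
    deg[deg == 0] = 1.0
    rows = np.repeat(np.arange(n), np.diff(adj.indptr))
    return csr_matrix((adj.data / deg[rows], adj.indices, adj.indptr), shape=(n, n))


def _sample_prob(prob: np.ndarray, vol_like: LabelVolume, points: np.ndarray) -> np.ndarray:
    idx = ((points - vol_like.origin) / vol_like.spacing).T
    return map_coordinates(prob, idx, order=1, mode="constant", cval=0.0)


def adapt_colon_to_t1fs(
    seg_t2: LabelVolume,
    field: DeformationField,
    t1fs: MRIVolume,
    config: AdaptationConfig | None = None,
) -> LabelVolume:
    """Transfer the T2 colon into T1-FS space and adapt it to the content.

    The transferred mask's triangle surface (marching cubes) is evolved for
    at most ``n_max`` iterations: each vertex moves outward along its
    normal by ``delta * (2 p - 1)`` where ``p`` is the strongest fecal-
    content probability found on a short probe outside the surface, then
    Laplacian smoothing is applied and the total per-vertex displacement is
    clamped to a corridor around the transferred surface. By default only
    expansion (toward adjacent feces) is enabled: wherever the probe sees
    no content the surface holds the transferred T2 shape, since gas, fat
    and tissue are indistinguishable evidence of the wall in T1-FS.
    """
    cfg = config or AdaptationConfig()
    transferred = transfer_labels(seg_t2, field, t1fs)
    if cfg.n_max == 0:
        return transferred
    mask = transferred.mask()
    if not np.any(mask):
        raise AdaptationError("transferred mask is empty on the T1-FS grid")

    cp = build_content_probability(t1fs, mask)
    # smooth the posterior before probing: isolated noisy tissue voxels
    # crossing 0.5 would otherwise ratchet the expansion-only surface
    # outward over many iterations
    prob = ndimage.gaussian_filter(cp.prob, sigma=1.0)

    padded = np.pad(mask.astype(np.float64), 1)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=tuple(t1fs.spacing))
    verts = verts - np.asarray(t1fs.spacing) + np.asarray(t1fs.origin)
    orig = verts.copy()
    adj = _adjacency(len(verts), faces)

    # orient normals outward (marching-cubes orientation depends on the
    # gradient convention): probe the mask just off the surface
    normals = _vertex_normals(verts, faces)
    probe = verts + normals * float(np.min(t1fs.spacing))
    inside_frac = _sample_prob(mask.astype(np.float64), transferred, probe).mean()
    flip = 1.0 if inside_frac < 0.5 else -1.0

    offsets = np.asarray(cfg.probe_offsets_mm)
    for _ in range(cfg.n_max):
        normals = flip * _vertex_normals(verts, faces)
        p_best = np.zeros(len(verts))
        for off in offsets:
            p = _sample_prob(prob, transferred, verts + normals * off)
            np.maximum(p_best, p, out=p_best)
        if cfg.allow_contraction:
            force = 2.0 * p_best - 1.0
        else:
            # expansion engages only on strong content evidence: the probe
            # samples a smoothed field, so the 0.5 level sits about a voxel
            # outside the true content boundary
            th = cfg.expand_threshold
            force = np.clip((p_best - th) / (1.0 - th), 0.0, 1.0)
        moved = verts + normals * (cfg.delta_mm * force)[:, None]
        # smooth the displacement field, not the positions: smoothing the
        # positions is a curvature flow that shrinks the tube toward its
        # centerline, destroying the preserved T2 shape
        disp = moved - orig
        disp = disp + cfg.smooth_weight * (adj @ disp - disp)
        moved = orig + disp
        mag = np.linalg.norm(disp, axis=1)
        over = mag > cfg.corridor_mm
        if np.any(over):
            moved[over] = orig[over] + disp[over] * (cfg.corridor_mm / mag[over])[:, None]
        # expansion is localized (most of the wall has no content evidence),
        # so convergence is judged on the largest vertex step rather than a
        # mean that is diluted by the stationary majority
        step = float(np.max(np.linalg.norm(moved - verts, axis=1))) if len(verts) else 0.0
        verts = moved
        if step < cfg.stop_disp_mm:
            break

    new_mask = _voxelize_adapted(verts, orig, faces, flip, mask, transferred, cfg)
    if cfg.content_snap:
        new_mask = _content_snap(new_mask, mask, prob, transferred, cfg)
    # re-apply segment labels from the transferred label volume
    lab_vox = np.argwhere(mask)
    lab_world = lab_vox * transferred.spacing + transferred.origin
    tree = cKDTree(lab_world)
    new_vox = np.argwhere(new_mask)
    new_world = new_vox * transferred.spacing + transferred.origin
    _, nearest = tree.query(new_world)
    labels = np.zeros(transferred.shape, dtype=np.int16)
    src_lab = transferred.labels[lab_vox[:, 0], lab_vox[:, 1], lab_vox[:, 2]]
    labels[new_vox[:, 0], new_vox[:, 1], new_vox[:, 2]] = src_lab[nearest]
    return LabelVolume(labels, transferred.spacing, transferred.origin, Modality.T1FS)


def _content_snap(
    mask: np.ndarray,
    transferred_mask: np.ndarray,
    prob_smooth: np.ndarray,
    ref: LabelVolume,
    cfg: AdaptationConfig,
) -> np.ndarray:
    """Conditional dilation into adjacent fecal content.

    The normal-driven surface only sees content along each vertex normal; a
    content pocket that the registration displaced sideways can evade it.
    This pass grows the mask voxel-by-voxel into 6-connected neighbors whose
    smoothed content posterior exceeds ``snap_threshold``, never farther
    than the corridor from the transferred mask, so any content region that
    touches the transferred colon is recovered while the shape-preservation
    budget still holds.
    """
    dt = ndimage.distance_transform_edt(~transferred_mask, sampling=ref.spacing)
    allowed = (prob_smooth > cfg.snap_threshold) & (dt <= cfg.corridor_mm)
    out = mask.copy()
    max_layers = int(np.ceil(cfg.corridor_mm / float(np.min(ref.spacing)))) + 1
    for _ in range(max_layers):
        layer = ndimage.binary_dilation(out) & ~out & allowed
        if not np.any(layer):
            break
        out |= layer
    return out


def _sweep_stamp(
    start: np.ndarray, end: np.ndarray, ref: LabelVolume, step_mm: float
) -> np.ndarray:
    """Voxels touched by the straight sweeps from ``start`` to ``end`` points."""
    disp = end - start
    mag = np.linalg.norm(disp, axis=1)
    moving = mag > 1e-9
    out = np.zeros(ref.shape, dtype=bool)
    if not np.any(moving):
        return out
    start, disp, mag = start[moving], disp[moving], mag[moving]
    n_steps = int(np.ceil(mag.max() / step_mm)) + 1
    shape = np.array(ref.shape)
    for t in np.linspace(0.0, 1.0, n_steps + 1):
        pts = start + t * disp
        vox = np.rint((pts - ref.origin) / ref.spacing).astype(int)
        ok = np.all((vox >= 0) & (vox < shape), axis=1)
        v = vox[ok]
        out[v[:, 0], v[:, 1], v[:, 2]] = True
    return out


def _voxelize_adapted(
    verts: np.ndarray,
    orig: np.ndarray,
    faces: np.ndarray,
    flip: float,
    transferred_mask: np.ndarray,
    ref: LabelVolume,
    cfg: AdaptationConfig,
) -> np.ndarray:
    """Update the transferred mask from the adapted surface.

    Vertices move along near-normal sweeps bounded by the corridor, so the
    volume swept between the transferred surface and the adapted one is
    rasterized directly from the vertex (and face-centroid) displacement
    segments: outward sweeps add voxels, inward sweeps (contraction mode)
    remove them. Pinholes left between sparse sweeps are sealed by a
    single binary closing restricted to the added region. By construction
    pure expansion can only grow the transferred mask, mirroring the
    surface energy, and nothing changes beyond the corridor.
    """
    step = 0.5 * float(np.min(ref.spacing))
    fc_orig = orig[faces].mean(axis=1)
    fc_new = verts[faces].mean(axis=1)
    starts = np.vstack([orig, fc_orig])
    ends = np.vstack([verts, fc_new])

    disp = ends - starts
    # split sweeps into growth and shrink by their sense relative to the
    # original outward surface normals
    vn = flip * _vertex_normals(orig, faces)
    fn = vn[faces].mean(axis=1)
    sense = np.einsum("ij,ij->i", disp, np.vstack([vn, fn]))

    out = transferred_mask.copy()
    grow = _sweep_stamp(starts[sense > 0], ends[sense > 0], ref, step)
    grow &= ~transferred_mask
    if np.any(grow):
        filled = ndimage.binary_closing(transferred_mask | grow, structure=np.ones((3, 3, 3)))
        grow |= filled & ~transferred_mask & ndimage.binary_dilation(grow, iterations=2)
        out |= grow
    if cfg.allow_contraction:
        shrink = _sweep_stamp(starts[sense < 0], ends[sense < 0], ref, step)
        out &= ~(shrink & transferred_mask)
    return out
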