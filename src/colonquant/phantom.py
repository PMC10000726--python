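"""Synthetic paired T2 / T1-FS abdominal phantoms with full ground truth.

The generator emulates the intensity semantics of unprepared abdominal MRI:

* **T2**: the colonic lumen is dark against a bright peri-colonic fat halo,
  with mid-intensity background tissue and dark small-bowel distractor
  tubes whose intensities are close to the colon lumen.
* **T1-FS**: fecal pockets are bright, colonic gas is dark, and fat is
  dark too — nearly indistinguishable from adjacent gas — so colon
  boundaries are invisible wherever no feces is present.

The two volumes are related by a smooth synthetic inter-acquisition
deformation (a sum of Gaussian-bump displacements, guaranteed invertible by
a displacement-gradient bound), standing in for the patient motion between
the two breath-hold acquisitions. All ground truth is retained: colon masks
in both spaces, the per-voxel gas/feces content map, the true deformation
field, the medial path, and anatomical markers — the synthetic counterpart
of a specialist's manual segmentation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .core_io import (
    BOUNDARY_TAGS,
    LabelVolume,
    Marker,
    MarkerSet,
    Modality,
    MRIVolume,
    ValidationError,
    write_label_volume,
    write_markers,
    write_volume,
)
from .paths import MedialPath, polyline_arc_length, resample_polyline
from .syncnav import DeformationField, write_field

__all__ = [
    "GaussianBump",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "sample_field",
    "evaluate_bumps",
    "default_path_controls",
    "straight_cylinder_spec",
    "write_phantom",
]

# Default per-tissue intensity means (arbitrary units). Only the orderings
# are semantically meaningful; the values reproduce the qualitative
# contrasts of clinical T2 / T1-FS sequences.
DEFAULT_INTENSITY = {
    "T2": {"lumen": 30.0, "feces": 30.0, "fat": 220.0, "background": 100.0,
           "distractor": 35.0, "liver": 140.0, "air": 5.0},
    "T1FS": {"lumen": 20.0, "feces": 210.0, "fat": 25.0, "background": 90.0,
             "distractor": 60.0, "liver": 70.0, "air": 5.0},
}

# Internal tissue codes used during rendering.
_BG, _GAS, _FECES, _FAT, _DISTRACTOR, _LIVER, _AIR = 0, 1, 2, 3, 4, 5, 6

# max gradient of a unit-amplitude Gaussian bump exp(-r^2 / 2 s^2) is
# exp(-1/2) / s, attained at r = s
_BUMP_GRAD = float(np.exp(-0.5))


@dataclass
class GaussianBump:
    """One smooth displacement bump: a * exp(-|p - c|^2 / (2 s^2))."""

    center: np.ndarray
    amplitude: np.ndarray  # mm, 3-vector
    scale: float  # mm

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=np.float64).reshape(3)
        self.amplitude = np.asarray(self.amplitude, dtype=np.float64).reshape(3)
        self.scale = float(self.scale)
        if self.scale <= 0:
            raise ValidationError("bump scale must be positive")


def evaluate_bumps(bumps: list[GaussianBump], points: np.ndarray) -> np.ndarray:
    """Analytic displacement (mm) of a bump sum at world point(s)."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    disp = np.zeros_like(pts)
    for b in bumps:
        r2 = np.sum((pts - b.center) ** 2, axis=1)
        disp += np.exp(-r2 / (2 * b.scale**2))[:, None] * b.amplitude
    return disp if np.asarray(points).ndim > 1 else disp[0]


def default_path_controls() -> list[tuple[str, np.ndarray]]:
    """Question-mark colon trajectory in fractional volume coordinates.

    Ascending up one side, transverse across with a slight arch, descending
    down the other side, pelvic loop back toward the midline. Scaled to the
    actual volume extent by :func:`generate_phantom`.
    """
    f = [
        ("cecum_start", (0.24, 0.50, 0.22)),
        ("intermediate", (0.23, 0.50, 0.46)),
        ("asc_trans", (0.25, 0.50, 0.72)),
        ("intermediate", (0.50, 0.54, 0.80)),
        ("trans_desc", (0.75, 0.50, 0.72)),
        ("intermediate", (0.78, 0.50, 0.46)),
        ("desc_pelvic", (0.76, 0.50, 0.24)),
        ("intermediate", (0.62, 0.50, 0.14)),
        ("pelvic_end", (0.48, 0.50, 0.20)),
    ]
    return [(tag, np.asarray(p)) for tag, p in f]


@dataclass
class PhantomSpec:
    """Full description of one synthetic subject.

    Deterministic given ``seed``. ``path`` is either ``"default"`` (the
    question-mark trajectory) or a list of ``(tag, point_mm)`` control
    points carrying the five boundary tags in order.
    """

    shape: tuple[int, int, int] = (96, 96, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 3.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    path: str | list[tuple[str, np.ndarray]] = "default"
    radius_mean: float = 10.0  # mm
    radius_variation: float = 2.0  # mm, smooth sinusoidal modulation
    radius_cycles: float = 3.0
    halo_thickness: float = 4.0  # mm of bright peri-colonic fat in T2
    pocket_length_range: tuple[float, float] = (20.0, 60.0)  # mm, uniform
    gas_fraction: float = 0.5
    intensity: dict = field(default_factory=lambda: {m: dict(v) for m, v in DEFAULT_INTENSITY.items()})
    noise_sigma: dict = field(default_factory=lambda: {"T2": 10.0, "T1FS": 10.0})
    noise_model: str = "gaussian"  # or "rician"
    n_bumps: int = 3
    bump_amplitude: float = 8.0  # mm
    bump_scale: float = 40.0  # mm
    bumps: list[GaussianBump] | None = None  # explicit bumps override the random ones
    distractors: bool = True
    liver_block: bool = True
    body_outline: bool = True  # abdominal ellipsoid with subcutaneous fat rim, air outside
    body_semiaxes_frac: tuple[float, float, float] = (0.48, 0.48, 0.48)
    body_fat_rim_frac: float = 0.90  # rim between this fraction of the ellipsoid and its surface
    seed: int = 0

    # -- geometry helpers ---------------------------------------------------

    @property
    def extent(self) -> np.ndarray:
        """World-space size of the voxel-center bounding box, mm."""
        return (np.asarray(self.shape) - 1) * np.asarray(self.spacing)

    def control_points(self) -> list[tuple[str, np.ndarray]]:
        if isinstance(self.path, str):
            if self.path != "default":
                raise ValidationError(f"unknown path preset {self.path!r}")
            ext, org = self.extent, np.asarray(self.origin)
            return [(tag, org + f * ext) for tag, f in default_path_controls()]
        return [(tag, np.asarray(p, dtype=np.float64)) for tag, p in self.path]

    def validate(self) -> None:
        errs = []
        if self.radius_mean - self.radius_variation < 2 * max(self.spacing):
            errs.append(
                f"tube radius (min {self.radius_mean - self.radius_variation} mm) must be "
                f">= 2 x max spacing ({2 * max(self.spacing)} mm) to be resolvable"
            )
        tags = [t for t, _ in self.control_points() if t in BOUNDARY_TAGS]
        if tags != list(BOUNDARY_TAGS):
            errs.append(f"path control points must carry boundary tags {BOUNDARY_TAGS} in order")
        t2, t1 = self.intensity["T2"], self.intensity["T1FS"]
        if not (t2["lumen"] < t2["background"] < t2["fat"]):
            errs.append("T2 intensity ordering must satisfy lumen < background < fat")
        if not (t1["lumen"] < t1["background"] < t1["feces"] and t1["fat"] < t1["background"]):
            errs.append("T1-FS intensity ordering must satisfy gas ~ fat < background < feces")
        if not (0.0 <= self.gas_fraction <= 1.0):
            errs.append("gas_fraction must be in [0, 1]")
        grad = self._gradient_bound()
        if grad >= 1.0:
            errs.append(
                f"deformation gradient bound {grad:.3f} >= 1: the field may fold; "
                "reduce bump amplitudes or increase scales"
            )
        if errs:
            raise ValidationError("; ".join(errs))

    def _resolved_bumps(self) -> list[GaussianBump]:
        if self.bumps is not None:
            return list(self.bumps)
        if self.n_bumps == 0 or self.bump_amplitude == 0:
            return []
        rng = np.random.default_rng(self.seed + 104729)  # decoupled from noise stream
        ext, org = self.extent, np.asarray(self.origin)
        bumps = []
        for _ in range(self.n_bumps):
            center = org + rng.uniform(0.2, 0.8, size=3) * ext
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            bumps.append(
                GaussianBump(center, direction * self.bump_amplitude, self.bump_scale)
            )
        return bumps

    def _gradient_bound(self) -> float:
        return sum(
            float(np.linalg.norm(b.amplitude)) * _BUMP_GRAD / b.scale
            for b in self._resolved_bumps()
        )

    # -- (de)serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "shape": list(self.shape),
            "spacing": list(self.spacing),
            "origin": list(self.origin),
            "radius_mean": self.radius_mean,
            "radius_variation": self.radius_variation,
            "radius_cycles": self.radius_cycles,
            "halo_thickness": self.halo_thickness,
            "pocket_length_range": list(self.pocket_length_range),
            "gas_fraction": self.gas_fraction,
            "intensity": self.intensity,
            "noise_sigma": self.noise_sigma,
            "noise_model": self.noise_model,
            "n_bumps": self.n_bumps,
            "bump_amplitude": self.bump_amplitude,
            "bump_scale": self.bump_scale,
            "distractors": self.distractors,
            "liver_block": self.liver_block,
            "seed": self.seed,
        }
        if isinstance(self.path, str):
            d["path"] = self.path
        else:
            d["path"] = [{"tag": t, "point_mm": np.asarray(p).tolist()} for t, p in self.path]
        if self.bumps is not None:
            d["bumps"] = [
                {"center": b.center.tolist(), "amplitude": b.amplitude.tolist(), "scale": b.scale}
                for b in self.bumps
            ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if isinstance(d.get("path"), list):
            d["path"] = [(e["tag"], np.asarray(e["point_mm"])) for e in d["path"]]
        if "bumps" in d and d["bumps"] is not None:
            d["bumps"] = [GaussianBump(b["center"], b["amplitude"], b["scale"]) for b in d["bumps"]]
        for key in ("shape", "spacing", "origin", "pocket_length_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PhantomSpec":
        text = Path(path).read_text()
        d = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
        return cls.from_dict(d)


def straight_cylinder_spec(
    length: float = 200.0,
    radius: float = 10.0,
    spacing: float = 1.0,
    margin: float = 20.0,
    noise: float = 0.0,
    seed: int = 0,
) -> PhantomSpec:
    """A straight-tube phantom along z with analytic volume pi r^2 L.

    Used by the generator's own validation suite: a cylinder has closed-form
    volume, radius and perimeter, so every morphology estimate can be
    checked against ground truth.
    """
    side = int(np.ceil(2 * (radius + margin) / spacing)) + 1
    nz = int(np.ceil((length + 2 * margin) / spacing)) + 1
    cx = (side - 1) * spacing / 2.0
    z0 = margin
    tags = list(BOUNDARY_TAGS)
    zs = z0 + np.linspace(0.0, length, 5)
    path = [(tag, np.array([cx, cx, z])) for tag, z in zip(tags, zs)]
    return PhantomSpec(
        shape=(side, side, nz),
        spacing=(spacing, spacing, spacing),
        path=path,
        radius_mean=radius,
        radius_variation=0.0,
        noise_sigma={"T2": noise, "T1FS": noise},
        n_bumps=0,
        bump_amplitude=0.0,
        distractors=False,
        liver_block=False,
        seed=seed,
    )


@dataclass
class PhantomTruth:
    """Everything the pipeline under test is asked to recover."""

    t2: MRIVolume
    t1fs: MRIVolume
    mask_t2: LabelVolume
    mask_t1fs: LabelVolume
    content_truth: np.ndarray  # T1-FS grid; 0 outside colon, 1 gas, 2 feces
    field_truth: DeformationField
    markers: MarkerSet
    path_truth: MedialPath
    analytic: dict
    spec: PhantomSpec


def sample_field(spec: PhantomSpec) -> DeformationField:
    """The phantom's true T2->T1-FS deformation, sampled on the T2 grid."""
    spec.validate()
    bumps = spec._resolved_bumps()
    shape = tuple(spec.shape)
    pts = MRIVolume(
        np.zeros(shape), spec.spacing, spec.origin, Modality.T2
    ).grid_points().reshape(-1, 3)
    disp = evaluate_bumps(bumps, pts).reshape(shape + (3,))
    return DeformationField(disp, spec.spacing, spec.origin)


def _build_centerline(spec: PhantomSpec) -> tuple[MedialPath, np.ndarray]:
    """Smooth spline through the control points, sampled at ~1 mm steps.

    Returns the path and the per-sample tube radius r(s).
    """
    controls = spec.control_points()
    ctrl_pts = np.array([p for _, p in controls])
    chord = polyline_arc_length(ctrl_pts)
    if chord[-1] <= 0:
        raise ValidationError("degenerate path control points")
    spline = CubicSpline(chord, ctrl_pts, axis=0)
    n = max(int(np.ceil(chord[-1])), 8)
    s_dense = np.linspace(0.0, chord[-1], 4 * n)
    dense = spline(s_dense)
    pts = resample_polyline(dense, 1.0)
    arc = polyline_arc_length(pts)

    # locate the five boundary controls on the resampled polyline
    tree = cKDTree(pts)
    b_idx = []
    for tag, p in controls:
        if tag in BOUNDARY_TAGS:
            _, i = tree.query(p)
            b_idx.append(int(i))
    b_idx[0], b_idx[-1] = 0, len(pts) - 1
    b_idx = np.maximum.accumulate(b_idx)  # guard monotonicity at sharp bends
    for k in range(1, 5):
        if b_idx[k] <= b_idx[k - 1]:
            b_idx[k] = b_idx[k - 1] + 1
    path = MedialPath(points=pts, boundary_indices=np.array(b_idx), arc_length=arc)

    total = arc[-1]
    radius = spec.radius_mean + spec.radius_variation * np.sin(
        2 * np.pi * spec.radius_cycles * arc / max(total, 1e-9)
    )
    return path, radius


def _content_pockets(spec: PhantomSpec, total_length: float, rng: np.random.Generator) -> list[tuple[float, float, int]]:
    """(s_start, s_end, tissue code) pockets partitioning the centerline.

    Pockets alternate feces/gas; a gas fraction g is realized by scaling gas
    pocket lengths by 2g and feces pockets by 2(1-g), keeping the stated
    uniform pocket-length distribution as the base draw.
    """
    a, b = spec.pocket_length_range
    g = spec.gas_fraction
    pockets = []
    s = 0.0
    kind = _FECES if rng.random() < 0.5 else _GAS
    while s < total_length:
        base = rng.uniform(a, b)
        length = base * (2 * g if kind == _GAS else 2 * (1 - g))
        length = max(length, 1.0)
        pockets.append((s, min(s + length, total_length), kind))
        s += length
        kind = _GAS if kind == _FECES else _FECES
    if g == 0.0:
        pockets = [(s0, s1, _FECES) for s0, s1, _ in pockets]
    elif g == 1.0:
        pockets = [(s0, s1, _GAS) for s0, s1, _ in pockets]
    return pockets


def _distractor_polylines(spec: PhantomSpec, path: MedialPath) -> list[np.ndarray]:
    """Small-bowel distractor tube centerlines near the cecum and sigmoid."""
    b = path.boundary_indices
    cecum = path.points[b[0]]
    pelvic_end = path.points[b[4]]
    offset = spec.radius_mean + spec.halo_thickness + 4.0  # just beyond the fat halo
    lines = []
    # tube parallel to the ascending colon, offset toward the midline
    top = path.points[b[1]]
    direction = top - cecum
    n = np.linalg.norm(direction)
    if n > 0:
        lines.append(np.array([cecum + [offset, 0, 0], cecum + [offset, 0, 0] + direction * 0.6]))
    # tube alongside the pelvic loop, offset anteriorly
    lines.append(
        np.array([pelvic_end + [0, offset, 0], pelvic_end + [0, offset, 0] + np.array([-45.0, 0.0, -8.0])])
    )
    return lines


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Render one synthetic subject; bit-deterministic given ``spec``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    path, radius_profile = _build_centerline(spec)
    shape = tuple(spec.shape)
    spacing = np.asarray(spec.spacing, dtype=np.float64)
    origin = np.asarray(spec.origin, dtype=np.float64)
    template = MRIVolume(np.zeros(shape), spacing, origin, Modality.T2)
    grid = template.grid_points().reshape(-1, 3)

    # ---- colon tube and segment labels in T2 space
    dist, nearest = path.distance_to(grid)
    r_at = radius_profile[nearest]
    colon = dist <= r_at
    halo = (~colon) & (dist <= r_at + spec.halo_thickness)
    seg_label = np.zeros(len(grid), dtype=np.int16)
    seg_label[colon] = path.segment_of_index(nearest[colon])

    # ---- content pockets along arc length
    pockets = _content_pockets(spec, path.total_length, rng)
    pocket_kind = np.full(len(path.points), _FECES, dtype=np.int16)
    arc = path.arc_length
    for s0, s1, kind in pockets:
        pocket_kind[(arc >= s0) & (arc <= s1)] = kind
    content_t2 = np.zeros(len(grid), dtype=np.int16)
    content_t2[colon] = pocket_kind[nearest[colon]]

    # ---- tissue map in T2 space
    tissue = np.zeros(len(grid), dtype=np.int16)
    tissue[colon] = content_t2[colon]
    tissue[halo] = _FAT
    if spec.distractors:
        for line in _distractor_polylines(spec, path):
            dense = resample_polyline(line, 1.0)
            d, _ = cKDTree(dense).query(grid)
            tube = (d <= 6.0) & (tissue == _BG)
            tissue[tube] = _DISTRACTOR
    ext = spec.extent
    frac = (grid - origin) / np.maximum(ext, 1e-9)
    if spec.liver_block:
        block = (
            (frac[:, 0] > 0.25) & (frac[:, 0] < 0.60)
            & (frac[:, 1] > 0.35) & (frac[:, 1] < 0.65)
            & (frac[:, 2] > 0.82) & (frac[:, 2] < 0.93)
            & (tissue == _BG)
        )
        tissue[block] = _LIVER
    if spec.body_outline:
        # abdominal contour: subcutaneous fat rim, then air outside; strong
        # anchoring structure for multimodal registration, present in both
        # sequences exactly as in real abdominal acquisitions
        r2 = np.sum(((frac - 0.5) / np.asarray(spec.body_semiaxes_frac)) ** 2, axis=1)
        rim = (r2 > spec.body_fat_rim_frac**2) & (r2 <= 1.0) & (tissue == _BG)
        outside = r2 > 1.0
        tissue[rim] = _FAT
        tissue[outside & (tissue == _BG)] = _AIR

    tissue_3d = tissue.reshape(shape)
    content_3d = content_t2.reshape(shape)
    seg_3d = seg_label.reshape(shape)

    # ---- T2 rendering (T2 space)
    t2_means = spec.intensity["T2"]
    lut_t2 = np.array(
        [t2_means["background"], t2_means["lumen"], t2_means["feces"],
         t2_means["fat"], t2_means["distractor"], t2_means["liver"],
         t2_means["air"]]
    )
    t2_clean = lut_t2[tissue_3d]
    t2_data = _add_noise(t2_clean, spec.noise_sigma["T2"], spec.noise_model, rng)

    # ---- deformation and pull-back to the T1-FS grid
    bumps = spec._resolved_bumps()
    field = sample_field(spec)
    if bumps:
        # invert the analytic field at every T1-FS voxel center: x + d(x) = q
        x = grid.copy()
        for _ in range(60):
            x_new = grid - evaluate_bumps(bumps, x)
            if np.max(np.linalg.norm(x_new - x, axis=1)) < 1e-3:
                x = x_new
                break
            x = x_new
        src_idx = np.rint((x - origin) / spacing).astype(int)
    else:
        src_idx = np.rint((grid - origin) / spacing).astype(int)
    inside = np.all((src_idx >= 0) & (src_idx < np.array(shape)), axis=1)
    flat = np.ravel_multi_index(src_idx[inside].T, shape)
    tissue_t1 = np.zeros(len(grid), dtype=np.int16)
    tissue_t1[inside] = tissue_3d.reshape(-1)[flat]
    seg_t1 = np.zeros(len(grid), dtype=np.int16)
    seg_t1[inside] = seg_3d.reshape(-1)[flat]
    content_t1 = np.zeros(len(grid), dtype=np.int16)
    content_t1[inside] = content_3d.reshape(-1)[flat]
    tissue_t1_3d = tissue_t1.reshape(shape)

    # ---- T1-FS rendering (T1-FS space)
    t1_means = spec.intensity["T1FS"]
    lut_t1 = np.array(
        [t1_means["background"], t1_means["lumen"], t1_means["feces"],
         t1_means["fat"], t1_means["distractor"], t1_means["liver"],
         t1_means["air"]]
    )
    t1_clean = lut_t1[tissue_t1_3d]
    t1_data = _add_noise(t1_clean, spec.noise_sigma["T1FS"], spec.noise_model, rng)

    markers = MarkerSet(
        anatomical=[
            Marker(tag, path.points[i])
            for tag, i in zip(BOUNDARY_TAGS, path.boundary_indices)
        ]
    )

    analytic = {
        "segment_lengths_mm": path.segment_lengths(),
        "total_length_mm": path.total_length,
        "radius_mean_mm": spec.radius_mean,
        "radius_variation_mm": spec.radius_variation,
        "bumps": bumps,
        "pockets": pockets,
    }

    return PhantomTruth(
        t2=MRIVolume(t2_data, spacing, origin, Modality.T2),
        t1fs=MRIVolume(t1_data, spacing, origin, Modality.T1FS),
        mask_t2=LabelVolume(seg_3d, spacing, origin, Modality.T2),
        mask_t1fs=LabelVolume(seg_t1.reshape(shape), spacing, origin, Modality.T1FS),
        content_truth=content_t1.reshape(shape),
        field_truth=field,
        markers=markers,
        path_truth=path,
        analytic=analytic,
        spec=spec,
    )


def _add_noise(clean: np.ndarray, sigma: float, model: str, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return clean.astype(np.float64)
    if model == "gaussian":
        noisy = clean + rng.normal(0.0, sigma, size=clean.shape)
        return np.clip(noisy, 0.0, None)
    if model == "rician":
        re = clean + rng.normal(0.0, sigma, size=clean.shape)
        im = rng.normal(0.0, sigma, size=clean.shape)
        return np.hypot(re, im)
    raise ValidationError(f"unknown noise model {model!r}")


def write_phantom(truth: PhantomTruth, out_dir: str | Path) -> None:
    """Write volumes, masks, markers, content map and field to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(truth.t2, out / "t2.nii.gz")
    write_volume(truth.t1fs, out / "t1fs.nii.gz")
    write_label_volume(truth.mask_t2, out / "mask_t2.nii.gz")
    write_label_volume(truth.mask_t1fs, out / "mask_t1fs.nii.gz")
    content = LabelVolume(
        truth.content_truth.astype(np.int16),
        truth.mask_t1fs.spacing,
        truth.mask_t1fs.origin,
        Modality.T1FS,
    )
    write_label_volume(content, out / "content_truth.nii.gz")
    write_field(truth.field_truth, out / "field_truth.nii.gz")
    write_markers(truth.markers, out / "markers.json")
    (out / "spec.json").write_text(json.dumps(truth.spec.to_dict(), indent=2))
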