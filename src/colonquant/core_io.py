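"""Domain types and file I/O shared by every pipeline stage.

Conventions used throughout the package
---------------------------------------
* Voxel indices are 0-based, axis order ``(x, y, z)`` = (left-right,
  anterior-posterior, inferior-superior).
* World coordinates are in millimetres; the world position of the *center*
  of voxel ``(0, 0, 0)`` is the volume origin, so the continuous voxel index
  of a world point ``p`` is ``(p - origin) / spacing``.
* NIfTI direction matrices must be axis-aligned with positive scales;
  anything else is rejected rather than silently reoriented, so the
  cross-modality correspondence math stays unambiguous.
* Intensities are never rescaled on read — MRI has no fixed tissue/intensity
  correspondence, and each stage normalizes robustly on its own.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "Modality",
    "Space",
    "MRIVolume",
    "MarkerSet",
    "Marker",
    "LabelVolume",
    "ContentReport",
    "SEGMENT_NAMES",
    "BOUNDARY_TAGS",
    "FormatError",
    "ValidationError",
    "read_volume",
    "write_volume",
    "read_markers",
    "write_markers",
    "read_label_volume",
    "write_label_volume",
]

#: Label semantics for colon segments in a :class:`LabelVolume`.
SEGMENT_NAMES = {1: "ascending", 2: "transverse", 3: "descending", 4: "pelvic"}

#: The five anatomical boundary tags, in anatomical order along the colon.
BOUNDARY_TAGS = ("cecum_start", "asc_trans", "trans_desc", "desc_pelvic", "pelvic_end")


class FormatError(ValueError):
    """A file exists but violates the expected format."""


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


class Modality(str, Enum):
    T2 = "T2"
    T1FS = "T1FS"


# The coordinate space a label volume lives in coincides with a modality grid.
Space = Modality


@dataclass
class MRIVolume:
    """A 3D scalar MRI volume with grid geometry.

    Parameters
    ----------
    data:
        3D array of intensities (finite, non-negative, arbitrary MRI units).
    spacing:
        mm per voxel along (x, y, z); strictly positive.
    origin:
        world position (mm) of the center of voxel (0, 0, 0).
    modality:
        ``Modality.T2`` or ``Modality.T1FS``.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    modality: Modality

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        self.modality = Modality(self.modality)
        if self.data.ndim != 3:
            raise ValidationError(f"volume data must be 3D, got {self.data.ndim}D")
        if any(s < 8 for s in self.data.shape):
            raise ValidationError(f"each dimension must be >= 8 voxels, got {self.data.shape}")
        if not np.all(self.spacing > 0):
            raise ValidationError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("volume intensities must be finite")
        if self.data.min() < 0:
            raise ValidationError("volume intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Continuous 0-based voxel index of world point(s) in mm."""
        return (np.asarray(points, dtype=np.float64) - self.origin) / self.spacing

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """World position (mm) of continuous voxel index(es)."""
        return np.asarray(idx, dtype=np.float64) * self.spacing + self.origin

    def in_bounds(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: which world points fall inside the voxel grid."""
        idx = np.atleast_2d(self.world_to_voxel(points))
        upper = np.array(self.shape) - 1
        ok = np.all((idx >= 0) & (idx <= upper), axis=1)
        return ok if np.asarray(points).ndim > 1 else bool(ok[0])

    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres."""
        return float(np.prod(self.spacing)) / 1000.0

    def grid_points(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape ``(*shape, 3)``."""
        axes = [self.origin[a] + self.spacing[a] * np.arange(self.shape[a]) for a in range(3)]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        return np.stack([xx, yy, zz], axis=-1)


@dataclass
class Marker:
    tag: str
    point_mm: np.ndarray

    def __post_init__(self) -> None:
        self.point_mm = np.asarray(self.point_mm, dtype=np.float64).reshape(3)


@dataclass
class MarkerSet:
    """Ordered anatomical reference points plus optional refinement markers.

    ``anatomical`` must contain each of the five boundary tags exactly once,
    in anatomical order; ``intermediate`` markers may appear between them.
    ``refinement`` holds ``(point, polarity)`` pairs with polarity ``include``
    or ``exclude``.
    """

    anatomical: list[Marker]
    refinement: list[tuple[np.ndarray, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.refinement = [
            (np.asarray(p, dtype=np.float64).reshape(3), str(pol)) for p, pol in self.refinement
        ]
        errors = []
        if len(self.anatomical) < 5:
            errors.append(f"need >= 5 anatomical points, got {len(self.anatomical)}")
        tags = [m.tag for m in self.anatomical]
        for tag in tags:
            if tag not in BOUNDARY_TAGS and tag != "intermediate":
                errors.append(f"unknown tag {tag!r}")
        boundary_seq = [t for t in tags if t in BOUNDARY_TAGS]
        if boundary_seq != list(BOUNDARY_TAGS):
            errors.append(
                f"boundary tags must each appear exactly once in order {BOUNDARY_TAGS}, got {boundary_seq}"
            )
        for p, pol in self.refinement:
            if pol not in ("include", "exclude"):
                errors.append(f"refinement polarity must be include/exclude, got {pol!r}")
        if errors:
            raise ValidationError("; ".join(errors))

    @property
    def points(self) -> np.ndarray:
        return np.array([m.point_mm for m in self.anatomical])

    def boundary_points(self) -> np.ndarray:
        """The five tagged boundary points, in order, shape (5, 3)."""
        return np.array([m.point_mm for m in self.anatomical if m.tag in BOUNDARY_TAGS])

    def validate_against(self, vol: MRIVolume) -> None:
        """Check that every marker lies inside ``vol``'s grid."""
        bad = []
        for m in self.anatomical:
            if not vol.in_bounds(m.point_mm):
                bad.append(f"anatomical {m.tag} at {m.point_mm.tolist()} outside volume")
        for p, pol in self.refinement:
            if not vol.in_bounds(p):
                bad.append(f"refinement ({pol}) at {p.tolist()} outside volume")
        if bad:
            raise ValidationError("; ".join(bad))


@dataclass
class LabelVolume:
    """Integer segment labels on the grid of a reference volume.

    0 = background, 1 = ascending, 2 = transverse, 3 = descending, 4 = pelvic.
    """

    labels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    space: Space

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("labels must be integers")
        self.labels = self.labels.astype(np.int16, copy=False)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        self.space = Space(self.space)
        if self.labels.ndim != 3:
            raise ValidationError("labels must be 3D")
        vals = np.unique(self.labels)
        if not np.all(np.isin(vals, [0, 1, 2, 3, 4])):
            raise ValidationError(f"labels must be in 0..4, got {vals}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def mask(self) -> np.ndarray:
        """Binary colon mask (any nonzero label)."""
        return self.labels > 0

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=np.float64) - self.origin) / self.spacing

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, dtype=np.float64) * self.spacing + self.origin

    def same_grid(self, other: "LabelVolume | MRIVolume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class ContentReport:
    """Per-segment gas/mixed/solid volumes, morphology, and evaluation stats.

    ``volumes_ml`` maps segment name -> {class name -> mL}; ``totals_ml``
    maps class name -> mL over the whole colon. ``solid_equivalent_ml`` is
    the fraction-weighted solid volume.  ``morphology`` maps segment name ->
    {"length_mm", "mean_perimeter_mm", "mean_radius_mm"}. ``evaluation`` may
    carry {"dsc": float in [0,1], "r_containment": percent}.
    """

    volumes_ml: dict[str, dict[str, float]] = field(default_factory=dict)
    totals_ml: dict[str, float] = field(default_factory=dict)
    solid_equivalent_ml: float = 0.0
    morphology: dict[str, dict[str, float]] = field(default_factory=dict)
    evaluation: dict[str, float] | None = None

    def validate(self) -> None:
        errs = []
        for seg, classes in self.volumes_ml.items():
            for cls, v in classes.items():
                if v < 0:
                    errs.append(f"negative volume {seg}/{cls}")
        if self.totals_ml:
            total = self.totals_ml.get("total", None)
            if total is not None:
                parts = sum(v for k, v in self.totals_ml.items() if k != "total")
                if abs(parts - total) > 1e-6:
                    errs.append(f"class volumes sum {parts} != total {total}")
        for seg, m in self.morphology.items():
            for k, v in m.items():
                if v < 0:
                    errs.append(f"negative morphology {seg}/{k}")
        if self.evaluation is not None:
            dsc = self.evaluation.get("dsc")
            if dsc is not None and not (0 <= dsc <= 1):
                errs.append(f"dsc out of [0,1]: {dsc}")
            r = self.evaluation.get("r_containment")
            if r is not None and not (0 <= r <= 100):
                errs.append(f"r_containment out of [0,100]: {r}")
        if errs:
            raise ValidationError("; ".join(errs))

    def to_json(self, path: str | Path) -> None:
        self.validate()
        obj = {
            "volumes_ml": self.volumes_ml,
            "totals_ml": self.totals_ml,
            "solid_equivalent_ml": self.solid_equivalent_ml,
            "morphology": self.morphology,
        }
        if self.evaluation is not None:
            obj["evaluation"] = self.evaluation
        Path(path).write_text(json.dumps(obj, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ContentReport":
        obj = json.loads(Path(path).read_text())
        rep = cls(
            volumes_ml=obj.get("volumes_ml", {}),
            totals_ml=obj.get("totals_ml", {}),
            solid_equivalent_ml=obj.get("solid_equivalent_ml", 0.0),
            morphology=obj.get("morphology", {}),
            evaluation=obj.get("evaluation"),
        )
        rep.validate()
        return rep

    def to_csv(self, path: str | Path) -> None:
        """Per-segment table: one row per segment, volumes then morphology."""
        classes = sorted({c for seg in self.volumes_ml.values() for c in seg})
        morph_keys = ["length_mm", "mean_perimeter_mm", "mean_radius_mm"]
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["segment"] + [f"{c}_ml" for c in classes] + morph_keys)
            segs = set(self.volumes_ml) | set(self.morphology)
            order = [SEGMENT_NAMES[i] for i in sorted(SEGMENT_NAMES) if SEGMENT_NAMES[i] in segs]
            order += sorted(segs - set(order))
            for seg in order:
                vols = self.volumes_ml.get(seg, {})
                morph = self.morphology.get(seg, {})
                w.writerow(
                    [seg]
                    + [f"{vols.get(c, 0.0):.6f}" for c in classes]
                    + [f"{morph.get(k, float('nan')):.3f}" for k in morph_keys]
                )


# ---------------------------------------------------------------------------
# NIfTI volume I/O
# ---------------------------------------------------------------------------

def _affine_from_geometry(spacing: np.ndarray, origin: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def _geometry_from_affine(aff: np.ndarray, path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    lin = aff[:3, :3]
    off_diag = lin - np.diag(np.diag(lin))
    if np.max(np.abs(off_diag)) > 1e-6 * max(1.0, np.max(np.abs(lin))):
        raise FormatError(
            f"{path}: NIfTI direction matrix is not axis-aligned; reorientation is not supported"
        )
    spacing = np.diag(lin).astype(np.float64)
    if np.any(spacing <= 0):
        raise FormatError(f"{path}: non-positive spacing in NIfTI affine diagonal {spacing}")
    return spacing, aff[:3, 3].astype(np.float64)


def read_volume(path: str | Path, modality: Modality | str | None = None) -> MRIVolume:
    """Read a 3D scalar NIfTI-1 volume.

    ``modality`` defaults to T2; pass explicitly when reading T1-FS images.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3D scalar image, got shape {data.shape} (dim field)")
    spacing, origin = _geometry_from_affine(img.affine, path)
    return MRIVolume(
        data=data.astype(np.float64),
        spacing=spacing,
        origin=origin,
        modality=Modality(modality) if modality is not None else Modality.T2,
    )


def write_volume(vol: MRIVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float64), _affine_from_geometry(vol.spacing, vol.origin))
    nib.save(img, str(path))


def read_label_volume(path: str | Path, space: Space | str = Space.T2) -> LabelVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3D label image, got shape {data.shape}")
    spacing, origin = _geometry_from_affine(img.affine, path)
    return LabelVolume(np.rint(data).astype(np.int16), spacing, origin, Space(space))


def write_label_volume(lab: LabelVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(
        lab.labels.astype(np.int16), _affine_from_geometry(lab.spacing, lab.origin)
    )
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Marker JSON I/O
# ---------------------------------------------------------------------------

def read_markers(path: str | Path, volume: MRIVolume | None = None) -> MarkerSet:
    """Read a marker JSON file; optionally validate bounds against ``volume``.

    Format::

        {"anatomical": [{"tag": "...", "point_mm": [x, y, z]}, ...],
         "refinement": [{"polarity": "include"|"exclude", "point_mm": [x, y, z]}, ...]}
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        obj = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"{path}: invalid JSON: {e}") from e
    try:
        anatomical = [Marker(m["tag"], m["point_mm"]) for m in obj.get("anatomical", [])]
        refinement = [(m["point_mm"], m["polarity"]) for m in obj.get("refinement", [])]
    except (KeyError, TypeError) as e:
        raise FormatError(f"{path}: malformed marker entry: {e}") from e
    ms = MarkerSet(anatomical=anatomical, refinement=refinement)
    if volume is not None:
        ms.validate_against(volume)
    return ms


def write_markers(ms: MarkerSet, path: str | Path) -> None:
    obj = {
        "anatomical": [
            {"tag": m.tag, "point_mm": m.point_mm.tolist()} for m in ms.anatomical
        ],
        "refinement": [
            {"polarity": pol, "point_mm": p.tolist()} for p, pol in ms.refinement
        ],
    }
    Path(path).write_text(json.dumps(obj, indent=2))
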