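"""Deformation-aware point and slice correspondence between T2 and T1-FS.

The non-rigid transformation mapping T2 world points to T1-FS world points
is represented as a dense displacement field ``d`` sampled on the T2 grid:

    forward:  q = p + d(p)          (T2 -> T1-FS)
    inverse:  p = q - d(p)          solved by fixed-point iteration

Trilinear interpolation is used for ``d`` between grid nodes. The inverse is
well defined whenever the displacement gradient is bounded below 1, which
the phantom generator guarantees by construction and real registrations
satisfy for physiologically plausible inter-acquisition motion.

This module is the headless engine behind synchronized dual-modality
inspection: it computes where a cursor (or slice) in one sequence lands in
the other. The interactive viewer itself is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

from .core_io import FormatError, MRIVolume, _affine_from_geometry, _geometry_from_affine

__all__ = [
    "DeformationField",
    "DomainError",
    "InversionError",
    "SliceCorrespondence",
    "map_t2_to_t1fs",
    "map_t1fs_to_t2",
    "corresponding_slice",
    "read_field",
    "write_field",
]


class DomainError(ValueError):
    """A query point lies outside the field domain."""


class InversionError(RuntimeError):
    """Fixed-point inversion failed to converge."""


@dataclass
class DeformationField:
    """Dense displacement field on the T2 grid, in mm.

    ``displacement`` has shape ``(nx, ny, nz, 3)``; component c at voxel
    (i, j, k) is the world-space displacement along axis c applied to the
    voxel-center point.
    """

    displacement: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.displacement.ndim != 4 or self.displacement.shape[3] != 3:
            raise ValueError(f"displacement must have shape (nx,ny,nz,3), got {self.displacement.shape}")
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacements must be finite")
        if not np.all(self.spacing > 0):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.displacement.shape[:3]  # type: ignore[return-value]

    @classmethod
    def identity(cls, like: MRIVolume) -> "DeformationField":
        return cls(np.zeros(like.shape + (3,)), like.spacing, like.origin)

    def in_domain(self, points: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d((np.asarray(points, float) - self.origin) / self.spacing)
        upper = np.array(self.shape) - 1
        return np.all((idx >= 0) & (idx <= upper), axis=1)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        """Trilinearly interpolated displacement at world point(s), mm.

        Out-of-domain points use edge extension (nearest in-domain value);
        callers that must reject them check :meth:`in_domain` first.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        idx = ((pts - self.origin) / self.spacing).T  # (3, n)
        out = np.empty((pts.shape[0], 3))
        for c in range(3):
            out[:, c] = map_coordinates(
                self.displacement[..., c], idx, order=1, mode="nearest"
            )
        return out if np.asarray(points).ndim > 1 else out[0]

    # -- forward / inverse point mapping -----------------------------------

    def map_forward(self, points: np.ndarray, check_domain: bool = True) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        if check_domain:
            ok = self.in_domain(pts)
            if not np.all(ok):
                raise DomainError(f"{np.count_nonzero(~ok)} point(s) outside the field domain")
        return pts + self(pts)

    def map_inverse(
        self,
        points: np.ndarray,
        tol: float = 0.05,
        max_iter: int = 50,
        raise_on_failure: bool = True,
    ) -> np.ndarray:
        """Invert the field at world point(s) by fixed-point iteration.

        Solves ``x + d(x) = q`` via ``x_{k+1} = q - d(x_k)``, starting from
        ``x_0 = q``; converged when every point moves < ``tol`` mm.
        """
        q = np.atleast_2d(np.asarray(points, dtype=np.float64))
        x = q.copy()
        residual = np.inf
        for _ in range(max_iter):
            x_new = q - self(x)
            residual = float(np.max(np.linalg.norm(x_new - x, axis=1)))
            x = x_new
            if residual < tol:
                break
        else:
            if raise_on_failure:
                raise InversionError(
                    f"fixed-point inversion did not converge: residual {residual:.4f} mm "
                    f"after {max_iter} iterations (tol {tol} mm)"
                )
        return x if np.asarray(points).ndim > 1 else x[0]

    def check_invertibility(self, n_samples: int = 1000, seed: int = 0, tol: float = 0.05) -> float:
        """Spot-check inversion on random in-domain points.

        Returns the mean forward-then-inverse residual (mm); raises
        :class:`InversionError` if the iteration diverges anywhere sampled.
        """
        rng = np.random.default_rng(seed)
        lo = self.origin
        hi = self.origin + (np.array(self.shape) - 1) * self.spacing
        pts = rng.uniform(lo, hi, size=(n_samples, 3))
        fwd = self.map_forward(pts)
        back = self.map_inverse(fwd, tol=tol)
        return float(np.mean(np.linalg.norm(back - pts, axis=1)))


def map_t2_to_t1fs(p: np.ndarray, field: DeformationField) -> np.ndarray:
    """World point in T2 space -> corresponding T1-FS world point."""
    return field.map_forward(p)


def map_t1fs_to_t2(q: np.ndarray, field: DeformationField) -> np.ndarray:
    """World point in T1-FS space -> corresponding T2 world point."""
    return field.map_inverse(q)


@dataclass
class SliceCorrespondence:
    slice_index: int
    cursor: tuple[float, float]
    in_view: bool


def corresponding_slice(
    slice_axis: int,
    slice_index: int,
    cursor: tuple[float, float],
    src: MRIVolume,
    dst: MRIVolume,
    field: DeformationField,
    direction: str,
) -> SliceCorrespondence:
    """Synchronized-navigation lookup: map a slice/cursor position across modalities.

    The 2D cursor holds the continuous voxel coordinates of the two in-slice
    axes of ``src`` (in axis order, the slice axis removed). Direction is
    ``"t2_to_t1fs"`` or ``"t1fs_to_t2"``. A mapped point that lands outside
    ``dst`` is returned flagged ``in_view=False`` (nearest slice, unclamped
    cursor) rather than raised, so a UI layer can decide what to do.
    """
    if slice_axis not in (0, 1, 2):
        raise ValueError(f"slice_axis must be 0, 1 or 2, got {slice_axis}")
    in_plane = [a for a in range(3) if a != slice_axis]
    vox = np.empty(3)
    vox[slice_axis] = slice_index
    vox[in_plane[0]], vox[in_plane[1]] = cursor
    world = src.voxel_to_world(vox)
    if direction == "t2_to_t1fs":
        mapped = map_t2_to_t1fs(world, field)
    elif direction == "t1fs_to_t2":
        mapped = map_t1fs_to_t2(world, field)
    else:
        raise ValueError(f"direction must be 't2_to_t1fs' or 't1fs_to_t2', got {direction!r}")
    dvox = dst.world_to_voxel(mapped)
    idx = int(np.rint(dvox[slice_axis]))
    out_cursor = (float(dvox[in_plane[0]]), float(dvox[in_plane[1]]))
    in_view = bool(np.all(dvox >= 0) and np.all(dvox <= np.array(dst.shape) - 1))
    return SliceCorrespondence(slice_index=idx, cursor=out_cursor, in_view=in_view)


# ---------------------------------------------------------------------------
# Field I/O: 3-component NIfTI on the T2 grid, displacements in mm
# ---------------------------------------------------------------------------

def write_field(field: DeformationField, path: str | Path) -> None:
    img = nib.Nifti1Image(
        field.displacement.astype(np.float64),
        _affine_from_geometry(field.spacing, field.origin),
    )
    nib.save(img, str(path))


def read_field(path: str | Path) -> DeformationField:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 5 and data.shape[3] == 1:  # NIfTI vector-image convention
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 3:
        raise FormatError(f"{path}: expected a 3-component displacement image, got {data.shape}")
    spacing, origin = _geometry_from_affine(img.affine, path)
    return DeformationField(data.astype(np.float64), spacing, origin)
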