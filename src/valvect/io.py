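"""Volume and valve-plane I/O.

Contracts established here and relied on everywhere else:

* intensities are Hounsfield units (HU), stored as float64 with any
  NIfTI ``scl_slope``/``scl_inter`` rescale already applied exactly once;
* all world coordinates are millimetres in a single RAS-style frame —
  volumes are reoriented to the closest canonical orientation on load;
* the valve plane is described by an annulus centre, a unit normal
  pointing from the annulus towards the aorta, and an ordered annulus
  contour lying in the plane.

The plane sidecar is a small YAML file::

    centre_mm: [x, y, z]
    normal: [x, y, z]          # need not be unit length; renormalised
    contour_mm:
      - [x, y, z]              # >= 3 points, each within 0.5 mm of plane
      - ...
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml
from shapely.geometry import LinearRing

from .exceptions import InputError, PlaneValidationError

#: Maximum allowed distance (mm) of a contour point from the annulus plane.
PLANE_TOL_MM = 0.5


@dataclass(frozen=True)
class CTVolume:
    """A 3-D CT intensity grid in HU with voxel-to-world geometry.

    Parameters
    ----------
    intensities : ndarray, shape (nx, ny, nz)
        Voxel intensities in Hounsfield units. May be negative (air ~ -1000).
    affine : ndarray, shape (4, 4)
        Voxel index -> world-mm map.
    frame : str
        Label of the world-axis convention; ``"RAS"`` after `read_volume`.
    """

    intensities: np.ndarray
    affine: np.ndarray
    frame: str = "RAS"

    def __post_init__(self) -> None:
        inten = np.asarray(self.intensities, dtype=np.float64)
        aff = np.asarray(self.affine, dtype=np.float64)
        if inten.ndim != 3:
            raise InputError(f"expected a 3-D volume, got shape {inten.shape}")
        if not np.all(np.isfinite(inten)):
            raise InputError("volume contains non-finite intensities")
        if aff.shape != (4, 4):
            raise InputError(f"affine must be 4x4, got {aff.shape}")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise InputError(f"affine is not invertible:\n{aff}")
        object.__setattr__(self, "intensities", inten)
        object.__setattr__(self, "affine", aff)
        if np.any(self.spacing <= 0):
            raise InputError(f"non-positive voxel spacing {self.spacing}")

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Map world-mm points (n, 3) to fractional voxel indices (n, 3)."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=np.float64))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(idx, dtype=np.float64))
        return pts @ self.affine[:3, :3].T + self.affine[:3, 3]


def in_plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal in-plane basis (u, v) for a unit normal.

    The first basis vector is the projection of the world axis least aligned
    with the normal, so an axis-aligned plane (normal +z) gets u=+x, v=+y.
    """
    n = np.asarray(normal, dtype=np.float64)
    axis = np.eye(3)[int(np.argmin(np.abs(n)))]
    u = axis - np.dot(axis, n) * n
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


@dataclass(frozen=True)
class ValvePlaneDefinition:
    """Annulus centre, valve-axis unit normal and annulus contour (world mm).

    The normal points from the annulus towards the aorta; slices are
    extracted at positive offsets along it. The contour must lie within
    `PLANE_TOL_MM` of the plane and be simple when projected into it.
    """

    centre: np.ndarray
    normal: np.ndarray
    contour: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        centre = np.asarray(self.centre, dtype=np.float64).reshape(3)
        normal = np.asarray(self.normal, dtype=np.float64).reshape(3)
        norm = np.linalg.norm(normal)
        if norm < 1e-12:
            raise PlaneValidationError("plane normal has zero length")
        normal = normal / norm
        contour = np.asarray(self.contour, dtype=np.float64)
        if contour.ndim != 2 or contour.shape[1] != 3 or contour.shape[0] < 3:
            raise PlaneValidationError(
                f"contour must be an (n>=3, 3) point list, got shape {contour.shape}"
            )
        dists = (contour - centre) @ normal
        worst = int(np.argmax(np.abs(dists)))
        if abs(dists[worst]) >= PLANE_TOL_MM:
            raise PlaneValidationError(
                f"contour point {worst} at {contour[worst]} lies "
                f"{abs(dists[worst]):.3f} mm off the annulus plane "
                f"(tolerance {PLANE_TOL_MM} mm)"
            )
        if not LinearRing(self.project_contour(centre, normal, contour)).is_simple:
            raise PlaneValidationError("projected annulus contour self-intersects")
        object.__setattr__(self, "centre", centre)
        object.__setattr__(self, "normal", normal)
        object.__setattr__(self, "contour", contour)

    @staticmethod
    def project_contour(
        centre: np.ndarray, normal: np.ndarray, contour: np.ndarray
    ) -> np.ndarray:
        u, v = in_plane_basis(normal)
        rel = contour - centre
        return np.column_stack([rel @ u, rel @ v])

    @property
    def contour_2d(self) -> np.ndarray:
        """Contour projected into the plane's (u, v) coordinates, mm."""
        return self.project_contour(self.centre, self.normal, self.contour)


def read_volume(path: str | Path) -> CTVolume:
    """Read a NIfTI-1/2 volume as HU, reoriented to the canonical RAS frame.

    nibabel's floating-point access applies ``scl_slope``/``scl_inter``
    exactly once, which is how stored integers become HU.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"volume file not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise InputError(f"could not parse {path} as NIfTI: {exc}") from exc
    img = nib.as_closest_canonical(img)
    affine = np.asarray(img.affine, dtype=np.float64)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise InputError(f"{path}: affine is not invertible:\n{affine}")
    data = np.asarray(img.get_fdata(dtype=np.float64))
    return CTVolume(intensities=data, affine=affine, frame="RAS")


def write_volume(volume: CTVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 (float32 intensities, no rescale)."""
    img = nib.Nifti1Image(volume.intensities.astype(np.float32), volume.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_plane_definition(path: str | Path) -> ValvePlaneDefinition:
    """Read and validate a valve-plane YAML sidecar."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"plane sidecar not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise InputError(f"could not parse plane sidecar {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise InputError(f"plane sidecar {path} is not a key-value mapping")
    missing = {"centre_mm", "normal", "contour_mm"} - set(raw)
    if missing:
        raise InputError(f"plane sidecar {path} missing keys: {sorted(missing)}")
    return ValvePlaneDefinition(
        centre=np.asarray(raw["centre_mm"], dtype=np.float64),
        normal=np.asarray(raw["normal"], dtype=np.float64),
        contour=np.asarray(raw["contour_mm"], dtype=np.float64),
    )


def write_plane_definition(plane: ValvePlaneDefinition, path: str | Path) -> None:
    payload = {
        "centre_mm": [float(x) for x in plane.centre],
        "normal": [float(x) for x in plane.normal],
        "contour_mm": [[float(x) for x in p] for p in plane.contour],
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
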