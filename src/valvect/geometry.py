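"""Valve short-axis geometry: oblique reslicing and annulus area.

The analysis frame mirrors the clinical workflow: a multiplanar
reconstruction oriented in the valve short-axis plane, with the annulus as
the reference boundary, resliced in 3 mm increments towards the aorta.
Each output pixel of a slice is the mean of several trilinear samples
spread through the 3 mm slab, emulating a thick-slice reconstruction of a
thin-slice acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from shapely import contains_xy
from shapely.geometry import Polygon

from .exceptions import GeometryError, PlaneValidationError
from .io import CTVolume, ValvePlaneDefinition, in_plane_basis

#: Analysis slab thickness (mm), chosen for consistency with 3 mm
#: non-contrast calcium-score reconstructions.
DEFAULT_SLICE_THICKNESS_MM = 3.0
DEFAULT_IN_PLANE_SPACING_MM = 0.5
DEFAULT_N_SLICES = 5
#: Number of trilinear samples averaged through the slab depth per pixel.
DEFAULT_SLAB_SAMPLES = 5
#: The default per-slice ROI is the annulus contour hull dilated by this
#: margin at the annulus, shrinking per slice moving towards the aorta so
#: that aortic-wall and coronary calcium is excluded from analysis.
DEFAULT_ROI_DILATE_MM = 2.0
DEFAULT_ROI_SHRINK_PER_SLICE_MM = 1.0


@dataclass(frozen=True)
class ValveSliceStack:
    """Ordered short-axis slabs above the annulus plane.

    ``slices[k]`` is a 2-D HU grid whose centre is ``origin_offsets[k]`` mm
    above the annulus along the valve normal; pixel (i, j) sits at in-plane
    coordinates ``grid_coords``. ``roi_mask[k]`` restricts analysis to the
    valve region on that slice.
    """

    slices: np.ndarray  # (n, H, W)
    slice_thickness: float
    in_plane_spacing: float
    origin_offsets: np.ndarray  # (n,)
    roi_mask: np.ndarray  # (n, H, W) bool
    centre: np.ndarray  # world mm
    basis_u: np.ndarray
    basis_v: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        if self.slices.shape != self.roi_mask.shape:
            raise GeometryError("roi_mask shape must match slices")
        steps = np.diff(self.origin_offsets)
        if len(steps) and not np.allclose(steps, self.slice_thickness, atol=1e-9):
            raise GeometryError("origin_offsets must increase by slice_thickness")
        if not np.isclose(
            self.origin_offsets[0], self.slice_thickness / 2.0, atol=1e-9
        ):
            raise GeometryError("first slice must be centred thickness/2 above annulus")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def pixel_area_mm2(self) -> float:
        return self.in_plane_spacing**2

    def grid_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """In-plane (u, v) mm coordinates of pixel centres, each (H, W)."""
        h, w = self.slices.shape[1:]
        u = (np.arange(w) - (w - 1) / 2.0) * self.in_plane_spacing
        v = (np.arange(h) - (h - 1) / 2.0) * self.in_plane_spacing
        return np.meshgrid(u, v, indexing="xy")


def _grid_axis(half_extent_mm: float, spacing: float) -> np.ndarray:
    n = int(np.ceil(half_extent_mm / spacing))
    return np.arange(-n, n + 1) * spacing


def reslice_valve(
    volume: CTVolume,
    plane: ValvePlaneDefinition,
    n_slices: int = DEFAULT_N_SLICES,
    thickness_mm: float = DEFAULT_SLICE_THICKNESS_MM,
    in_plane_spacing_mm: float = DEFAULT_IN_PLANE_SPACING_MM,
    n_slab_samples: int = DEFAULT_SLAB_SAMPLES,
    half_extent_mm: float | None = None,
    roi_dilate_mm: float = DEFAULT_ROI_DILATE_MM,
    roi_shrink_per_slice_mm: float = DEFAULT_ROI_SHRINK_PER_SLICE_MM,
) -> ValveSliceStack:
    """Reslice a volume into ``n_slices`` slabs above the annulus plane.

    The stack covers [0, n_slices * thickness] mm along the valve normal,
    the first slab being [0, thickness]. Pixel values are slab-averaged
    intensities: the mean of ``n_slab_samples`` trilinear samples taken at
    the centres of equal sub-slabs.

    Raises
    ------
    GeometryError
        If any sample of any slab falls outside the volume; the first
        offending slice index is reported.
    """
    if n_slices < 1 or thickness_mm <= 0 or in_plane_spacing_mm <= 0:
        raise GeometryError("n_slices, thickness and spacing must be positive")
    u, v = in_plane_basis(plane.normal)
    contour2d = plane.contour_2d
    if half_extent_mm is None:
        half_extent_mm = float(np.abs(contour2d).max() + roi_dilate_mm + 2.0)
    ax = _grid_axis(half_extent_mm, in_plane_spacing_mm)
    uu, vv = np.meshgrid(ax, ax, indexing="xy")  # (H, W)
    base = plane.centre + uu[..., None] * u + vv[..., None] * v  # (H, W, 3)

    # sub-slab sample offsets relative to the slab centre
    rel = (np.arange(n_slab_samples) + 0.5) / n_slab_samples - 0.5
    rel *= thickness_mm

    offsets = (np.arange(n_slices) + 0.5) * thickness_mm
    shape = np.asarray(volume.shape, dtype=np.float64)
    slices = np.empty((n_slices, *uu.shape), dtype=np.float64)
    for k, off in enumerate(offsets):
        acc = np.zeros(uu.shape, dtype=np.float64)
        for dz in rel:
            pts = base + (off + dz) * plane.normal
            vox = volume.world_to_voxel(pts.reshape(-1, 3))
            if (vox < -1e-6).any() or (vox > shape - 1 + 1e-6).any():
                raise GeometryError(
                    f"slice {k} (offset {off:.1f} mm) samples outside the volume"
                )
            acc += map_coordinates(
                volume.intensities, vox.T, order=1, mode="nearest"
            ).reshape(uu.shape)
        slices[k] = acc / n_slab_samples

    hull = Polygon(contour2d).convex_hull
    roi = np.zeros((n_slices, *uu.shape), dtype=bool)
    for k in range(n_slices):
        margin = roi_dilate_mm - k * roi_shrink_per_slice_mm
        poly = hull.buffer(margin)
        if poly.is_empty:
            continue
        roi[k] = contains_xy(poly, uu.ravel(), vv.ravel()).reshape(uu.shape)

    return ValveSliceStack(
        slices=slices,
        slice_thickness=float(thickness_mm),
        in_plane_spacing=float(in_plane_spacing_mm),
        origin_offsets=offsets,
        roi_mask=roi,
        centre=plane.centre,
        basis_u=u,
        basis_v=v,
        normal=plane.normal,
    )


def annulus_area(plane: ValvePlaneDefinition) -> float:
    """Polygon (shoelace) area of the annulus contour, in cm^2.

    Orientation-independent; raises if the projected contour
    self-intersects.
    """
    pts = plane.contour_2d
    ring = Polygon(pts)
    if not ring.is_valid:
        raise PlaneValidationError("annulus contour self-intersects; area undefined")
    x, y = pts[:, 0], pts[:, 1]
    area_mm2 = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return float(area_mm2 / 100.0)
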