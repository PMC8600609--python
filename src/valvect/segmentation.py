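"""Seeded region growing of calcific and non-calcific leaflet tissue.

Mirrors the slice-by-slice clinical workflow: on each 3 mm short-axis
slab, voxels within a calibrated HU band are selected by 8-connected
region growing from seed points inside the valve ROI. Automatic seeding
(one seed at the maximum-HU pixel of each sufficiently large in-band
component) stands in for the operator's clicks; explicit seed lists are
accepted for parity with the manual workflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .calibration import ThresholdSet
from .exceptions import SegmentationError
from .geometry import ValveSliceStack

#: Connectivity structure for in-plane region growing (8-connected).
_STRUCT8 = np.ones((3, 3), dtype=bool)
#: Components smaller than this are never auto-seeded (suppresses
#: single-pixel noise; matches the calcium-score lesion floor).
DEFAULT_MIN_COMPONENT_MM2 = 1.0


@dataclass(frozen=True)
class SliceSegmentation:
    """Per-slice calcific / non-calcific masks (disjoint by construction)."""

    calc_mask: np.ndarray
    noncalc_mask: np.ndarray
    slice_index: int
    calc_seeds: tuple[tuple[int, int], ...] = ()
    noncalc_seeds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.calc_mask.shape != self.noncalc_mask.shape:
            raise SegmentationError("class masks must share a shape")
        if np.any(self.calc_mask & self.noncalc_mask):
            raise SegmentationError("calcific and non-calcific masks overlap")

    @property
    def seed_points(self) -> tuple[tuple[int, int], ...]:
        return self.calc_seeds + self.noncalc_seeds


def _in_band(
    slice_hu: np.ndarray,
    hu_range: tuple[float, float],
    inclusive_low: bool,
) -> np.ndarray:
    low, high = hu_range
    lower = slice_hu >= low if inclusive_low else slice_hu > low
    return lower & (slice_hu < high)


def region_grow(
    slice_hu: np.ndarray,
    seeds: list[tuple[int, int]] | tuple[tuple[int, int], ...],
    hu_range: tuple[float, float],
    roi: np.ndarray | None = None,
    inclusive_low: bool = True,
) -> np.ndarray:
    """Union of 8-connected in-band components containing each seed.

    ``hu_range`` is [low, high) when ``inclusive_low`` (the non-calcific
    convention) and (low, high) otherwise (the calcium convention, where
    ``high`` is typically +inf).

    Raises
    ------
    SegmentationError
        If a seed lies outside the ROI or outside the HU band (the seed and
        its HU value are reported).
    """
    slice_hu = np.asarray(slice_hu, dtype=np.float64)
    if roi is None:
        roi = np.ones(slice_hu.shape, dtype=bool)
    band = _in_band(slice_hu, hu_range, inclusive_low) & roi
    labels, _ = ndimage.label(band, structure=_STRUCT8)
    mask = np.zeros(slice_hu.shape, dtype=bool)
    for r, c in seeds:
        r, c = int(r), int(c)
        if not (0 <= r < slice_hu.shape[0] and 0 <= c < slice_hu.shape[1]):
            raise SegmentationError(f"seed ({r}, {c}) outside the slice")
        if not roi[r, c]:
            raise SegmentationError(f"seed ({r}, {c}) lies outside the ROI")
        if not band[r, c]:
            raise SegmentationError(
                f"seed ({r}, {c}) HU {slice_hu[r, c]:.1f} outside band "
                f"{hu_range} (inclusive_low={inclusive_low})"
            )
        mask |= labels == labels[r, c]
    return mask


def auto_seed(
    slice_hu: np.ndarray,
    hu_range: tuple[float, float],
    roi: np.ndarray | None = None,
    spacing_mm: float = 0.5,
    min_component_mm2: float = DEFAULT_MIN_COMPONENT_MM2,
    inclusive_low: bool = True,
) -> list[tuple[int, int]]:
    """One seed (max-HU pixel) per in-band component of sufficient area.

    Ties at the maximum HU break deterministically in row-major order.
    Returns an empty list when nothing is in band.
    """
    slice_hu = np.asarray(slice_hu, dtype=np.float64)
    if roi is None:
        roi = np.ones(slice_hu.shape, dtype=bool)
    band = _in_band(slice_hu, hu_range, inclusive_low) & roi
    labels, n = ndimage.label(band, structure=_STRUCT8)
    if n == 0:
        return []
    min_pixels = int(np.ceil(min_component_mm2 / spacing_mm**2))
    counts = np.bincount(labels.ravel())
    seeds: list[tuple[int, int]] = []
    flat = slice_hu.ravel()
    for lab in range(1, n + 1):
        if counts[lab] < min_pixels:
            continue
        idx = np.flatnonzero(labels.ravel() == lab)
        best = idx[np.argmax(flat[idx])]  # argmax -> first (row-major) tie win
        seeds.append((int(best // slice_hu.shape[1]), int(best % slice_hu.shape[1])))
    return seeds


def segment_slice(
    slice_hu: np.ndarray,
    thresholds: ThresholdSet,
    roi: np.ndarray | None = None,
    spacing_mm: float = 0.5,
    slice_index: int = 0,
    calc_seeds: list[tuple[int, int]] | None = None,
    noncalc_seeds: list[tuple[int, int]] | None = None,
    min_component_mm2: float = DEFAULT_MIN_COMPONENT_MM2,
) -> SliceSegmentation:
    """Grow both tissue classes on one slice.

    Calcium grows in (calc_lower, inf); non-calcific tissue in
    [30, noncalc_upper) with the calcium mask subtracted afterwards so the
    classes partition the leaflet even if configuration widens the bands.
    Auto-seeded unless explicit seeds are supplied.
    """
    calc_band = (thresholds.calc_lower_hu, np.inf)
    noncalc_band = thresholds.noncalc_band
    if calc_seeds is None:
        calc_seeds = auto_seed(
            slice_hu, calc_band, roi, spacing_mm, min_component_mm2,
            inclusive_low=False,
        )
    if noncalc_seeds is None:
        noncalc_seeds = auto_seed(
            slice_hu, noncalc_band, roi, spacing_mm, min_component_mm2,
            inclusive_low=True,
        )
    calc_mask = region_grow(slice_hu, calc_seeds, calc_band, roi, inclusive_low=False)
    noncalc_mask = region_grow(
        slice_hu, noncalc_seeds, noncalc_band, roi, inclusive_low=True
    )
    noncalc_mask &= ~calc_mask
    return SliceSegmentation(
        calc_mask=calc_mask,
        noncalc_mask=noncalc_mask,
        slice_index=slice_index,
        calc_seeds=tuple((int(r), int(c)) for r, c in calc_seeds),
        noncalc_seeds=tuple((int(r), int(c)) for r, c in noncalc_seeds),
    )


def segment_stack(
    stack: ValveSliceStack,
    thresholds: ThresholdSet,
    min_component_mm2: float = DEFAULT_MIN_COMPONENT_MM2,
) -> list[SliceSegmentation]:
    """Segment every slice of a stack within its per-slice ROI."""
    return [
        segment_slice(
            stack.slices[k],
            thresholds,
            roi=stack.roi_mask[k],
            spacing_mm=stack.in_plane_spacing,
            slice_index=k,
            min_component_mm2=min_component_mm2,
        )
        for k in range(stack.n_slices)
    ]


def labels_from_segmentations(segs: list[SliceSegmentation]) -> np.ndarray:
    """Stack per-slice masks into a label map: 0 bg, 1 non-calcific, 2 calcific."""
    out = np.zeros((len(segs), *segs[0].calc_mask.shape), dtype=np.uint8)
    for k, seg in enumerate(segs):
        out[k][seg.noncalc_mask] = 1
        out[k][seg.calc_mask] = 2
    return out
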