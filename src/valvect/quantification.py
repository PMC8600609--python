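"""Valve quantification: volumes, annulus indexing, fibrocalcific scores,
and the standard non-contrast calcium (Agatston) score.

The headline outputs, matching the units of clinical reporting:

* indexed calcific / non-calcific volumes, mm^3 per cm^2 of annulus area;
* fibrocalcific volume = indexed calcific + indexed non-calcific;
* fibrocalcific ratio  = indexed non-calcific / indexed calcific, with an
  explicit ``UNDEFINED_RATIO`` sentinel (not a float infinity) when the
  valve carries no calcium — such valves rank above every finite ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import total_ordering

import numpy as np
from scipy import ndimage

from .exceptions import InputError, ValvectError
from .geometry import ValveSliceStack
from .io import CTVolume
from .segmentation import SliceSegmentation

FIBROSIS_PREDOMINANT = "fibrosis-predominant"
CALCIUM_DOMINANT = "calcium-dominant"

#: Agatston constants: HU floor, lesion area floor, weight band edges.
AGATSTON_HU_THRESHOLD = 130.0
AGATSTON_MIN_LESION_MM2 = 1.0
_AGATSTON_WEIGHT_EDGES = np.array([200.0, 300.0, 400.0])
_STRUCT4 = ndimage.generate_binary_structure(2, 1)


@total_ordering
class _UndefinedRatio:
    """Sentinel for a fibrocalcific ratio with zero calcific volume.

    Compares greater than every number, so valves without calcium sort
    above all finite ratios in rank-based statistics.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNDEFINED_RATIO"

    def __eq__(self, other) -> bool:
        return other is self

    def __gt__(self, other) -> bool:
        return other is not self

    def __hash__(self) -> int:
        return hash("UNDEFINED_RATIO")


UNDEFINED_RATIO = _UndefinedRatio()


@dataclass(frozen=True)
class ValveQuantification:
    """Absolute and annulus-indexed leaflet volumes plus derived scores."""

    calc_volume_mm3: float
    noncalc_volume_mm3: float
    annulus_area_cm2: float
    indexed_calc: float
    indexed_noncalc: float
    fibrocalcific_volume: float
    fibrocalcific_ratio: float | _UndefinedRatio
    n_slices: int
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        ratio = self.fibrocalcific_ratio
        return {
            "calc_volume_mm3": self.calc_volume_mm3,
            "noncalc_volume_mm3": self.noncalc_volume_mm3,
            "annulus_area_cm2": self.annulus_area_cm2,
            "indexed_calc_mm3_per_cm2": self.indexed_calc,
            "indexed_noncalc_mm3_per_cm2": self.indexed_noncalc,
            "fibrocalcific_volume_mm3_per_cm2": self.fibrocalcific_volume,
            "fibrocalcific_ratio": None if ratio is UNDEFINED_RATIO else ratio,
            "n_slices": self.n_slices,
            "flags": list(self.flags),
        }


@dataclass(frozen=True)
class AgatstonResult:
    """Standard calcium score with per-slice subtotals."""

    score: float
    n_lesions: int
    per_slice: tuple[float, ...] = field(repr=False, default=())

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValvectError("Agatston score cannot be negative")
        if (self.score == 0) != (self.n_lesions == 0):
            raise ValvectError("score must be zero exactly when no lesions exist")


def mask_volume(
    masks: list[np.ndarray] | np.ndarray,
    in_plane_spacing_mm: float,
    slice_thickness_mm: float,
) -> float:
    """Total volume (mm^3) of true pixels across per-slice masks."""
    masks = [np.asarray(m, dtype=bool) for m in masks]
    if len({m.shape for m in masks}) > 1:
        raise InputError("per-slice masks must share a shape")
    count = sum(int(m.sum()) for m in masks)
    return count * in_plane_spacing_mm**2 * slice_thickness_mm


def quantify_valve(
    segs: list[SliceSegmentation],
    geometry: ValveSliceStack,
    annulus_area_cm2: float,
    extra_flags: tuple[str, ...] = (),
) -> ValveQuantification:
    """Assemble the quantification record from per-slice segmentations.

    Upstream audit flags (e.g. a clamped threshold set) are propagated via
    ``extra_flags``; a valve with no calcific tissue gets the
    ``no-calcium`` flag and the undefined-ratio sentinel.
    """
    if annulus_area_cm2 <= 0:
        raise InputError(f"annulus area must be positive, got {annulus_area_cm2}")
    calc = mask_volume(
        [s.calc_mask for s in segs], geometry.in_plane_spacing, geometry.slice_thickness
    )
    noncalc = mask_volume(
        [s.noncalc_mask for s in segs],
        geometry.in_plane_spacing,
        geometry.slice_thickness,
    )
    indexed_calc = calc / annulus_area_cm2
    indexed_noncalc = noncalc / annulus_area_cm2
    flags = tuple(extra_flags)
    if calc == 0:
        ratio: float | _UndefinedRatio = UNDEFINED_RATIO
        flags += ("no-calcium",)
    else:
        ratio = indexed_noncalc / indexed_calc
    return ValveQuantification(
        calc_volume_mm3=calc,
        noncalc_volume_mm3=noncalc,
        annulus_area_cm2=float(annulus_area_cm2),
        indexed_calc=indexed_calc,
        indexed_noncalc=indexed_noncalc,
        fibrocalcific_volume=indexed_calc + indexed_noncalc,
        fibrocalcific_ratio=ratio,
        n_slices=len(segs),
        flags=flags,
    )


def classify_predominance(q: ValveQuantification) -> str:
    """Fibrosis-predominant (ratio > 1, or no calcium with non-calcific
    tissue present) versus calcium-dominant (ratio <= 1).

    The boundary itself is calcium-dominant: a ratio of exactly 1.0 means
    at least half the measured volume is calcification.
    """
    if q.calc_volume_mm3 == 0 and q.noncalc_volume_mm3 == 0:
        raise ValvectError("empty valve: both tissue volumes are zero")
    ratio = q.fibrocalcific_ratio
    if ratio is UNDEFINED_RATIO:
        return FIBROSIS_PREDOMINANT
    return FIBROSIS_PREDOMINANT if ratio > 1.0 else CALCIUM_DOMINANT


def _agatston_weight(peak_hu: float) -> int:
    return int(np.searchsorted(_AGATSTON_WEIGHT_EDGES, peak_hu, side="right")) + 1


def agatston_score(
    volume: CTVolume,
    roi: np.ndarray | None = None,
    allow_nonstandard_thickness: bool = False,
) -> AgatstonResult:
    """Standard Agatston score of a non-contrast volume on 3 mm axial slices.

    Per slice, 4-connected lesions of pixels >= 130 HU with area >= 1 mm^2
    contribute area (mm^2) times a peak-HU weight (130-199 -> 1,
    200-299 -> 2, 300-399 -> 3, >= 400 -> 4). This is the comparison path
    against non-contrast calcium scoring, not the contrast-CT method.

    ``roi`` may be a per-slice boolean array of shape (nx, ny, nz) limiting
    scoring to the valve region.
    """
    sx, sy, sz = volume.spacing
    if not np.isclose(sz, 3.0, atol=0.01) and not allow_nonstandard_thickness:
        raise InputError(
            f"Agatston scoring expects 3 mm slices, got {sz:.3f} mm; pass "
            "allow_nonstandard_thickness=True to override"
        )
    pixel_area = sx * sy
    min_pixels_area = AGATSTON_MIN_LESION_MM2
    data = volume.intensities
    if roi is not None and roi.shape != data.shape:
        raise InputError("roi shape must match the volume")
    score = 0.0
    n_lesions = 0
    per_slice: list[float] = []
    for k in range(data.shape[2]):
        sl = data[:, :, k]
        mask = sl >= AGATSTON_HU_THRESHOLD
        if roi is not None:
            mask &= roi[:, :, k]
        labels, n = ndimage.label(mask, structure=_STRUCT4)
        subtotal = 0.0
        for lab in range(1, n + 1):
            lesion = labels == lab
            area = lesion.sum() * pixel_area
            if area < min_pixels_area:
                continue
            subtotal += area * _agatston_weight(float(sl[lesion].max()))
            n_lesions += 1
        per_slice.append(subtotal)
        score += subtotal
    return AgatstonResult(
        score=float(score), n_lesions=n_lesions, per_slice=tuple(per_slice)
    )
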