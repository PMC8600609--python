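"""End-to-end quantification pipeline.

Wires the stages together: read volume + valve plane, reslice into 3 mm
short-axis slabs, sample the blood pool, derive adaptive thresholds,
segment each slab, and index the resulting volumes to the annulus area.
`RunConfig` holds every tunable with defaults reproducing the method's
constants (30 HU floor, 3 SD calcium bound, 41.46 + 0.42 x blood pool,
3 mm slabs).
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from . import calibration as cal
from . import geometry, segmentation
from .io import CTVolume, ValvePlaneDefinition, read_plane_definition, read_volume
from .quantification import ValveQuantification, quantify_valve

log = logging.getLogger("valvect")


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one quantification run."""

    volume_path: str = ""
    plane_path: str = ""
    out_dir: str | None = None
    n_slices: int = geometry.DEFAULT_N_SLICES
    slice_thickness_mm: float = geometry.DEFAULT_SLICE_THICKNESS_MM
    in_plane_spacing_mm: float = geometry.DEFAULT_IN_PLANE_SPACING_MM
    intercept: float = cal.CALIBRATION_INTERCEPT_HU
    slope: float = cal.CALIBRATION_SLOPE
    sd_multiplier: float = cal.SD_MULTIPLIER
    fixed_lower_hu: float = cal.FIXED_NONCALC_LOWER_HU
    roi_area_mm2: float = cal.DEFAULT_ROI_AREA_MM2
    blood_pool_slice: int = -1
    min_component_mm2: float = segmentation.DEFAULT_MIN_COMPONENT_MM2
    seed: int = 0


@dataclass(frozen=True)
class PipelineResult:
    quantification: ValveQuantification
    thresholds: cal.ThresholdSet
    blood_pool: cal.BloodPoolStats
    stack: geometry.ValveSliceStack
    segmentations: list[segmentation.SliceSegmentation]


def quantify_volume(
    volume: CTVolume,
    plane: ValvePlaneDefinition,
    config: RunConfig = RunConfig(),
) -> PipelineResult:
    """Run the full quantification chain on in-memory inputs.

    The blood pool is sampled on the slice ``config.blood_pool_slice``
    (default: the most aortic slab, standing in for the sinotubular
    junction level) in a circular ROI centred on the valve axis.
    """
    stack = geometry.reslice_valve(
        volume,
        plane,
        n_slices=config.n_slices,
        thickness_mm=config.slice_thickness_mm,
        in_plane_spacing_mm=config.in_plane_spacing_mm,
    )
    bp_slice = stack.slices[config.blood_pool_slice]
    blood = cal.sample_blood_pool(
        bp_slice, stack.in_plane_spacing, roi_area_mm2=config.roi_area_mm2
    )
    thresholds = cal.derive_thresholds(
        blood,
        intercept=config.intercept,
        slope=config.slope,
        sd_multiplier=config.sd_multiplier,
        fixed_lower_hu=config.fixed_lower_hu,
    )
    log.info(
        "blood pool %.1f +/- %.1f HU -> calcium > %.1f HU, "
        "non-calcific [%.0f, %.1f) HU %s",
        blood.mean_hu,
        blood.sd_hu,
        thresholds.calc_lower_hu,
        thresholds.noncalc_lower_hu,
        thresholds.noncalc_upper_hu,
        thresholds.flags,
    )
    segs = segmentation.segment_stack(
        stack, thresholds, min_component_mm2=config.min_component_mm2
    )
    quant = quantify_valve(
        segs, stack, geometry.annulus_area(plane), extra_flags=thresholds.flags
    )
    return PipelineResult(
        quantification=quant,
        thresholds=thresholds,
        blood_pool=blood,
        stack=stack,
        segmentations=segs,
    )


def _stack_affine(stack: geometry.ValveSliceStack) -> np.ndarray:
    """Affine mapping (col, row, slice) label-map indices to world mm."""
    h, w = stack.slices.shape[1:]
    s = stack.in_plane_spacing
    origin = (
        stack.centre
        - (w - 1) / 2.0 * s * stack.basis_u
        - (h - 1) / 2.0 * s * stack.basis_v
        + stack.origin_offsets[0] * stack.normal
    )
    aff = np.eye(4)
    aff[:3, 0] = stack.basis_u * s
    aff[:3, 1] = stack.basis_v * s
    aff[:3, 2] = stack.normal * stack.slice_thickness
    aff[:3, 3] = origin
    return aff


def write_outputs(result: PipelineResult, config: RunConfig, out_dir: str | Path) -> None:
    """Write quantification CSV/JSON, the label map, and a structured log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    record = result.quantification.to_dict()

    with open(out / "quantification.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        keys = list(record)
        writer.writerow(keys)
        writer.writerow(
            [";".join(record[k]) if k == "flags" else record[k] for k in keys]
        )
    (out / "quantification.json").write_text(json.dumps(record, indent=2))

    labels = segmentation.labels_from_segmentations(result.segmentations)
    # label-map axes: (in-plane col, in-plane row, slice)
    img = nib.Nifti1Image(
        np.moveaxis(labels, 0, -1).transpose(1, 0, 2).astype(np.uint8),
        _stack_affine(result.stack),
    )
    nib.save(img, str(out / "labels.nii.gz"))

    run_log = {
        "config": dataclasses.asdict(config),
        "blood_pool": dataclasses.asdict(result.blood_pool),
        "thresholds": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(result.thresholds).items()
        },
        "flags": list(result.quantification.flags),
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2))


def run_quantify(config: RunConfig) -> ValveQuantification:
    """File-to-file entry point: read inputs, quantify, write artefacts."""
    volume = read_volume(config.volume_path)
    plane = read_plane_definition(config.plane_path)
    result = quantify_volume(volume, plane, config)
    if config.out_dir:
        write_outputs(result, config, config.out_dir)
    return result.quantification
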