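"""Digital valve phantoms and synthetic patient cohorts.

`generate_valve_phantom` builds a contrast-CT aortic root: a cylinder of
contrast-opacified blood, surrounding soft tissue, and a tri-leaflet ring
of valve tissue sitting on the annulus plane. Tissue is carved on analysis
columns (0.5 mm x 0.5 mm in-plane, one 3 mm slab deep) so that a clean
phantom resliced on the matching grid reproduces the ground-truth volumes
exactly; calcific tissue is placed as a nodule cluster embedded inside the
fibrotic arcs. Optional Gaussian partial-volume blur (applied to the clean
tissue map) and additive Gaussian noise emulate acquisition physics; truth
volumes are recorded before either.

`simulate_cohort` draws patients with the statistical structure of an
aortic-stenosis imaging cohort: a latent fibrocalcific burden drives peak
jet velocity, and females carry a lower calcific fraction of that burden
at matched velocity, so their fibrocalcific ratio is higher.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates

from .exceptions import CapacityError, InputError
from .geometry import ValveSliceStack
from .io import CTVolume, ValvePlaneDefinition

LABEL_BACKGROUND, LABEL_FIBROSIS, LABEL_CALCIUM = 0, 1, 2


@dataclass(frozen=True)
class PhantomSpec:
    """Configuration of one synthetic valve scan.

    Defaults describe a fibrosis-rich stenotic valve in a typically
    opacified root (blood pool 400 HU, cohort median ~401); fibrosis at
    150 HU sits mid-band for that opacification, calcium at 800 HU is
    always above mean + 3 SD for physiological pools. ``column_mm`` is the
    analysis-column pitch and must be an integer multiple of ``voxel_mm``.
    """

    blood_pool_hu: float = 400.0
    blood_pool_noise_sd: float = 0.0
    fibrosis_hu: float = 150.0
    calcium_hu: float = 800.0
    leaflet_count: int = 3
    fibrotic_volume_mm3: float = 1200.0
    calcific_volume_mm3: float = 240.0
    annulus_radius_mm: float = 12.5
    blur_sigma_px: float = 0.0
    seed: int = 0
    voxel_mm: float = 0.25
    column_mm: float = 0.5
    slab_thickness_mm: float = 3.0
    n_tissue_slabs: int = 2
    inner_radius_mm: float = 2.5
    sector_half_angle_deg: float = 50.0
    n_nodules: int = 1
    background_hu: float = 40.0
    lumen_margin_mm: float = 3.0

    def __post_init__(self) -> None:
        if not 200.0 <= self.blood_pool_hu <= 700.0:
            raise InputError(
                f"blood pool {self.blood_pool_hu} HU outside plausible "
                "contrast range [200, 700]"
            )
        if self.fibrotic_volume_mm3 < 0 or self.calcific_volume_mm3 < 0:
            raise InputError("target tissue volumes must be >= 0")
        if self.leaflet_count not in (2, 3):
            raise InputError("leaflet_count must be 2 (bicuspid) or 3")
        ratio = self.column_mm / self.voxel_mm
        if abs(ratio - round(ratio)) > 1e-9:
            raise InputError("column_mm must be an integer multiple of voxel_mm")

    @property
    def column_volume_mm3(self) -> float:
        return self.column_mm**2 * self.slab_thickness_mm


@dataclass(frozen=True)
class ValvePhantom:
    """A generated phantom: volume, plane, voxel truth labels, truth volumes."""

    volume: CTVolume
    plane: ValvePlaneDefinition
    labels: np.ndarray = field(repr=False)
    truth_fibrotic_mm3: float
    truth_calcific_mm3: float
    spec: PhantomSpec

    def truth_column_masks(self, stack: ValveSliceStack) -> dict[str, np.ndarray]:
        """Ground-truth per-slice class masks on a reslice grid.

        Looks up the truth label at each slice pixel centre (nearest
        voxel), giving masks directly comparable with segmentation output.
        """
        uu, vv = stack.grid_coords()
        fib = np.zeros((stack.n_slices, *uu.shape), dtype=bool)
        calc = np.zeros_like(fib)
        inv = np.linalg.inv(self.volume.affine)
        for k, off in enumerate(stack.origin_offsets):
            pts = (
                stack.centre
                + uu[..., None] * stack.basis_u
                + vv[..., None] * stack.basis_v
                + off * stack.normal
            )
            vox = pts.reshape(-1, 3) @ inv[:3, :3].T + inv[:3, 3]
            lab = map_coordinates(self.labels, vox.T, order=0, mode="nearest")
            lab = lab.reshape(uu.shape)
            fib[k] = lab == LABEL_FIBROSIS
            calc[k] = lab == LABEL_CALCIUM
        return {"noncalc": fib, "calc": calc}


def _leaflet_angles(count: int) -> np.ndarray:
    return np.deg2rad(90.0 + 360.0 / count * np.arange(count))


def generate_valve_phantom(spec: PhantomSpec) -> ValvePhantom:
    """Build a phantom volume with ground truth.

    Tissue is selected greedily on analysis columns by distance to leaflet
    anchor points (nodule anchors first for calcium, all anchors for
    fibrosis), which yields compact nodules wrapped in fibrotic tissue on
    every leaflet. Requested volumes are matched to within one analysis
    column (0.75 mm^3 at defaults); the realised truth volumes are
    recorded on the returned object.

    Raises
    ------
    CapacityError
        If the requested volumes exceed the leaflet band's capacity; the
        message reports the capacity in mm^3.
    """
    vox = spec.voxel_mm
    lumen_r = spec.annulus_radius_mm + spec.lumen_margin_mm
    half = lumen_r + 5.0
    n_half = int(math.ceil(half / vox))
    ax = np.arange(-n_half, n_half + 1) * vox
    z_below = 6.0
    z_above = max(18.0, spec.n_tissue_slabs * spec.slab_thickness_mm + 12.0)
    z_ax = np.arange(round(-z_below / vox), round(z_above / vox) + 1) * vox

    xx, yy = np.meshgrid(ax, ax, indexing="ij")
    lumen = (xx**2 + yy**2) <= lumen_r**2
    intens = np.full(
        (ax.size, ax.size, z_ax.size), spec.background_hu, dtype=np.float64
    )
    intens[lumen, :] = spec.blood_pool_hu

    # --- candidate analysis columns inside the leaflet band -----------------
    n_col_half = int(math.floor(spec.annulus_radius_mm / spec.column_mm))
    col_ax = np.arange(-n_col_half, n_col_half + 1) * spec.column_mm
    cxx, cyy = np.meshgrid(col_ax, col_ax, indexing="ij")
    rr = np.hypot(cxx, cyy)
    theta = np.arctan2(cyy, cxx)
    angles = _leaflet_angles(spec.leaflet_count)
    half_sector = np.deg2rad(spec.sector_half_angle_deg)
    ang_dist = np.min(
        np.abs((theta[..., None] - angles + np.pi) % (2 * np.pi) - np.pi), axis=-1
    )
    in_band = (
        (rr >= spec.inner_radius_mm)
        & (rr <= spec.annulus_radius_mm)
        & (ang_dist <= half_sector)
    )
    cx, cy = cxx[in_band], cyy[in_band]

    slab_t = spec.slab_thickness_mm
    slabs = np.arange(spec.n_tissue_slabs)
    col_x = np.tile(cx, spec.n_tissue_slabs)
    col_y = np.tile(cy, spec.n_tissue_slabs)
    col_s = np.repeat(slabs, cx.size)
    col_z = col_s * slab_t + slab_t / 2.0

    col_vol = spec.column_volume_mm3
    n_calc = int(round(spec.calcific_volume_mm3 / col_vol))
    n_fib = int(round(spec.fibrotic_volume_mm3 / col_vol))
    capacity = col_x.size
    if n_calc + n_fib > capacity:
        raise CapacityError(
            f"requested {n_calc + n_fib} tissue columns "
            f"({(n_calc + n_fib) * col_vol:.0f} mm^3) exceed leaflet capacity "
            f"of {capacity} columns ({capacity * col_vol:.0f} mm^3)"
        )

    mid_r = 0.5 * (spec.inner_radius_mm + spec.annulus_radius_mm)
    anchors = np.column_stack(
        [mid_r * np.cos(angles), mid_r * np.sin(angles), np.full(angles.size, slab_t / 2)]
    )
    pos = np.column_stack([col_x, col_y, col_z])

    def _greedy(dist: np.ndarray, available: np.ndarray, n: int) -> np.ndarray:
        order = np.lexsort((col_x, col_y, col_s, dist))
        order = order[available[order]]
        return order[:n]

    available = np.ones(capacity, dtype=bool)
    calc_idx = np.empty(0, dtype=int)
    if n_calc > 0:
        n_nod = max(1, min(spec.n_nodules, spec.leaflet_count))
        d_nod = np.min(
            np.linalg.norm(pos[:, None, :] - anchors[None, :n_nod, :], axis=-1), axis=1
        )
        calc_idx = _greedy(d_nod, available, n_calc)
        available[calc_idx] = False
    d_all = np.min(
        np.linalg.norm(pos[:, None, :] - anchors[None, :, :], axis=-1), axis=1
    )
    fib_idx = _greedy(d_all, available, n_fib)

    # --- paint columns into voxel labels ------------------------------------
    labels = np.zeros(intens.shape, dtype=np.uint8)
    k_per = int(round(spec.column_mm / vox))  # voxels per column per in-plane axis
    nz_per = int(round(slab_t / vox))

    def _paint(idx: np.ndarray, label: int) -> None:
        for i in idx:
            ix = int(round((col_x[i] - ax[0]) / vox))
            iy = int(round((col_y[i] - ax[0]) / vox))
            iz = int(round((col_s[i] * slab_t - z_ax[0]) / vox))
            labels[ix : ix + k_per, iy : iy + k_per, iz : iz + nz_per] = label

    _paint(fib_idx, LABEL_FIBROSIS)
    _paint(calc_idx, LABEL_CALCIUM)
    intens[labels == LABEL_FIBROSIS] = spec.fibrosis_hu
    intens[labels == LABEL_CALCIUM] = spec.calcium_hu

    if spec.blur_sigma_px > 0:
        intens = gaussian_filter(intens, sigma=spec.blur_sigma_px)
    if spec.blood_pool_noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        intens = intens + rng.normal(0.0, spec.blood_pool_noise_sd, size=intens.shape)

    affine = np.diag([vox, vox, vox, 1.0])
    affine[:3, 3] = [ax[0], ax[0], z_ax[0]]
    volume = CTVolume(intensities=intens, affine=affine, frame="RAS")

    phi = np.linspace(0.0, 2 * np.pi, 64, endpoint=False)
    contour = np.column_stack(
        [
            spec.annulus_radius_mm * np.cos(phi),
            spec.annulus_radius_mm * np.sin(phi),
            np.zeros_like(phi),
        ]
    )
    plane = ValvePlaneDefinition(
        centre=np.zeros(3), normal=np.array([0.0, 0.0, 1.0]), contour=contour
    )
    return ValvePhantom(
        volume=volume,
        plane=plane,
        labels=labels,
        truth_fibrotic_mm3=float(n_fib * col_vol),
        truth_calcific_mm3=float(n_calc * col_vol),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# End-to-end recovery study conditions
# ---------------------------------------------------------------------------

#: Image noise (HU) and partial-volume blur (voxels) of the noisy condition.
RECOVERY_NOISE_SD_HU = 15.0
RECOVERY_BLUR_SIGMA_PX = 1.0
RECOVERY_BP_RANGE_HU = (250.0, 650.0)
#: Fibrosis attenuation for the recovery sweep: inside the non-calcific band
#: for every blood pool in the sweep range (the band's upper bound at
#: 250 HU blood pool is 146.5 HU) and 3 noise SDs above the 30 HU floor.
RECOVERY_FIBROSIS_HU = 75.0


def fwhm_balanced_calcium_hu(
    blood_pool_hu: float,
    fibrosis_hu: float = RECOVERY_FIBROSIS_HU,
    noise_sd: float = RECOVERY_NOISE_SD_HU,
) -> float:
    """Nodule attenuation whose calcium threshold sits at the blurred-edge
    half-maximum: c = 2 * (blood_pool + 3 * noise_sd) - fibrosis.

    Threshold crossing at the half-maximum is the condition under which a
    threshold segmentation of a blurred boundary recovers the true extent
    (the rationale behind full-width-half-maximum sizing in CT).
    """
    return 2.0 * (blood_pool_hu + 3.0 * noise_sd) - fibrosis_hu


def recovery_study_specs(
    n: int = 10, seed: int = 0, noisy: bool = True
) -> list[PhantomSpec]:
    """Phantom specs for the end-to-end recovery study.

    Blood-pool means are evenly spaced over 250-650 HU; fibrosis is fixed
    at `RECOVERY_FIBROSIS_HU` and calcium follows the FWHM-balance rule.
    With ``noisy=False`` the same geometries are returned clean (no noise,
    no blur), where recovery must be exact.
    """
    bps = np.linspace(*RECOVERY_BP_RANGE_HU, n)
    specs = []
    for i, bp in enumerate(bps):
        specs.append(
            PhantomSpec(
                blood_pool_hu=float(bp),
                blood_pool_noise_sd=RECOVERY_NOISE_SD_HU if noisy else 0.0,
                fibrosis_hu=RECOVERY_FIBROSIS_HU,
                calcium_hu=fwhm_balanced_calcium_hu(float(bp)),
                blur_sigma_px=RECOVERY_BLUR_SIGMA_PX if noisy else 0.0,
                seed=seed * 1000 + i,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# Cohort simulator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticPatient:
    """One simulated patient with ground-truth indexed volumes."""

    sex: str  # "F" or "M"
    age: float
    true_indexed_calc: float
    true_indexed_noncalc: float
    peak_velocity_ms: float
    severity: str  # mild / moderate / severe


#: Cohort simulator defaults, anchored on the imaging-cohort pattern:
#: median fibrocalcific burden ~200 mm^3/cm^2 in males with a lower burden
#: and a markedly lower calcific fraction in females.
COHORT_DEFAULTS = dict(
    female_fraction=36 / 164,
    burden_log_median_male=math.log(200.0),
    burden_log_sd=0.55,
    sex_burden_log_shift=0.55,
    calc_fraction_logit_male=0.24,  # logit(0.56)
    sex_calcific_logit_shift=0.77,  # female fraction -> ~0.37
    calc_fraction_logit_sd=0.8,
    velocity_intercept=1.1,
    velocity_sqrt_slope=0.17,
    velocity_log2_level=3.4,
    velocity_log2_slope=0.45,
    velocity_noise_sd=0.30,
)


def _severity(v: float) -> str:
    if v > 4.0:
        return "severe"
    if v >= 3.0:
        return "moderate"
    return "mild"


def simulate_cohort(
    n: int,
    female_fraction: float | None = None,
    seed: int = 0,
    sex_calcific_logit_shift: float | None = None,
    sex_burden_log_shift: float | None = None,
    sex_velocity_interaction: float = 0.0,
    velocity_model: str = "sqrt",
    **overrides,
) -> list[SyntheticPatient]:
    """Simulate an aortic-stenosis cohort.

    Each patient draws a latent indexed fibrocalcific burden B (log-normal)
    and a calcific fraction p (logit-normal); peak jet velocity is a
    monotone noisy function of B, ``a + b*sqrt(B) + noise``. Female sex
    shifts the calcific-fraction logit down by ``sex_calcific_logit_shift``
    and the log-burden by ``sex_burden_log_shift`` (set both to 0 for a
    null cohort with no sex structure). ``sex_velocity_interaction`` adds
    ``beta * female * (log2(B) - log2(187))`` to velocity, for power
    studies of the sex-by-score interaction.

    ``velocity_model`` selects the velocity link: ``"sqrt"`` (default,
    realistic saturating severity growth) or ``"log2"`` (linear in the
    log2 burden, exactly the form `velocity_regression` fits — use this
    for type-I error and power studies, where the null must satisfy the
    fitted model).
    """
    if n < 1:
        raise InputError("cohort size must be >= 1")
    p = dict(COHORT_DEFAULTS, **overrides)
    if female_fraction is not None:
        p["female_fraction"] = female_fraction
    if sex_calcific_logit_shift is not None:
        p["sex_calcific_logit_shift"] = sex_calcific_logit_shift
    if sex_burden_log_shift is not None:
        p["sex_burden_log_shift"] = sex_burden_log_shift

    rng = np.random.default_rng(seed)
    female = rng.random(n) < p["female_fraction"]
    age = np.clip(rng.normal(71.0, 7.0, n), 50.0, 95.0)
    mu = p["burden_log_median_male"] - p["sex_burden_log_shift"] * female
    burden = np.exp(rng.normal(mu, p["burden_log_sd"]))
    logit = rng.normal(
        p["calc_fraction_logit_male"] - p["sex_calcific_logit_shift"] * female,
        p["calc_fraction_logit_sd"],
    )
    calc_frac = 1.0 / (1.0 + np.exp(-logit))
    if velocity_model == "sqrt":
        trend = p["velocity_intercept"] + p["velocity_sqrt_slope"] * np.sqrt(burden)
    elif velocity_model == "log2":
        trend = p["velocity_log2_level"] + p["velocity_log2_slope"] * (
            np.log2(burden) - np.log2(187.0)
        )
    else:
        raise InputError(f"unknown velocity_model: {velocity_model!r}")
    velocity = trend + rng.normal(0.0, p["velocity_noise_sd"], n)
    if sex_velocity_interaction:
        velocity = velocity + sex_velocity_interaction * female * (
            np.log2(burden) - np.log2(187.0)
        )
    return [
        SyntheticPatient(
            sex="F" if female[i] else "M",
            age=float(age[i]),
            true_indexed_calc=float(calc_frac[i] * burden[i]),
            true_indexed_noncalc=float((1.0 - calc_frac[i]) * burden[i]),
            peak_velocity_ms=float(velocity[i]),
            severity=_severity(float(velocity[i])),
        )
        for i in range(n)
    ]


def cohort_frame(patients: list[SyntheticPatient]) -> pd.DataFrame:
    """Tabulate a simulated cohort, adding derived score columns."""
    df = pd.DataFrame([vars(pt) for pt in patients])
    df["true_fibrocalcific_volume"] = (
        df["true_indexed_calc"] + df["true_indexed_noncalc"]
    )
    df["fibrocalcific_ratio"] = df["true_indexed_noncalc"] / df["true_indexed_calc"]
    return df
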