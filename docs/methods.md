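# Methods

## Coordinate and intensity contracts

All world coordinates are millimetres in a single RAS-style frame;
volumes are reoriented to the closest canonical orientation on load, so
downstream geometry never sees an orientation convention. Intensities are
Hounsfield units, with any NIfTI `scl_slope`/`scl_inter` rescale applied
exactly once at read time. The valve plane is supplied explicitly (annulus
centre, unit normal pointing annulus → aorta, annulus contour): the
operator's interactive multiplanar alignment is replaced by this
inspectable sidecar, which is also what makes runs reproducible.

## Reslicing

The valve is analysed on 3 mm slabs perpendicular to the valve normal,
the annulus plane being the reference boundary: slab *k* covers
[3*k*, 3(*k*+1)] mm above the annulus. Each output pixel is the mean of 5
trilinear samples taken at the centres of equal sub-slabs, emulating a
thick-slice reconstruction of a thin-slice (0.75 mm class) acquisition;
slab averaging is deterministic and, for a field linear in depth, returns
the value at the slab centre. Defaults: 5 slabs (15 mm), 0.5 mm in-plane
grid centred on the annulus centre. The per-slice analysis ROI is the
convex hull of the annulus contour dilated by 2 mm, shrinking 1 mm per
slab moving towards the aorta — an automated stand-in for the operator's
care to exclude aortic-wall and coronary calcium; callers may override
it per slice.

## Threshold calibration

Blood-pool attenuation is sampled in a circular 2 cm² ROI (radius
≈ 7.98 mm) centred on the valve axis, on the most aortic slab of the
stack (standing in for the sinotubular-junction level); the SD is taken
from the same ROI, sample SD over all pixels whose centres fall in the
circle. Thresholds:

* calcium: HU **strictly above** mean + 3 SD. The strict inequality is
  this package's convention: at the degenerate zero-variance limit
  (noise-free phantoms) it keeps the blood pool itself out of the calcium
  class while changing nothing in any noisy setting.
* non-calcific: HU in **[30, 41.46 + 0.42·mean)**, half-open so the two
  bands partition tissue exactly; HU between the bands is unclassified
  opacified blood.

Degenerate cases are flagged rather than silently altered: if the
computed upper bound exceeds the calcium bound (noisy pool on a
low-contrast scan) it is clamped to it and flagged
`noncalc-upper-clamped`; if the calcium bound falls below the 30 HU floor
(an essentially uncontrasted pool) the computed upper bound is kept and
the set flagged `calc-below-noncalc-band`, the class partition then being
restored at segmentation time by subtracting the calcium mask. A
blood-pool mean low enough to push the upper bound to 30 HU or below
(≈ −27 HU) is rejected as non-physiological for a contrast scan.

The calibration line itself is reproduced numerically: the derivation
simulation draws blood-pool means uniform on 250–650 HU (bracketing the
cohort interquartile range 326–511), places true thresholds on the line,
adds Gaussian observer noise sized so the expected fit quality is
r² = 0.90, and optionally snaps thresholds to the observers' 25 HU
titration grid (start 200 HU, nearest grid point, ties to the even step).
OLS of threshold on blood-pool mean over 200 such replicate cohorts of
n = 100 recovers the slope and intercept; this is what
`scripts/acceptance.py` reports.

## Segmentation

Per-slab seeded region growing with 8-connectivity, one class at a time,
restricted to the slice ROI — matching the slice-by-slice clinical
workflow rather than 3-D growing. Automatic seeding places one seed at
the maximum-HU pixel of every in-band connected component of at least
1 mm² (the same floor as the calcium-score lesion minimum; suppresses
single-pixel noise), with row-major tie-breaking; explicit seed lists are
accepted for parity with the manual workflow and raise descriptive errors
when a seed is out of band or outside the ROI. The non-calcific mask has
the calcium mask subtracted so the classes stay disjoint under any
configuration.

## Quantification

Volume = true-pixel count × pixel area × slab thickness, summed over
slabs. Indexed quantities divide by the annulus polygon area in cm²
(shoelace formula on the contour projected into the annulus plane).
The fibrocalcific volume is the sum of the indexed class volumes; the
fibrocalcific ratio divides non-calcific by calcific indexed volume. A
valve with no calcium has an *undefined* ratio, represented by an explicit
sentinel object (not a float infinity) that sorts above every finite
ratio — so rank statistics treat calcium-free valves as maximally
fibrosis-predominant, while arithmetic on the sentinel fails loudly
instead of propagating infinities. The predominance boundary assigns
ratio = 1.0 to the calcium-dominant class (at 1.0, at least half the
measured volume is calcification).

The Agatston scorer is the standard published algorithm (3 mm slices,
130 HU floor, 4-connected lesions ≥ 1 mm², weights 1–4 by peak HU,
contribution = area × weight) and is the comparison path against
non-contrast calcium scoring, not part of the contrast method.

## The valve phantom

The phantom emulates a contrast scan of the aortic root: a blood-filled
cylinder (lumen radius = annulus radius + 3 mm) at the configured
opacification, soft tissue at 40 HU outside it, and a tri-leaflet ring of
valve tissue on the annulus plane — three 100°-wide annular sectors
(two for the bicuspid switch), two 3 mm slabs thick, between radii 2.5
and 12.5 mm. Tissue is carved on analysis columns (0.5 × 0.5 mm in-plane
× one slab deep) selected greedily by distance to per-leaflet anchor
points: the calcific nodule first (nearest the nodule anchor), fibrotic
tissue next (nearest any anchor), which wraps the nodule in fibrosis and
fills all leaflets compactly. Requested volumes are matched to within one
column (0.75 mm³); realised truth volumes are recorded before noise and
blur.

Acquisition voxels are 0.25 mm isotropic. Because columns are integer
multiples of the voxel grid and span whole slabs, a clean phantom
resliced on the matching 0.5 mm grid classifies every column exactly, and
the pipeline recovers the truth volumes with zero error — this is the
reference point that separates algorithmic error from physics. Physics is
modelled as Gaussian partial-volume blur of the clean tissue map
(σ in voxels; 1 voxel = 0.25 mm, the scale of a CT reconstruction PSF)
followed by additive white Gaussian noise of the stated SD, so "noise
σ = 15 HU" is the image noise actually measured in the blood pool.

Default tissue HU: fibrosis 150 (mid-band for typical opacification),
calcium 800 (above mean + 3 SD for any physiological pool). Default
volumes: fibrotic 1200 mm³, calcific 240 mm³ as a single nodule. These
were set by a partial-volume budget: threshold segmentation of a blurred
boundary mis-sizes a structure by O(σ) times the distance of the
threshold from the edge half-maximum, so class volumes must be large
enough (structures well above 3 mm across, fibrotic shell around the
nodule > 1 mm) for sub-millimetre edge bias to stay within the tested
tolerances.

### Recovery study conditions

The end-to-end recovery study spans blood pools 250–650 HU (evenly
spaced, 10 seeds). Two deliberate parameter choices, fixed once for the
whole sweep:

* **fibrosis 75 HU** — the default 150 HU lies *outside* the non-calcific
  band at the low end of the sweep (upper bound 41.46 + 0.42·250
  = 146.5 HU), so the sweep uses a value inside the band for every blood
  pool and 3 noise SDs above the 30 HU floor. A useful coincidence of the
  calibration line's slope: a fixed 75 HU tissue sits at a nearly
  constant quantile of the tissue/blood edge profile across the entire
  range, making edge bias uniform over the sweep.
* **calcium = 2·(blood pool + 3·15) − 75 HU** — the FWHM-balance rule:
  the calcium threshold then falls at the half-maximum of the blurred
  nodule edge, the condition under which threshold segmentation recovers
  true extent (the rationale behind full-width-half-maximum sizing in
  CT). The resulting nodule attenuations (≈ 515–1315 HU) are within the
  range of real calcific nodules.

Under these conditions the pipeline recovers non-calcific volumes to
about −6 % and calcific volumes to about +2 % (noise σ = 15 HU, 1-pixel
blur), and exactly in the clean configuration. At the default fibrosis of
150 HU — closer to the band's upper edge — non-calcific volume
under-estimates by roughly 16 % under the same physics: that is the
method's own behaviour for tissue approaching the thresholds, a
limitation the adaptive-threshold approach explicitly carries, and the
per-class Dice against ground truth remains ≥ 0.90.

### What the phantom does not model

Beam hardening, photon-starvation streaks, motion, bicuspid raphe
morphology, non-planar annuli, calcium extending into the aortic wall or
LVOT, and continuous (non-columnar) tissue boundaries. Passing the
recovery tests therefore demonstrates correctness of the geometry,
calibration, growing and indexing chain and its first-order robustness to
noise and partial volume — not clinical accuracy on real scans.

## The cohort simulator

Each patient draws a latent indexed fibrocalcific burden
B ~ LogNormal(log 200 − 0.55·female, 0.55) (medians ≈ 200 male / 116
female, mm³/cm²) and a calcific fraction p with
logit(p) ~ N(0.24 − 0.77·female, 0.8) (median fractions ≈ 0.56 male /
0.37 female) — females thus carry a lower calcific fraction and burden,
hence a higher fibrocalcific ratio, reproducing the cohort's sex pattern.
Peak jet velocity is a monotone noisy function of burden,
v = 1.1 + 0.17·√B + N(0, 0.3) m/s (medians ≈ 3.4 m/s, severity split
roughly 30/47/22 % mild/moderate/severe), with severity labelled from
velocity (< 3.0 mild, 3.0–4.0 moderate, > 4.0 severe; the nominal band
gap 2.9–3.0 is folded into mild). The √ link keeps the severe tail
realistic; an alternative `velocity_model="log2"` makes velocity linear
in log2 B — exactly the form the velocity regression fits — and is the
correct null for type-I-error and power studies of the sex × score
interaction (the √ model is deliberately misspecified for that
regression, which would otherwise inflate the interaction test).
`sex_velocity_interaction` injects a true interaction of configurable
size (0.2 m/s per log2 unit gives > 80 % power at n = 164).

## Statistics

Spearman uses average ranks; undefined ratios enter as the largest
values. ICC(2,1) is computed from the two-way ANOVA mean squares with the
standard F-based confidence interval (validated against the classic
6 × 4 judges example: 0.290, CI 0.019–0.761); rows with missing cells are
rejected, never imputed. The velocity model is OLS of peak velocity on
age + female + log2(score) + female:log2(score), α = 0.05 two-sided;
non-positive scores are an error (log2 undefined), and analyses excluding
undefined-ratio valves report the excluded count.

## Numerical choices

* Interval conventions as above; all ties and tie-breaks deterministic
  (row-major seeds, even-step titration ties, lexicographic column
  ordering in the phantom).
* Reslicing uses order-1 (trilinear) interpolation with an explicit
  bounds check; a stack exiting the volume names the first offending
  slice.
* Annulus contours must lie within 0.5 mm of the annulus plane and be
  simple when projected; areas are orientation-independent.
* All randomness flows through `numpy.random.default_rng` seeds carried
  by the objects that use them; identical configuration + seed gives
  byte-identical outputs.

## Known limitations

Single-plane (non-cusp-wise) quantification; automatic seeding is a
stand-in for operator clicks and has no notion of anatomy beyond the ROI;
the ROI taper is a heuristic for excluding non-valve calcium; the
phantom's tissue HU values are stand-ins, since the true attenuation
distribution of valvular fibrosis is not established; the Agatston path
assumes the standard coronary lesion floor.
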