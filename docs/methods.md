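# Methods

## Coordinate conventions

All geometry lives in the DICOM patient coordinate system (LPS,
millimetres). Positions refer to voxel/pixel *centers*, following the
`ImagePositionPatient` convention; indices are 0-based. A `VolumeGrid`
maps voxel (i, j, k) to

    origin + i·s_row·r̂ + j·s_col·ĉ + k·s_slice·n̂,

with mutually orthonormal direction cosines (checked to 1e-4, the slack
absorbing decimal-string DICOM tags). `ImageOrientationPatient` stores
the column-direction vector first; the containers name cosines by the
index they advance, so the tag maps to `[col_cosine, row_cosine]`.

Volume series are assembled by sorting slices along the projection of
their positions onto `r̂ × ĉ`, making the result independent of file
order. Inter-slice spacing must be uniform to a relative 1e-3 — loose
enough for truncated tags, tight enough to catch a missing slice.
Multi-frame (enhanced) DICOM input is rejected with a clear message.

## The two-step reformatting model

**Step 1 — sampling.** The reference plane's pixel centers are computed
from its origin, in-plane cosines and pixel spacing. The through-plane
slice thickness is discretized into `num = round(t / (2·z_res))`
parallel slices per side at spacing `dist = t / (2·num)`, so the 2·num+1
offsets span exactly [−t/2, +t/2]; `z_res` is the volume's slice
spacing. The volume is sampled at every pixel center and offset by
trilinear interpolation on its native regular grid (no oblique
re-gridding of the volume itself). Trilinear is the standard choice for
regular-grid resampling and is what makes the phantom's hand
calculations exactly reproducible: the phantom's value law is piecewise
linear with breakpoints only on grid planes.

**Step 2 — totalization.** Samples are collapsed with slice-profile
weights `w_k = w(k/num)` into `round(Σ w_k v_k / Σ w_k)`. Weights are
not pre-normalized; the denominator carries the normalization so that
dropped samples (below) renormalize automatically.

**Rounding.** Both `num` and the output values round half *away from
zero* — the everyday rounding a hand calculation uses — rather than
banker's rounding, which would silently change `num` at exact .5
boundaries.

## Slice profiles

The profiles are symmetric weight functions of the normalized offset
u = k/num ∈ [−1, 1]:

| name           | w(u)                  | comment                         |
|----------------|-----------------------|---------------------------------|
| rectangular    | 1                     | ideal slice, strongest partial-volume mixing |
| triangular     | 1 − \|u\|             | zero at the borders             |
| cosine_plus_1  | cos(πu) + 1           | smooth taper                    |
| sinc           | sin(πu)/(πu), w(0)=1  | zero at the borders             |
| std_normal_2   | exp(−(2u)²/2)         | Gaussian, border at 2σ          |
| std_normal_5   | exp(−(5u)²/2)         | Gaussian, border at 5σ: border weight/center ≈ 3.7e−6 |

These closed forms are this package's conventions, chosen to match the
profile names; the acceptance checks rely numerically only on the fully
determined rectangular profile, plus the qualitative ordering (the
faster a profile decays toward the borders, the less it blurs, so
`std_normal_5` keeps the highest sharpness and `rectangular` the
lowest). At 0 mm thickness `num = 0`, the scheme collapses to the
single central slice, and the profile provably has no influence — the
outputs are bit-identical.

## Degenerate and boundary inputs

* Thickness outside [0, 99.99] mm is rejected. A positive thickness
  below the volume's slice spacing rounds to `num = 0`; it is treated
  as 0 mm with a warning, since the requested width cannot be resolved.
* Samples outside the volume's bounding box (voxel-center convention,
  index tolerance 1e-6 to absorb tag truncation) are excluded and the
  remaining weights renormalized, avoiding artificial darkening at the
  volume border; zero-filling was the rejected alternative because it
  biases border pixels toward 0. Pixels left with *no weighted*
  in-volume sample are set to 0 and counted in a reported out-of-volume
  tally. This includes the corner case where a border-zero profile
  (triangular, sinc) meets a pixel whose only in-volume samples sit at
  the stack borders: the effective weight is zero, and treating the
  pixel as out-of-volume is preferred over aborting the reslice.
* A reference plane entirely outside the volume raises "no overlap".

## DICOM export

Exports copy the reference slice's geometry (position, orientation,
pixel spacing, matrix size) and study UID; every export generates fresh
series and SOP instance UIDs and a new series number, by default
3000 + the source 3D series number (the choice of 3000 is arbitrary but
keeps exports visually grouped apart from acquired series). The
slice-thickness tag records the reslicing thickness actually used.
Pixels are stored as unsigned 16-bit with rescale slope/intercept 1/0;
rounded values clip to [0, 65535], matching typical magnitude-MR DICOM.
Decimal tags are written with `%.10g` formatting, so geometry
round-trips to ~1e-10 mm.

## Sharpness metric

The Frequency Domain Image Blur Measure is computed in six steps: 2D
DFT, zero-frequency shift to the center, magnitudes, maximum M, count of
coefficients strictly above M/1000, divided by the pixel count. The
1000 divisor is the constant of the metric's standard formulation. FM is
invariant to positive scaling (threshold scales with M) but *not* to
adding a constant (the DC term changes), so no such invariance is
asserted. FM can be computed on the pre-rounding floating-point image
(the pipeline's QC path, used by `--fm`) or on stored integer pixels
(the `fm` subcommand on DICOM files); the CLI labels which one it used.

## Phantoms and what passing tests show

**Validation cube.** 11³ voxels at 1 mm isotropic, iso-center at the
midpoint; constant in x/y, linear in z from 100 at the center by −20/mm
to 0 at both borders. Three 11×11 reference slices: in-plane at z=0,
perpendicular at y=0, and 45° in y-z through the iso-center with
1 × √2 mm pixels; the diagonal slice is centered so its 11 diagonal
steps span exactly the cube's 10·√2 mm y-z diagonal (the stated counts
and spacings only fit under this centering). All carry a 2 mm thickness
tag. Because the value law is closed-form, an independent oracle (no
shared interpolation code) reproduces every reformatted value by hand
for the rectangular profile at 0, 2, 2.82 and 4.23 mm; the pipeline
matches it at every pixel. This validates the geometry and the
interpolation — it says nothing about noise, coil shading or motion.

**Oblique-edge phantom.** A synthetic stand-in for clinical 3D LGE
acquisitions (which cannot be redistributed): 48³ voxels at 1.25 mm
isotropic, two compartments of 600 and 100 separated by a sharp planar
boundary whose normal ∝ (1, 0.25, 0.4) is oblique to all grid axes, plus
Gaussian noise σ=25 (SNR ≈ 24 for the bright compartment) — realistic
orders of magnitude for LGE. An axial 40×40 reference with a 7 mm
thickness tag sits at the volume center. On this phantom the FM
properties of the through-plane model hold: FM is monotone
non-increasing over 0/7/14 mm with the rectangular profile (≈44% drop
at 7 mm vs 0 mm) and `std_normal_5` stays at least as sharp as
`rectangular` at equal thickness. The phantom is deliberately
non-degenerate: a noise-free edge that is uniform along one image axis
confines the spectrum to a single frequency line and makes FM behave
pathologically; real anatomy has neither property. The phantom does not
emulate anatomy, intensity inhomogeneity or motion, so these tests
demonstrate the model's qualitative blur behaviour, not clinical effect
sizes.

## Problem sizes

The test suite runs entirely on the 11³ validation cube, the 48³ edge
phantom, and ≤16³ random volumes for the 100-configuration brute-force
oracle comparison — sizes chosen so every check is exhaustive at the
pixel level while the whole suite completes in seconds.

## Known limitations

* Single-frame DICOM only; no enhanced multi-frame, DICOMDIR or network
  services; no compressed transfer syntaxes on write.
* The in-plane pixel grid is fixed to the reference's; no supersampling
  of the pixel footprint beyond its center point, and no sinc/spline
  volume interpolation options.
* Time-resolved (4D) data is out of scope.
* Patient motion between the 3D and the reference acquisition is not
  correctable; the reslice is only as co-registered as the scanner's
  geometry tags.
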