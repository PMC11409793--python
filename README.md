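# reslice3d2d

Reformat a 3D DICOM volume at the exact patient-space location of a 2D
reference DICOM slice.

In cardiovascular MR, quantification is established on conventional 2D
acquisitions, while novel 3D sequences (3D LGE, 3D CINE, …) lack a
standardized post-processing path. `reslice3d2d` bridges the two: it
resamples a 3D acquisition on the pixel grid of an already-acquired 2D
slice — same position, orientation and pixel spacing — and exports the
result as DICOM, so conventional 2D analysis tools can quantify 3D data
and 3D sequences can be compared against their 2D counterparts at the
identical anatomical location. It is aimed at clinical researchers
post-processing CMR studies, but works on any single-frame DICOM data
carrying standard geometry tags.

## Method

Reformatting is a two-step interpolation. With a reference plane of
pixel centers `c(i,j)` and unit normal `n̂`, a through-plane slice
thickness is discretized into `num` parallel slices on each side,

    num  = round(slice_thickness / (2 · z_res)),      dist = slice_thickness / (2 · num),

where `z_res` is the 3D volume's inter-slice spacing, giving signed
offsets `k·dist`, k = −num…num, that span exactly ±thickness/2. The
volume is sampled trilinearly at `c(i,j) + k·dist·n̂` and the samples
are collapsed with slice-profile weights `w_k = w(k/num)`:

    value(i,j) = round( Σₖ wₖ·value(i,j,k) / Σₖ wₖ ).

Six symmetric profiles are available — `rectangular` (ideal slice),
`triangular`, `cosine_plus_1`, `sinc`, `std_normal_2`, `std_normal_5`
(Gaussians whose border lies at 2σ resp. 5σ) — modelling how a real
scanner's slice sensitivity tapers toward the slice borders. Thickness
may be any value in [0, 99.99] mm (0 samples the plane itself), or the
presets `reference_2d` / `volume_z`. Samples leaving the volume are
dropped with weight renormalization and reported in an out-of-volume
tally.

Sharpness of the results can be quantified with the Frequency Domain
Image Blur Measure (FM): the fraction of 2D-FFT magnitude coefficients
exceeding 1/1000 of the spectral maximum. Partial-volume blur from
thicker slices suppresses high frequencies and lowers FM.

A built-in validation phantom (an 11³ cube at 1 mm with a known linear
value law, probed by in-plane, perpendicular and 45°-diagonal reference
slices) makes every reformatted value checkable against a closed-form
hand calculation.

## Worked example

```python
from reslice3d2d import generate_validation_dataset, reslice

ds = generate_validation_dataset()          # 11³ cube + 3 reference slices
thin  = reslice(ds.volume, ds.diagplane, 0.0,  "rectangular")
thick = reslice(ds.volume, ds.diagplane, 4.23, "rectangular")
print(thin.values[5].tolist())
print(thick.values[5].tolist())
```

prints

```
[0, 20, 40, 60, 80, 100, 80, 60, 40, 20, 0]
[0, 20, 40, 60, 76, 82, 76, 60, 40, 20, 0]
```

At 0 mm the diagonal slice reads the cube's value law directly (100 at
the iso-center, −20 per mm of |z|). At 4.23 mm the five parallel slices
average values across ±2.115 mm along the plane normal, flattening the
peak: the center becomes round((70.9 + 85.0 + 100 + 85.0 + 70.9)/5) = 82,
exactly the hand calculation.

The partial-volume effect on sharpness, on the bundled oblique-edge
phantom (a synthetic stand-in for a 1.25 mm isotropic 3D LGE scan):

```python
from reslice3d2d import compute_fm
from reslice3d2d.phantom import generate_edge_phantom, edge_reference_header

vol = generate_edge_phantom(seed=0)
ref = edge_reference_header(vol)            # axial 7 mm "2D" reference
for t in (0.0, 7.0, 14.0):
    r = reslice(vol, ref, t, "rectangular")
    print(t, round(compute_fm(r.float_values).fm, 4))
```

```
0.0 0.7306
7.0 0.4106
14.0 0.2919
```

FM drops by ~44% from 0 mm to 7 mm: thicker slices blur the edge.

## Command line

```
reslice3d2d make-phantom --out phantom_dir
reslice3d2d reslice --volume phantom_dir/volume \
    --reference phantom_dir/parplane.dcm \
    --thickness 0,2,4.23 --profile rectangular,std_normal_5 \
    --out results_dir --fm
reslice3d2d fm results_dir/*.dcm
```

`reslice` writes one DICOM per reference × thickness × profile, copying
the reference's geometry, with fresh series/SOP UIDs, a new series
number (3000 + source series number by default) and the reslicing
thickness in the slice-thickness tag.

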