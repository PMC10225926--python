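# ctcompat

Mass-conserving 2× upsampling of computed-tomography volumes in Hounsfield
units (HU), as a Python library and a small command-line tool.

## The problem

Hounsfield units are a linear rescaling of the X-ray attenuation
coefficient, and attenuation is exponential in path length.  A consequence
is that when a voxel is split into two congruent halves, the parent value
must equal the *mean* of the two children:

    HU₀ = (HU₁ + HU₂) / 2

Plain linear or cubic-spline interpolation violates this: the interpolated
children generally average to something other than the parent, which
distorts HU-derived quantities (density, hence mass) that radiotherapy
dosimetry and other clinical calculations depend on.

## The method

Write the children as HU₁ = HU₀ − α and HU₂ = HU₀ + α, which satisfies the
average constraint for every α, and choose the α that minimizes the
squared HU distance to a pair of classical reference values (HU_l, HU_r)
taken half a voxel below and above the parent's center:

    f(α) = (HU₀ − α − HU_l)² + (HU₀ + α − HU_r)²
    α* = (HU_r − HU_l) / 2

With the linear reference (midpoint averages with each axial neighbor) the
closed form collapses to α* = (HU_next − HU_prev)/4; a natural cubic
spline evaluated at the half-integer coordinates is available as an
alternative reference.  Whole volumes are processed by two composable
flavors — **Z** doubles the number of slices, **XY** doubles in-plane
resolution — which can be chained ("Z,XY,Z" cuts slice thickness by 4).
Output HU are floored at air (−1024) by default.  Because every split
conserves the parent mean, mean-pool downsampling is an exact left inverse
of upsampling, which is also the package's built-in verification.

## Worked example

`examples/01_split_one_voxel.py` splits a −50 HU voxel lying between
neighbors at 0 and 100 HU:

```
    linear: children = ( -25.000,   25.000)  mean =    0.000  delta = 50.000
    spline: children = ( -43.750,    6.250)  mean =  -18.750  delta = 31.250
conserving: children = ( -75.000,  -25.000)  mean =  -50.000  delta =  0.000
```

`delta` is |mean(children) − parent|: linear interpolation silently moves
this voxel's HU estimate by 50 HU, the spline by 31.25 HU, while the
conserving split (α = (100 − 0)/4 = 25) keeps it exact.

`examples/02_upsample_phantom.py` runs the Z,XY chain on a sphere phantom:

```
input : (32, 32, 6) at 0.7 x 0.7 x 1.5 mm
output: (64, 64, 12) at 0.35 x 0.35 x 0.75 mm
conservation: max delta = 0 HU over 43008 parent voxels, 0 children clamped
mean HU before: -30.078125  after: -30.078125
```

Dims double and voxel sizes halve along each processed axis; the unchanged
mean shows total HU (hence mass) is preserved.  The other examples cover
the lowered-resolution verification protocol and the CSV slice-series
format.

## Command line

```sh
ctcompat phantom series/ --kind sphere --dims 32 32 6
ctcompat upsample series/ hires/ --flavors Z,XY --reference linear
ctcompat verify series/ hires/ --flavors Z,XY
ctcompat table1 comparison.csv
```

Volumes on disk are directories with one uncompressed CSV per slice plus a
`metadata.csv` (grid size, pixel sizes and slice thickness in mm); DICOM
conversion is out of scope.

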