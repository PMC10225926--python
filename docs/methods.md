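# Methods

## Model and assumptions

The package treats a CT volume as a 3D array of Hounsfield units indexed
`[z][y][x]`, with each value located at its voxel center, plus physical
voxel sizes (dx, dy in-plane, dz slice thickness, all mm).  No world
origin or orientation is modeled: the resampler only needs sizes, and
halving a voxel halves the corresponding size exactly.  HU are stored as
double-precision floats throughout — the comparison table's spline column
is fractional, so integer HU storage would be lossy.

Because HU is a linear rescaling of the X-ray attenuation coefficient and
attenuation is exponential in path length, splitting a voxel into two
congruent halves must preserve the parent value as the mean of the
children.  The split is parameterized as HU₀ ∓ α, which enforces the
constraint identically, and α is the minimizer of the squared distance to
two classical reference values taken half a voxel on either side of the
parent center:

    f(α) = (HU₀ − α − HU_l)² + (HU₀ + α − HU_r)²  ⇒  α* = (HU_r − HU_l)/2

α* does not depend on HU₀.  The child carrying HU₀ − α occupies the
lower-index half, so with the linear reference the lower child tracks the
lower-index neighbor.

## Reference modes

* **linear** (default): HU_l and HU_r are the midpoint averages of the
  parent with its lower and upper axial neighbor.  The two midpoints'
  difference cancels the center value, so α* = (HU_next − HU_prev)/4 —
  cheap, local and linear in the data (good error-propagation behavior).
* **spline**: a natural cubic spline is fitted through the full 1D profile
  along the processing axis (knots at integer indices, unit spacing;
  physical spacing does not enter) and evaluated at index ∓ 0.5.  Natural
  boundary conditions (zero second derivative at the profile ends) are
  used at every length; on 3-point profiles this reproduces the worked
  comparison table exactly.  Fitting is delegated to
  `scipy.interpolate.CubicSpline(bc_type="natural")`; the test suite
  cross-checks it against an independent dense tridiagonal solve.

At profile ends both modes use replicate padding (the edge value stands in
for the missing neighbor; the spline evaluates its nearest piece half a
voxel beyond the end knot).  This keeps α bounded and avoids extrapolation
blow-up at volume borders.

## Flavors, chaining, pass order

"Z" is one conserving pass along the slice axis; "XY" is realized as two
sequential 1D passes (x then y by default).  The sequential construction
reuses the same per-voxel machinery, conserves by construction, and
preserves the 1D marginal behavior.  Since each pass is a linear operator
acting along a single axis, the two in-plane orders commute in exact
arithmetic; the `axis_order_xy` option exists for reproducibility of the
floating-point bit pattern, not because the results differ materially.
Chains apply flavors left to right; sizes double and spacings halve
multiplicatively ("Z,XY,Z" divides slice thickness by 4).

## Clamping

Children below the clamp floor (default −1024, the scanner encoding of
air) are raised to the floor, per child, after the split; nothing is
redistributed to the sibling, because redistribution would silently alter
values the optimization fixed.  A clamped child breaks the parent-average
identity; the `ConservationReport` returned by every resampling call
exposes the resulting defect (max/mean of |mean(children) − parent|) and
the clamp count instead of hiding them.  There is no upper clamp.  In
chained runs each pass clamps its own output before the next pass runs.

Note the floor makes conservation conditional: e.g. uniform noise in
[−900, 2000] under the linear reference can produce α up to 725 HU and
push a child of a −900 HU parent to −1625, which clamps.  The exact
round-trip guarantee below therefore holds either with clamping disabled
or on data whose splits provably stay above the floor.

## Verification: mean pooling as inverse

Downsampling averages adjacent disjoint pairs along an axis (2×2 blocks
for XY) — the unique pooling under which a conserving upsampler is a right
inverse.  With clamping off, `downsample(upsample(V)) = V` holds to 1e−9
HU (pure double-precision rounding; the identity is exact in reals).  The
`verify` command and `conservation_audit` implement exactly this check,
which is also how the method is validated when no high-resolution ground
truth exists: lower the resolution, upsample, lower again, and require the
two low-resolution volumes to be identical.

## Numerical choices

* Conservation tolerance: 1e−9 HU everywhere ("identical" on the HU scale
  of ~10³ leaves ~6 orders of margin above double-precision rounding).
* The quadratic objective is never minimized numerically in production —
  the closed form is used; the objective function is retained as a test
  oracle, checked by grid search (coarse-to-fine bracketing, valid because
  the objective is a convex parabola, plus dense full-range scans on a
  subsample).
* Degenerate profiles: length 1 yields α = 0 (both references equal the
  value); length 2 degrades the spline to the straight line.
* Zero-length axes and odd-length downsampling inputs are errors, not
  silent no-ops.

## Synthetic phantoms

Clinical series are not redistributable, so tests run on generated
volumes: uniform blocks, axial ramps (the configuration where all three
interpolation methods coincide), spheres, a crude multi-ellipse head-like
slice, and seeded uniform noise.  Default HU follow clinical convention
(air −1000, water 0, soft tissue ≈ 40, bone ≈ 700) purely for magnitude
realism.  The phantoms exercise conservation, locality, boundary handling
and metadata arithmetic; they do not emulate CT physics — no noise
spectra, beam hardening, partial-volume blur or reconstruction-kernel
texture — so passing tests demonstrate the algebraic guarantees and
plumbing, not perceptual quality on real scans.  Problem sizes used in
tests and the acceptance script (volumes up to 64×64×16, one
metadata-only run at 512×512×3) were chosen as the smallest sizes that
exercise every code path and the clinical-scale metadata arithmetic.

## Known limitations

* Only factor-2 resampling along device axes; no arbitrary factors,
  rotations or registration.
* The XY flavor is separable; a direct 2×2-constrained 2D optimization is
  a documented alternative that was not implemented (all 1D behavior and
  printed values are identical either way).
* New half-voxels inherit only sizes; quarter-offset slice positions are
  not tracked, matching the metadata model of the CSV format.
* DICOM and NIfTI I/O are deliberately out of scope; the CSV slice-series
  dialect documented in `io_csv` is normative for this package.
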