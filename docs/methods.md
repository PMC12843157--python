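# Methods

## Problem and model

A slicer converts a reference surface mesh (STL, mm units) into layered
toolpaths.  The G-code encodes nozzle-center motion: the printed surface is
offset from it by half the line width laterally, and the deposited bead
lies one layer height *below* the commanded nozzle plane.  `gcodeqc`
inverts this encoding geometrically — no physics, no printer — so that the
difference between the encoded geometry and the reference mesh isolates
the slicer's contribution to dimensional error.

The bead model is deliberately simple: a rectangular cross-section of
width `w` (nominal line width) and height `h` (layer height), centered
laterally on the nozzle path and extending from the nozzle plane downward.
Real beads are elliptical and flow-dependent; since slicers plan with the
nominal width, the nominal model is the right baseline for evaluating the
*slicer*.

## Pipeline stages and the decisions behind them

**Parsing.**  Linear moves only; arcs (G2/G3) raise an error rather than
being linearized — silent approximation would fold our own tolerance into
the measurement.  Retraction handling: E-decreasing moves and the
subsequent recovery are travels; deposition resumes only once cumulative E
exceeds its pre-retraction maximum.  This prevents phantom segments from
prime/retract cycles.  Process metadata is taken from slicer header
comments, then from modal analysis of Z steps between extrusion layers,
then from user defaults (with a warning); the source of each value is
recorded.

**Sampling.**  Segments are sampled at ≤ 0.05 mm (half the voxel size), a
Nyquist-style bound guaranteeing the rasterizer cannot skip voxels.
Tangents are taken from the neighbouring *G-code vertices* (central
difference at junctions, one-sided at open ends, wrap-around on closed
loops), not from resampled points, so dense sampling does not flatten
corner tangents.

**Voxelization (0.10 mm grid).**  Each sampled point stamps its bead
footprint: a lateral disc of radius w/2 and a vertical column one layer
height tall ending at the point's own voxel.  A morphological closing with
a radius-1 ball (26-connectivity) then fuses residual voids between
adjacent lines.  The grid origin is snapped to the voxel lattice below the
cloud's bounding box, making maps reproducible run to run, and a one-voxel
empty margin is guaranteed.  Quantization uncertainty is ±0.05 mm per
axis; an experiment (see Verification) shows halving the voxel size moves
the final MSD by well under 0.005 mm.

**Classification.**  The exterior empty region is found by 6-connected
flood fill from the grid border (the standard complementary pairing with
26-connected occupancy).  Occupied voxels 26-adjacent to it form the SHELL
crust; everything else occupied is INTERIOR.  Enclosed cavities smaller
than the closing kernel were already filled; larger ones (hollow models)
remain EMPTY, and material facing them stays INTERIOR.

**Shell membership of points.**  Because occupancy is footprint-dilated,
the crust lies up to w/2 away from any centerline.  A sampled point
therefore belongs to the shell iff *its bead footprint* touches the crust;
an undilated map falls back to the literal own-voxel test.  The same idea
drives the XY infill test, but with the *vertical column only*: a
candidate position counts as surface material iff the one-layer column it
would deposit contains a crust voxel.  Including the lateral disc there
was measured to overreach at concave junctions (where the calibration
step's wall meets its shelf), misclassifying buried points as surface and
biasing registration by ~0.07 mm in Z; the column-only rule removes that
bias while still covering top and bottom faces symmetrically.

**XY correction.**  Offset magnitude w/2 = 0.20 mm along the in-plane
normal of the local tangent; the two candidates share the base point's Z.
Decision logic: one candidate in infill → keep the other; neither → keep
both ("single line"); both → drop and count as an error diagnostic.  No
tangent smoothing is applied; the voxel shell test absorbs tangent noise.

**Z correction.**  All points move down by h; a point whose pre-shift
voxel has EMPTY directly above is a superior-edge point — there the nozzle
plane is the printed top — and moves back up.  Points pushed below the
grid floor (bottom layer) are clamped with a warning.

**Calibration registration.**  The step object (bounding box exactly
10.00 × 6.25 × 8.75 mm; three perpendicular reference faces; no rotational
symmetry) is identified among the scene's two 26-connected components by
bounding-box match (±0.5 mm per axis plus footprint slack); points are
assigned to components through a KD-tree over occupied voxel centers.
Alignment is center-of-mass translation (point mean onto volumetric
centroid) followed by rigid ICP: correspondences are
point-to-nearest-point-on-triangle with no outlier trimming; the
least-squares update is *point-to-plane* (residuals minimized along the
pseudo-normal at the closest point), chosen because it converges in a
handful of iterations on clean data — so the stopping rule (RMS residual
change < 0.02 mm, cap 50 iterations) only fires once the alignment has
genuinely converged, whereas point-to-point updates converge linearly and
would stop ~0.3 mm early under the same rule.  The stop condition must
hold for two consecutive iterations: near the quantization-noise floor the
RMS change can dip below threshold one iteration before the transform
settles, and that patience is worth ~5 µm of recovered accuracy.  Five
consecutive residual increases raise a divergence error.  Everything is deterministic; ties in
nearest-triangle selection break by lowest index.

The step's internal shelf is placed at z = 4.4 mm, on the 0.2 mm layer
lattice.  Only the overall bounding box is constrained by the fiducial's
design; a shelf between deposition planes would be encoded 0.025 mm high
by *any* slicer at this layer height, and that quantization bias would
leak into the registration-accuracy experiment rather than measure it.

**Metrics.**  One-sided signed distances from the registered cloud to the
reference surface: magnitude from an exact nearest-point-on-triangle scan
(vectorized over all triangles, first-minimum tie-break, making results
directly comparable to a brute-force oracle), sign from the dot product
with the normal at the closest point.  Off-face normals use the
angle-weighted pseudo-normal (vertex/edge average of incident face
normals), keeping the sign continuous across edges.  Hausdorff-style
symmetric metrics are deliberately not reported; the reference is ground
truth, so the one-sided deviation is the interpretable quantity.  The
signed minimum is reported as the most-negative deviation, with the
unsigned minimum carried alongside for debugging.

**Layer reconstruction.**  Per layer, corrected points are chained through
their G-code links; one representative per base point (single-line doubles
collapse to the outermost candidate), chains closing within ε = w/4 =
0.10 mm become polygons, snap-rounded to 1 µm and cleaned.  Rings nest
even-odd; rings consisting mostly of single-line doubles may only be outer
boundaries — on top/bottom layers the *inner* perimeter survives the shell
filter and would otherwise punch a spurious hole through the slab.  Caps
are constrained-Delaunay triangulations, walls follow the rings, each slab
is a watertight prism of volume (net area × h), and slabs merge with
coincident interface faces cancelled on a shared snapped vertex grid.

When adjacent layers trace *identical* contours (prismatic models) the
merged mesh is strictly watertight.  When contours differ at floating-
point level, exactly-cancelling internal face pairs can remain; the merged
surface is still closed in the integration sense (every directed edge
balanced by its reverse), so the signed-tetrahedron volume is exact and
equals the slab sum to 1e-9 relative.  Volume operations accept exactly
this closure condition and refuse anything weaker, reporting the
non-manifold edge count.

## Synthetic fixtures

The mini-slicer emulates the *structure* of commercial slicer output —
cross-sections at mid-layer planes, two mitered perimeter insets (miter
limit 2), 100% rectilinear infill at spacing w alternating 0°/90°,
absolute-E moves with volumetric filament accounting (nominal 1.75 mm
filament; the constant is arbitrary but fixed, only Δ E > 0 matters
downstream), deterministic seam at the lexicographically smallest vertex,
header comments carrying h and w.  It reproduces no particular slicer's
toolpaths; it provides *ground truth* with known placement, known solids
and byte-deterministic output.

When the layer height does not divide the scene height, a remainder larger
than h/4 is printed as a final layer shifted to the true top height (the
way most slicers close the top surface); smaller remainders are omitted.
The shifted final layer matters: the calibration object is 8.75 mm tall,
and omitting the 0.15 mm remainder would put its encoded top face at
8.60 mm — a fiducial defect that would dominate the very registration
error the fiducial exists to eliminate.  A consequence is that models
whose height is not a multiple of h produce an overlapping final slab and
cannot be layer-reconstructed; all built-in fixture models use lattice
heights.

What the fixtures do *not* emulate: seam scattering, gap fill, bridging,
perimeter-overlap trimming, toolpath resampling and the other
slicer-specific heuristics that produce the deviations observed on real
G-code.  Passing the fixture suite therefore shows the *measurement
pipeline* is accurate (corrections land on the encoded surface, placement
recovery at the micrometre scale, volume bookkeeping exact); it does not
predict the magnitude of any particular slicer's error on anatomical
models.

## Verification experiments (`gcodeqc.verification`)

* **Deposition-plane alignment** — fraction of PC4 points within ±0.10 mm
  of a layer-height multiple on a box + calibration scene; ≥ 99.9% is
  required, ~100% observed.
* **Voxel-size sensitivity** — full pipeline at 0.10 mm vs 0.05 mm voxels
  on a 20×20×5 mm box and an L-shaped solid; max |ΔMSD| ≤ 0.005 mm.
* **Registration recovery** — 20 seeded in-plane placements (|t| ≤ 150 mm,
  |θ| ≤ 5° about Z — the degrees of freedom a build plate has); recovered
  within 0.01 mm per axis and 0.05°, with MSD perturbation ≤ 0.001 mm.
* **Repeatability** — re-running any placement is byte-identical (the
  mini-slicer and pipeline are deterministic); across different placements
  the analysis contributes only floating-point-level variation (~1e-5 mm),
  since coordinate rounding, the voxel lattice and ICP are not exactly
  translation-equivariant.

Problem sizes (10–20 mm solids, 0.2 mm layers, ~10⁵ points per scene) were
chosen as the smallest scale at which every mechanism of the method —
perimeters vs infill, top/bottom faces, the full calibration object — is
exercised with thousands of points per surface.

## Known limitations

* Solid, watertight models only; internal voids are out of scope (cavity
  walls are filtered as INTERIOR and holes punched only by true hole
  rings).
* Uniform layer height and line width; adaptive heights and per-segment
  widths are rejected or ignored.
* Concave voxel-quantization artifacts: within ~1 voxel of a concave
  junction (e.g. a shelf meeting a wall), a small number of points can be
  mis-shadowed by neighbouring beads' dilation and end up one layer low
  (measured: ~100 of 3×10⁴ calibration points at −0.2 mm; negligible for
  registration after the column-reach rule).
* Registration assumes the calibration object is intact in the G-code;
  heavy occlusion or fragmentation is not mitigated.
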