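# Methods

This note records the model, the numerical choices and their rationale,
what the synthetic fixtures do and do not establish, and the known
limitations.  Nothing here states an empirical number that the test suite
or `scripts/acceptance.py` does not itself compute.

## Model overview and assumptions

The segmentation target is the boundary of one connected object in a 2-D
grayscale image.  The method assumes the boundary manifests as an
intensity gradient at least somewhere along its length; stretches with no
gradient at all are treated as *gaps* to be bridged, not as evidence of
absence.  The mechanical surrogate is a linear-elastic, brittle,
variable-thickness plate in plane stress:

- **Geometry.** One bilinear quadrilateral element per pixel, nodes at
  pixel corners, pixel side `L_p = 1`.  The element's out-of-plane
  thickness is the mapped intensity `h ∈ [1, H]`.  This is a deliberate
  dimensional reduction of a voxel-stacked 3-D plate: under in-plane
  load, membrane stress scales as force/(width × thickness), so thin
  elements (grooves) concentrate stress exactly as a milled notch does,
  at a fraction of the cost.  A plane-stress membrane has no
  through-thickness asymmetry by construction — the benefit a symmetric,
  double-sided groove geometry buys in a 3-D model comes for free.
- **Material.** E = 210 GPa, ν = 0.49, maximum principal stress threshold
  220 MPa, fracture energy 42 200 J/m² (accepted but unused — see crack
  growth).  Only the ratio of threshold to applied load matters for
  onset; the SI values are conventions, not requirements.  The
  near-incompressible ν keeps element volumes nearly constant; the large
  E keeps displacements small relative to the mesh.
- **Crack representation.** An explicit polyline along mesh edges.
  Displacement discontinuity is obtained by node splitting: every vertex
  strictly interior to the path is duplicated and the elements on either
  side rewired to opposite copies (tip and entry stay shared; border
  vertices are not split because the window border is fully constrained
  anyway).  This replaces enrichment-based approaches: for a contour that
  is ultimately quantized to pixels, sub-element crack geometry buys
  nothing.
- **Crack growth** is instantaneous-brittle: when the onset criterion is
  met the crack extends one full edge, with no softening law.  The
  fracture-energy parameter is therefore accepted in the material record
  but not consulted.

## Loading and the ramp

The load is a pair of equal-and-opposite nodal force patches (radius 3 px)
straddling the crack 2 px behind the tip, directed along ± the normal of
the smoothed travel direction — Mode-I opening that follows the crack
around curves.  The window border is fully fixed, which removes
rigid-body modes for any crack orientation and keeps far material quiet.

The force ramps linearly from zero.  Because the problem is linear, the
whole ramp is evaluated with a single unit-load solve per crack
configuration: the onset load is the smallest multiple of the ramp step
(fixed at 1/10 of the first extension's required load) at which the
maximum principal stress on the forward ridge reaches the threshold.
This is identical to literally stepping the ramp, at a fraction of the
solves.  Per-step onset loads are recorded in the crack log.

**Ramp cap.** The prescription is a cap "large enough to break every thin
structure" but not the full plate.  Early experiments with absolute caps
(a fixed multiple of the first or median onset) failed: legitimate
in-groove onset loads vary by ~2.5× along a rasterized curved groove,
while tunneling through full-thickness material needs only ~2–3× the
groove onset, so no multiplicative margin separates the two.  The cap is
therefore implemented structurally: growth continues wherever the forward
stress ridge lies on *thin* material (thickness below
`min + 0.35 (max − min)` of the window's range), and stalls where only
thick material lies ahead.  An explicit finite `ramp_cap` remains
available and is honored as a hard bound (used, e.g., to demonstrate that
a uniform plate under a small cap does not crack).

## Extension direction

Each step solves at unit load and locates the *failure ridge*: the
maximum-σ₁ element among thin elements within a 3 px forward cone of the
tip (positive projection on the travel direction smoothed over the last
three segments).  The crack takes the lattice step whose landing node is
closest to the stress-weighted centroid of the failing neighborhood;
ties fall to alignment with the direction perpendicular to the ridge
element's principal stress direction (the opening-growth direction — this
also resolves the isotropic case by falling through to the previous
travel direction).

Why not score the three forward edges by their flanking elements
directly?  On rasterized curved grooves that rule is structurally
unstable: the straight edge alongside a failing groove element and the
turn edge into it always tie on the shared element, and at 45° valley
junctions the true valley element is diagonal to the tip, flanked by no
candidate edge at all.  The ridge search sees past both artifacts.

Two recovery mechanisms handle what greedy stepping cannot:

- **Gap bridging.**  When no thin material lies ahead, up to `gap_max = 3`
  forced straight steps probe across the interruption (re-checking after
  each); failing that, single lateral probes recover staircase corners.
  Probes that do not lead to resumed cracking are rolled back.
- **Backtracking.**  A stalled front rewinds to the most recent genuinely
  ambiguous side choice (a diagonal ridge target, both landings
  equidistant) within the last 6 vertices and takes the other branch, at
  most 12 times per window.  A lattice crack that passes a one-pixel-wide
  valley on the wrong side cannot re-cross it locally — the stall is the
  only reliable signal that the earlier choice was wrong.

Both mechanisms are deterministic.

## The windowed driver

Windows are squares of side 2L+1 (Chebyshev ball), L = 15 by default.
The gradient is computed globally once; the negative rescale and gamma
transform are applied *per window*, so the thickness range [1, H] is
always fully used by whatever contrast the window actually has — faint
local edges become full-depth grooves.  Per-window normalization is also
why gaps are well-defined: a window with no gradient information at all
is flagged degenerate and handled as a gap rather than producing a
spurious noise-groove.

The window step is α = 10 px along the total-least-squares line through
the tail of the current crack (TLS rather than an ordinary slope so that
vertical boundaries are routine; the step's sign continues the previous
travel).  α < 2L guarantees overlap, so the next window contains the
previous crack's tail, which — snapped to the new window's lattice — is
its initial crack.  Vertices grown within 2 px of a window border are
discarded before hand-off: the fully clamped border distorts the local
stress field, and the overlapping next window re-traces that zone.

Closure is detected per vertex: once the front has traveled at least
2α from its start, the first new vertex within 3 px of the contour start
closes the loop (the trace is truncated at the closest approach).  A
tip-only closure test at window granularity can step across the start
and send the front around the object a second time.

When a front stalls and short-range bridging has failed, the driver scans
along the fitted boundary direction (anchored a few vertices back — the
last vertices of a stalled front are failed probes) with a widening
transverse cone, looking for the gradient to recover a quarter of the
median edge strength seen so far.  A second front is seeded there by the
automatic ray-sweep seeder, oriented to continue the same travel sense,
and the blank span becomes a straight bridge at merge time.  Fragments
are concatenated in order, de-duplicated in the overlaps (1.5 px
proximity), smoothed with a 5-point moving average (wrap-around for
closed contours, exact endpoint preservation for open ones), and closed
contours are oriented counterclockwise.  Masks rasterize the polygon at
pixel centers.

## Default parameters

| parameter | default | units | role |
|---|---|---|---|
| σ (gradient smoothing) | 0.8 | px | width of the derivative-of-Gaussian kernels; keeps the thickness valley ≈1 px wide so a lattice-edge crack can track its floor.  Larger values (1.5+) widen the valley into a flat bottom that gives the follower no transverse signal. |
| γ (gamma transform) | 2.0 | — | deepens grooves relative to background texture |
| H (max thickness) | 20 | px | thickness contrast groove↔plain; 20 rather than 10 roughly doubles the stress contrast between groove cracking and tunneling |
| L (window half-size) | 15 | px | local model size; boundaries are near-straight at this scale |
| α (window step) | 10 | px | overlap 2L−α = 20 px; generous overlap stabilizes seed hand-off on curved boundaries |
| patch radius | 3 | px | tip-load footprint |
| gap_max | 3 | px | forced straight steps across a groove gap |
| look radius | 3 | px | forward ridge search |
| thin threshold | 0.35 | — | fraction of the window thickness range counted as groove |
| closure tolerance | 3 | px | per-vertex closure test |

All are exposed in `LcpmConfig` / the YAML config.

## Synthetic fixtures: what they do and do not show

`synthetic.gen_phantom` produces star-convex objects (disk, ellipse,
Fourier-perturbed blob with harmonics k ≤ 5 and amplitudes ≤ 0.10) over
uniform, linearly ramped, or radially shaded intensities, with optional
sinusoidal/checker background texture, seeded additive Gaussian noise,
and boundary gaps.  Gaps blend the image toward the local background in a
thin band around the boundary (fully erased core over the central 40% of
the arc, cosine-tapered in angle, Gaussian-tapered radially) — the edge
becomes invisible without creating new edges and without touching the
ground-truth mask.  Everything is exactly reproducible from (spec, seed).

These fixtures exercise the failure modes the method is designed for —
inhomogeneous intensity, texture, noise, discontinuity — but they are not
medical images: real data have anisotropic point-spread, speckle,
multiple competing boundaries at close range, and partial-volume edges
softer than anything generated here.  Passing the synthetic benchmark
demonstrates the mechanics of the method, not clinical performance.

`gen_groove_plate` builds thickness fields directly.  Its default groove
cross-section is a Gaussian of width 0.8 px — the shape an image edge
actually produces through the transform pipeline.  A binary single-pixel
groove (`profile="flat"`) is kept for the simplest tests; its staircase
corners on curved paths are artifacts no lattice-edge crack can follow
and do not occur in image-derived thickness fields.

Crack/groove agreement is measured on the smoothed crack trace (the
5-point moving average that the contour integration applies), not on raw
lattice vertices: on a diagonal valley the best possible lattice path has
corners ≈1.1 px from the centerline by construction, while its smoothed
trace is the curve the method actually reports.

## Numerical notes

- Assembly uses one reference 8×8 stiffness (2×2 Gauss, exact for the
  congruent square elements) scaled by per-element thickness; systems of
  ≈2000 unknowns per window are solved with SuperLU (`spsolve`).  One
  solve per crack extension.
- Stresses are evaluated at element centroids (the optimal sampling point
  of the bilinear quad); σ₁ and its direction come from the closed-form
  2-D eigendecomposition.
- Degenerate inputs: constant windows flag `degenerate` (gap semantics);
  constant gradient inputs return an all-ones rescale with the same flag;
  both-empty masks define Dice = 1 with a warning; an all-foreground
  reference makes TNR/FPR undefined and raises.
- Determinism: there is no randomness anywhere in the solver or driver;
  phantom noise is generated by seeded `default_rng`.  Two identical runs
  produce byte-identical contour JSON.

## Problem sizes

Default experiments run 128² phantoms with ≈30 px object radii, windows
of 31² pixels (≈2048 DOF), and 10–16 windows per contour; one
segmentation takes a few seconds on one CPU.  The acceptance script's
benchmark is 5 regimes × 10 seeds at these sizes.

## Known limitations

- Single object, single front pair: no simultaneous multi-region
  segmentation.
- The first window must contain a detectable piece of boundary; fully
  automatic seeding still requires the user to choose that window.
- Very wide invisible stretches (beyond `gap_scan` = 40 px, or where the
  resume scan's straight continuation diverges from a sharply curving
  boundary) leave an open contour with a diagnostic rather than a guess.
- Contours are pixel-scale: no sub-pixel refinement of the crack path
  beyond the smoothing pass.
- The plane-stress reduction discards any true through-thickness
  mechanics; it is an argument about stress *scaling*, not a solved 3-D
  plate.
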