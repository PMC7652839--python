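# crackseg — mechanical image segmentation by crack propagation

`crackseg` segments objects in 2-D grayscale images by turning the
segmentation problem into a fracture-mechanics problem, the way a glass
cutter works: score a groove, load the plate, and the crack follows the
score line.  It is aimed at biomedical image analysis — organs and soft
tissues in MR/CT/ultrasound slices — and is strongest exactly where
intensity-based methods leak: blurred and even *discontinuous* boundaries,
which a crack crosses by stress concentration at its tip.

## The model

A grayscale image `I_o` becomes a thin elastic plate whose thickness
encodes edge information:

1. **Gradient map** — `I_G = |∇(G_σ * I_o)|²`, the squared magnitude of the
   Gaussian-smoothed gradient (computed with derivative-of-Gaussian
   kernels, default σ = 0.8 px).
2. **Negative rescale** — `Î_G = 1 − (I_G − min) / (max − min)`, so
   boundaries (high gradient) become *low* values.
3. **Gamma transform** — `I_M = Î_G^γ` (default γ = 2) deepens the contrast
   between boundary and background.
4. **Thickness map** — within a local window,
   `h = (I_M − min)(H − 1)/(max − min) + 1 ∈ [1, H]` (default H = 20):
   object boundaries become grooves of depth H−1 in the plate.

The plate is meshed with one bilinear plane-stress quadrilateral per pixel,
carrying `h` as its out-of-plane thickness.  A short seed crack is placed
on the boundary (user polyline, or automatically via a ray sweep against a
Canny edge map).  Equal-and-opposite force patches just behind the crack
tip ramp up linearly until the maximum principal stress σ₁ in the thin
material ahead of the tip reaches the material strength (220 MPa for the
default steel-like material, E = 210 GPa, ν = 0.49); the crack then
extends one mesh edge toward the failing material, the crack faces are
decoupled by node splitting, and the ramp restarts.  Stress concentrates
in the groove — roughly in proportion to the thickness contrast — so the
crack traces the image boundary at pixel resolution.

Rather than cracking one huge plate, the driver walks the boundary with
small overlapping windows (half-size L = 15, step α = 10): each window
re-normalizes its own contrast (faint local edges always span the full
thickness range), inherits the previous crack's tail as its seed, and
hands the fitted boundary direction to the next window.  Where the
boundary vanishes entirely, the front either bridges a short gap under
tip stress or a second front is spawned beyond the blank region; all
fragments are merged, smoothed, and rasterized to a mask.  Dice,
Hausdorff, TNR and FPR metrics against reference masks are included.

## Worked example

```bash
python examples/04_segment_noisy_ellipse.py
```

segments an ellipse with a background intensity ramp and Gaussian noise
and prints:

```
windows: 11, closed: True
Dice vs ground truth: 0.9837  (1.0 = perfect overlap)
Hausdorff distance:  1.41 px (worst boundary mismatch)
```

Eleven local fracture simulations walked the boundary and closed the
contour; the recovered mask overlaps the ground truth at Dice 0.98 with a
worst boundary error of 1.4 px.  The other examples show the individual
stages: `01` the image→thickness transform, `02` stress concentration
versus groove depth, `03` a single crack tracing a quarter-circle groove
(mean error 0.53 px), and `05` the dual-front recovery across a 12-row
stretch of invisible boundary (edge recovered to 0.8 px elsewhere).

The same pipeline is scriptable from a shell:

```bash
crackseg synth --preset fig4e --seed 7 --out img.png --truth truth.png
crackseg run --image img.png --center 34,63 --seed "33.5,60.5:33.5,63.5" \
             --out contour.json --mask mask.png
crackseg eval --pred mask.png --truth truth.png
```

## Layout

- `src/crackseg/image_transform.py` — intensity pipeline
- `src/crackseg/plate_model.py` — windows, thickness map, mesh
- `src/crackseg/fem.py` — plane-stress solver, principal stress
- `src/crackseg/fracture.py` — crack growth: ramp, node splitting, gaps
- `src/crackseg/crack_init.py` — manual and ray-sweep seeding
- `src/crackseg/lcpm.py` — windowed driver, contour merging
- `src/crackseg/metrics.py` — Dice / Hausdorff / TNR / FPR
- `src/crackseg/synthetic.py` — phantoms with exact ground truth
- `src/crackseg/config.py`, `cli.py` — YAML config and `crackseg` CLI
- `docs/methods.md` — modeling choices, parameters, limitations
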