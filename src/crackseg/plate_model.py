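"""Local windows and their conversion to variable-thickness plate meshes.

A local window is a (2L+1) x (2L+1) patch of the enhanced image (Chebyshev
ball of radius L around the window center).  The window's intensities are
mapped linearly onto plate heights in [1, H]; low intensities (boundaries)
become grooves of height ~1 in an otherwise thick plate.  The mesh is a
structured grid with one bilinear quadrilateral element per pixel; the
element carries the pixel's height as an out-of-plane thickness, which is
the plane-stress reduction of stacking voxels: under in-plane load, stress
scales with 1/thickness, so grooves concentrate stress exactly as a milled
notch does, and the model is through-thickness symmetric by construction
(no bending degrees of freedom exist at all).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class WindowError(ValueError):
    """Window specification is invalid for the given image."""


@dataclass(frozen=True)
class WindowSpec:
    """Square local window: center pixel (row, col) and half-size L."""

    center: tuple[int, int]
    half_size: int

    def __post_init__(self) -> None:
        if self.half_size < 4:
            raise WindowError(f"window half-size must be >= 4, got {self.half_size}")


@dataclass(frozen=True)
class WindowPatch:
    """Pixels of a window plus its placement in the parent image."""

    pixels: np.ndarray
    origin: tuple[int, int]  # (row, col) of the patch's top-left pixel
    spec: WindowSpec
    clamped: bool = False


@dataclass(frozen=True)
class ThicknessField:
    """Plate heights over a window, in [1, H].

    ``degenerate`` marks a constant window: no groove exists there and the
    driver must treat the region as a boundary gap.
    """

    h: np.ndarray
    H: float
    degenerate: bool = False


@dataclass(frozen=True)
class MaterialParams:
    """Linear-elastic brittle material of the plate.

    Defaults are steel-like values with a near-incompressible Poisson ratio:
    a stiff plate barely deforms while the crack grows, and nu close to 0.5
    keeps element volumes nearly constant under load.  Only the ratio of
    max_principal_stress to the applied load matters for crack onset, so
    these are conventions, not requirements.
    """

    youngs_modulus: float = 210e9       # Pa
    poisson_ratio: float = 0.49
    max_principal_stress: float = 220e6  # Pa, failure threshold
    fracture_energy: float = 42200.0     # J/m^2, accepted but unused (brittle extension)

    def __post_init__(self) -> None:
        if not (0.0 < self.poisson_ratio < 0.5):
            raise ValueError("poisson_ratio must be in (0, 0.5)")
        if min(self.youngs_modulus, self.max_principal_stress, self.fracture_energy) <= 0:
            raise ValueError("material magnitudes must be positive")


@dataclass
class PlateMesh:
    """Structured quad mesh over a window with per-element thickness.

    Nodes sit at pixel corners: the structured grid node (i, j) of a
    rows x cols element mesh has window-local coordinates (x=j, y=i) in
    pixel units, i.e. element (r, c) spans [c, c+1] x [r, r+1] and its
    centroid coincides with pixel (r, c) at (c+0.5, r+0.5).  Node splitting
    (see fracture module) appends duplicated nodes past the structured
    block; ``grid_node`` maps every node id back to its structured (i, j).
    """

    rows: int
    cols: int
    node_xy: np.ndarray          # (n_nodes, 2) float, window-local (x, y)
    elem_nodes: np.ndarray       # (n_elems, 4) int, CCW in (x, y)
    thickness: np.ndarray        # (n_elems,) float
    material: MaterialParams
    pixel_size: float = 1.0
    origin: tuple[int, int] = (0, 0)  # image (row, col) of element (0, 0)
    grid_node: np.ndarray = field(default=None)  # (n_nodes, 2) int (i, j)

    @property
    def n_nodes(self) -> int:
        return self.node_xy.shape[0]

    @property
    def n_elems(self) -> int:
        return self.elem_nodes.shape[0]

    def structured_node(self, i: int, j: int) -> int:
        """Node id of structured grid position (i, j) before any splitting."""
        return i * (self.cols + 1) + j

    def border_nodes(self) -> np.ndarray:
        """Ids of all nodes lying on the window border (splits included)."""
        gi, gj = self.grid_node[:, 0], self.grid_node[:, 1]
        on = (gi == 0) | (gi == self.rows) | (gj == 0) | (gj == self.cols)
        return np.flatnonzero(on)

    def elem_index(self, r: int, c: int) -> int:
        return r * self.cols + c

    def dump_json(self, path: str) -> None:
        """Write nodes, connectivity and thickness for external rendering."""
        import json

        with open(path, "w") as fh:
            json.dump(
                {
                    "rows": self.rows,
                    "cols": self.cols,
                    "origin": list(self.origin),
                    "pixel_size": self.pixel_size,
                    "node_xy": self.node_xy.tolist(),
                    "elem_nodes": self.elem_nodes.tolist(),
                    "thickness": self.thickness.tolist(),
                },
                fh,
            )


def extract_window(image: np.ndarray, spec: WindowSpec) -> WindowPatch:
    """Cut the Chebyshev-ball window around ``spec.center`` from an image.

    Windows that would overhang the image border are clamped to it (the
    clamp is recorded); mirroring is deliberately not used, as reflected
    intensities would fabricate spurious grooves.
    """
    pixels = image if isinstance(image, np.ndarray) else image.pixels
    r, c = int(round(spec.center[0])), int(round(spec.center[1]))
    nr, nc = pixels.shape
    if not (0 <= r < nr and 0 <= c < nc):
        raise WindowError(f"window center {spec.center} outside image {pixels.shape}")
    L = spec.half_size
    r0, r1 = r - L, r + L + 1
    c0, c1 = c - L, c + L + 1
    clamped = r0 < 0 or c0 < 0 or r1 > nr or c1 > nc
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, nr), min(c1, nc)
    return WindowPatch(pixels[r0:r1, c0:c1].copy(), origin=(r0, c0), spec=spec, clamped=clamped)


def thickness_map(window: np.ndarray, H: float) -> ThicknessField:
    """Map window intensities linearly onto plate heights in [1, H].

    h = (I - I_min) (H - 1) / (I_max - I_min) + 1, so the darkest pixel
    (the boundary, after the negative rescale) gets height exactly 1 and
    the brightest exactly H.  A constant window has no groove; it is
    returned at uniform height H with the degenerate flag set.
    """
    if H < 2:
        raise ValueError(f"maximum thickness H must be >= 2, got {H}")
    w = np.asarray(window, dtype=float)
    if w.size == 0:
        raise WindowError("empty window")
    lo, hi = float(w.min()), float(w.max())
    if hi == lo:
        return ThicknessField(np.full_like(w, float(H)), H=float(H), degenerate=True)
    h = (w - lo) * (H - 1.0) / (hi - lo) + 1.0
    return ThicknessField(h, H=float(H), degenerate=False)


def build_mesh(
    thickness: ThicknessField | np.ndarray,
    material: MaterialParams | None = None,
    pixel_size: float = 1.0,
    origin: tuple[int, int] = (0, 0),
) -> PlateMesh:
    """Build the structured plate mesh for a thickness field.

    One quad element per pixel, (rows+1) x (cols+1) nodes; the element's
    out-of-plane thickness is h * pixel_size.
    """
    h = thickness.h if isinstance(thickness, ThicknessField) else np.asarray(thickness, float)
    rows, cols = h.shape
    material = material or MaterialParams()

    jj, ii = np.meshgrid(np.arange(cols + 1), np.arange(rows + 1))
    node_xy = np.column_stack([jj.ravel().astype(float), ii.ravel().astype(float)]) * pixel_size
    grid_node = np.column_stack([ii.ravel(), jj.ravel()]).astype(np.int64)

    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    n00 = r * (cols + 1) + c
    # CCW in (x, y): (c, r) -> (c+1, r) -> (c+1, r+1) -> (c, r+1)
    elem_nodes = np.column_stack(
        [n00.ravel(), (n00 + 1).ravel(), (n00 + cols + 2).ravel(), (n00 + cols + 1).ravel()]
    ).astype(np.int64)

    return PlateMesh(
        rows=rows,
        cols=cols,
        node_xy=node_xy,
        elem_nodes=elem_nodes,
        thickness=h.ravel() * pixel_size,
        material=material,
        pixel_size=pixel_size,
        origin=origin,
        grid_node=grid_node,
    )
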