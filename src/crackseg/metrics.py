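"""Segmentation agreement metrics: Dice, Hausdorff, TNR/FPR.

Conventions: masks are boolean arrays of identical shape; boundaries are
point sets in (row, col) pixel coordinates.  Distances are reported in
pixels, or scaled by ``pixel_spacing`` into physical units when given.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class SegMetrics:
    dsc: float
    hausdorff: float
    tnr: float
    fpr: float

    def as_dict(self) -> dict:
        return {"dsc": self.dsc, "hausdorff": self.hausdorff, "tnr": self.tnr, "fpr": self.fpr}


def dice(pred_mask: np.ndarray, ref_mask: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|).

    Symmetric; 1.0 iff the masks are identical and non-empty.  Two empty
    masks are defined as perfect agreement (1.0, with a warning), since
    both raters assert the structure is absent.
    """
    a = np.asarray(pred_mask, bool)
    b = np.asarray(ref_mask, bool)
    if a.shape != b.shape:
        raise MetricError(f"mask shapes differ: {a.shape} vs {b.shape}")
    sa, sb = int(a.sum()), int(b.sum())
    if sa == 0 and sb == 0:
        warnings.warn("both masks empty: Dice defined as 1.0", stacklevel=2)
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


def mask_boundary(mask: np.ndarray) -> np.ndarray:
    """8-connected outline of a mask: pixels inside with a 4-neighbor outside."""
    m = np.asarray(mask, bool)
    eroded = ndimage.binary_erosion(
        m, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return np.argwhere(m & ~eroded).astype(float)


def hausdorff(
    pred_boundary: np.ndarray, ref_boundary: np.ndarray, pixel_spacing: float = 1.0
) -> float:
    """Symmetric Hausdorff distance between two boundary point sets.

    max over both directed distances sup_a inf_b d(a, b); in pixels,
    multiplied by ``pixel_spacing`` for physical units.
    """
    a = np.atleast_2d(np.asarray(pred_boundary, float))
    b = np.atleast_2d(np.asarray(ref_boundary, float))
    if a.size == 0 or b.size == 0:
        raise MetricError("empty boundary point set")
    d_ab = cKDTree(b).query(a)[0].max()
    d_ba = cKDTree(a).query(b)[0].max()
    return float(max(d_ab, d_ba)) * pixel_spacing


def tnr_fpr(pred_mask: np.ndarray, ref_mask: np.ndarray) -> tuple[float, float]:
    """True-negative and false-positive rates over the reference background.

    tnr = TN/(TN+FP), fpr = FP/(FP+TN); the two sum to 1 exactly.  The
    reference must contain at least one background pixel.
    """
    a = np.asarray(pred_mask, bool)
    b = np.asarray(ref_mask, bool)
    if a.shape != b.shape:
        raise MetricError(f"mask shapes differ: {a.shape} vs {b.shape}")
    bg = ~b
    n_bg = int(bg.sum())
    if n_bg == 0:
        raise MetricError("reference mask has no background: TNR/FPR undefined")
    fp = int((a & bg).sum())
    tn = n_bg - fp
    return tn / n_bg, fp / n_bg


def evaluate(
    pred_mask: np.ndarray, ref_mask: np.ndarray, pixel_spacing: float = 1.0
) -> SegMetrics:
    """All four metrics for a predicted mask against a reference mask."""
    t, f = tnr_fpr(pred_mask, ref_mask)
    return SegMetrics(
        dsc=dice(pred_mask, ref_mask),
        hausdorff=hausdorff(mask_boundary(pred_mask), mask_boundary(ref_mask), pixel_spacing),
        tnr=t,
        fpr=f,
    )
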