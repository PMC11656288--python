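"""Segmentation evaluation: Dice coefficient and 95th-percentile Hausdorff
distance (HD95) in physical units.

HD95 is taken over the pooled, bidirectional surface-to-surface distances
between the boundary voxels of the two masks (a symmetric convention).
Boundary voxels are foreground voxels with at least one face-adjacent
(6-connected) background neighbour; voxels on the array border count as
boundary.  Probability maps should be binarized at 0.5 first
(:func:`binarize`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "MetricResult",
    "binarize",
    "dice_coefficient",
    "boundary_voxels",
    "hd95",
    "summarize",
]

logger = logging.getLogger(__name__)

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def binarize(probability_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    return np.asarray(probability_map) > threshold


@dataclass
class MetricResult:
    """Mean +/- SD summary of per-sample Dice (as %) and HD95 (mm)."""

    dsc_mean: float
    dsc_sd: float
    hd95_mean: float
    hd95_sd: float
    n_samples: int
    n_hd95_undefined: int
    per_sample: List[Tuple[float, float]] = field(default_factory=list)


def _check_masks(a: np.ndarray, b: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask extents differ: {a.shape} vs {b.shape}")
    return a, b


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """``2|A n B| / (|A| + |B|)``; defined as 1.0 when both masks are empty."""
    a, b = _check_masks(a, b)
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / total


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Indices (k, 3) of foreground voxels with a 6-adjacent background
    neighbour; out-of-volume neighbours count as background."""
    mask = np.asarray(mask).astype(bool)
    interior = ndimage.binary_erosion(mask, structure=_STRUCT6, border_value=0)
    return np.argwhere(mask & ~interior)


def hd95(
    a: np.ndarray,
    b: np.ndarray,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
) -> float:
    """95th percentile of pooled symmetric boundary distances, in mm.

    Returns ``nan`` (the undefined flag) when either mask is empty, never a
    silent 0.
    """
    a, b = _check_masks(a, b)
    if not a.any() or not b.any():
        return float("nan")
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise ValueError(f"spacing must be 3 positive values, got {spacing}")
    pa = boundary_voxels(a) * spacing
    pb = boundary_voxels(b) * spacing
    d_ab = cKDTree(pb).query(pa, k=1)[0]
    d_ba = cKDTree(pa).query(pb, k=1)[0]
    return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))


def summarize(
    per_sample: Sequence[Tuple[float, float]],
    dsc_as_percent: bool = True,
) -> MetricResult:
    """Aggregate (dice, hd95) pairs into mean +/- sample SD (n-1 denominator).

    Undefined (nan) HD95 entries are excluded from the HD95 statistics and
    their count is logged and reported.
    """
    if len(per_sample) == 0:
        raise ValueError("need at least one sample")
    dsc = np.asarray([d for d, _ in per_sample], dtype=float)
    if dsc_as_percent:
        dsc = dsc * 100.0
    hd = np.asarray([h for _, h in per_sample], dtype=float)
    defined = ~np.isnan(hd)
    n_undefined = int((~defined).sum())
    if n_undefined:
        logger.info("excluding %d undefined HD95 value(s) from the summary", n_undefined)
    hd = hd[defined]

    def _sd(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1)) if x.size > 1 else 0.0

    return MetricResult(
        dsc_mean=float(dsc.mean()),
        dsc_sd=_sd(dsc),
        hd95_mean=float(hd.mean()) if hd.size else float("nan"),
        hd95_sd=_sd(hd) if hd.size else float("nan"),
        n_samples=len(per_sample),
        n_hd95_undefined=n_undefined,
        per_sample=list(per_sample),
    )
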