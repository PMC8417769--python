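"""Segmentation-quality metrics: hard Dice and surface distances.

Dice measures voxel overlap; because it is biased against small, thin
structures such as the hypothalamic subunits, it is complemented by two
surface metrics: the average boundary distance (symmetrised mean of
directed mean nearest-neighbour distances between the two segmentation
surfaces) and the Hausdorff distance (the corresponding maximum, i.e. the
furthest misclassified boundary voxel).  Surfaces are taken as the centres
of mask voxels with at least one 6-neighbour outside the mask (volume
borders count as outside), converted to mm via the voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .io import LabelMap

__all__ = [
    "SurfacePointSet",
    "MetricReport",
    "hard_dice",
    "surface_voxels",
    "average_boundary_distance",
    "hausdorff_distance",
    "evaluate_segmentation",
    "paired_signed_rank",
]


@dataclass
class SurfacePointSet:
    """Boundary voxel centres of a binary mask, in mm."""

    points: np.ndarray  # (n, 3)
    source: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("surface points must be finite")


def _as_bool(mask) -> np.ndarray:
    m = np.asarray(mask)
    if m.ndim != 3:
        raise ValueError(f"mask must be 3D, got shape {m.shape}")
    return m.astype(bool)


def hard_dice(x, y) -> float:
    """Hard Dice 2|X∩Y| / (|X|+|Y|); 1 if both empty, 0 if exactly one is."""
    x, y = _as_bool(x), _as_bool(y)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    nx, ny = int(x.sum()), int(y.sum())
    if nx == 0 and ny == 0:
        return 1.0
    if nx == 0 or ny == 0:
        return 0.0
    return 2.0 * int((x & y).sum()) / (nx + ny)


_SIX_CONN = ndimage.generate_binary_structure(3, 1)


def surface_voxels(mask, voxel_size=(1.0, 1.0, 1.0)) -> SurfacePointSet:
    """Mask voxels with a 6-neighbour outside the mask (or on the border)."""
    m = _as_bool(mask)
    if not m.any():
        raise ValueError("cannot extract the surface of an empty mask")
    interior = ndimage.binary_erosion(m, structure=_SIX_CONN, border_value=0)
    pts = np.argwhere(m & ~interior).astype(float) * np.asarray(voxel_size, dtype=float)
    return SurfacePointSet(pts)


def _directed_stats(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """(mean, max) nearest-neighbour distance from each point of a to b."""
    d, _ = cKDTree(b).query(a, k=1)
    return float(d.mean()), float(d.max())


def average_boundary_distance(x, y, voxel_size=(1.0, 1.0, 1.0)) -> float:
    """Mean of the two directed mean surface distances, in mm."""
    sx, sy = surface_voxels(x, voxel_size), surface_voxels(y, voxel_size)
    mxy, _ = _directed_stats(sx.points, sy.points)
    myx, _ = _directed_stats(sy.points, sx.points)
    return 0.5 * (mxy + myx)


def hausdorff_distance(x, y, voxel_size=(1.0, 1.0, 1.0)) -> float:
    """Max of the two directed maximum surface distances, in mm."""
    sx, sy = surface_voxels(x, voxel_size), surface_voxels(y, voxel_size)
    _, dxy = _directed_stats(sx.points, sy.points)
    _, dyx = _directed_stats(sy.points, sx.points)
    return max(dxy, dyx)


@dataclass
class MetricReport:
    """Per-structure dice / average boundary distance / Hausdorff table.

    Distance entries are NaN (and listed in ``undefined``) when either mask
    of a structure is empty — never silently zero.
    """

    rows: list[dict] = field(default_factory=list)
    undefined: list[str] = field(default_factory=list)

    def add(self, structure: str, dice: float, abd: float | None, hd: float | None):
        if abd is None or hd is None:
            self.undefined.append(structure)
        self.rows.append(
            {
                "structure": structure,
                "dice": dice,
                "avg_boundary_distance": np.nan if abd is None else abd,
                "hausdorff": np.nan if hd is None else hd,
            }
        )

    def __getitem__(self, structure: str) -> dict:
        for row in self.rows:
            if row["structure"] == structure:
                return row
        raise KeyError(structure)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def _metric_triplet(mx, my, voxel_size):
    dice = hard_dice(mx, my)
    if mx.any() and my.any():
        return dice, average_boundary_distance(mx, my, voxel_size), hausdorff_distance(
            mx, my, voxel_size
        )
    return dice, None, None


def evaluate_segmentation(pred: LabelMap, gt: LabelMap) -> MetricReport:
    """Per-label, per-side and whole-structure metrics for two label maps.

    'whole' is the union of all foreground labels on both sides; the
    per-side unions ('whole left'/'whole right') are reported as well.
    """
    if pred.shape != gt.shape:
        raise ValueError(f"grid mismatch: {pred.shape} vs {gt.shape}")
    if pred.taxonomy != gt.taxonomy:
        raise ValueError("taxonomy mismatch between prediction and ground truth")
    tax = gt.taxonomy
    vs = gt.voxel_size
    report = MetricReport()
    for code in tax.foreground_codes:
        mx, my = pred.data == code, gt.data == code
        report.add(tax.name_of(code), *_metric_triplet(mx, my, vs))

    fg_codes = np.asarray(tax.foreground_codes)
    left = [c for c in tax.foreground_codes if tax.lr_swap[c] > c]
    right = [c for c in tax.foreground_codes if tax.lr_swap[c] < c]
    for name, codes in (("whole left", left), ("whole right", right), ("whole", fg_codes)):
        mx = np.isin(pred.data, codes)
        my = np.isin(gt.data, codes)
        report.add(name, *_metric_triplet(mx, my, vs))
    return report


def paired_signed_rank(scores_a, scores_b, sidedness: str = "two-sided") -> float:
    """Wilcoxon signed-rank p-value for paired score lists.

    ``sidedness`` is 'two-sided', 'greater' (a tends above b) or 'less';
    zero differences are dropped.  Requires at least 5 pairs.
    """
    a, b = np.asarray(scores_a, dtype=float), np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("scores must be equal-length 1D sequences")
    if a.size < 5:
        raise ValueError("need at least 5 paired scores")
    if np.all(a == b):
        raise ValueError("all paired differences are zero; test is degenerate")
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative=sidedness)
    return float(res.pvalue)
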