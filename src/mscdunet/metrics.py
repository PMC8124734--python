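"""Segmentation evaluation metrics.

Per class: Dice overlap (percent), 95th-percentile symmetric
Hausdorff distance (mm), absolute volume difference (percent) and
average symmetric surface distance (mm). Surfaces are the foreground
voxels with at least one 6-neighbor outside the mask (out-of-grid
counts as outside); distances are Euclidean between surface voxel
centers in physical (mm) coordinates. Percentiles interpolate
linearly between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .io_prep import LabelMap

__all__ = [
    "EmptyStructureError",
    "MetricsReport",
    "dice",
    "surface_voxels",
    "hd95",
    "avd",
    "asd",
    "evaluate",
]

CLASS_NAMES = {0: "background", 1: "GM", 2: "WM", 3: "CSF"}


class EmptyStructureError(ValueError):
    """Raised when a surface/volume metric is undefined on an empty mask."""


def _check_shapes(g, p):
    g = np.asarray(g, dtype=bool)
    p = np.asarray(p, dtype=bool)
    if g.shape != p.shape:
        raise ValueError(f"mask shapes differ: {g.shape} vs {p.shape}")
    return g, p


def dice(g, p) -> float:
    """2|G∩P| / (|G|+|P|) in percent; two empty masks agree perfectly (100)."""
    g, p = _check_shapes(g, p)
    denom = g.sum() + p.sum()
    if denom == 0:
        return 100.0
    return float(200.0 * np.logical_and(g, p).sum() / denom)


_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def surface_voxels(mask, spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Physical coordinates (mm) of the 6-connectivity surface voxels."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyStructureError("surface of an empty mask is undefined")
    interior = ndimage.binary_erosion(mask, structure=_STRUCT6, border_value=0)
    surf = mask & ~interior
    idx = np.argwhere(surf)
    return idx * np.asarray(spacing, dtype=np.float64)


def _directed_distances(a_pts, b_pts):
    return cKDTree(b_pts).query(a_pts, k=1)[0]


def hd95(g, p, spacing=(1.0, 1.0, 1.0)) -> float:
    """Symmetric 95th-percentile Hausdorff distance in mm."""
    g, p = _check_shapes(g, p)
    gs = surface_voxels(g, spacing)
    ps = surface_voxels(p, spacing)
    d_gp = np.percentile(_directed_distances(gs, ps), 95)
    d_pg = np.percentile(_directed_distances(ps, gs), 95)
    return float(max(d_gp, d_pg))


def avd(g, p) -> float:
    """|V_g - V_p| / V_g in percent (voxel-count volumes)."""
    g, p = _check_shapes(g, p)
    vg = g.sum()
    if vg == 0:
        raise EmptyStructureError("AVD undefined for empty ground truth")
    return float(100.0 * abs(int(vg) - int(p.sum())) / vg)


def asd(g, p, spacing=(1.0, 1.0, 1.0)) -> float:
    """Average symmetric surface distance in mm."""
    g, p = _check_shapes(g, p)
    gs = surface_voxels(g, spacing)
    ps = surface_voxels(p, spacing)
    return float(
        0.5
        * (
            _directed_distances(gs, ps).mean()
            + _directed_distances(ps, gs).mean()
        )
    )


@dataclass
class MetricsReport:
    """Per-class metric table; classes absent from the ground truth are
    reported with NaN values and missing=True, never as silent zeros."""

    per_class: pd.DataFrame
    spacing: tuple

    def to_csv(self, path):
        self.per_class.to_csv(path, index=False)

    def mean_foreground_dice(self) -> float:
        fg = self.per_class[(self.per_class["class"] != 0) & ~self.per_class["missing"]]
        return float(fg["dice_pct"].mean())


def evaluate(pred: LabelMap, truth: LabelMap, classes=(1, 2, 3)) -> MetricsReport:
    """Binarize each listed class and compute all four metrics."""
    if pred.data.shape != truth.data.shape:
        raise ValueError(
            f"prediction grid {pred.data.shape} does not match truth {truth.data.shape}"
        )
    if tuple(pred.spacing) != tuple(truth.spacing):
        raise ValueError("prediction and truth spacing differ")
    spacing = tuple(truth.spacing)
    rows = []
    for c in classes:
        g = truth.data == c
        p = pred.data == c
        if not g.any():
            rows.append(
                {
                    "class": c,
                    "name": CLASS_NAMES.get(c, str(c)),
                    "dice_pct": np.nan,
                    "hd95_mm": np.nan,
                    "avd_pct": np.nan,
                    "asd_mm": np.nan,
                    "missing": True,
                }
            )
            continue
        has_p = p.any()
        rows.append(
            {
                "class": c,
                "name": CLASS_NAMES.get(c, str(c)),
                "dice_pct": dice(g, p),
                "hd95_mm": hd95(g, p, spacing) if has_p else np.nan,
                "avd_pct": avd(g, p),
                "asd_mm": asd(g, p, spacing) if has_p else np.nan,
                "missing": False,
            }
        )
    return MetricsReport(per_class=pd.DataFrame.from_records(rows), spacing=spacing)
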