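"""Segmentation metrics and paired volume-agreement statistics.

Per structure the package reports:

* **DSC** — Dice similarity coefficient ``2|A∩B| / (|A|+|B|)``; defined as 1
  when both voxel sets are empty and 0 when exactly one is (documented
  conventions).
* **HD** — the classical (maximum) Hausdorff distance between the boundary
  voxel sets, in millimetres using the physical spacing; HD95 is available
  as an option.  Boundary voxels are the erosion difference under
  4-connectivity (2-D) / 6-connectivity (3-D).
* **Volume** — voxel count x voxel volume (mm^3) / 1000, in ml.

Volume agreement between manual and automatic segmentation is tested per
structure on the paired differences: Shapiro–Wilk normality at alpha = 0.05
gates between the paired t-test (normal) and the Wilcoxon signed-rank test
(non-normal), with medians and quartiles reported as M (Q1, Q3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .grid import LabelMask
from .labels import LABEL_NAMES, STRUCTURES

ALPHA = 0.05


@dataclass
class StructureMetrics:
    dsc: float
    hd_mm: float | None
    volume_pred_ml: float
    volume_ref_ml: float


@dataclass
class MetricsReport:
    per_structure: dict[int, StructureMetrics]
    mean_dsc: float
    mean_hd_mm: float | None
    sd_hd_mm: float | None

    def to_frame(self, case: str = "case") -> pd.DataFrame:
        rows = [
            {
                "case": case,
                "structure": LABEL_NAMES[lab],
                "dsc": m.dsc,
                "hd_mm": m.hd_mm,
                "vol_pred_ml": m.volume_pred_ml,
                "vol_ref_ml": m.volume_ref_ml,
            }
            for lab, m in self.per_structure.items()
        ]
        return pd.DataFrame(rows)


@dataclass
class StatsResult:
    test_used: str  # "paired-t" or "wilcoxon"
    statistic: float
    p_value: float
    significant: bool
    manual_summary: dict = field(default_factory=dict)
    auto_summary: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# overlap and distance metrics
# ---------------------------------------------------------------------------

def _as_array(mask) -> np.ndarray:
    return mask.data if isinstance(mask, LabelMask) else np.asarray(mask)


def dsc(a, b, label: int) -> float:
    """Dice similarity coefficient of one label's voxel sets.

    Both-empty pairs score 1.0; one-empty pairs score 0.0.
    """
    av, bv = _as_array(a), _as_array(b)
    if av.shape != bv.shape:
        raise ValueError(f"mask shapes differ: {av.shape} vs {bv.shape}")
    sa, sb = av == label, bv == label
    na, nb = int(sa.sum()), int(sb.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int(np.logical_and(sa, sb).sum()) / (na + nb)


def _boundary(sel: np.ndarray) -> np.ndarray:
    """Erosion-difference boundary under face connectivity."""
    struct = ndimage.generate_binary_structure(sel.ndim, 1)
    return sel & ~ndimage.binary_erosion(sel, structure=struct, border_value=0)


def _directed_distances(from_pts: np.ndarray, to_set: np.ndarray, spacing):
    """Distances (mm) from each boundary voxel of one set to the other set."""
    dt = ndimage.distance_transform_edt(~to_set, sampling=spacing)
    return dt[from_pts]


def hausdorff_mm(a, b, label: int, spacing, percentile: float | None = None) -> float:
    """Symmetric Hausdorff distance (mm) between one label's boundaries.

    ``percentile`` switches to a percentile Hausdorff (e.g. 95 for HD95);
    the default is the classical maximum.  Raises if either mask lacks the
    label.
    """
    av, bv = _as_array(a), _as_array(b)
    if av.shape != bv.shape:
        raise ValueError(f"mask shapes differ: {av.shape} vs {bv.shape}")
    sa, sb = av == label, bv == label
    if not sa.any() or not sb.any():
        raise ValueError(
            f"Hausdorff distance undefined: label {label} empty in "
            f"{'first' if not sa.any() else 'second'} mask"
        )
    ba, bb = _boundary(sa), _boundary(sb)
    d_ab = _directed_distances(ba, bb, spacing)
    d_ba = _directed_distances(bb, ba, spacing)
    if percentile is None:
        return float(max(d_ab.max(), d_ba.max()))
    return float(max(np.percentile(d_ab, percentile),
                     np.percentile(d_ba, percentile)))


def volume_ml(mask, label: int, spacing) -> float:
    """Voxel count x voxel volume (mm^3) / 1000."""
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing components must be positive")
    arr = _as_array(mask)
    return float(np.count_nonzero(arr == label) * np.prod(spacing) / 1000.0)


def evaluate_case(pred, ref, spacing) -> MetricsReport:
    """All six per-structure metric triples plus cross-structure averages.

    HD is reported as None for structures empty in either mask (with DSC
    still defined by its conventions)."""
    per = {}
    for lab in STRUCTURES:
        d = dsc(pred, ref, lab)
        try:
            hd = hausdorff_mm(pred, ref, lab, spacing)
        except ValueError:
            hd = None
        per[lab] = StructureMetrics(
            dsc=d,
            hd_mm=hd,
            volume_pred_ml=volume_ml(pred, lab, spacing),
            volume_ref_ml=volume_ml(ref, lab, spacing),
        )
    hds = [m.hd_mm for m in per.values() if m.hd_mm is not None]
    return MetricsReport(
        per_structure=per,
        mean_dsc=float(np.mean([m.dsc for m in per.values()])),
        mean_hd_mm=float(np.mean(hds)) if hds else None,
        sd_hd_mm=float(np.std(hds, ddof=1)) if len(hds) > 1 else None,
    )


# ---------------------------------------------------------------------------
# paired statistics
# ---------------------------------------------------------------------------

def _summary(x: np.ndarray) -> dict:
    """Range, median and median-inclusive (type-2) quartiles."""
    q1, med, q3 = np.percentile(x, [25, 50, 75], method="averaged_inverted_cdf")
    return {
        "min": float(x.min()),
        "max": float(x.max()),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
    }


def paired_volume_stats(manual, auto, alpha: float = ALPHA) -> StatsResult:
    """Compare paired manual vs automatic volumes.

    Shapiro–Wilk on the paired differences selects the test: paired t when
    normality is not rejected, Wilcoxon signed-rank otherwise.  Differences
    that are constant and nonzero have no defined normality test and go to
    the Wilcoxon branch; all-zero differences are a degenerate case and
    raise.
    """
    m = np.asarray(manual, dtype=float)
    a = np.asarray(auto, dtype=float)
    if m.shape != a.shape or m.ndim != 1:
        raise ValueError("manual and auto must be equal-length 1-D sequences")
    if m.size < 6:
        raise ValueError(f"need at least 6 pairs, got {m.size}")
    diff = a - m
    if np.all(diff == 0.0):
        raise ValueError(
            "degenerate comparison: automatic and manual volumes are identical"
        )
    if np.ptp(diff) == 0.0:
        normal = False  # constant nonzero shift: normality undefined
    else:
        normal = stats.shapiro(diff).pvalue >= alpha
    if normal:
        res = stats.ttest_rel(a, m)
        test_used = "paired-t"
    else:
        res = stats.wilcoxon(a, m)
        test_used = "wilcoxon"
    return StatsResult(
        test_used=test_used,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        significant=bool(res.pvalue < alpha),
        manual_summary=_summary(m),
        auto_summary=_summary(a),
    )
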