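"""Per-muscle segmentation accuracy metrics and model comparisons.

Three complementary metrics per muscle, comparing an automatic mask A to a
reference mask R on the same voxel grid:

* relative volume error, ``RVE = 100 (V_A - V_R) / V_R`` in percent, with
  volumes as voxel count times voxel volume;
* Dice similarity coefficient, ``DSC = 2 |A ∩ R| / (|A| + |R|)``;
* Hausdorff distance, ``HD = max{ max_a min_r d(a, r), max_r min_a d(r, a) }``
  in mm, between the surface voxels of the two masks (foreground voxels
  with at least one six-connected background neighbour), using
  voxel-centre coordinates scaled by the spacing.

Subject-level reports cover only the schema's analysis-included classes.
Group comparisons follow the usual non-parametric route: a
Kolmogorov-Smirnov normality check, then a Kruskal-Wallis omnibus test for
independent groups or a Wilcoxon signed-rank test for paired designs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .schema import MuscleSchema
from .volumes import LabelVolume, labelmap_to_mask


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given masks (e.g. an empty reference)."""

    def __init__(self, message: str, code: str):
        super().__init__(message)
        self.code = code


@dataclass(frozen=True)
class MuscleMetrics:
    """Per-muscle metric row; ``hd`` is None when undefined (empty mask)."""

    class_id: int
    rve: float
    dsc: float
    hd: float | None
    auto_volume: float
    ref_volume: float


@dataclass(frozen=True)
class EvaluationReport:
    subject_id: str
    metrics: tuple[MuscleMetrics, ...]
    summary: dict

    def metric_values(self, name: str) -> np.ndarray:
        vals = [getattr(m, name) for m in self.metrics]
        return np.array([v for v in vals if v is not None], dtype=float)


def _as_bool(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask).astype(bool)


def _check_shapes(auto_mask: np.ndarray, ref_mask: np.ndarray) -> None:
    if auto_mask.shape != ref_mask.shape:
        raise ValueError(f"mask shapes differ: {auto_mask.shape} vs {ref_mask.shape}")


def relative_volume_error(
    auto_mask: np.ndarray, ref_mask: np.ndarray, spacing: Sequence[float] = (1.0, 1.0, 1.0)
) -> float:
    """Signed percent volume difference of the automatic vs reference mask."""
    a, r = _as_bool(auto_mask), _as_bool(ref_mask)
    _check_shapes(a, r)
    voxel = float(np.prod(spacing))
    v_r = r.sum() * voxel
    if v_r == 0:
        raise UndefinedMetricError("reference mask is empty; RVE undefined", "empty-reference")
    v_a = a.sum() * voxel
    return float(100.0 * (v_a - v_r) / v_r)


def dice_coefficient(auto_mask: np.ndarray, ref_mask: np.ndarray) -> float:
    """Dice similarity coefficient, 2|A∩R| / (|A|+|R|)."""
    a, r = _as_bool(auto_mask), _as_bool(ref_mask)
    _check_shapes(a, r)
    total = int(a.sum()) + int(r.sum())
    if total == 0:
        raise UndefinedMetricError("both masks empty; DSC undefined", "both-empty")
    return float(2.0 * np.logical_and(a, r).sum() / total)


_SIX_CONNECTED = ndimage.generate_binary_structure(3, 1)


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Coordinates (N, 3) of foreground voxels on the 6-connected surface.

    A surface voxel has at least one six-connected neighbour that is
    background or lies outside the grid; the grid border therefore counts
    as surface.
    """
    m = _as_bool(mask)
    if not m.any():
        return np.empty((0, 3), dtype=np.intp)
    eroded = ndimage.binary_erosion(m, structure=_SIX_CONNECTED, border_value=0)
    return np.argwhere(m & ~eroded)


def hausdorff_distance(
    auto_mask: np.ndarray, ref_mask: np.ndarray, spacing: Sequence[float] = (1.0, 1.0, 1.0)
) -> float:
    """Symmetric Hausdorff distance between mask surfaces, in mm."""
    a, r = _as_bool(auto_mask), _as_bool(ref_mask)
    _check_shapes(a, r)
    if not a.any():
        raise UndefinedMetricError("automatic mask empty; HD undefined", "empty-auto")
    if not r.any():
        raise UndefinedMetricError("reference mask empty; HD undefined", "empty-reference")
    sp = np.asarray(spacing, dtype=float)
    pa = surface_voxels(a) * sp
    pr = surface_voxels(r) * sp
    d_ar, _ = cKDTree(pr).query(pa)
    d_ra, _ = cKDTree(pa).query(pr)
    return float(max(d_ar.max(), d_ra.max()))


def evaluate_subject(
    pred: LabelVolume, ref: LabelVolume, schema: MuscleSchema, subject_id: str = ""
) -> EvaluationReport:
    """Per-muscle metrics over the schema's analysis-included classes.

    Muscles the prediction misses entirely are reported with RVE = -100,
    DSC = 0 and an undefined (None) HD; undefined HDs are excluded from
    the HD summary and counted.
    """
    if not pred.same_geometry(ref):
        raise ValueError("prediction and reference volumes must share geometry")
    spacing = ref.spacing
    rows = []
    for class_id in schema.included_ids:
        a = labelmap_to_mask(pred, class_id)
        r = labelmap_to_mask(ref, class_id)
        voxel = float(np.prod(spacing))
        v_a, v_r = a.sum() * voxel, r.sum() * voxel
        if not r.any():
            rows.append(MuscleMetrics(class_id, np.nan, np.nan, None, v_a, v_r))
            continue
        if not a.any():
            rows.append(MuscleMetrics(class_id, -100.0, 0.0, None, 0.0, v_r))
            continue
        rows.append(
            MuscleMetrics(
                class_id,
                relative_volume_error(a, r, spacing),
                dice_coefficient(a, r),
                hausdorff_distance(a, r, spacing),
                v_a,
                v_r,
            )
        )
    rve = np.array([m.rve for m in rows if np.isfinite(m.rve)])
    dsc = np.array([m.dsc for m in rows if np.isfinite(m.dsc)])
    hd = np.array([m.hd for m in rows if m.hd is not None])
    summary = {
        "rve_mean": float(rve.mean()) if rve.size else np.nan,
        "rve_sd": float(rve.std(ddof=1)) if rve.size > 1 else np.nan,
        "dsc_mean": float(dsc.mean()) if dsc.size else np.nan,
        "dsc_sd": float(dsc.std(ddof=1)) if dsc.size > 1 else np.nan,
        "hd_mean_mm": float(hd.mean()) if hd.size else np.nan,
        "hd_sd_mm": float(hd.std(ddof=1)) if hd.size > 1 else np.nan,
        "hd_undefined_count": int(sum(1 for m in rows if m.hd is None)),
        "n_classes": len(rows),
    }
    return EvaluationReport(subject_id=subject_id, metrics=tuple(rows), summary=summary)


# ---------------------------------------------------------------------------
# Statistical comparison across models


def _ks_normality(x: np.ndarray) -> float:
    """KS test of the standardised sample against the standard normal."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.0  # a constant sample is as non-normal as it gets
    z = (x - x.mean()) / sd
    return float(stats.kstest(z, "norm").pvalue)


def compare_models(
    metric_tables: Mapping[str, Sequence[float]],
    design: str = "independent",
    alpha: float = 0.05,
) -> dict:
    """Compare one metric across >= 2 models.

    ``metric_tables`` maps model name to that model's per-muscle metric
    values.  Normality is screened per group with a Kolmogorov-Smirnov
    test; the group comparison is a Kruskal-Wallis omnibus rank test for
    independent groups, or a Wilcoxon signed-rank test for a paired design
    (which requires exactly two equal-length, muscle-aligned groups).
    """
    if design not in ("independent", "paired"):
        raise ValueError("design must be 'independent' or 'paired'")
    groups = {k: np.asarray(v, dtype=float) for k, v in metric_tables.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    for name, g in groups.items():
        if g.size < 3:
            raise ValueError(f"group {name!r} has fewer than 3 values; test refused")
    normality = {name: _ks_normality(g) for name, g in groups.items()}
    if design == "paired":
        if len(groups) != 2:
            raise ValueError("paired design compares exactly two groups")
        g1, g2 = groups.values()
        if g1.size != g2.size:
            raise ValueError("paired groups must be equal length and aligned")
        diffs = g1 - g2
        if np.all(diffs == 0):
            statistic, pvalue = 0.0, 1.0
        else:
            res = stats.wilcoxon(g1, g2)
            statistic, pvalue = float(res.statistic), float(res.pvalue)
        test_name = "wilcoxon-signed-rank"
    else:
        res = stats.kruskal(*groups.values())
        statistic, pvalue = float(res.statistic), float(res.pvalue)
        test_name = "kruskal-wallis"
    return {
        "design": design,
        "test": test_name,
        "normality_p": normality,
        "statistic": statistic,
        "pvalue": pvalue,
        "significant": bool(pvalue < alpha),
        "alpha": alpha,
        "group_means": {name: float(g.mean()) for name, g in groups.items()},
    }
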