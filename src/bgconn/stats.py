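"""Segmentation agreement, ROI volumetry and hemispheric asymmetry tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .phantom import LabelVolume, StructureKey

__all__ = ["AgreementResult", "AsymmetryResult", "agreement_index",
           "roi_volumes", "agreement_table", "asymmetry_tests"]


@dataclass
class AgreementResult:
    key: StructureKey
    v1_mm3: float
    v2_mm3: float
    ai: float


@dataclass
class AsymmetryResult:
    """Left/right comparison of one quantity across datasets."""

    left: np.ndarray
    right: np.ndarray
    t_statistic: float
    t_p: float
    ks_statistic: float
    ks_p: float
    alpha: float
    degenerate: bool = False

    @property
    def t_significant(self) -> bool:
        return bool(self.t_p < self.alpha)

    @property
    def ks_significant(self) -> bool:
        return bool(self.ks_p < self.alpha)


def agreement_index(v1: float, v2: float) -> float:
    """AI = 1 - |V1 - V2| / (0.5 (V1 + V2)); 1 for identical volumes.

    Defined for nonnegative volumes with V1 + V2 > 0; ranges down to -1 when
    one volume vanishes.
    """
    if v1 < 0 or v2 < 0:
        raise ValueError("volumes must be nonnegative")
    if v1 + v2 == 0:
        raise ValueError("agreement index undefined for V1 = V2 = 0")
    return 1.0 - abs(v1 - v2) / (0.5 * (v1 + v2))


def roi_volumes(labels: LabelVolume,
                voxel_size: tuple[float, float, float] | None = None
                ) -> dict[StructureKey, float]:
    """Volume in mm^3 of every structure: voxel count x voxel volume."""
    vs = voxel_size or labels.voxel_size
    vox_mm3 = float(np.prod(vs))
    counts = np.bincount(labels.labels.ravel(),
                         minlength=max(labels.label_table, default=0) + 1)
    return {key: float(counts[lab]) * vox_mm3
            for lab, key in labels.label_table.items()}


def agreement_table(day1: LabelVolume, day2: LabelVolume) -> list[AgreementResult]:
    """Per-structure agreement indices between two repeated segmentations."""
    v1 = roi_volumes(day1)
    v2 = roi_volumes(day2)
    out = []
    for key in v1:
        if key not in v2:
            continue
        out.append(AgreementResult(key, v1[key], v2[key],
                                   agreement_index(v1[key], v2[key])))
    return out


def asymmetry_tests(left, right, alpha: float = 0.05) -> AsymmetryResult:
    """Paired two-sided t-test and two-sample KS test on per-dataset values.

    The t-test pairs left/right observations of the same dataset; the KS
    test compares the two samples as distributions (exact p-values for
    n <= 10). If every paired difference is exactly zero the t statistic is
    undefined and reported as p = 1 with the degenerate flag set.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape or left.ndim != 1:
        raise ValueError("left and right must be 1-D arrays of equal length")
    if left.size < 3:
        raise ValueError("need at least 3 paired observations")

    diffs = left - right
    if np.all(diffs == 0.0):
        ks = sps.ks_2samp(left, right, method="exact")
        return AsymmetryResult(left, right, 0.0, 1.0,
                               float(ks.statistic), float(ks.pvalue),
                               alpha, degenerate=True)
    t = sps.ttest_rel(left, right)
    method = "exact" if left.size <= 10 else "auto"
    ks = sps.ks_2samp(left, right, method=method)
    return AsymmetryResult(left, right, float(t.statistic), float(t.pvalue),
                           float(ks.statistic), float(ks.pvalue), alpha)
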