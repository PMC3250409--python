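"""Seed-based resting-state functional connectivity.

Preprocessing follows the classic single-subject recipe: frame drop,
per-slice mean-intensity adjustment, GLM high-pass drift removal with a
low-order Fourier basis, then spatial (4 mm FWHM) and temporal (2-frame)
Gaussian smoothing. Connectivity maps come from voxelwise OLS regression of
each time course on the seed ROI's mean course plus confounds, thresholded
by Benjamini-Hochberg FDR at q < 0.01 with a minimum cluster extent of
10 voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats as sps
from statsmodels.stats.multitest import multipletests

from .phantom import BoldSeries

__all__ = ["FCParams", "ActivationMap", "OverlapResult", "preprocess_bold",
           "seed_fc_map", "fdr_threshold", "threshold_activation",
           "overlap_structure_function", "drift_basis"]

_CONNECTIVITY_STRUCTS = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class FCParams:
    spatial_fwhm_mm: float = 4.0
    temporal_kernel_pts: float = 2.0
    highpass_pairs: int = 2
    q: float = 0.01
    min_cluster: int = 10
    cluster_connectivity: int = 26
    #: interpretation of the temporal kernel width: "fwhm" (the convention of
    #: the classic single-subject GLM packages, default) or "sd"
    temporal_kernel_mode: str = "fwhm"
    #: correct t statistics for temporal-smoothing-induced autocorrelation
    #: (Satterthwaite effective df + contrast variance under the known kernel)
    autocorr_correction: bool = True

    def __post_init__(self):
        if not (0.0 < self.q < 1.0):
            raise ValueError("q must be in (0, 1)")
        if self.min_cluster < 1:
            raise ValueError("min_cluster must be >= 1")
        if self.cluster_connectivity not in _CONNECTIVITY_STRUCTS:
            raise ValueError("cluster_connectivity must be 6, 18 or 26")
        if self.temporal_kernel_mode not in ("sd", "fwhm"):
            raise ValueError("temporal_kernel_mode must be 'sd' or 'fwhm'")


@dataclass
class ActivationMap:
    """Voxelwise seed-regression statistics and the thresholded mask."""

    beta: np.ndarray       # (X, Y, Z) seed regression coefficient
    t: np.ndarray          # (X, Y, Z)
    p: np.ndarray          # (X, Y, Z) two-sided p-values (1 outside mask)
    mask: np.ndarray       # bool; voxels analysed
    seed_name: str = ""
    q_values: np.ndarray | None = None
    thresholded: np.ndarray | None = None  # bool, after FDR + cluster filter
    df: float = 0.0


@dataclass
class OverlapResult:
    dice: float
    n_intersection: int
    n_a: int
    n_b: int


def drift_basis(n_frames: int, n_pairs: int) -> np.ndarray:
    """Intercept, linear trend, and ``n_pairs`` sine/cosine pairs."""
    t = np.arange(n_frames, dtype=float)
    cols = [np.ones(n_frames), t - t.mean()]
    for k in range(1, n_pairs + 1):
        cols.append(np.sin(2.0 * np.pi * k * t / n_frames))
        cols.append(np.cos(2.0 * np.pi * k * t / n_frames))
    return np.column_stack(cols)


def preprocess_bold(series: BoldSeries, params: FCParams,
                    voxel_size_mm: tuple[float, float, float] = (1.5, 1.5, 1.5)
                    ) -> BoldSeries:
    """Frame drop, slice-mean adjustment, drift GLM, and smoothing.

    The first frame is discarded (150 -> 149 frames on the default
    acquisition). Each slice's mean intensity per frame is rescaled to its
    value in the reference (first retained) frame; the Fourier drift basis is
    regressed out per voxel with the temporal mean re-added; 3-D and 1-D
    Gaussian smoothing follow at the stated widths.
    """
    if series.n_frames < 10:
        raise ValueError("need at least 10 frames to preprocess")
    data = series.data[..., 1:].astype(float).copy()
    if np.allclose(data, 0.0):
        raise ValueError("constant-zero series cannot be preprocessed")
    T = data.shape[3]

    # per-slice (z) mean intensity adjustment against the reference frame
    ref = data[..., 0]
    ref_means = ref.mean(axis=(0, 1))                        # (Z,)
    means = data.mean(axis=(0, 1))                           # (Z, T)
    with np.errstate(invalid="ignore", divide="ignore"):
        gain = np.where(np.abs(means) > 1e-12, ref_means[:, None] / means, 1.0)
    data *= gain[None, None, :, :]

    # GLM high-pass: project onto drift basis, keep residual + mean
    X = drift_basis(T, params.highpass_pairs)
    flat = data.reshape(-1, T)
    beta = np.linalg.lstsq(X, flat.T, rcond=None)[0]
    fitted = (X @ beta).T
    mean = flat.mean(axis=1, keepdims=True)
    flat = flat - fitted + mean
    data = flat.reshape(data.shape)

    if params.spatial_fwhm_mm > 0:
        sigmas = [params.spatial_fwhm_mm / 2.354820045 / v for v in voxel_size_mm]
        for fr in range(T):
            data[..., fr] = ndimage.gaussian_filter(data[..., fr], sigmas)
    if params.temporal_kernel_pts > 0:
        sd = params.temporal_kernel_pts
        if params.temporal_kernel_mode == "fwhm":
            sd = sd / 2.354820045
        data = ndimage.gaussian_filter1d(data, sd, axis=3, truncate=4.0)
    return BoldSeries(data, series.tr)


def seed_fc_map(series: BoldSeries, roi_mask: np.ndarray,
                confounds: np.ndarray | None = None,
                params: FCParams | None = None,
                brain_mask: np.ndarray | None = None,
                seed_name: str = "",
                include_global_mean: bool = True) -> ActivationMap:
    """Voxelwise OLS of each time course on the seed ROI mean course.

    The design is [intercept, seed mean, global mean (optional), confounds];
    the returned t statistic and two-sided p-value refer to the seed
    regressor. The series is assumed to have been preprocessed with the same
    ``params``: when a temporal smoothing kernel is configured (and
    ``autocorr_correction`` is on), the contrast variance and degrees of
    freedom are corrected for the autocorrelation that kernel induces —
    noise smoothed in time otherwise yields wildly anti-conservative
    voxelwise p-values.
    """
    params = params or FCParams()
    if not np.any(roi_mask):
        raise ValueError("seed ROI mask is empty")
    data = series.data
    T = data.shape[3]
    if brain_mask is None:
        brain_mask = np.ones(data.shape[:3], dtype=bool)

    seed_ts = data[roi_mask].mean(axis=0)
    cols = [np.ones(T), seed_ts]
    names = ["intercept", "seed"]
    if include_global_mean:
        cols.append(data[brain_mask].mean(axis=0))
        names.append("global_mean")
    if confounds is not None:
        confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
        if confounds.shape[0] == T and confounds.shape[1] != T:
            confounds = confounds.T
        for ci, c in enumerate(confounds):
            cols.append(c)
            names.append(f"confound_{ci}")
    X = np.column_stack(cols)
    # center (and unit-scale) regressors against the intercept; leaves the
    # seed t statistic unchanged but keeps the design well conditioned
    for c in range(1, X.shape[1]):
        X[:, c] = X[:, c] - X[:, c].mean()
        sd = X[:, c].std()
        if sd > 0:
            X[:, c] /= sd
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify (approximately) collinear columns via QR pivots
        _, R = np.linalg.qr(X)
        bad = [names[i] for i in range(X.shape[1])
               if abs(R[i, i]) < 1e-10 * abs(R[0, 0])]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    Y = data[brain_mask].T                       # (T, nvox)
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y                              # (ncol, nvox)
    resid = Y - X @ beta

    sd = params.temporal_kernel_pts
    if params.temporal_kernel_mode == "fwhm":
        sd = sd / 2.354820045
    if params.autocorr_correction and sd > 0:
        # noise covariance after Gaussian temporal smoothing: V = K K^T
        K = ndimage.gaussian_filter1d(np.eye(T), sd, axis=0, truncate=4.0)
        V = K @ K.T
        R = np.eye(T) - X @ pinv
        RV = R @ V
        tr_rv = np.trace(RV)
        df = tr_rv ** 2 / np.trace(RV @ RV)      # Satterthwaite effective df
        var_scale = (pinv @ V @ pinv.T)[1, 1]
        sigma2 = (resid ** 2).sum(axis=0) / tr_rv
    else:
        df = T - X.shape[1]
        var_scale = np.linalg.inv(X.T @ X)[1, 1]
        sigma2 = (resid ** 2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * var_scale, 1e-300))
    tvals = beta[1] / se
    pvals = 2.0 * sps.t.sf(np.abs(tvals), df)

    shape = data.shape[:3]
    out = ActivationMap(beta=np.zeros(shape), t=np.zeros(shape),
                        p=np.ones(shape), mask=brain_mask,
                        seed_name=seed_name, df=df)
    out.beta[brain_mask] = beta[1]
    out.t[brain_mask] = tvals
    out.p[brain_mask] = pvals
    return out


def fdr_threshold(pmap: np.ndarray, q: float = 0.01, min_cluster: int = 10,
                  connectivity: int = 26,
                  mask: np.ndarray | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up over in-mask voxels plus cluster filtering.

    Returns ``(thresholded_mask, q_values)``; clusters of fewer than
    ``min_cluster`` voxels (under the chosen 3-D connectivity) are removed.
    """
    pmap = np.asarray(pmap, dtype=float)
    if mask is None:
        mask = np.ones(pmap.shape, dtype=bool)
    if not np.any(mask):
        raise ValueError("empty brain mask")
    pv = pmap[mask]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, qv, _, _ = multipletests(pv, alpha=q, method="fdr_bh")

    rej = np.zeros(pmap.shape, dtype=bool)
    rej[mask] = reject
    qmap = np.ones(pmap.shape)
    qmap[mask] = qv

    structure = ndimage.generate_binary_structure(
        3, _CONNECTIVITY_STRUCTS[connectivity])
    lab, n = ndimage.label(rej, structure=structure)
    if n:
        sizes = np.bincount(lab.ravel())
        small = np.flatnonzero(sizes < min_cluster)
        rej[np.isin(lab, small[small > 0])] = False
    return rej, qmap


def threshold_activation(amap: ActivationMap, params: FCParams) -> ActivationMap:
    """Apply the FDR + cluster rule of ``params`` to an unthresholded map."""
    mask, qmap = fdr_threshold(amap.p, params.q, params.min_cluster,
                               params.cluster_connectivity, amap.mask)
    amap.q_values = qmap
    amap.thresholded = mask
    return amap


def overlap_structure_function(pathway_mask: np.ndarray,
                               activation_mask: np.ndarray,
                               within_roi: np.ndarray | None = None
                               ) -> OverlapResult:
    """Dice overlap between a structural pathway and a functional activation,
    optionally restricted to a region of interest. Both-empty is undefined
    (NaN Dice)."""
    a = np.asarray(pathway_mask, dtype=bool)
    b = np.asarray(activation_mask, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    if within_roi is not None:
        a = a & within_roi
        b = b & within_roi
    na, nb = int(a.sum()), int(b.sum())
    ni = int((a & b).sum())
    dice = 2.0 * ni / (na + nb) if (na + nb) else float("nan")
    return OverlapResult(dice, ni, na, nb)
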