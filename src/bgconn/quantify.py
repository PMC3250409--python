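"""From connectivity distributions to connectome deliverables.

Implements the two threshold rules of the analysis — pathway extraction at
10% of the distribution maximum (strict), sub-territory definition at 50%
of the per-target maximum (non-strict) — the probability-of-connection
statistic (mean proportion over the sub-territory), sub-territory volume
proportions, and the per-hemisphere structure-by-structure connection
matrix with cross-dataset aggregation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import STRUCTURES
from .tracking import ConnectivityDistribution, VoxelTargetProfile

__all__ = ["PathwayMask", "Parcellation", "ConnectionMatrix",
           "extract_pathway", "parcellate_roi", "connection_probability",
           "subterritory_volumes", "matrix_from_profiles", "aggregate_matrices"]


@dataclass
class PathwayMask:
    mask: np.ndarray  # bool (X, Y, Z)
    seed_structure: str
    target_structure: str
    hemisphere: str
    threshold_frac: float

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class Parcellation:
    """Connectivity-based subdivision of one ROI.

    ``sub_territories[t]`` flags, over the ROI voxel list, membership in the
    sub-territory connected to target ``t``; voxels may belong to several.
    ``dominant`` holds the winning target index (into ``targets``) where at
    least one sub-territory covers the voxel and -1 elsewhere.
    """

    structure: str
    hemisphere: str
    voxels: np.ndarray                 # (ns, 3)
    targets: tuple[str, ...]
    sub_territories: dict[str, np.ndarray]  # target -> bool (ns,)
    dominant: np.ndarray               # (ns,) int; -1 = unassigned
    threshold_frac: float

    @property
    def unassigned(self) -> np.ndarray:
        return self.dominant < 0

    def dominant_label_volume(self, grid_shape) -> np.ndarray:
        """Dense map: 1 + index into STRUCTURES of the dominant target."""
        out = np.zeros(grid_shape, dtype=np.int16)
        for vi, (i, j, k) in enumerate(self.voxels):
            d = self.dominant[vi]
            if d >= 0:
                out[i, j, k] = 1 + STRUCTURES.index(self.targets[d])
        return out

    def sub_territory_volume(self, grid_shape, target: str) -> np.ndarray:
        out = np.zeros(grid_shape, dtype=bool)
        sel = self.sub_territories[target]
        for (i, j, k) in self.voxels[sel]:
            out[i, j, k] = True
        return out


@dataclass
class ConnectionMatrix:
    """Structure x structure probability-of-connection values, one hemisphere.

    Row = seed structure, column = target; the diagonal is undefined (NaN),
    as are pairs whose sub-territory is empty.
    """

    values: np.ndarray  # (7, 7) float, NaN where undefined
    hemisphere: str
    structures: tuple[str, ...] = STRUCTURES

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.structures),
                            columns=list(self.structures))

    def pair_value(self, a: str, b: str) -> float:
        """Undirected pair summary: mean of the finite (a->b, b->a) entries."""
        ia, ib = self.structures.index(a), self.structures.index(b)
        vals = np.array([self.values[ia, ib], self.values[ib, ia]])
        finite = vals[np.isfinite(vals)]
        return float(finite.mean()) if finite.size else float("nan")


def extract_pathway(dist: ConnectivityDistribution,
                    threshold_frac: float = 0.10) -> PathwayMask:
    """Retain voxels whose streamline proportion exceeds ``threshold_frac``
    of the distribution maximum (strict inequality).

    The rule is applied to raw counts; with the shared per-target
    normalization denominator this is identical to applying it to the
    normalized proportions.
    """
    raw = dist.raw
    mx = raw.max()
    if mx == 0:
        warnings.warn(f"no pathway found for {dist.seed_structure}-"
                      f"{dist.target_structure} ({dist.hemisphere}): "
                      "all-zero distribution")
        mask = np.zeros_like(raw, dtype=bool)
    else:
        mask = raw > threshold_frac * mx
    return PathwayMask(mask, dist.seed_structure, dist.target_structure,
                       dist.hemisphere, threshold_frac)


def parcellate_roi(profile: VoxelTargetProfile,
                   threshold_frac: float = 0.50,
                   denominator: str = "retained") -> Parcellation:
    """Subdivide an ROI by its voxelwise connectivity profile.

    For each target the sub-territory collects voxels whose proportion of
    streamlines to that target is at least ``threshold_frac`` times the
    maximum proportion over the ROI (non-strict). The dominant map assigns
    each covered voxel the target with the largest proportion; ties break by
    the fixed structure order.
    """
    props = profile.proportions(denominator)
    ns, nt = props.shape
    subs: dict[str, np.ndarray] = {}
    if props.max() == 0:
        warnings.warn(f"ROI {profile.seed_structure} ({profile.hemisphere}) "
                      "has zero streamlines everywhere; all voxels unassigned")
    for t_i, t in enumerate(profile.targets):
        col = props[:, t_i]
        mx = col.max()
        if mx == 0:
            subs[t] = np.zeros(ns, dtype=bool)
        else:
            subs[t] = col >= threshold_frac * mx
    covered = np.zeros(ns, dtype=bool)
    for t in profile.targets:
        covered |= subs[t]
    # dominant target: largest proportion, ties by fixed structure order
    order = np.array([STRUCTURES.index(t) for t in profile.targets])
    rank = np.argsort(order)  # column indices in canonical order
    dominant = np.full(ns, -1, dtype=np.int64)
    best = np.full(ns, -1.0)
    for c in rank[::-1]:
        col = props[:, c]
        upd = covered & (col >= best)
        dominant[upd] = c
        best[upd] = col[upd]
    # a dominant target must also cover the voxel with its sub-territory or
    # any sub-territory; keep the argmax over all targets where covered
    return Parcellation(profile.seed_structure, profile.hemisphere,
                        profile.voxels, profile.targets, subs, dominant,
                        threshold_frac)


def connection_probability(profile: VoxelTargetProfile,
                           parcellation: Parcellation,
                           denominator: str = "retained") -> dict[str, float]:
    """Probability of connection of this ROI with each target.

    The entry for target T is the mean, over the voxels of the sub-territory
    connected to T, of the per-voxel proportion of streamlines reaching T;
    NaN when the sub-territory is empty.
    """
    if parcellation.structure != profile.seed_structure or \
            parcellation.hemisphere != profile.hemisphere:
        raise ValueError("parcellation does not belong to this profile")
    props = profile.proportions(denominator)
    out: dict[str, float] = {}
    for t_i, t in enumerate(profile.targets):
        sel = parcellation.sub_territories[t]
        out[t] = float(props[sel, t_i].mean()) if sel.any() else float("nan")
    return out


def subterritory_volumes(parcellation: Parcellation) -> dict[str, float]:
    """Volume of each sub-territory as a proportion of the whole ROI."""
    n_roi = parcellation.voxels.shape[0]
    if n_roi == 0:
        raise ValueError("parcellation covers an empty ROI")
    return {t: float(sel.sum()) / n_roi
            for t, sel in parcellation.sub_territories.items()}


def matrix_from_profiles(profiles: dict[str, VoxelTargetProfile],
                         hemisphere: str, threshold_frac: float = 0.50,
                         denominator: str = "retained") -> ConnectionMatrix:
    """Assemble the 7x7 probability-of-connection matrix of one hemisphere."""
    values = np.full((len(STRUCTURES), len(STRUCTURES)), np.nan)
    for s, prof in profiles.items():
        parc = parcellate_roi(prof, threshold_frac, denominator)
        row = connection_probability(prof, parc, denominator)
        i = STRUCTURES.index(s)
        for t, v in row.items():
            values[i, STRUCTURES.index(t)] = v
    return ConnectionMatrix(values, hemisphere)


def aggregate_matrices(matrices: list[ConnectionMatrix]) -> tuple[np.ndarray, np.ndarray]:
    """Mean and standard deviation across datasets, ignoring missing cells."""
    if not matrices:
        raise ValueError("no matrices to aggregate")
    stack = np.stack([m.values for m in matrices])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1) if len(matrices) > 1 \
            else np.zeros_like(mean)
    return mean, sd
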