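"""Probabilistic streamline tractography over a fiber field.

A streamline sample is launched from a seed voxel in both initial signs of a
drawn orientation; the two halves are concatenated and counted as one
sample. At each step one fiber population of the current voxel is chosen
with probability proportional to its volume fraction, an orientation is
drawn (Watson-style dispersion for ground-truth fields, bootstrap clouds for
estimated fields), the sign is aligned with the running direction, and the
position advances by a fixed step. Propagation terminates on brain-mask
exit, step-count exhaustion, excessive turning, fiber-free voxels, or entry
into a target structure. Visit counts of retained samples accumulate into
per-pair connectivity distributions; per-seed-voxel target tallies form the
connectivity profile used for parcellation.

Orientation lookup is nearest-voxel; world coordinates put voxel centers at
``index * voxel_size`` with half-open voxel boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .phantom import FiberField, KAPPA_INF, LabelVolume, STRUCTURES
from .fibers import OrientationSamples

__all__ = ["TrackingParams", "ConnectivityDistribution", "VoxelTargetProfile",
           "TrackResult", "propagate_streamline", "track_pairwise",
           "track_all_pairs", "TERMINATION_REASONS"]

# termination codes of the propagation kernel
_REASON_NO_FIBER = 0
_REASON_MASK_EXIT = 1
_REASON_MAX_STEPS = 2
_REASON_CURVATURE = 3
_REASON_TARGET = 4

TERMINATION_REASONS = {
    _REASON_NO_FIBER: "no_fiber",
    _REASON_MASK_EXIT: "mask_exit",
    _REASON_MAX_STEPS: "max_steps",
    _REASON_CURVATURE: "curvature",
    _REASON_TARGET: "target",
}


@dataclass(frozen=True)
class TrackingParams:
    """Streamline propagation parameters (defaults near common practice:
    half-voxel steps, 80 degree curvature stop, 1000 samples per voxel)."""

    n_samples_per_voxel: int = 1000
    step_size: float = 0.75
    max_steps: int = 2000
    curvature_threshold: float = 80.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if not (0.0 < self.curvature_threshold <= 180.0):
            raise ValueError("curvature_threshold must be in (0, 180]")
        if self.n_samples_per_voxel < 1:
            raise ValueError("n_samples_per_voxel must be >= 1")


@dataclass
class ConnectivityDistribution:
    """Streamline visit counts connecting one seed ROI to one target ROI."""

    seed_structure: str
    target_structure: str
    hemisphere: str
    raw: np.ndarray          # (X, Y, Z) int64 visit counts
    launched: int
    retained: int

    @property
    def discarded(self) -> int:
        return self.launched - self.retained

    @property
    def normalized(self) -> np.ndarray:
        """Counts normalized by the total retained for this target, in [0,1]."""
        if self.retained == 0:
            return np.zeros_like(self.raw, dtype=float)
        return np.clip(self.raw / float(self.retained), 0.0, 1.0)


@dataclass
class VoxelTargetProfile:
    """Per seed-ROI-voxel proportions of streamlines reaching each target."""

    seed_structure: str
    hemisphere: str
    voxels: np.ndarray        # (ns, 3) voxel coordinates of the seed ROI
    targets: tuple[str, ...]  # column order
    counts: np.ndarray        # (ns, n_targets) retained-sample tallies
    n_launched_per_voxel: int

    def proportions(self, denominator: str = "retained") -> np.ndarray:
        """Per-voxel proportions to each target.

        ``denominator="retained"`` divides by the voxel's samples retained for
        any listed structure (the probability-of-connection convention);
        ``"launched"`` divides by all samples launched from the voxel.
        """
        c = self.counts.astype(float)
        if denominator == "retained":
            tot = c.sum(axis=1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                p = np.where(tot > 0, c / tot, 0.0)
            return p
        if denominator == "launched":
            return c / float(self.n_launched_per_voxel)
        raise ValueError("denominator must be 'retained' or 'launched'")


@dataclass
class TrackResult:
    distributions: dict[str, ConnectivityDistribution]
    profile: VoxelTargetProfile
    launched: int
    retained_total: int
    discarded: int


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sample_direction(orients, kappas, row, k):
    B = orients.shape[2]
    b = int(np.random.random() * B)
    if b >= B:
        b = B - 1
    vx = orients[row, k, b, 0]
    vy = orients[row, k, b, 1]
    vz = orients[row, k, b, 2]
    kap = kappas[row, k]
    if kap < 1e9:  # finite concentration: Watson-like tangent perturbation
        if kap < 1e-6:
            kap = 1e-6
        sd = 1.0 / np.sqrt(2.0 * kap)
        vx += sd * np.random.normal()
        vy += sd * np.random.normal()
        vz += sd * np.random.normal()
        n = np.sqrt(vx * vx + vy * vy + vz * vz)
        if n < 1e-12:
            vx = orients[row, k, b, 0]
            vy = orients[row, k, b, 1]
            vz = orients[row, k, b, 2]
        else:
            vx /= n
            vy /= n
            vz /= n
    return vx, vy, vz


@njit(cache=True)
def _choose_fiber(fracs, nfib, row):
    total = 0.0
    for k in range(nfib):
        total += fracs[row, k]
    r = np.random.random() * total
    acc = 0.0
    for k in range(nfib):
        acc += fracs[row, k]
        if r <= acc:
            return k
    return nfib - 1


@njit(cache=True)
def _propagate_half(px, py, pz, dx, dy, dz, step, cos_thresh, max_steps,
                    vsx, vsy, vsz, nx, ny, nz,
                    voxidx, nfibs, fracs, orients, kappas, stop_labels,
                    vox_buf, pos_buf):
    """Propagate one half-streamline; returns (n_voxels, n_steps, reason, hit).

    New voxels entered are written to ``vox_buf``; positions after each step
    to ``pos_buf``. The starting voxel is not recorded (the caller owns it).
    """
    cx = int(np.floor(px / vsx + 0.5))
    cy = int(np.floor(py / vsy + 0.5))
    cz = int(np.floor(pz / vsz + 0.5))
    nvox = 0
    steps = 0
    reason = _REASON_MAX_STEPS
    hit = 0
    while steps < max_steps:
        px += step * dx
        py += step * dy
        pz += step * dz
        steps += 1
        ix = int(np.floor(px / vsx + 0.5))
        iy = int(np.floor(py / vsy + 0.5))
        iz = int(np.floor(pz / vsz + 0.5))
        if ix < 0 or iy < 0 or iz < 0 or ix >= nx or iy >= ny or iz >= nz:
            reason = _REASON_MASK_EXIT
            break
        pos_buf[steps - 1, 0] = px
        pos_buf[steps - 1, 1] = py
        pos_buf[steps - 1, 2] = pz
        if ix != cx or iy != cy or iz != cz:
            cx, cy, cz = ix, iy, iz
            vox_buf[nvox, 0] = ix
            vox_buf[nvox, 1] = iy
            vox_buf[nvox, 2] = iz
            nvox += 1
            lbl = stop_labels[ix, iy, iz]
            if lbl > 0:
                reason = _REASON_TARGET
                hit = lbl
                break
        row = voxidx[ix, iy, iz]
        if row < 0 or nfibs[row] == 0:
            reason = _REASON_NO_FIBER
            break
        k = _choose_fiber(fracs, nfibs[row], row)
        vx, vy, vz = _sample_direction(orients, kappas, row, k)
        dot = vx * dx + vy * dy + vz * dz
        if dot < 0.0:
            vx, vy, vz = -vx, -vy, -vz
            dot = -dot
        if dot < cos_thresh:
            reason = _REASON_CURVATURE
            break
        dx, dy, dz = vx, vy, vz
    return nvox, steps, reason, hit


@njit(cache=True)
def _track_kernel(seed_vox, n_samples, step, cos_thresh, max_steps,
                  vsx, vsy, vsz, voxidx, nfibs, fracs, orients, kappas,
                  stop_labels, n_targets, rng_seed):
    np.random.seed(rng_seed)
    nx, ny, nz = voxidx.shape
    ns = seed_vox.shape[0]
    counts = np.zeros((n_targets, nx, ny, nz), dtype=np.int64)
    profile = np.zeros((ns, n_targets), dtype=np.int64)
    retained = np.zeros(n_targets, dtype=np.int64)
    launched = 0
    discarded = 0
    buf1 = np.empty((max_steps + 1, 3), dtype=np.int64)
    buf2 = np.empty((max_steps + 1, 3), dtype=np.int64)
    pbuf = np.empty((max_steps + 1, 3), dtype=np.float64)
    for s in range(ns):
        i = seed_vox[s, 0]
        j = seed_vox[s, 1]
        k = seed_vox[s, 2]
        row = voxidx[i, j, k]
        px0 = i * vsx
        py0 = j * vsy
        pz0 = k * vsz
        for rep in range(n_samples):
            launched += 1
            if row < 0 or nfibs[row] == 0:
                discarded += 1
                continue
            kf = _choose_fiber(fracs, nfibs[row], row)
            vx, vy, vz = _sample_direction(orients, kappas, row, kf)
            n1, st1, r1, hit1 = _propagate_half(
                px0, py0, pz0, vx, vy, vz, step, cos_thresh, max_steps,
                vsx, vsy, vsz, nx, ny, nz, voxidx, nfibs, fracs, orients,
                kappas, stop_labels, buf1, pbuf)
            n2, st2, r2, hit2 = _propagate_half(
                px0, py0, pz0, -vx, -vy, -vz, step, cos_thresh, max_steps,
                vsx, vsy, vsz, nx, ny, nz, voxidx, nfibs, fracs, orients,
                kappas, stop_labels, buf2, pbuf)
            hit = hit1 if hit1 > 0 else hit2
            if hit == 0:
                discarded += 1
                continue
            t = hit - 1
            retained[t] += 1
            profile[s, t] += 1
            counts[t, i, j, k] += 1
            for q in range(n1):
                counts[t, buf1[q, 0], buf1[q, 1], buf1[q, 2]] += 1
            for q in range(n2):
                counts[t, buf2[q, 0], buf2[q, 1], buf2[q, 2]] += 1
    return counts, profile, retained, launched, discarded


@njit(cache=True)
def _propagate_single(px, py, pz, has_dir, d0x, d0y, d0z, sign,
                      step, cos_thresh, max_steps, vsx, vsy, vsz,
                      voxidx, nfibs, fracs, orients, kappas, stop_labels,
                      rng_seed):
    np.random.seed(rng_seed)
    nx, ny, nz = voxidx.shape
    ix = int(np.floor(px / vsx + 0.5))
    iy = int(np.floor(py / vsy + 0.5))
    iz = int(np.floor(pz / vsz + 0.5))
    pos = np.empty((max_steps + 1, 3), dtype=np.float64)
    pos[0, 0] = px
    pos[0, 1] = py
    pos[0, 2] = pz
    row = voxidx[ix, iy, iz]
    if not has_dir:
        if row < 0 or nfibs[row] == 0:
            return pos[:1], _REASON_NO_FIBER, 0
        kf = _choose_fiber(fracs, nfibs[row], row)
        d0x, d0y, d0z = _sample_direction(orients, kappas, row, kf)
    d0x *= sign
    d0y *= sign
    d0z *= sign
    vox_buf = np.empty((max_steps + 1, 3), dtype=np.int64)
    pos_buf = np.empty((max_steps + 1, 3), dtype=np.float64)
    nvox, steps, reason, hit = _propagate_half(
        px, py, pz, d0x, d0y, d0z, step, cos_thresh, max_steps,
        vsx, vsy, vsz, nx, ny, nz, voxidx, nfibs, fracs, orients, kappas,
        stop_labels, vox_buf, pos_buf)
    nkeep = steps if reason != _REASON_MASK_EXIT else steps - 1
    pos[1:1 + nkeep] = pos_buf[:nkeep]
    return pos[:1 + nkeep], reason, hit


# ---------------------------------------------------------------------------
# substrate adaptation
# ---------------------------------------------------------------------------

def _as_substrate(obj):
    """Compact (voxidx, nfib, fracs, orients, kappas, voxel_size) arrays."""
    if isinstance(obj, FiberField):
        sel = obj.nfib > 0
        n = int(sel.sum())
        voxidx = np.full(obj.grid_shape, -1, dtype=np.int32)
        voxidx[sel] = np.arange(n, dtype=np.int32)
        nfib = obj.nfib[sel].astype(np.int8)
        fracs = np.ascontiguousarray(obj.fractions[sel])
        orients = np.ascontiguousarray(obj.orientations[sel][:, :, None, :])
        kappas = np.ascontiguousarray(obj.kappas[sel])
        kappas = np.where(kappas >= KAPPA_INF, 1e18, kappas)
        return voxidx, nfib, fracs, orients, kappas, obj.voxel_size
    if isinstance(obj, OrientationSamples):
        kappas = np.full(obj.fractions.shape, 1e18)
        return (obj.voxel_index, obj.nfib.astype(np.int8),
                np.ascontiguousarray(obj.fractions),
                np.ascontiguousarray(obj.samples.astype(np.float64)),
                kappas, obj.voxel_size)
    raise TypeError("expected a FiberField or OrientationSamples")


def _child_seed(base: int, salt: int) -> int:
    ss = np.random.SeedSequence([int(base), int(salt)])
    return int(ss.generate_state(1, np.uint32)[0] % (2 ** 31 - 1))


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def propagate_streamline(field_or_samples, start_point_mm,
                         params: TrackingParams, seed: int | None = None,
                         *, direction=None, sign: float = 1.0,
                         stop_labels: np.ndarray | None = None):
    """Propagate a single streamline from a world-coordinate start point.

    Returns ``(points, reason)`` where ``points`` is an (n, 3) polyline in mm
    (the start point included) and ``reason`` one of
    ``TERMINATION_REASONS.values()``. The initial orientation is drawn from
    the start voxel's fiber populations unless ``direction`` is given.
    """
    voxidx, nfib, fracs, orients, kappas, vs = _as_substrate(field_or_samples)
    p = np.asarray(start_point_mm, dtype=float)
    idx = np.floor(p / np.asarray(vs) + 0.5).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(voxidx.shape)):
        raise ValueError(f"start point {tuple(p)} outside the brain mask")
    if stop_labels is None:
        stop_labels = np.zeros(voxidx.shape, dtype=np.int16)
    has_dir = direction is not None
    if has_dir:
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
    else:
        d = np.zeros(3)
    rng_seed = params.rng_seed if seed is None else seed
    cos_thresh = float(np.cos(np.radians(params.curvature_threshold)))
    pts, reason, hit = _propagate_single(
        p[0], p[1], p[2], has_dir, d[0], d[1], d[2], float(sign),
        params.step_size, cos_thresh, params.max_steps,
        vs[0], vs[1], vs[2], voxidx, nfib, fracs, orients, kappas,
        np.ascontiguousarray(stop_labels, dtype=np.int16), int(rng_seed))
    return pts, TERMINATION_REASONS[reason]


def track_pairwise(field_or_samples, labels: LabelVolume, seed_structure: str,
                   hemisphere: str, params: TrackingParams,
                   target_structures: Sequence[str] | None = None,
                   rng_seed: int | None = None) -> TrackResult:
    """Launch samples from every voxel of a seed structure toward targets.

    Targets default to the six other structures of the same hemisphere.
    Each sample is retained for the first target it enters and discarded if
    it reaches none; retained samples increment the visit counts of every
    voxel they traverse.
    """
    key = (seed_structure, hemisphere)
    if key not in labels.key_to_label:
        raise ValueError(f"seed structure {key} absent from label volume")
    if target_structures is None:
        target_structures = [s for s in STRUCTURES if s != seed_structure
                             and (s, hemisphere) in labels.key_to_label]
    targets = tuple(target_structures)
    stop = np.zeros(labels.labels.shape, dtype=np.int16)
    for t_i, t in enumerate(targets, start=1):
        stop[labels.mask((t, hemisphere))] = t_i

    seed_vox = np.ascontiguousarray(np.argwhere(labels.mask(key)))
    if seed_vox.shape[0] == 0:
        raise ValueError(f"seed ROI {key} is empty")

    voxidx, nfib, fracs, orients, kappas, vs = _as_substrate(field_or_samples)
    cos_thresh = float(np.cos(np.radians(params.curvature_threshold)))
    kseed = params.rng_seed if rng_seed is None else rng_seed
    counts, profile, retained, launched, discarded = _track_kernel(
        seed_vox, params.n_samples_per_voxel, params.step_size, cos_thresh,
        params.max_steps, vs[0], vs[1], vs[2], voxidx, nfib, fracs, orients,
        kappas, stop, len(targets), int(kseed))

    dists = {}
    for t_i, t in enumerate(targets):
        dists[t] = ConnectivityDistribution(
            seed_structure, t, hemisphere, counts[t_i],
            launched=launched, retained=int(retained[t_i]))
    prof = VoxelTargetProfile(seed_structure, hemisphere, seed_vox, targets,
                              profile, params.n_samples_per_voxel)
    return TrackResult(dists, prof, launched, int(retained.sum()), discarded)


def track_all_pairs(field_or_samples, labels: LabelVolume, hemisphere: str,
                    params: TrackingParams
                    ) -> tuple[dict[frozenset, ConnectivityDistribution],
                               dict[str, VoxelTargetProfile]]:
    """Track from every structure of a hemisphere and fold the results into
    undirected pairwise connectivity distributions (A->B and B->A launches
    accumulated into one map) plus per-structure voxel profiles.
    """
    structures = [s for s in STRUCTURES if (s, hemisphere) in labels.key_to_label]
    results: dict[str, TrackResult] = {}
    for i, s in enumerate(structures):
        rng_seed = _child_seed(params.rng_seed,
                               1000 * (1 if hemisphere == "R" else 2) + i)
        results[s] = track_pairwise(field_or_samples, labels, s, hemisphere,
                                    params, rng_seed=rng_seed)
    pairs: dict[frozenset, ConnectivityDistribution] = {}
    for ia, a in enumerate(structures):
        for b in structures[ia + 1:]:
            da = results[a].distributions[b]
            db = results[b].distributions[a]
            pairs[frozenset((a, b))] = ConnectivityDistribution(
                a, b, hemisphere, da.raw + db.raw,
                launched=da.launched + db.launched,
                retained=da.retained + db.retained)
    profiles = {s: results[s].profile for s in structures}
    return pairs, profiles
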