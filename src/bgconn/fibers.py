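"""Per-voxel diffusion modelling: tensor/FA fit and crossing-fiber estimation.

The tensor stage is a weighted log-linear least-squares fit with the
standard FA formula. The multi-fiber stage estimates a ball-and-stick model
(up to three sticks) per voxel by nonlinear least squares, growing the model
greedily from the tensor eigenvectors, and quantifies orientation
uncertainty with a residual bootstrap. This plays the role an MCMC
crossing-fiber sampler plays in large-scale pipelines, with the same
contract: per-fiber orientation sample clouds plus point-estimate fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .phantom import DWIProtocol, MAX_FIBERS

__all__ = ["TensorFit", "OrientationSamples", "fit_tensor",
           "estimate_fiber_orientations", "fractional_anisotropy",
           "angular_error_deg"]

SIGNAL_FLOOR = 1e-6


@dataclass
class TensorFit:
    tensor: np.ndarray      # (X, Y, Z, 3, 3) mm^2/s
    evals: np.ndarray       # (X, Y, Z, 3) sorted descending
    evecs: np.ndarray       # (X, Y, Z, 3, 3); evecs[..., :, k] pairs evals[..., k]
    fa: np.ndarray          # (X, Y, Z) in [0, 1]
    s0: np.ndarray          # (X, Y, Z)
    mask: np.ndarray        # bool; voxels actually fitted
    excluded: np.ndarray    # bool; voxels dropped for nonpositive signal


@dataclass
class OrientationSamples:
    """Sparse per-voxel fiber orientation estimates with bootstrap clouds."""

    voxel_index: np.ndarray   # (X, Y, Z) int32; -1 where no estimate
    voxels: np.ndarray        # (n, 3) int; voxel coordinates
    nfib: np.ndarray          # (n,) int8; retained fibers per voxel
    fractions: np.ndarray     # (n, MAX_FIBERS)
    mean_orientations: np.ndarray  # (n, MAX_FIBERS, 3) point estimates
    samples: np.ndarray       # (n, MAX_FIBERS, B, 3) bootstrap unit vectors
    f_min: float
    voxel_size: tuple[float, float, float]

    @property
    def n_bootstrap(self) -> int:
        return int(self.samples.shape[2])

    def angular_sd_deg(self, row: int, k: int) -> float:
        """Dispersion of bootstrap orientations about the point estimate."""
        mean = self.mean_orientations[row, k]
        cloud = self.samples[row, k]
        dots = np.abs(cloud @ mean).clip(0.0, 1.0)
        return float(np.degrees(np.sqrt(np.mean(np.arccos(dots) ** 2))))


def fractional_anisotropy(evals: np.ndarray) -> np.ndarray:
    """FA = sqrt(3/2) * ||lambda - mean||  / ||lambda||, clipped to [0, 1]."""
    ev = np.asarray(evals, dtype=float)
    mean = ev.mean(axis=-1, keepdims=True)
    num = np.sqrt(((ev - mean) ** 2).sum(axis=-1))
    den = np.sqrt((ev ** 2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0)


def _design_matrix(protocol: DWIProtocol) -> np.ndarray:
    b = protocol.bvals
    g = protocol.bvecs
    return np.column_stack([
        np.ones_like(b),
        -b * g[:, 0] ** 2,
        -b * g[:, 1] ** 2,
        -b * g[:, 2] ** 2,
        -2.0 * b * g[:, 0] * g[:, 1],
        -2.0 * b * g[:, 0] * g[:, 2],
        -2.0 * b * g[:, 1] * g[:, 2],
    ])


def _params_to_tensor(p: np.ndarray) -> np.ndarray:
    """(..., 7) log-linear params -> (..., 3, 3) symmetric tensors."""
    D = np.empty(p.shape[:-1] + (3, 3))
    D[..., 0, 0] = p[..., 1]
    D[..., 1, 1] = p[..., 2]
    D[..., 2, 2] = p[..., 3]
    D[..., 0, 1] = D[..., 1, 0] = p[..., 4]
    D[..., 0, 2] = D[..., 2, 0] = p[..., 5]
    D[..., 1, 2] = D[..., 2, 1] = p[..., 6]
    return D


def fit_tensor(dwi: np.ndarray, protocol: DWIProtocol,
               mask: np.ndarray | None = None) -> TensorFit:
    """Weighted log-linear diffusion tensor fit.

    An OLS solve of ``ln S = ln S0 - b g^T D g`` initializes signal weights
    (W = predicted signal squared), followed by one weighted refinement —
    the standard WLS scheme. Voxels with any nonpositive signal are excluded
    from the output mask and reported in ``excluded``.
    """
    dwi = np.asarray(dwi, dtype=float)
    shape = dwi.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    if protocol.n_volumes != dwi.shape[3]:
        raise ValueError("protocol length does not match number of volumes")
    n_dirs = int(np.unique(np.round(protocol.bvecs[protocol.dwi_mask], 6),
                           axis=0).shape[0])
    if protocol.n_volumes < 7 or n_dirs < 6:
        raise ValueError("tensor fit needs >= 7 volumes spanning >= 6 "
                         "nonzero-b directions")

    bad = np.any(dwi <= 0, axis=3)
    excluded = mask & bad
    fit_mask = mask & ~bad

    X = _design_matrix(protocol)                     # (N, 7)
    Y = np.log(np.maximum(dwi[fit_mask], SIGNAL_FLOOR))  # (nvox, N)
    beta = np.linalg.lstsq(X, Y.T, rcond=None)[0].T      # (nvox, 7)
    # one WLS refinement with weights = predicted signal^2
    pred = beta @ X.T
    w = np.exp(2.0 * pred)
    A = np.einsum("vn,ni,nj->vij", w, X, X)
    rhs = np.einsum("vn,ni,vn->vi", w, X, Y)
    beta = np.linalg.solve(A, rhs[..., None])[..., 0]

    D = _params_to_tensor(beta)
    evals, evecs = np.linalg.eigh(D)                 # ascending
    evals = evals[:, ::-1]
    evecs = evecs[:, :, ::-1]

    out = TensorFit(
        tensor=np.zeros(shape + (3, 3)),
        evals=np.zeros(shape + (3,)),
        evecs=np.zeros(shape + (3, 3)),
        fa=np.zeros(shape),
        s0=np.zeros(shape),
        mask=fit_mask,
        excluded=excluded,
    )
    out.tensor[fit_mask] = D
    out.evals[fit_mask] = evals
    out.evecs[fit_mask] = evecs
    out.fa[fit_mask] = fractional_anisotropy(evals)
    out.s0[fit_mask] = np.exp(beta[:, 0])
    return out


# ---------------------------------------------------------------------------
# ball-and-stick NLLS with residual bootstrap
# ---------------------------------------------------------------------------

def _sph_to_unit(theta, phi):
    st = np.sin(theta)
    return np.array([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


def _unit_to_sph(v):
    v = v / np.linalg.norm(v)
    theta = float(np.arccos(np.clip(v[2], -1.0, 1.0)))
    phi = float(np.arctan2(v[1], v[0]))
    return theta, phi


def _bs_model(params, b, g, K):
    """Ball-and-stick signal for K sticks; params = [s0, d, (f, th, ph)*K]."""
    s0, d = params[0], params[1]
    fsum = 0.0
    sig = np.zeros(b.shape)
    for k in range(K):
        f, th, ph = params[2 + 3 * k: 5 + 3 * k]
        v = _sph_to_unit(th, ph)
        sig = sig + f * np.exp(-b * d * (g @ v) ** 2)
        fsum += f
    sig = sig + (1.0 - fsum) * np.exp(-b * d)
    return s0 * sig


def _fit_bs_voxel(signal, b, g, K, init):
    def resid(p):
        return _bs_model(p, b, g, K) - signal

    lo = [1e-6, 1e-5] + [0.0, -np.pi, -2 * np.pi] * K
    hi = [np.inf, 5e-3] + [1.0, 2 * np.pi, 2 * np.pi] * K
    init = np.clip(init, lo, hi)
    res = least_squares(resid, init, bounds=(lo, hi), method="trf",
                        xtol=1e-10, ftol=1e-10, max_nfev=200)
    return res.x, res.cost


def estimate_fiber_orientations(dwi: np.ndarray, protocol: DWIProtocol,
                                mask: np.ndarray, *, max_fibers: int = MAX_FIBERS,
                                n_boot: int = 50, f_min: float = 0.05,
                                seed: int = 0,
                                voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5)
                                ) -> OrientationSamples:
    """Greedy ball-and-stick fit with residual-bootstrap orientation clouds.

    Fibers are added one at a time, initialized from the tensor eigenvectors,
    while the incremental fitted fraction stays at or above ``f_min``.
    Retained fibers are re-ordered by decreasing fraction. For each bootstrap
    replicate the residuals are resampled with replacement, added to the
    fitted signal, and the chosen model refitted from the point estimate;
    bootstrap fibers are matched to point-estimate fibers by largest absolute
    dot product (orientations are antipodally symmetric throughout).
    """
    if n_boot < 50:
        raise ValueError("n_boot must be >= 50 for a usable bootstrap")
    nz = protocol.bvals[protocol.dwi_mask]
    if nz.size and not np.allclose(nz, nz[0]):
        raise ValueError("multi-fiber estimation expects a single nonzero b shell")
    if max_fibers > MAX_FIBERS:
        raise ValueError(f"max_fibers capped at {MAX_FIBERS}")

    tf = fit_tensor(dwi, protocol, mask)
    voxels = np.argwhere(tf.mask)
    b = protocol.bvals
    g = protocol.bvecs
    rng = np.random.default_rng(seed)

    shape = dwi.shape[:3]
    rows = []
    for vi, (i, j, k) in enumerate(voxels):
        signal = dwi[i, j, k].astype(float)
        evecs = tf.evecs[i, j, k]
        s0_init = max(float(tf.s0[i, j, k]), SIGNAL_FLOOR)
        d_init = float(np.clip(tf.evals[i, j, k].mean(), 1e-4, 4e-3))

        best = np.array([s0_init, d_init])
        best_K = 0
        best_cost = 0.5 * float(((signal - _bs_model(best, b, g, 0)) ** 2).sum())
        for K in range(1, max_fibers + 1):
            th, ph = _unit_to_sph(evecs[:, K - 1])
            init = np.concatenate([best[:2 + 3 * (K - 1)], [0.2, th, ph]]) \
                if K > 1 else np.array([s0_init, d_init, 0.5, th, ph])
            p, cost = _fit_bs_voxel(signal, b, g, K, init)
            new_frac = p[2 + 3 * (K - 1)]
            if new_frac < f_min:
                break
            best, best_K, best_cost = p, K, cost

        if best_K == 0:
            continue

        fracs = best[2::3][:best_K]
        dirs = np.stack([_sph_to_unit(best[3 + 3 * q], best[4 + 3 * q])
                         for q in range(best_K)])
        order = np.argsort(-fracs)
        fracs, dirs = fracs[order], dirs[order]

        fitted = _bs_model(best, b, g, best_K)
        residuals = signal - fitted
        clouds = np.zeros((MAX_FIBERS, n_boot, 3))
        for bi in range(n_boot):
            res_star = rng.choice(residuals, size=residuals.size, replace=True)
            p_star, _ = _fit_bs_voxel(fitted + res_star, b, g, best_K, best)
            dirs_star = np.stack([_sph_to_unit(p_star[3 + 3 * q], p_star[4 + 3 * q])
                                  for q in range(best_K)])
            # match bootstrap fibers to point-estimate fibers (antipodal)
            taken = set()
            for q in range(best_K):
                dots = np.abs(dirs_star @ dirs[q])
                for cand in np.argsort(-dots):
                    if cand not in taken:
                        taken.add(int(cand))
                        v = dirs_star[cand]
                        if v @ dirs[q] < 0:
                            v = -v
                        clouds[q, bi] = v
                        break
        rows.append(((i, j, k), best_K, fracs, dirs, clouds))

    if not rows:
        warnings.warn("no voxel passed f_min; empty orientation result")
    n = len(rows)
    voxel_index = np.full(shape, -1, dtype=np.int32)
    vox = np.zeros((n, 3), dtype=np.int64)
    nfib = np.zeros(n, dtype=np.int8)
    fractions = np.zeros((n, MAX_FIBERS))
    means = np.zeros((n, MAX_FIBERS, 3))
    samples = np.zeros((n, MAX_FIBERS, max(n_boot, 1), 3))
    for r, ((i, j, k), K, fr, dr, cl) in enumerate(rows):
        voxel_index[i, j, k] = r
        vox[r] = (i, j, k)
        nfib[r] = K
        fractions[r, :K] = fr
        means[r, :K] = dr
        samples[r] = cl
    return OrientationSamples(voxel_index, vox, nfib, fractions, means,
                              samples, f_min, voxel_size)


def angular_error_deg(v: np.ndarray, w: np.ndarray) -> float:
    """Angle between two axes (antipodally symmetric), in degrees."""
    v = np.asarray(v, float) / np.linalg.norm(v)
    w = np.asarray(w, float) / np.linalg.norm(w)
    return float(np.degrees(np.arccos(np.clip(abs(v @ w), 0.0, 1.0))))
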