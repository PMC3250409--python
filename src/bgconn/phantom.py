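"""Ground-truth digital phantoms of the basal ganglia and thalamus.

The phantom emulates the data a subject-level connectome study consumes:

* a label volume with the seven deep structures per hemisphere
  (CN, Pu, GPe, GPi, SN, STN, Tha) rasterized as axis-aligned ellipsoids;
* a per-voxel crossing-fiber field (up to three sticks) realizing a set of
  white-matter bundles between structure pairs;
* single-shell diffusion-weighted volumes simulated with a ball-and-stick
  forward model plus Rician noise (b = 1500 s/mm², 128 uniform directions
  and interleaved b0 volumes by default);
* resting-state BOLD series (150 frames at TR 2 s by default) with planted
  inter-structure correlations, slow drift and Gaussian noise;
* perturbed "day 2" segmentations for test–retest agreement studies.

Everything is deterministic given the seed carried by the spec or passed to
the simulators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "STRUCTURES",
    "HEMISPHERES",
    "StructureKey",
    "ROIDef",
    "BundleDef",
    "BoldSpec",
    "PhantomSpec",
    "LabelVolume",
    "FiberField",
    "DWIProtocol",
    "BoldSeries",
    "build_label_volume",
    "build_fiber_field",
    "simulate_dwi",
    "simulate_bold",
    "perturb_segmentation",
    "default_spec",
    "corridor_spec",
]

#: canonical structure order used for labels, matrices and tie-breaking
STRUCTURES = ("CN", "Pu", "GPe", "GPi", "SN", "STN", "Tha")
HEMISPHERES = ("L", "R")

#: (structure, hemisphere) pair, e.g. ("SN", "L")
StructureKey = tuple[str, str]

MAX_FIBERS = 3
#: cap on the summed stick fractions after bundle superposition
MAX_TOTAL_FRACTION = 0.95
#: kappa at or above this value means "no dispersion"
KAPPA_INF = 1e9


# ---------------------------------------------------------------------------
# specification dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROIDef:
    """Axis-aligned ellipsoid definition of one structure in one hemisphere."""

    structure: str
    hemisphere: str
    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]

    def __post_init__(self):
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")
        if any(r <= 0 for r in self.radii_mm):
            raise ValueError("ellipsoid radii must be positive")

    @property
    def key(self) -> StructureKey:
        return (self.structure, self.hemisphere)


@dataclass(frozen=True)
class BundleDef:
    """A white-matter bundle realized as a tube around a polyline centerline.

    ``points_mm`` runs from inside ``roi_a`` to inside ``roi_b``; if omitted
    the centerline is the straight segment between the two ROI centers.
    """

    roi_a: StructureKey
    roi_b: StructureKey
    radius_mm: float = 2.2
    stick_fraction: float = 0.5
    kappa: float = KAPPA_INF
    points_mm: tuple[tuple[float, float, float], ...] | None = None

    def __post_init__(self):
        if not (0.0 < self.stick_fraction <= 1.0):
            raise ValueError("stick_fraction must be in (0, 1]")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")

    @property
    def pair(self) -> frozenset:
        return frozenset((self.roi_a, self.roi_b))


@dataclass(frozen=True)
class BoldSpec:
    """Resting-state series parameters with planted inter-ROI correlations."""

    n_frames: int = 150
    tr: float = 2.0
    correlations: tuple[tuple[StructureKey, StructureKey, float], ...] = ()
    drift_amplitude: float = 0.2
    noise_sd: float = 0.5
    baseline: float = 100.0

    def __post_init__(self):
        for a, b, rho in self.correlations:
            if not (-1.0 <= rho <= 1.0):
                raise ValueError(f"correlation {rho} for {a}-{b} outside [-1, 1]")


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (48, 56, 40)
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5)
    roi_defs: tuple[ROIDef, ...] = ()
    bundle_defs: tuple[BundleDef, ...] = ()
    noise_sigma_dwi: float = 0.0
    bold_spec: BoldSpec = field(default_factory=BoldSpec)
    rng_seed: int = 0

    def __post_init__(self):
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("grid_shape must be at least 8 voxels per axis")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        if self.noise_sigma_dwi < 0:
            raise ValueError("noise_sigma_dwi must be >= 0")
        keys = [r.key for r in self.roi_defs]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (structure, hemisphere) in roi_defs")
        for b in self.bundle_defs:
            for key in (b.roi_a, b.roi_b):
                if key not in keys:
                    raise ValueError(f"bundle endpoint {key} has no ROI definition")

    def roi(self, key: StructureKey) -> ROIDef:
        for r in self.roi_defs:
            if r.key == key:
                return r
        raise KeyError(key)


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class LabelVolume:
    """Integer label grid (0 = background) plus label -> structure table."""

    labels: np.ndarray  # int16, shape (X, Y, Z)
    label_table: dict[int, StructureKey]
    voxel_size: tuple[float, float, float]

    def __post_init__(self):
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.label_table)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from label_table")

    @property
    def key_to_label(self) -> dict[StructureKey, int]:
        return {v: k for k, v in self.label_table.items()}

    def mask(self, key: StructureKey) -> np.ndarray:
        return self.labels == self.key_to_label[key]

    def keys(self) -> list[StructureKey]:
        return list(self.label_table.values())


@dataclass
class FiberField:
    """Per-voxel stick orientations, fractions, and Watson-style dispersion."""

    orientations: np.ndarray  # float64 (X, Y, Z, MAX_FIBERS, 3), unit or 0
    fractions: np.ndarray     # float64 (X, Y, Z, MAX_FIBERS)
    kappas: np.ndarray        # float64 (X, Y, Z, MAX_FIBERS)
    nfib: np.ndarray          # int8 (X, Y, Z)
    voxel_size: tuple[float, float, float]
    brain_mask: np.ndarray | None = None  # bool (X, Y, Z); None = whole grid

    def __post_init__(self):
        if self.brain_mask is None:
            self.brain_mask = np.ones(self.nfib.shape, dtype=bool)
        total = self.fractions.sum(axis=-1)
        if np.any(total > 1.0 + 1e-9):
            raise ValueError("stick fractions sum above 1")
        if np.any(self.nfib > MAX_FIBERS):
            raise ValueError("more than MAX_FIBERS fibers in a voxel")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.nfib.shape)


@dataclass(frozen=True)
class DWIProtocol:
    """Single- or multi-volume acquisition scheme (FSL bval/bvec convention)."""

    bvals: np.ndarray  # (N,)
    bvecs: np.ndarray  # (N, 3); rows with b > 0 are unit vectors

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.shape != (bvals.size, 3):
            raise ValueError("bvecs must have shape (len(bvals), 3)")
        nz = bvals > 0
        norms = np.linalg.norm(bvecs[nz], axis=1)
        if nz.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("gradients of nonzero-b volumes must be unit vectors")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def n_volumes(self) -> int:
        return int(self.bvals.size)

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvals > 0

    @classmethod
    def uniform(cls, n_directions: int = 128, n_b0: int = 15,
                b: float = 1500.0) -> "DWIProtocol":
        """Golden-spiral directions on the sphere, b0 interleaved every 10 DWIs."""
        dirs = _golden_spiral_directions(n_directions)
        bvals, bvecs = [], []
        b0_left = n_b0
        di = 0
        while di < n_directions:
            if b0_left > 0:
                bvals.append(0.0)
                bvecs.append((0.0, 0.0, 0.0))
                b0_left -= 1
            for _ in range(10):
                if di >= n_directions:
                    break
                bvals.append(b)
                bvecs.append(tuple(dirs[di]))
                di += 1
        for _ in range(b0_left):
            bvals.append(0.0)
            bvecs.append((0.0, 0.0, 0.0))
        return cls(np.asarray(bvals), np.asarray(bvecs))


@dataclass
class BoldSeries:
    """4-D BOLD series (x, y, z, t) with its repetition time."""

    data: np.ndarray
    tr: float

    def __post_init__(self):
        if self.data.ndim != 4 or self.data.shape[3] < 2:
            raise ValueError("BOLD series must be 4-D with at least 2 frames")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD series contains non-finite values")

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[3])


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _golden_spiral_directions(n: int) -> np.ndarray:
    """n approximately uniform unit vectors on the sphere."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def voxel_centers_mm(grid_shape, voxel_size) -> tuple[np.ndarray, ...]:
    """Coordinate grids of voxel centers (world = index * voxel_size)."""
    axes = [np.arange(n) * v for n, v in zip(grid_shape, voxel_size)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_mask(grid_shape, voxel_size, center_mm, radii_mm) -> np.ndarray:
    xx, yy, zz = voxel_centers_mm(grid_shape, voxel_size)
    q = ((xx - center_mm[0]) / radii_mm[0]) ** 2 \
        + ((yy - center_mm[1]) / radii_mm[1]) ** 2 \
        + ((zz - center_mm[2]) / radii_mm[2]) ** 2
    return q <= 1.0


def point_in_roi(point_mm, roi: ROIDef) -> bool:
    q = sum(((p - c) / r) ** 2
            for p, c, r in zip(point_mm, roi.center_mm, roi.radii_mm))
    return q <= 1.0


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_label_volume(spec: PhantomSpec) -> LabelVolume:
    """Rasterize the spec's ellipsoid ROIs into a label volume.

    Labels are assigned 1..n in ``roi_defs`` order. Overlapping ROIs are a
    specification error and raise ``ValueError`` naming the colliding pair.
    """
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    table: dict[int, StructureKey] = {}
    for i, roi in enumerate(spec.roi_defs, start=1):
        m = _ellipsoid_mask(spec.grid_shape, spec.voxel_size,
                            roi.center_mm, roi.radii_mm)
        clash = labels[m]
        clash = clash[clash > 0]
        if clash.size:
            other = table[int(clash[0])]
            raise ValueError(
                f"ROIs overlap after rasterization: {roi.key} and {other}")
        labels[m] = i
        table[i] = roi.key
    return LabelVolume(labels, table, spec.voxel_size)


def _centerline_points(spec: PhantomSpec, bundle: BundleDef) -> np.ndarray:
    if bundle.points_mm is not None:
        pts = np.asarray(bundle.points_mm, dtype=float)
    else:
        a = spec.roi(bundle.roi_a)
        b = spec.roi(bundle.roi_b)
        pts = np.asarray([a.center_mm, b.center_mm], dtype=float)
    if pts.shape[0] < 2:
        raise ValueError("bundle centerline needs at least 2 points")
    return pts


def build_fiber_field(spec: PhantomSpec, labels: LabelVolume) -> FiberField:
    """Paint each bundle's tube into a crossing-fiber field.

    Every voxel whose center lies within ``radius_mm`` of a bundle centerline
    receives that bundle's local unit tangent, stick fraction and dispersion.
    A voxel covered by more than three bundles exceeds the crossing-fiber
    model capacity and raises. Summed fractions are rescaled to at most
    ``MAX_TOTAL_FRACTION`` where bundles superpose.
    """
    shape = spec.grid_shape
    orientations = np.zeros(shape + (MAX_FIBERS, 3))
    fractions = np.zeros(shape + (MAX_FIBERS,))
    kappas = np.zeros(shape + (MAX_FIBERS,))
    nfib = np.zeros(shape, dtype=np.int8)

    xx, yy, zz = voxel_centers_mm(shape, spec.voxel_size)
    pts_grid = np.stack([xx, yy, zz], axis=-1)  # (X,Y,Z,3)

    for bundle in spec.bundle_defs:
        pts = _centerline_points(spec, bundle)
        for key, endpoint in ((bundle.roi_a, pts[0]), (bundle.roi_b, pts[-1])):
            if not point_in_roi(endpoint, spec.roi(key)):
                raise ValueError(
                    f"bundle endpoint {endpoint} lies outside ROI {key}")
        # distance of each voxel center to the polyline; tangent at closest point
        best_d2 = np.full(shape, np.inf)
        best_tan = np.zeros(shape + (3,))
        for p0, p1 in zip(pts[:-1], pts[1:]):
            seg = p1 - p0
            seg_len2 = float(seg @ seg)
            if seg_len2 == 0.0:
                continue
            t = np.clip(((pts_grid - p0) @ seg) / seg_len2, 0.0, 1.0)
            closest = p0 + t[..., None] * seg
            d2 = np.sum((pts_grid - closest) ** 2, axis=-1)
            upd = d2 < best_d2
            best_d2[upd] = d2[upd]
            best_tan[upd] = seg / math.sqrt(seg_len2)
        inside = best_d2 <= bundle.radius_mm ** 2
        idx = np.argwhere(inside)
        for i, j, k in idx:
            m = nfib[i, j, k]
            if m >= MAX_FIBERS:
                raise ValueError(
                    f"voxel {(i, j, k)} covered by more than {MAX_FIBERS} bundles")
            orientations[i, j, k, m] = best_tan[i, j, k]
            fractions[i, j, k, m] = bundle.stick_fraction
            kappas[i, j, k, m] = bundle.kappa
            nfib[i, j, k] = m + 1

    total = fractions.sum(axis=-1)
    over = total > MAX_TOTAL_FRACTION
    if np.any(over):
        scale = np.ones_like(total)
        scale[over] = MAX_TOTAL_FRACTION / total[over]
        fractions *= scale[..., None]
    return FiberField(orientations, fractions, kappas, nfib, spec.voxel_size)


def simulate_dwi(field: FiberField, protocol: DWIProtocol, *,
                 S0: float = 1000.0, d: float = 1.7e-3,
                 noise_sigma: float = 0.0, seed: int = 0) -> np.ndarray:
    """Ball-and-stick forward simulation with optional Rician noise.

    The noiseless signal is
    ``S(g, b) = S0 [ (1 - sum f_k) e^{-b d} + sum_k f_k e^{-b d (g.v_k)^2} ]``;
    Rician noise of scale ``noise_sigma * S0`` is applied to the magnitude.
    """
    if S0 <= 0:
        raise ValueError("S0 must be positive")
    if d < 0:
        raise ValueError("diffusivity d must be >= 0")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")

    shape = field.grid_shape
    n = protocol.n_volumes
    out = np.empty(shape + (n,))
    f = field.fractions                     # (X,Y,Z,3)
    ball = 1.0 - f.sum(axis=-1)             # (X,Y,Z)
    v = field.orientations                  # (X,Y,Z,3,3)
    for vol in range(n):
        b = protocol.bvals[vol]
        if b == 0.0:
            out[..., vol] = S0
            continue
        g = protocol.bvecs[vol]
        dot = v @ g                         # (X,Y,Z,3)
        att = np.exp(-b * d * dot ** 2)
        out[..., vol] = S0 * (ball * math.exp(-b * d) + (f * att).sum(axis=-1))

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        s = noise_sigma * S0
        e1 = rng.normal(0.0, s, out.shape)
        e2 = rng.normal(0.0, s, out.shape)
        out = np.sqrt((out + e1) ** 2 + e2 ** 2)
    return out


def _roi_correlation_matrix(keys: Sequence[StructureKey],
                            planted: Iterable[tuple[StructureKey, StructureKey, float]]
                            ) -> np.ndarray:
    n = len(keys)
    index = {k: i for i, k in enumerate(keys)}
    R = np.eye(n)
    for a, b, rho in planted:
        if a not in index or b not in index:
            raise ValueError(f"planted correlation references unknown ROI {a} or {b}")
        i, j = index[a], index[b]
        R[i, j] = R[j, i] = rho
    evals = np.linalg.eigvalsh(R)
    if evals.min() < -1e-10:
        raise ValueError("planted correlation matrix is not positive semidefinite")
    return R


def simulate_bold(spec: PhantomSpec, labels: LabelVolume, seed: int = 0,
                  *, zone_overrides: Mapping[StructureKey, np.ndarray] | None = None
                  ) -> BoldSeries:
    """Simulate a resting-state series with planted inter-ROI coupling.

    Each ROI carries a unit-variance latent time course; the latents are
    jointly Gaussian with the spec's planted correlations. A voxel's course is
    its ROI latent plus white noise and a slow random-phase cosine drift, on a
    constant baseline. ``zone_overrides`` restricts the latent of a structure
    to a sub-zone mask (voxels of the ROI outside the zone get noise only) —
    used to plant focal functional coupling.
    """
    bs = spec.bold_spec
    T = bs.n_frames
    if T < 3:
        raise ValueError("n_frames must be at least 3")
    rng = np.random.default_rng(seed)
    keys = labels.keys()
    R = _roi_correlation_matrix(keys, bs.correlations)
    L = np.linalg.cholesky(R + 1e-12 * np.eye(len(keys)))
    latents = rng.standard_normal((T, len(keys))) @ L.T  # (T, nroi)

    shape = labels.labels.shape
    data = np.empty(shape + (T,))
    t = np.arange(T)
    # slow drift: random-phase cosine, about half a period over the run
    nvox = int(np.prod(shape))
    phases = rng.uniform(0.0, 2.0 * np.pi, nvox).reshape(shape)
    drift = bs.drift_amplitude * np.cos(np.pi * t / T + phases[..., None])
    data[:] = bs.baseline + drift
    data += rng.normal(0.0, bs.noise_sd, data.shape)

    for i, key in enumerate(keys):
        m = labels.mask(key)
        if zone_overrides and key in zone_overrides:
            m = m & zone_overrides[key]
        data[m] += latents[:, i]
    return BoldSeries(data, bs.tr)


def perturb_segmentation(labels: LabelVolume, flip_rate: float,
                         seed: int = 0) -> LabelVolume:
    """Toggle ROI boundary voxels with probability ``flip_rate``.

    Boundary voxels of an ROI (6-connectivity) are dropped to background, and
    background voxels adjacent to exactly one ROI are absorbed into it, each
    independently with probability ``flip_rate``. Interiors are preserved, so
    repeated "day 2" segmentations differ only at the rim, mimicking
    intra-observer variability.
    """
    if not (0.0 <= flip_rate <= 1.0):
        raise ValueError("flip_rate must be in [0, 1]")
    lab = labels.labels
    rng = np.random.default_rng(seed)
    out = lab.copy()

    # 6-neighbour shifted views
    def neighbours(arr):
        padded = np.pad(arr, 1, mode="constant")
        shifts = []
        for ax in range(3):
            for d in (-1, 1):
                sl = [slice(1, -1)] * 3
                sl[ax] = slice(1 + d, arr.shape[ax] + 1 + d)
                shifts.append(padded[tuple(sl)])
        return shifts

    neigh = neighbours(lab)
    # ROI boundary: labelled voxel with any 6-neighbour of different label
    boundary = np.zeros(lab.shape, dtype=bool)
    for nb in neigh:
        boundary |= (lab > 0) & (nb != lab)
    flips = rng.random(lab.shape) < flip_rate
    out[boundary & flips] = 0

    # background voxels adjacent to exactly one distinct ROI label
    stacked = np.stack(neigh)
    bg = lab == 0
    nb_max = stacked.max(axis=0)
    one_label = np.ones(lab.shape, dtype=bool)
    for nb in neigh:
        one_label &= (nb == 0) | (nb == nb_max)
    grow = bg & (nb_max > 0) & one_label
    flips = rng.random(lab.shape) < flip_rate
    sel = grow & flips
    out[sel] = nb_max[sel]

    return LabelVolume(out, dict(labels.label_table), labels.voxel_size)


# ---------------------------------------------------------------------------
# ready-made specs
# ---------------------------------------------------------------------------

# right-hemisphere structure layout, in voxel units on the default grid;
# mirrored about the x midline for the left hemisphere. Structures are
# placed so the seven bundle routes meet only inside shared ROIs and never
# cross mid-route: at a crossing, probabilistic propagation can hop between
# tubes at shallow angles and fabricate connections the phantom never
# planted. Hops at shared-ROI junctions are harmless (they either stay on a
# planted route or violate the curvature limit and terminate).
_RIGHT_CENTERS_VOX = {
    "CN": (29.0, 44.0, 27.0),
    "Pu": (41.0, 30.0, 22.0),
    "GPe": (39.0, 38.0, 24.0),
    "GPi": (27.0, 30.0, 20.0),
    "SN": (33.0, 22.0, 12.0),
    "STN": (45.0, 34.0, 18.0),
    "Tha": (33.0, 38.0, 25.0),
}
_RADII_MM = {
    "CN": (3.0, 4.5, 3.0),
    "Pu": (3.5, 5.5, 4.0),
    "GPe": (2.8, 4.0, 3.2),
    "GPi": (2.5, 3.2, 2.8),
    "SN": (2.8, 3.6, 2.4),
    "STN": (2.4, 2.8, 2.2),
    "Tha": (3.5, 5.0, 4.0),
}

#: the seven bundles of the default phantom: nigrostriatal, nigropallidal,
#: nigrothalamic, subthalamopallidal, pallidothalamic, striatopallidal,
#: thalamostriatal
DEFAULT_PATHWAYS = (
    ("SN", "Pu"),
    ("SN", "GPi"),
    ("SN", "Tha"),
    ("STN", "GPe"),
    ("GPi", "Tha"),
    ("Pu", "GPe"),
    ("Tha", "CN"),
)


def default_spec(seed: int = 0, *, kappa: float = 30.0,
                 stick_fraction: float = 0.5, bundle_radius_mm: float = 2.2,
                 noise_sigma_dwi: float = 0.0,
                 bold_spec: BoldSpec | None = None) -> PhantomSpec:
    """Mirror-symmetric 14-ROI phantom with the seven canonical pathways.

    The grid is 48x56x40 voxels at 1.5 mm isotropic; per-bundle dispersion
    defaults to kappa = 30 (about 7 degrees angular sd).
    """
    grid = (48, 56, 40)
    vs = (1.5, 1.5, 1.5)
    rois = []
    for hemi in ("L", "R"):
        for s in STRUCTURES:
            cx, cy, cz = _RIGHT_CENTERS_VOX[s]
            if hemi == "L":
                cx = (grid[0] - 1) - cx
            rois.append(ROIDef(s, hemi,
                               (cx * vs[0], cy * vs[1], cz * vs[2]),
                               _RADII_MM[s]))
    bundles = []
    for hemi in ("L", "R"):
        for a, b in DEFAULT_PATHWAYS:
            bundles.append(BundleDef((a, hemi), (b, hemi),
                                     radius_mm=bundle_radius_mm,
                                     stick_fraction=stick_fraction,
                                     kappa=kappa))
    return PhantomSpec(grid, vs, tuple(rois), tuple(bundles),
                       noise_sigma_dwi=noise_sigma_dwi,
                       bold_spec=bold_spec or BoldSpec(),
                       rng_seed=seed)


def corridor_spec(seed: int = 0, *, length_vox: int = 14,
                  roi_radius_mm: float = 2.4, tube_radius_mm: float = 3.2,
                  kappa: float = KAPPA_INF) -> PhantomSpec:
    """Two small ROIs (SN and Tha, right hemisphere) joined by one straight
    zero-dispersion bundle along x — the analytic corridor oracle phantom.

    The tube is wider than the ROIs so every seed voxel carries a fiber.
    """
    grid = (32, 16, 16)
    vs = (1.5, 1.5, 1.5)
    ya = 8 * vs[1]
    za = 8 * vs[2]
    xa = 8 * vs[0]
    xb = (8 + length_vox) * vs[0]
    r = roi_radius_mm
    rois = (
        ROIDef("SN", "R", (xa, ya, za), (r, r, r)),
        ROIDef("Tha", "R", (xb, ya, za), (r, r, r)),
    )
    bundles = (BundleDef(("SN", "R"), ("Tha", "R"), radius_mm=tube_radius_mm,
                         stick_fraction=0.6, kappa=kappa,
                         points_mm=((xa, ya, za), (xb, ya, za))),)
    return PhantomSpec(grid, vs, rois, bundles, rng_seed=seed)
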