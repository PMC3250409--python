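"""Independent analytic oracle for the straight-corridor phantom.

Re-derives, with plain Python loops and the analytic tube geometry (no use
of the package's fiber-field or tracking code), the exact set of voxels a
deterministic zero-dispersion streamline visits from every seed voxel, and
whether it reaches the target. Used to check the tracking kernel's count
maps exactly.
"""

import math

import numpy as np


def _in_ellipsoid(p_mm, center_mm, radii_mm):
    return sum(((p - c) / r) ** 2
               for p, c, r in zip(p_mm, center_mm, radii_mm)) <= 1.0


def _seg_dist(p, a, b):
    ap = [p[i] - a[i] for i in range(3)]
    ab = [b[i] - a[i] for i in range(3)]
    denom = sum(x * x for x in ab)
    t = max(0.0, min(1.0, sum(ap[i] * ab[i] for i in range(3)) / denom))
    return math.sqrt(sum((p[i] - (a[i] + t * ab[i])) ** 2 for i in range(3)))


def corridor_expectations(spec, step=0.75, max_steps=2000):
    """Per-sample visit counts and retention for every seed voxel.

    Returns (count_map, n_retained_seeds, seed_voxels); the kernel's raw map
    at n samples per voxel must equal count_map * n exactly.
    """
    vs = spec.voxel_size
    grid = spec.grid_shape
    roi_a = next(r for r in spec.roi_defs if r.structure == "SN")
    roi_b = next(r for r in spec.roi_defs if r.structure == "Tha")
    bundle = spec.bundle_defs[0]
    line_a, line_b = bundle.points_mm

    def voxel_of(p):
        return tuple(int(math.floor(p[i] / vs[i] + 0.5)) for i in range(3))

    def center(v):
        return tuple(v[i] * vs[i] for i in range(3))

    def has_fiber(v):
        return _seg_dist(center(v), line_a, line_b) <= bundle.radius_mm

    def in_target(v):
        return _in_ellipsoid(center(v), roi_b.center_mm, roi_b.radii_mm)

    seeds = [tuple(v) for v in np.ndindex(*grid)
             if _in_ellipsoid(center(v), roi_a.center_mm, roi_a.radii_mm)]

    def walk(seed, sign):
        """Visited-new-voxel list of one half; True if it enters the target."""
        p = list(center(seed))
        cur = seed
        visited = []
        for _ in range(max_steps):
            p[0] += sign * step
            v = voxel_of(p)
            if any(v[i] < 0 or v[i] >= grid[i] for i in range(3)):
                return visited, False
            if v != cur:
                cur = v
                visited.append(v)
                if in_target(v):
                    return visited, True
            if not has_fiber(v):
                return visited, False
        return visited, False

    counts = np.zeros(grid, dtype=np.int64)
    retained = 0
    for seed in seeds:
        fwd, hit_f = walk(seed, +1)
        bwd, hit_b = walk(seed, -1)
        if not (hit_f or hit_b):
            continue
        retained += 1
        counts[seed] += 1
        for v in fwd + bwd:
            counts[v] += 1
    return counts, retained, seeds
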