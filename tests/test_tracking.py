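import numpy as np
import pytest

import bgconn
from bgconn.phantom import BundleDef, PhantomSpec, ROIDef
from bgconn.tracking import TrackingParams, propagate_streamline, track_pairwise

from conftest import make_field, set_fiber
from corridor_oracle import corridor_expectations

VS = (1.5, 1.5, 1.5)


def det_params(**kw):
    kw.setdefault("n_samples_per_voxel", 1)
    kw.setdefault("rng_seed", 0)
    return TrackingParams(**kw)


class TestPropagateStreamline:
    def test_straight_corridor_step_count_matches_geometry(self):
        field = make_field((24, 8, 8))
        for i in range(2, 20):
            set_fiber(field, (i, 4, 4), (1, 0, 0), 0.6)
        params = det_params(step_size=0.75)
        pts, reason = propagate_streamline(field, (3.0, 6.0, 6.0), params,
                                           direction=(1, 0, 0))
        assert reason == "no_fiber"
        # corridor spans x in [2, 19] voxels; from x=2 the streamline leaves
        # the fiber region upon entering voxel 20 (x = 30 mm)
        dists = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        np.testing.assert_allclose(dists, 0.75, atol=1e-12)
        corridor_len = pts[-1][0] - pts[0][0]
        assert len(pts) - 1 == pytest.approx(corridor_len / 0.75, abs=1)
        # straight: y and z never change
        assert np.ptp(pts[:, 1]) == 0 and np.ptp(pts[:, 2]) == 0

    def test_start_voxel_without_fiber_terminates_immediately(self):
        field = make_field((8, 8, 8))
        pts, reason = propagate_streamline(field, (6.0, 6.0, 6.0), det_params())
        assert len(pts) == 1
        assert reason == "no_fiber"

    def test_right_angle_flip_terminates_at_interface(self):
        field = make_field((16, 16, 8))
        for i in range(1, 8):
            set_fiber(field, (i, 4, 4), (1, 0, 0), 0.6)
        for i in range(8, 15):
            set_fiber(field, (i, 4, 4), (0, 1, 0), 0.6)
        params = det_params(curvature_threshold=80.0)
        pts, reason = propagate_streamline(field, (1.5, 6.0, 6.0), params,
                                           direction=(1, 0, 0))
        assert reason == "curvature"
        # terminates in the first voxel of the orthogonal segment
        last_voxel = np.floor(pts[-1] / 1.5 + 0.5).astype(int)
        assert last_voxel[0] == 8

    def test_start_outside_grid_rejected(self):
        field = make_field((8, 8, 8))
        with pytest.raises(ValueError, match="outside"):
            propagate_streamline(field, (100.0, 0.0, 0.0), det_params())

    def test_mask_exit_termination(self):
        field = make_field((8, 8, 8))
        for i in range(8):
            set_fiber(field, (i, 4, 4), (1, 0, 0), 0.6)
        pts, reason = propagate_streamline(field, (0.0, 6.0, 6.0),
                                           det_params(), direction=(1, 0, 0))
        assert reason == "mask_exit"


class TestCorridorOracle:
    def test_count_map_matches_analytic_enumeration_exactly(self, corridor_phantom):
        spec, labels, field = corridor_phantom
        n = 50
        res = track_pairwise(field, labels, "SN", "R",
                             det_params(n_samples_per_voxel=n, rng_seed=9))
        expected, retained_seeds, seeds = corridor_expectations(spec)
        assert np.array_equal(res.distributions["Tha"].raw, expected * n)
        assert res.retained_total == retained_seeds * n
        assert res.launched == len(seeds) * n

    def test_high_retention_and_support(self, corridor_phantom):
        spec, labels, field = corridor_phantom
        res = track_pairwise(field, labels, "SN", "R",
                             det_params(n_samples_per_voxel=100, rng_seed=2))
        assert res.retained_total / res.launched >= 0.99
        expected, _, _ = corridor_expectations(spec)
        assert np.array_equal(res.distributions["Tha"].raw > 0, expected > 0)

    def test_no_bundle_means_no_retention(self):
        rois = [ROIDef("SN", "R", (6.0, 9.0, 9.0), (2.5, 2.5, 2.5)),
                ROIDef("Tha", "R", (18.0, 9.0, 9.0), (2.5, 2.5, 2.5))]
        spec = PhantomSpec((16, 12, 12), VS, tuple(rois), ())
        labels = bgconn.build_label_volume(spec)
        field = bgconn.build_fiber_field(spec, labels)
        res = track_pairwise(field, labels, "SN", "R",
                             det_params(n_samples_per_voxel=10))
        assert res.retained_total == 0
        assert res.distributions["Tha"].raw.sum() == 0


class TestConservationAndDeterminism:
    def test_retained_plus_discarded_equals_launched(self, default_phantom):
        _, labels, field = default_phantom
        params = det_params(n_samples_per_voxel=20, rng_seed=3)
        for s in ("SN", "Tha"):
            res = track_pairwise(field, labels, s, "R", params)
            assert res.retained_total + res.discarded == res.launched
            for d in res.distributions.values():
                assert d.retained + d.discarded == d.launched

    def test_same_seed_gives_bitwise_identical_maps(self, default_phantom):
        _, labels, field = default_phantom
        params = det_params(n_samples_per_voxel=50, rng_seed=11)
        a = track_pairwise(field, labels, "GPi", "R", params)
        b = track_pairwise(field, labels, "GPi", "R", params)
        for t in a.distributions:
            assert np.array_equal(a.distributions[t].raw,
                                  b.distributions[t].raw)
        assert np.array_equal(a.profile.counts, b.profile.counts)

    def test_different_seed_changes_sampling(self, default_phantom):
        _, labels, field = default_phantom
        a = track_pairwise(field, labels, "SN", "R",
                           det_params(n_samples_per_voxel=50, rng_seed=1))
        b = track_pairwise(field, labels, "SN", "R",
                           det_params(n_samples_per_voxel=50, rng_seed=2))
        assert not np.array_equal(a.distributions["Tha"].raw,
                                  b.distributions["Tha"].raw)

    def test_empty_seed_roi_rejected(self, default_phantom):
        _, labels, field = default_phantom
        bad = bgconn.LabelVolume(labels.labels.copy(),
                                 dict(labels.label_table), labels.voxel_size)
        bad.labels[bad.labels == bad.key_to_label[("SN", "R")]] = 0
        with pytest.raises(ValueError, match="empty"):
            track_pairwise(field, bad, "SN", "R", det_params())


@pytest.fixture(scope="module")
def junction():
    rois = [ROIDef("SN", "R", (4.5, 6.0, 6.0), (2.2, 2.2, 2.2)),
            ROIDef("Tha", "R", (25.5, 6.0, 6.0), (2.2, 2.2, 2.2)),
            ROIDef("CN", "R", (24.0, 16.5, 6.0), (2.2, 2.2, 2.2))]
    shared = ((4.5, 6.0, 6.0), (13.5, 6.0, 6.0))
    spec = PhantomSpec((22, 16, 10), VS, tuple(rois), (
        BundleDef(("SN", "R"), ("Tha", "R"), radius_mm=2.0,
                  points_mm=(shared[0], shared[1], (25.5, 6.0, 6.0))),
        BundleDef(("SN", "R"), ("CN", "R"), radius_mm=2.0,
                  points_mm=(shared[0], shared[1], (24.0, 16.5, 6.0))),
    ))
    labels = bgconn.build_label_volume(spec)
    field = bgconn.build_fiber_field(spec, labels)
    return spec, labels, field


class TestYJunctionBookkeeping:
    """A bundle from A forks toward B and C; per-streamline accounting must
    assign every sample to exactly one target or discard it, and the A-B map
    must not contain the C branch."""

    def test_every_sample_accounted_once(self, junction):
        _, labels, field = junction
        res = track_pairwise(field, labels, "SN", "R",
                             det_params(n_samples_per_voxel=1, rng_seed=4))
        per_target = sum(d.retained for d in res.distributions.values())
        assert per_target == res.retained_total
        assert res.retained_total + res.discarded == res.launched
        assert res.profile.counts.sum(axis=1).max() <= 1

    def test_branch_maps_are_disjoint_beyond_junction(self, junction):
        _, labels, field = junction
        res = track_pairwise(field, labels, "SN", "R",
                             det_params(n_samples_per_voxel=30, rng_seed=4))
        raw_b = res.distributions["Tha"].raw
        raw_c = res.distributions["CN"].raw
        assert res.distributions["Tha"].retained > 0
        assert res.distributions["CN"].retained > 0
        # beyond the fork, the straight-on branch lives at y <= 7 and the
        # diagonal branch at y >= 8 (voxel units); maps must not mix
        assert raw_b[:, 9:, :].sum() == 0
        assert raw_c[16:, :7, :].sum() == 0


class TestMirrorSymmetry:
    def test_mirrored_count_maps_agree(self, default_phantom):
        _, labels, field = default_phantom
        params = det_params(n_samples_per_voxel=1000, rng_seed=21)
        r = track_pairwise(field, labels, "SN", "R", params)
        l = track_pairwise(field, labels, "SN", "L",
                           det_params(n_samples_per_voxel=1000, rng_seed=22))
        raw_r = r.distributions["Tha"].raw
        raw_l = l.distributions["Tha"].raw[::-1]  # mirror x
        support = (raw_r > 0) | (raw_l > 0)
        corr = np.corrcoef(raw_r[support], raw_l[support])[0, 1]
        assert corr > 0.95
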