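import numpy as np
import pytest

import bgconn
from bgconn.phantom import (BoldSpec, BundleDef, PhantomSpec, ROIDef,
                            DWIProtocol, build_fiber_field,
                            build_label_volume, perturb_segmentation,
                            simulate_bold, simulate_dwi)

from conftest import make_field


VS = (1.5, 1.5, 1.5)


def small_spec(rois, bundles=(), grid=(16, 16, 16), **kw):
    return PhantomSpec(grid, VS, tuple(rois), tuple(bundles), **kw)


class TestLabelVolume:
    def test_default_phantom_has_fourteen_rois(self, default_phantom):
        _, labels, _ = default_phantom
        nonzero = set(np.unique(labels.labels)) - {0}
        assert len(nonzero) == 14
        assert len(labels.label_table) == 14
        structures = {s for s, _ in labels.keys()}
        assert structures == set(bgconn.STRUCTURES)

    def test_empty_roi_defs_gives_empty_volume(self):
        lv = build_label_volume(small_spec([]))
        assert lv.labels.sum() == 0
        assert lv.label_table == {}

    def test_overlapping_ellipsoids_rejected_with_pair_names(self):
        rois = [ROIDef("SN", "R", (12.0, 12.0, 12.0), (3.0, 3.0, 3.0)),
                ROIDef("STN", "R", (13.5, 12.0, 12.0), (3.0, 3.0, 3.0))]
        with pytest.raises(ValueError, match="SN.*STN|STN.*SN"):
            build_label_volume(small_spec(rois))

    def test_mirror_symmetric_volumes(self, default_phantom):
        _, labels, _ = default_phantom
        from bgconn.stats import roi_volumes
        v = roi_volumes(labels)
        for s in bgconn.STRUCTURES:
            assert v[(s, "L")] == v[(s, "R")]


class TestFiberField:
    def test_single_straight_bundle_paints_unit_tangent(self):
        rois = [ROIDef("SN", "R", (6.0, 12.0, 12.0), (2.5, 2.5, 2.5)),
                ROIDef("Tha", "R", (18.0, 12.0, 12.0), (2.5, 2.5, 2.5))]
        spec = small_spec(rois, [BundleDef(("SN", "R"), ("Tha", "R"))])
        field = build_fiber_field(spec, build_label_volume(spec))
        covered = field.nfib > 0
        assert covered.any()
        assert field.nfib[covered].max() == 1
        # corridor voxel midway: one fiber along +x
        assert field.nfib[8, 8, 8] == 1
        np.testing.assert_allclose(np.abs(field.orientations[8, 8, 8, 0]),
                                   [1, 0, 0], atol=1e-12)

    def test_orthogonal_crossing_has_two_fibers_and_bounded_fractions(self):
        rois = [ROIDef("SN", "R", (3.0, 12.0, 12.0), (2.0, 2.0, 2.0)),
                ROIDef("Tha", "R", (21.0, 12.0, 12.0), (2.0, 2.0, 2.0)),
                ROIDef("CN", "R", (12.0, 3.0, 12.0), (2.0, 2.0, 2.0)),
                ROIDef("Pu", "R", (12.0, 21.0, 12.0), (2.0, 2.0, 2.0))]
        spec = small_spec(rois, [BundleDef(("SN", "R"), ("Tha", "R")),
                                 BundleDef(("CN", "R"), ("Pu", "R"))])
        field = build_fiber_field(spec, build_label_volume(spec))
        assert field.nfib[8, 8, 8] == 2
        assert field.fractions[8, 8, 8].sum() <= 1.0

    def test_no_bundles_gives_empty_field(self):
        spec = small_spec([ROIDef("SN", "R", (12.0, 12.0, 12.0), (2, 2, 2))])
        field = build_fiber_field(spec, build_label_volume(spec))
        assert not field.nfib.any()

    def test_more_than_three_bundles_in_voxel_rejected(self):
        rois = [ROIDef("SN", "R", (12.0, 12.0, 12.0), (2, 2, 2)),
                ROIDef("Tha", "R", (12.0, 12.0, 3.0), (2, 2, 2))]
        # four coincident tubes through the same corridor
        bundles = [BundleDef(("SN", "R"), ("Tha", "R"))] * 4
        spec = small_spec(rois, bundles)
        with pytest.raises(ValueError, match="more than 3"):
            build_fiber_field(spec, build_label_volume(spec))

    def test_endpoint_outside_roi_rejected(self):
        rois = [ROIDef("SN", "R", (6.0, 12.0, 12.0), (2, 2, 2)),
                ROIDef("Tha", "R", (18.0, 12.0, 12.0), (2, 2, 2))]
        bundle = BundleDef(("SN", "R"), ("Tha", "R"),
                           points_mm=((6.0, 3.0, 12.0), (18.0, 12.0, 12.0)))
        spec = small_spec(rois, [bundle])
        with pytest.raises(ValueError, match="outside ROI"):
            build_fiber_field(spec, build_label_volume(spec))


class TestSimulateDWI:
    @pytest.fixture()
    def stick_field(self):
        field = make_field((4, 4, 4))
        from conftest import set_fiber
        set_fiber(field, (1, 1, 1), (0, 0, 1), 0.7)  # stick along z
        return field

    def test_b0_returns_s0_exactly(self, stick_field):
        proto = DWIProtocol(np.zeros(3), np.zeros((3, 3)))
        sig = simulate_dwi(stick_field, proto, S0=500.0)
        assert np.all(sig == 500.0)

    def test_empty_voxel_isotropic_attenuation(self, stick_field):
        proto = DWIProtocol.uniform(n_directions=16, n_b0=1)
        sig = simulate_dwi(stick_field, proto, S0=1000.0, d=1.7e-3)
        dwis = sig[0, 0, 0][proto.dwi_mask]  # K = 0 voxel
        expected = 1000.0 * np.exp(-1500.0 * 1.7e-3)
        np.testing.assert_allclose(dwis, expected, rtol=1e-12)

    def test_perpendicular_vs_parallel_ratio_matches_forward_model(self, stick_field):
        b, d, f, S0 = 1500.0, 1.7e-3, 0.7, 1000.0
        proto = DWIProtocol(np.array([b, b]),
                            np.array([[1.0, 0, 0], [0, 0, 1.0]]))
        sig = simulate_dwi(stick_field, proto, S0=S0, d=d)
        perp, para = sig[1, 1, 1]
        # direct evaluation of the ball-and-stick equation
        e = np.exp(-b * d)
        assert perp == pytest.approx(S0 * ((1 - f) * e + f), rel=1e-12)
        assert para == pytest.approx(S0 * e, rel=1e-12)
        assert perp > para

    def test_noiseless_simulation_is_deterministic(self, stick_field):
        proto = DWIProtocol.uniform(n_directions=8, n_b0=1)
        a = simulate_dwi(stick_field, proto, seed=1)
        b = simulate_dwi(stick_field, proto, seed=2)
        assert np.array_equal(a, b)

    def test_rician_noise_seeded(self, stick_field):
        proto = DWIProtocol.uniform(n_directions=8, n_b0=1)
        a = simulate_dwi(stick_field, proto, noise_sigma=0.05, seed=3)
        b = simulate_dwi(stick_field, proto, noise_sigma=0.05, seed=3)
        c = simulate_dwi(stick_field, proto, noise_sigma=0.05, seed=4)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)
        assert np.all(a >= 0)

    @pytest.mark.parametrize("kw", [{"d": -1e-3}, {"S0": 0.0}, {"S0": -5.0}])
    def test_invalid_parameters_rejected(self, stick_field, kw):
        proto = DWIProtocol.uniform(n_directions=8, n_b0=1)
        with pytest.raises(ValueError):
            simulate_dwi(stick_field, proto, **kw)


def _two_roi_bold_spec(rho, noise_sd=0.5, drift=0.2, n_frames=150):
    rois = [ROIDef("SN", "R", (6.0, 12.0, 12.0), (2.5, 2.5, 2.5)),
            ROIDef("Tha", "R", (18.0, 12.0, 12.0), (2.5, 2.5, 2.5))]
    bold = BoldSpec(n_frames=n_frames, correlations=(
        (("SN", "R"), ("Tha", "R"), rho),),
        noise_sd=noise_sd, drift_amplitude=drift)
    return small_spec(rois, bold_spec=bold)


class TestSimulateBold:
    def test_default_frame_count_is_150(self, default_phantom):
        spec, labels, _ = default_phantom
        series = simulate_bold(spec, labels, seed=0)
        assert series.n_frames == 150
        assert series.tr == 2.0

    def test_perfect_coupling_no_noise_gives_identical_mean_courses(self):
        spec = _two_roi_bold_spec(1.0, noise_sd=0.0, drift=0.0)
        labels = build_label_volume(spec)
        series = simulate_bold(spec, labels, seed=1)
        a = series.data[labels.mask(("SN", "R"))].mean(axis=0)
        b = series.data[labels.mask(("Tha", "R"))].mean(axis=0)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_uncoupled_rois_have_near_zero_mean_correlation(self):
        spec = _two_roi_bold_spec(0.0, n_frames=150)
        labels = build_label_volume(spec)
        rs = []
        for seed in range(100):
            series = simulate_bold(spec, labels, seed=seed)
            a = series.data[labels.mask(("SN", "R"))].mean(axis=0)
            b = series.data[labels.mask(("Tha", "R"))].mean(axis=0)
            rs.append(np.corrcoef(a, b)[0, 1])
        assert abs(np.mean(rs)) < 3.0 / np.sqrt(150)

    @pytest.mark.parametrize("rho", [0.0, 0.5, 0.9])
    def test_planted_correlation_recovered(self, rho):
        # generator calibration: mean sample correlation across 200 seeds
        spec = _two_roi_bold_spec(rho)
        labels = build_label_volume(spec)
        ma = labels.mask(("SN", "R"))
        mb = labels.mask(("Tha", "R"))
        rs = []
        for seed in range(200):
            series = simulate_bold(spec, labels, seed=seed)
            a = series.data[ma].mean(axis=0)
            b = series.data[mb].mean(axis=0)
            rs.append(np.corrcoef(a, b)[0, 1])
        assert np.mean(rs) == pytest.approx(rho, abs=0.05)

    def test_too_few_frames_rejected(self):
        spec = _two_roi_bold_spec(0.0, n_frames=2)
        labels = build_label_volume(spec)
        with pytest.raises(ValueError, match="frames"):
            simulate_bold(spec, labels)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            _two_roi_bold_spec(1.5)


class TestPerturbSegmentation:
    def test_zero_flip_rate_is_identity(self, default_phantom):
        _, labels, _ = default_phantom
        out = perturb_segmentation(labels, 0.0, seed=1)
        assert np.array_equal(out.labels, labels.labels)

    def test_full_rate_toggles_every_boundary_voxel_of_shell(self):
        spec = small_spec([ROIDef("SN", "R", (12.0, 12.0, 12.0),
                                  (2.0, 2.0, 2.0))])
        labels = build_label_volume(spec)
        out = perturb_segmentation(labels, 1.0, seed=0)
        # every ROI voxel of a thin shell is a boundary voxel: all erased
        lab = labels.labels
        boundary = np.zeros_like(lab, dtype=bool)
        for ax in range(3):
            for d in (-1, 1):
                shifted = np.roll(lab, d, axis=ax)
                boundary |= (lab > 0) & (shifted != lab)
        assert np.all(out.labels[boundary] == 0)

    def test_moderate_rate_changes_volumes_but_preserves_interior(self, default_phantom):
        _, labels, _ = default_phantom
        out = perturb_segmentation(labels, 0.1, seed=7)
        assert not np.array_equal(out.labels, labels.labels)
        from bgconn.stats import agreement_table
        rows = agreement_table(labels, out)
        ais = [row.ai for row in rows]
        assert all(a > 0.5 for a in ais)
        assert np.mean(ais) < 1.0
        assert sum(a < 1.0 for a in ais) >= len(ais) - 1

    def test_deterministic_given_seed(self, default_phantom):
        _, labels, _ = default_phantom
        a = perturb_segmentation(labels, 0.3, seed=5)
        b = perturb_segmentation(labels, 0.3, seed=5)
        assert np.array_equal(a.labels, b.labels)

    @pytest.mark.parametrize("rate", [-0.1, 1.1])
    def test_invalid_rate_rejected(self, default_phantom, rate):
        _, labels, _ = default_phantom
        with pytest.raises(ValueError):
            perturb_segmentation(labels, rate)


class TestProtocol:
    def test_uniform_matches_acquisition_scheme(self):
        proto = DWIProtocol.uniform()
        assert proto.n_volumes == 143
        assert (proto.bvals == 1500.0).sum() == 128
        assert (proto.bvals == 0.0).sum() == 15
        norms = np.linalg.norm(proto.bvecs[proto.dwi_mask], axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)

    def test_nonunit_gradient_rejected(self):
        with pytest.raises(ValueError):
            DWIProtocol(np.array([1500.0]), np.array([[1.0, 1.0, 0.0]]))
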