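import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dosekit import (
    BeamSetup,
    Pose,
    Spectrum,
    beam_contains,
    load_spectrum,
    make_analytic_spectrum,
    reference_point,
    sample_spectrum_energy,
    source_pose,
)


def random_rotation(seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def make_setup(**kw):
    defaults = dict(primary_angle=0.0, sod=800.0, sid=1200.0,
                    opening_phi=3.0, opening_theta=2.0,
                    spectrum=Spectrum(np.array([60.0]), np.array([1.0]), 60.0))
    defaults.update(kw)
    return BeamSetup(**defaults)


class TestPose:
    @given(st.integers(0, 50))
    @settings(max_examples=25, deadline=None)
    def test_inverse_composes_to_identity(self, seed):
        rng = np.random.default_rng(seed + 1000)
        p = Pose(random_rotation(seed), rng.normal(size=3) * 100)
        ident = p.inverse() @ p
        np.testing.assert_allclose(ident.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(ident.translation, 0.0, atol=1e-9)

    @given(st.integers(0, 30))
    @settings(max_examples=15, deadline=None)
    def test_composition_associative(self, seed):
        poses = [Pose(random_rotation(seed * 3 + k),
                      np.random.default_rng(seed * 3 + k).normal(size=3))
                 for k in range(3)]
        a, b, c = poses
        left = (a @ b) @ c
        right = a @ (b @ c)
        np.testing.assert_allclose(left.rotation, right.rotation, atol=1e-12)
        np.testing.assert_allclose(left.translation, right.translation, atol=1e-9)

    def test_identity_neutral(self):
        p = Pose(random_rotation(7), np.array([1.0, 2.0, 3.0]))
        q = p @ Pose.identity()
        np.testing.assert_allclose(q.rotation, p.rotation)
        np.testing.assert_allclose(q.translation, p.translation)

    def test_improper_rotation_rejected(self):
        with pytest.raises(ValueError):
            Pose(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestSourcePose:
    def test_pa_source_position(self):
        pose = source_pose(make_setup(primary_angle=0.0, sod=800.0))
        np.testing.assert_allclose(pose.translation, [0.0, -800.0, 0.0], atol=1e-9)

    @pytest.mark.parametrize("angle", [0.0, 30.0, 45.0, 90.0, 135.0])
    def test_source_distance_is_sod(self, angle):
        setup = make_setup(primary_angle=angle)
        pose = source_pose(setup)
        assert np.linalg.norm(pose.translation - setup.isocenter) == pytest.approx(800.0)

    def test_lateral_is_rotated_pa(self):
        p0 = source_pose(make_setup(primary_angle=0.0)).translation
        p90 = source_pose(make_setup(primary_angle=90.0)).translation
        a = np.deg2rad(90)
        Rz = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
        np.testing.assert_allclose(p90, Rz @ p0, atol=1e-9)

    def test_central_ray_points_at_isocenter(self):
        setup = make_setup(primary_angle=45.0)
        pose = source_pose(setup)
        ray = pose.rotation[:, 2]
        np.testing.assert_allclose(pose.translation + setup.sod * ray,
                                   setup.isocenter, atol=1e-9)


class TestBeamContains:
    def test_isocenter_inside(self):
        assert beam_contains(make_setup(), np.zeros(3))

    def test_just_outside_phi_edge(self):
        setup = make_setup(opening_phi=3.0)
        pose = source_pose(setup)
        d = 900.0
        off = np.tan(np.deg2rad(4.0)) * d
        point = pose.translation + pose.rotation @ np.array([off, 0.0, d])
        assert not beam_contains(setup, point)
        inside = pose.translation + pose.rotation @ np.array(
            [np.tan(np.deg2rad(2.0)) * d, 0.0, d])
        assert beam_contains(setup, inside)

    def test_source_point_rejected(self):
        setup = make_setup()
        with pytest.raises(ValueError, match="source"):
            beam_contains(setup, source_pose(setup).translation)

    def test_agrees_with_detector_plane_projection(self):
        """Oracle: project each point onto the detector plane and compare
        against the rectangular field extents there."""
        setup = make_setup(primary_angle=37.0, opening_phi=4.0, opening_theta=1.5)
        pose = source_pose(setup)
        rng = np.random.default_rng(11)
        pts = rng.uniform(-300, 300, size=(1000, 3))
        for p in pts:
            local = pose.rotation.T @ (p - pose.translation)
            if abs(local[2]) < 1.0:
                continue
            if local[2] <= 0:
                expect = False
            else:
                u = local[0] / local[2] * setup.sid
                v = local[1] / local[2] * setup.sid
                half_u = np.tan(np.deg2rad(setup.opening_phi)) * setup.sid
                half_v = np.tan(np.deg2rad(setup.opening_theta)) * setup.sid
                expect = abs(u) <= half_u and abs(v) <= half_v
            assert beam_contains(setup, p) == expect

    @given(st.floats(-180, 180), st.integers(0, 20))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_joint_rigid_motion(self, alpha, seed):
        """Rotating the C-arm and the point jointly about the longitudinal
        axis (plus a common translation) must not change containment."""
        rng = np.random.default_rng(seed)
        p = rng.uniform(-150, 150, size=3)
        t = rng.uniform(-50, 50, size=3)
        base = make_setup(primary_angle=10.0)
        a = np.deg2rad(alpha)
        Rz = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
        moved = make_setup(primary_angle=10.0 + alpha, isocenter=Rz @ base.isocenter + t)
        assert beam_contains(base, p) == beam_contains(moved, Rz @ p + t)


class TestReferencePoint:
    def test_default_offset_distance_from_source(self):
        setup = make_setup(sod=800.0)
        rp = reference_point(setup)
        assert np.linalg.norm(rp - source_pose(setup).translation) == pytest.approx(650.0)

    def test_zero_offset_is_isocenter(self):
        np.testing.assert_allclose(reference_point(make_setup(), 0.0), np.zeros(3))

    def test_collinear_with_central_ray(self):
        setup = make_setup(primary_angle=63.0)
        rp = reference_point(setup, 120.0)
        src = source_pose(setup).translation
        cross = np.cross(rp - src, setup.isocenter - src)
        assert np.linalg.norm(cross) < 1e-9 * 800 * 800

    def test_offset_beyond_source_rejected(self):
        with pytest.raises(ValueError, match="offset"):
            reference_point(make_setup(sod=800.0), 800.0)


class TestSpectra:
    def test_csv_single_bin_is_delta(self, tmp_path):
        path = tmp_path / "sp.csv"
        path.write_text("energy_keV,relative_fluence\n59.5,3.2\n")
        sp = load_spectrum(path)
        assert sp.energies.tolist() == [59.5]
        assert sp.weights.tolist() == [1.0]

    def test_malformed_csv_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("kev,stuff\n10,1\n")
        with pytest.raises(ValueError, match="columns"):
            load_spectrum(path)

    def test_analytic_endpoint(self):
        sp = make_analytic_spectrum(90.0)
        assert sp.energies.max() <= 90.0
        assert sp.weights[sp.energies > 89.5].sum() < 1e-6

    def test_copper_hardens_beam(self):
        bare = make_analytic_spectrum(90.0)
        hard = make_analytic_spectrum(90.0, filtration_mm=0.3)
        # summation oracle for the mean energy
        mean = lambda s: sum(e * w for e, w in zip(s.energies, s.weights))
        assert mean(hard) > mean(bare)

    def test_normalization_idempotent(self):
        sp = Spectrum(np.array([30.0, 60.0]), np.array([2.0, 6.0]), kvp=70.0)
        again = Spectrum(sp.energies, sp.weights, kvp=70.0)
        np.testing.assert_allclose(again.weights, sp.weights)
        assert sp.weights.sum() == pytest.approx(1.0)

    def test_energy_above_kvp_rejected(self):
        with pytest.raises(ValueError, match="kVp"):
            Spectrum(np.array([80.0]), np.array([1.0]), kvp=70.0)

    def test_unknown_filtration_material(self):
        with pytest.raises(ValueError, match="unknown filtration"):
            make_analytic_spectrum(90.0, filtration_mm=1.0,
                                   filtration_material="unobtainium")


class TestSampling:
    def test_delta_always_that_energy(self, mono60):
        rng = np.random.default_rng(0)
        draws = sample_spectrum_energy(mono60, rng, size=1000)
        assert np.all(draws == 60.0)

    def test_two_equal_bins_split_within_4_sigma(self):
        sp = Spectrum(np.array([30.0, 60.0]), np.array([1.0, 1.0]), kvp=70.0)
        n = 100_000
        draws = sample_spectrum_energy(sp, np.random.default_rng(42), size=n)
        n_low = int(np.sum(draws == 30.0))
        assert abs(n_low - n / 2) <= 4 * np.sqrt(n * 0.25)

    def test_same_seed_same_sequence(self, spectrum_120):
        a = sample_spectrum_energy(spectrum_120, np.random.default_rng(7), size=500)
        b = sample_spectrum_energy(spectrum_120, np.random.default_rng(7), size=500)
        assert np.array_equal(a, b)


class TestBeamSetupValidation:
    def test_sod_must_be_below_sid(self):
        with pytest.raises(ValueError, match="SOD"):
            make_setup(sod=1300.0)

    @pytest.mark.parametrize("phi", [0.0, 50.0])
    def test_opening_angle_range(self, phi):
        with pytest.raises(ValueError, match="opening"):
            make_setup(opening_phi=phi)
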