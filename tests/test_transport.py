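import numpy as np
import pytest

from dosekit import (
    BeamSetup,
    LabelVolume,
    ScalarVolume,
    Spectrum,
    beam_mask,
    estimate_uncertainty,
    scale_to_air_kerma,
    simulate,
)
from dosekit.transport import DoseResult

from oracles import absorption_only_library, expected_first_interaction_deposits


def pencil_setup(mono, phi=0.02, theta=0.02):
    return BeamSetup(primary_angle=0.0, sod=800.0, sid=1200.0,
                     opening_phi=phi, opening_theta=theta, spectrum=mono)


@pytest.fixture(scope="module")
def water_slab(lib=None):
    from dosekit import build_material_library
    lib = build_material_library()
    # 9x9 columns, 40 voxels deep along the beam (y), 2 mm voxels
    labels = np.full((9, 40, 9), lib.label_for("water"), dtype=np.int16)
    vol = LabelVolume(labels, (2.0, 2.0, 2.0), (-9.0, -40.0, -9.0))
    return vol, lib


class TestAnalyticTransport:
    def test_beer_lambert_primary_attenuation(self, water_slab, mono60):
        """Surviving-primary fraction vs depth follows exp(-mu d) within
        3 sigma at 1e6 histories (absorption-only water, 60 keV pencil)."""
        vol, lib = water_slab
        photo = absorption_only_library(lib)
        n = 1_000_000
        res = simulate(vol, photo, pencil_setup(mono60), n, seed=5, n_batches=5)
        mu_mm = lib.by_name("water").mu_rho_at(60.0) * 1.0 / 10.0
        edep = (res.primary_dose.values + res.scatter_dose.values)
        # back to energy per voxel, summed over each depth plane
        mass = 1.0 * vol.voxel_volume_cm3
        plane_kev = edep.sum(axis=(0, 2)) * mass / 1.602176634e-10
        frac_interacted = np.cumsum(plane_kev) / (n * 60.0)
        for depth_voxels in (5, 10, 20, 40):
            d_mm = depth_voxels * 2.0
            surviving = 1.0 - frac_interacted[depth_voxels - 1]
            p = np.exp(-mu_mm * d_mm)
            sigma = np.sqrt(p * (1 - p) / n)
            assert abs(surviving - p) <= 3 * sigma, (depth_voxels, surviving, p)

    def test_delta_tracking_matches_ray_march_oracle(self, mono60):
        """Woodcock tracking on a heterogeneous 8^3 phantom agrees with the
        closed-form ray-marched expectation within 3 sigma per voxel."""
        from dosekit import build_material_library
        lib = build_material_library()
        labels = np.full((8, 8, 8), lib.label_for("water"), dtype=np.int16)
        labels[:, 2:4, :] = lib.label_for("bone")
        labels[:, 6, :] = lib.label_for("adipose")
        vol = LabelVolume(labels, (2.0, 2.0, 2.0), (-8.0, -8.0, -8.0))
        photo = absorption_only_library(lib)
        # pencil beam through the column of voxels at x index 4, z index 4
        iso = np.array([1.0, 0.0, 1.0])
        setup = BeamSetup(primary_angle=0.0, sod=800.0, sid=1200.0,
                          opening_phi=0.01, opening_theta=0.01,
                          spectrum=mono60, isocenter=iso)
        n = 400_000
        res = simulate(vol, photo, setup, n, seed=9, n_batches=10)
        col_labels = labels[4, :, 4]
        mu_mm = np.array([lib[int(l)].mu_rho_at(60.0) * lib[int(l)].density / 10.0
                          for l in col_labels])
        expected_kev = expected_first_interaction_deposits(
            mu_mm, np.full(8, 2.0), 60.0) * n
        mass = np.array([lib[int(l)].density for l in col_labels]) * vol.voxel_volume_cm3
        total = res.primary_dose.values + res.scatter_dose.values
        got_kev = total[4, :, 4] * mass / 1.602176634e-10
        sigma = np.sqrt(np.maximum(expected_kev * 60.0, 1.0))  # Poisson, 60 keV quanta
        assert np.all(np.abs(got_kev - expected_kev) <= 3 * sigma), (
            got_kev, expected_kev)


class TestBookkeeping:
    def test_air_only_phantom(self, lib, mono60):
        labels = LabelVolume(np.zeros((8, 8, 8), dtype=np.int16),
                             (4.0, 4.0, 4.0), (-16.0, -16.0, -16.0))
        with pytest.warns(UserWarning, match="does not intersect"):
            res = simulate(labels, lib, pencil_setup(mono60, 1.0, 1.0),
                           50_000, seed=1, n_batches=2)
        assert res.ref_point_air_kerma > 0
        assert res.energy_deposited_kev / res.energy_emitted_kev < 5e-3

    def test_seeded_determinism(self, head64, lib, head_setup):
        a = simulate(head64, lib, head_setup, 50_000, seed=3, n_batches=5)
        b = simulate(head64, lib, head_setup, 50_000, seed=3, n_batches=5)
        assert np.array_equal(a.primary_dose.values, b.primary_dose.values)
        assert np.array_equal(a.scatter_dose.values, b.scatter_dose.values)
        assert a.ref_point_air_kerma == b.ref_point_air_kerma

    def test_batch_partition_does_not_change_physics(self, head64, lib, head_setup):
        """Counter-based per-history streams: 2 vs 5 batches, same dose."""
        a = simulate(head64, lib, head_setup, 40_000, seed=4, n_batches=2)
        b = simulate(head64, lib, head_setup, 40_000, seed=4, n_batches=5)
        np.testing.assert_allclose(a.total_dose.values, b.total_dose.values,
                                   rtol=1e-12, atol=1e-300)

    def test_energy_conservation(self, head64, lib, head_setup):
        res = simulate(head64, lib, head_setup, 200_000, seed=2, n_batches=4)
        balance = res.energy_deposited_kev + res.energy_escaped_kev
        assert abs(balance - res.energy_emitted_kev) / res.energy_emitted_kev < 1e-6

    def test_total_is_primary_plus_scatter(self, head64, lib, head_setup):
        res = simulate(head64, lib, head_setup, 30_000, seed=6, n_batches=3)
        np.testing.assert_allclose(
            res.total_dose.values,
            res.primary_dose.values + res.scatter_dose.values)

    def test_scatter_zero_when_channels_disabled(self, head64, lib, head_setup):
        photo = absorption_only_library(lib)
        res = simulate(head64, photo, head_setup, 100_000, seed=7, n_batches=4)
        assert np.all(res.scatter_dose.values == 0.0)
        assert res.primary_dose.values.sum() > 0

    def test_primary_dose_confined_to_collimation(self, head64, lib, head_setup):
        """Primary dose appears only in voxels that intersect the beam
        pyramid (checked on voxel corners); scatter may leak outside."""
        res = simulate(head64, lib, head_setup, 300_000, seed=8, n_batches=4)
        hit = res.primary_dose.values > 0
        corners_inside = np.zeros(head64.shape, dtype=bool)
        sx, sy, sz = head64.spacing
        for dx in (-0.5, 0.5):
            for dy in (-0.5, 0.5):
                for dz in (-0.5, 0.5):
                    shifted = LabelVolume(head64.labels, head64.spacing,
                                          (head64.origin[0] + dx * sx,
                                           head64.origin[1] + dy * sy,
                                           head64.origin[2] + dz * sz))
                    corners_inside |= beam_mask(head_setup, shifted)
        assert not np.any(hit & ~corners_inside)
        assert np.any(res.scatter_dose.values[~corners_inside] > 0)

    def test_empty_beam_intersection_warns(self, head64, lib, spectrum_120):
        setup = BeamSetup(primary_angle=0.0, sod=800.0, sid=1200.0,
                          opening_phi=1.0, opening_theta=1.0,
                          spectrum=spectrum_120,
                          isocenter=np.array([500.0, 0.0, 0.0]))
        with pytest.warns(UserWarning, match="does not intersect"):
            res = simulate(head64, lib, setup, 10_000, seed=1, n_batches=2)
        assert res.total_dose.values.sum() == 0.0


def _result_from_batches(batches):
    batches = np.asarray(batches, dtype=np.float32)
    total = batches.sum(axis=0).astype(float)
    half = total / 2
    return DoseResult(
        primary_dose=ScalarVolume(half), scatter_dose=ScalarVolume(half),
        n_histories=100, batch_doses=batches, ref_point_air_kerma=1.0,
        seed=0, energy_emitted_kev=1.0, energy_escaped_kev=0.0,
        energy_deposited_kev=1.0)


class TestUncertainty:
    def test_identical_batches_zero(self):
        b = np.ones((4, 2, 2, 2))
        res = _result_from_batches(b)
        assert np.all(estimate_uncertainty(res).values == 0.0)

    def test_two_batch_closed_form(self):
        a, c = 3.0, 5.0
        batches = np.zeros((2, 1, 1, 1))
        batches[0, 0, 0, 0] = a
        batches[1, 0, 0, 0] = c
        rel = estimate_uncertainty(_result_from_batches(batches)).values[0, 0, 0]
        assert rel == pytest.approx(100.0 * 2 * abs(a - c) / (a + c))

    def test_zero_dose_flagged_100_percent(self):
        res = _result_from_batches(np.zeros((3, 1, 1, 1)))
        assert estimate_uncertainty(res).values[0, 0, 0] == 100.0

    def test_single_batch_rejected(self):
        res = _result_from_batches(np.ones((1, 1, 1, 1)))
        with pytest.raises(ValueError, match="two batches"):
            estimate_uncertainty(res)

    def test_sqrt_n_scaling(self, head64, lib, head_setup):
        body = head64.labels > 0
        in_beam = beam_mask(head_setup, head64) & body
        med = {}
        for n in (150_000, 600_000):
            res = simulate(head64, lib, head_setup, n, seed=12, n_batches=10)
            med[n] = np.median(estimate_uncertainty(res).values[in_beam])
        ratio = med[600_000] / med[150_000]
        assert ratio == pytest.approx(0.5, rel=0.2)


class TestAirKermaScaling:
    def test_measured_over_simulated_factor(self, head64, lib, head_setup):
        res = simulate(head64, lib, head_setup, 20_000, seed=1, n_batches=2)
        res.ref_point_air_kerma = 2.0
        scaled = scale_to_air_kerma(res, 49.28)
        np.testing.assert_allclose(scaled.primary_dose.values,
                                   res.primary_dose.values * 24.64)
        assert scaled.ref_point_air_kerma == 49.28

    def test_identity_when_equal(self, head64, lib, head_setup):
        res = simulate(head64, lib, head_setup, 20_000, seed=1, n_batches=2)
        scaled = scale_to_air_kerma(res, res.ref_point_air_kerma)
        np.testing.assert_allclose(scaled.total_dose.values,
                                   res.total_dose.values)

    def test_round_trip_linearity(self, head64, lib, head_setup):
        res = simulate(head64, lib, head_setup, 20_000, seed=1, n_batches=2)
        k = res.ref_point_air_kerma
        back = scale_to_air_kerma(scale_to_air_kerma(res, 7.5 * k), k)
        np.testing.assert_allclose(back.total_dose.values,
                                   res.total_dose.values, rtol=1e-12)

    def test_zero_simulated_kerma_rejected(self):
        res = _result_from_batches(np.ones((2, 1, 1, 1)))
        res.ref_point_air_kerma = 0.0
        with pytest.raises(ValueError, match="kerma"):
            scale_to_air_kerma(res, 10.0)
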