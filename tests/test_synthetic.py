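"""Generator contracts: prescribed stationary statistics and reproducibility."""

import numpy as np
import pytest

from vsdye import (
    GapGenSpec,
    OrientationGenSpec,
    PotentialFractionProfile,
    TrackGenSpec,
    VoltageCondition,
    block_average,
    generate_atom_tracks,
    generate_energy_gap_series,
    generate_orientation_series,
    generate_potential_grids,
    interpolate_f,
    potential_fraction_profile,
)

COND0_ES = VoltageCondition(v_mp=0.0, state="excited")
COND0_GS = VoltageCondition(v_mp=0.0, state="ground")


class TestEnergyGapSeries:
    def test_zero_noise_series_is_exactly_constant(self):
        spec = GapGenSpec(mu0=59.8181, kappa=0.0, sigma=0.0, rho=0.0)
        s = generate_energy_gap_series(spec, COND0_ES, 100, seed=1)
        assert np.all(s.values == 59.8181)

    def test_sample_mean_converges_to_stationary_mean(self):
        # iid case: 3-sigma law-of-large-numbers band around the target mean
        spec = GapGenSpec(mu0=67.0694, kappa=0.0, sigma=2.0, rho=0.0)
        s = generate_energy_gap_series(spec, COND0_GS, 10**5, seed=42)
        assert abs(s.values.mean() - 67.0694) < 3 * 2.0 / np.sqrt(10**5)

    def test_voltage_sensitivity_shifts_the_mean(self):
        spec = GapGenSpec(mu0=60.0, kappa=0.002, sigma=0.0, rho=0.0)
        s = generate_energy_gap_series(
            spec, VoltageCondition(v_mp=-500.0, state="excited"), 10, seed=0
        )
        assert np.allclose(s.values, 59.0)

    def test_lag1_autocorrelation_matches_ar1_closed_form(self):
        spec = GapGenSpec(mu0=0.0, kappa=0.0, sigma=1.0, rho=0.8)
        x = generate_energy_gap_series(spec, COND0_ES, 10**5, seed=3).values
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r1 - 0.8) < 0.02
        assert abs(x.std() - 1.0) < 0.02

    def test_fixed_seed_is_bit_identical(self):
        spec = GapGenSpec(mu0=50.0, sigma=2.0, rho=0.9)
        a = generate_energy_gap_series(spec, COND0_ES, 5000, seed=99)
        b = generate_energy_gap_series(spec, COND0_ES, 5000, seed=99)
        assert np.array_equal(a.values, b.values)

    @pytest.mark.parametrize("n", [0, -5])
    def test_non_positive_frame_count_rejected(self, n):
        with pytest.raises(ValueError, match="n_frames"):
            generate_energy_gap_series(GapGenSpec(mu0=1.0), COND0_ES, n, seed=0)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            GapGenSpec(mu0=1.0, sigma=-0.1)

    def test_rho_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            GapGenSpec(mu0=1.0, rho=1.0)


class TestAtomTracks:
    def test_zero_sd_track_is_constant_at_its_mean(self):
        # bundled es/0 mV default for the amino nitrogen, noise switched off
        spec = TrackGenSpec(stats={"N2": (7.5, 0.0)}, rho=0.0)
        tracks = generate_atom_tracks(spec, COND0_ES, 50, seed=5)
        assert np.all(tracks["N2"].z == 7.5)

    def test_single_frame_zero_sd_equals_mean(self):
        spec = TrackGenSpec(stats={"S": (22.1, 0.0)})
        tracks = generate_atom_tracks(spec, COND0_GS, 1, seed=5)
        assert len(tracks["S"]) == 1 and tracks["S"].z[0] == 22.1

    def test_sulfur_mean_recovery_within_3_block_se(self):
        spec = TrackGenSpec(stats={"S": (22.1, 2.5)}, rho=0.9)
        tracks = generate_atom_tracks(spec, COND0_GS, 10**5, seed=8)
        mean, se = block_average(tracks["S"].z, n_blocks=10)
        assert abs(mean - 22.1) < 3 * se

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown atom label"):
            TrackGenSpec(stats={"P": (1.0, 0.1)})

    def test_fixed_seed_is_bit_identical(self):
        spec = TrackGenSpec(stats={"S": (22.1, 2.5), "N1": (18.1, 2.3)})
        a = generate_atom_tracks(spec, COND0_GS, 2000, seed=7)
        b = generate_atom_tracks(spec, COND0_GS, 2000, seed=7)
        for label in a:
            assert np.array_equal(a[label].z, b[label].z)


class TestOrientationSeries:
    def test_zero_sd_zero_mean_gives_membrane_normal(self):
        o = generate_orientation_series(OrientationGenSpec(0.0, 0.0), 10, seed=1)
        assert np.allclose(o.vectors[:, 2], 1.0)
        assert np.allclose(o.vectors[:, :2], 0.0)

    def test_zero_sd_in_plane_tilt_is_exactly_90(self):
        o = generate_orientation_series(OrientationGenSpec(90.0, 0.0), 10, seed=1)
        assert np.allclose(o.tilt_angles(), 90.0)

    def test_vectors_are_unit_length(self):
        o = generate_orientation_series(
            OrientationGenSpec(48.3, 17.6, rho=0.9), 10**4, seed=2
        )
        assert np.abs(np.linalg.norm(o.vectors, axis=1) - 1.0).max() <= 1e-9

    def test_tilt_mean_recovery(self):
        # excited-state default tilt; truncation bias at [0, 180] is ~0.16 deg
        o = generate_orientation_series(
            OrientationGenSpec(48.3, 17.6, rho=0.9), 10**5, seed=3
        )
        assert abs(o.tilt_angles().mean() - 48.3) < 0.5

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="tilt_sd"):
            OrientationGenSpec(45.0, -1.0)

    def test_fixed_seed_is_bit_identical(self):
        spec = OrientationGenSpec(25.9, 14.1, rho=0.9)
        a = generate_orientation_series(spec, 2000, seed=11)
        b = generate_orientation_series(spec, 2000, seed=11)
        assert np.array_equal(a.vectors, b.vectors)


def _sigmoid_profile():
    z = np.linspace(-36.0, 36.0, 73)
    return PotentialFractionProfile(z=z, f=1.0 / (1.0 + np.exp((z - 14.0) / 3.0)))


class TestPotentialGrids:
    def test_noiseless_grids_recover_profile_exactly(self):
        prof = _sigmoid_profile()
        gv, g0 = generate_potential_grids(prof, v_mp=-500.0, noise_sd=0.0, seed=1)
        rec = potential_fraction_profile(gv, g0, -500.0)
        truth = interpolate_f(prof, gv.z_nodes)
        assert np.allclose(rec.f, truth, rtol=1e-12, atol=1e-13)

    def test_noisy_grids_recover_profile_within_xy_averaging_band(self):
        # SD 5 mV on the grid difference, averaged over 40x40 xy voxels
        prof = _sigmoid_profile()
        gv, g0 = generate_potential_grids(prof, v_mp=-500.0, noise_sd=5.0, seed=11)
        assert gv.shape[:2] == (40, 40)
        rec = potential_fraction_profile(gv, g0, -500.0)
        truth = interpolate_f(prof, gv.z_nodes)
        tol = 3.0 * (5.0 / 500.0) / np.sqrt(40 * 40)
        assert np.abs(rec.f - truth).max() < tol

    def test_flat_zero_profile_recovers_zero_within_noise(self):
        z = np.linspace(-36.0, 36.0, 73)
        prof = PotentialFractionProfile(z=z, f=np.zeros_like(z))
        gv, g0 = generate_potential_grids(prof, v_mp=200.0, noise_sd=2.0, seed=4)
        rec = potential_fraction_profile(gv, g0, 200.0)
        tol = 3.0 * (2.0 / 200.0) / np.sqrt(40 * 40)
        assert np.abs(rec.f).max() < tol

    def test_zero_voltage_rejected(self):
        with pytest.raises(ValueError, match="v_mp"):
            generate_potential_grids(_sigmoid_profile(), v_mp=0.0)

    def test_non_positive_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            generate_potential_grids(_sigmoid_profile(), v_mp=100.0, spacing=0.0)

    def test_indivisible_spacing_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            generate_potential_grids(
                _sigmoid_profile(), v_mp=100.0, box=(60.0, 60.0, 70.0), spacing=1.5
            )

    def test_fixed_seed_is_bit_identical(self):
        prof = _sigmoid_profile()
        a = generate_potential_grids(prof, v_mp=100.0, noise_sd=3.0, seed=21)
        b = generate_potential_grids(prof, v_mp=100.0, noise_sd=3.0, seed=21)
        assert np.array_equal(a[0].values, b[0].values)
        assert np.array_equal(a[1].values, b[1].values)
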