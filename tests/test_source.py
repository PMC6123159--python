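"""Courant-Snyder optics, fitting and phase-space sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbsmc import source as S


class TestDriftOptics:
    def test_sigma_at_isocenter(self):
        assert S.sigma_at(5.0, 0.005, 0.2, 0.0) == pytest.approx(5.0)

    def test_sigma_example(self):
        # sigma0 = 5 mm, rho0 = 0, sigma_theta = 5 mrad, Z = 200 mm
        assert S.sigma_at(5.0, 0.005, 0.0, 200.0) == pytest.approx(
            np.sqrt(26.0), abs=1e-9
        )

    def test_parabola_vertex(self):
        s0, st, r0 = 5.0, 0.005, 0.3
        z_star = r0 * s0 / st
        z = np.linspace(z_star - 200, z_star + 200, 41)
        var = S.sigma_at(s0, st, r0, z) ** 2
        assert np.argmin(var) == 20  # vertex at rho0*sigma0/sigma_theta

    def test_rho_at_isocenter(self):
        assert S.rho_at(5.0, 0.005, 0.3, 0.0) == pytest.approx(0.3)

    def test_rho_sign_focusing_side(self):
        # rho0 = 0: downstream of the waist the beam is focusing toward it
        assert S.rho_at(5.0, 0.005, 0.0, 100.0) < 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        s0=st.floats(0.5, 10.0),
        st_=st.floats(1e-4, 0.02),
        r0=st.floats(-0.95, 0.95),
        z=st.floats(-300.0, 500.0),
    )
    def test_matrix_propagation_matches_closed_forms(self, s0, st_, r0, z):
        cov = S.covariance_at(s0, st_, r0, z)
        sigma = S.sigma_at(s0, st_, r0, z)
        rho = S.rho_at(s0, st_, r0, z)
        assert np.sqrt(cov[0, 0]) == pytest.approx(sigma, abs=1e-10 * max(1, sigma))
        assert cov[0, 1] / (sigma * st_) == pytest.approx(rho, abs=1e-10)
        assert cov[1, 1] == pytest.approx(st_**2, abs=1e-12)


PLANES = (455.0, 330.0, 200.0, 100.0, 0.0, -100.0)


class TestFitOptics:
    def test_noise_free_recovery(self):
        s0, st_, r0 = 5.6, 0.0055, 0.17
        meas = [(z, S.sigma_at(s0, st_, r0, z)) for z in PLANES]
        fit = S.fit_optics(meas)
        assert fit.sigma0 == pytest.approx(s0, abs=1e-6)
        assert fit.sigma_theta == pytest.approx(st_, abs=1e-9)
        assert fit.rho0 == pytest.approx(r0, abs=1e-6)
        assert fit.rms_residual_mm < 1e-9
        assert fit.physical

    def test_noisy_recovery_median(self, rng):
        # 1% sigma noise on the six standard planes (100-seed study).  The
        # spot size recovers tightly; the divergence is amplified because the
        # quadratic term contributes only ~20% of sigma^2 even at the
        # furthest plane, giving a ~10% median error at this noise level.
        s0, st_, r0 = 5.6, 0.0055, 0.17
        err_s0, err_st = [], []
        for _ in range(100):
            meas = [
                (z, S.sigma_at(s0, st_, r0, z) * (1 + 0.01 * rng.standard_normal()))
                for z in PLANES
            ]
            fit = S.fit_optics(meas)
            err_s0.append(abs(fit.sigma0 / s0 - 1))
            err_st.append(abs(fit.sigma_theta / st_ - 1))
        assert np.median(err_s0) < 0.02
        assert np.median(err_st) < 0.10

    def test_too_few_planes(self):
        with pytest.raises(ValueError):
            S.fit_optics([(0.0, 5.0), (100.0, 5.1)])

    def test_collinear_degenerate(self):
        with pytest.raises(ValueError):
            S.fit_optics([(0.0, 5.0), (0.0, 5.1), (0.0, 5.2)])


class TestEffectiveSad:
    def test_printed_fx_from_two_planes(self):
        # deflection at 100 mm iso offset: x(0) = 100, x(100) = 94.62
        f = S.fit_effective_sad([[(0.0, 100.0), (100.0, 94.62)]])
        assert f == pytest.approx(100.0 * 100.0 / (100.0 - 94.62), rel=1e-9)
        assert f == pytest.approx(1859.1, abs=0.5)

    def test_parallel_beam_flagged_infinite(self):
        f = S.fit_effective_sad([[(0.0, 100.0), (100.0, 100.0)]])
        assert np.isinf(f)

    def test_three_planes_consistent_with_two(self):
        f_true = 1859.1
        planes2 = [(z, 100.0 * (f_true - z) / f_true) for z in (0.0, 100.0)]
        planes3 = [(z, 100.0 * (f_true - z) / f_true) for z in (0.0, 100.0, 200.0)]
        assert S.fit_effective_sad([planes2]) == pytest.approx(
            S.fit_effective_sad([planes3]), abs=1e-6
        )


class TestInterpolation:
    def test_exact_at_nodes(self, machine):
        for e in machine.energies:
            opt, emod, ppmu = S.interpolate_machine(machine, e)
            assert opt == machine.optics[e]
            assert emod == machine.energy_model[e]
            assert ppmu == machine.protons_per_mu[e]

    def test_midpoint_is_mean(self, machine):
        e0, e1 = machine.energies[0], machine.energies[1]
        opt, emod, ppmu = S.interpolate_machine(machine, (e0 + e1) / 2)
        o0, o1 = machine.optics[e0], machine.optics[e1]
        assert opt.sigma0_x == pytest.approx((o0.sigma0_x + o1.sigma0_x) / 2)
        assert ppmu == pytest.approx(
            (machine.protons_per_mu[e0] + machine.protons_per_mu[e1]) / 2
        )
        assert emod.energy_spread_pct == pytest.approx(
            (machine.energy_model[e0].energy_spread_pct
             + machine.energy_model[e1].energy_spread_pct) / 2
        )

    def test_outside_band_raises(self, machine):
        with pytest.raises(ValueError):
            S.interpolate_machine(machine, 90.0)


class TestPhaseSpaceSampling:
    def test_isocenter_covariance_recovery(self, machine):
        rng = np.random.default_rng(7)
        b = S.sample_spot_phase_space(machine, 115.0, (0.0, 0.0), 100_000, rng)
        s = b.z / -b.dz  # drift path to the isocenter plane
        x_iso = b.x + b.dx * s
        theta = b.dx / np.abs(b.dz)
        opt = machine.optics[115.0]
        assert x_iso.std() == pytest.approx(opt.sigma0_x, rel=0.02)
        assert theta.std() == pytest.approx(opt.sigma_theta_x, rel=0.02)
        assert np.corrcoef(x_iso, theta)[0, 1] == pytest.approx(opt.rho0_x, abs=0.02)

    def test_sigma_follows_drift_parabola(self, machine):
        rng = np.random.default_rng(8)
        b = S.sample_spot_phase_space(machine, 150.0, (0.0, 0.0), 100_000, rng)
        opt = machine.optics[150.0]
        for zp in (455.0, 200.0, 0.0, -100.0):
            xp = b.x + b.dx * ((b.z - zp) / -b.dz)
            expected = S.sigma_at(*opt.axis("x"), zp)
            assert xp.std() == pytest.approx(expected, rel=0.02)

    def test_scan_aiming(self, machine):
        rng = np.random.default_rng(9)
        b = S.sample_spot_phase_space(machine, 115.0, (100.0, 0.0), 50_000, rng)
        tangent = (b.dx / np.abs(b.dz)).mean()
        assert tangent == pytest.approx(100.0 / 1859.1, rel=0.02)

    def test_vacuum_drift_preserves_divergence(self, machine):
        rng = np.random.default_rng(10)
        b = S.sample_spot_phase_space(machine, 115.0, (0.0, 0.0), 50_000, rng)
        # divergence is a property of the direction vectors alone; any drift
        # leaves them untouched by construction
        theta = b.dx / np.abs(b.dz)
        assert theta.std() == pytest.approx(
            machine.optics[115.0].sigma_theta_x, rel=0.03
        )

    def test_energy_outside_band(self, machine):
        with pytest.raises(ValueError):
            S.sample_spot_phase_space(machine, 80.0, (0.0, 0.0), 10, 0)


class TestMachineIO:
    def test_round_trip(self, machine, tmp_path):
        path = tmp_path / "machine.json"
        machine.save(path)
        loaded = S.MachineModel.load(path)
        assert loaded.energies == machine.energies
        assert loaded.optics == machine.optics
        assert loaded.energy_model == machine.energy_model
        assert loaded.protons_per_mu == machine.protons_per_mu
        assert loaded.geometry == machine.geometry
        assert loaded.range_shifter == machine.range_shifter
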