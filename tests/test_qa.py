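"""QA analysis: FSF, profile metrics, gamma index, DVH, radial halo."""

import numpy as np
import pytest
from scipy.special import erf

from pbsmc import qa


def make_grid(dose_array, spacing=1.0):
    """Wrap a 3D array in a DoseGrid-like object centered on the axis."""
    from pbsmc.transport import DoseGrid

    nx, ny, nz = dose_array.shape
    g = DoseGrid(
        origin=(-nx * spacing / 2, -ny * spacing / 2, -nz * spacing),
        shape=dose_array.shape,
        spacing=(spacing, spacing, spacing),
    )
    g.energy = dose_array.astype(float)
    return g


class TestFieldSizeFactor:
    def test_reference_is_unity(self):
        g = make_grid(np.ones((60, 60, 30)))
        fsf = qa.field_size_factor({40.0: g, 100.0: g}, 10.0, 100.0)
        assert fsf[100.0] == 1.0
        assert fsf[40.0] == pytest.approx(1.0)

    def test_monotone_with_field_size(self, machine, kernel_115):
        # nested square fields: central dose non-decreasing with size
        doses = qa.kernel_central_doses(kernel_115, [40.0, 48.0, 96.0, 200.0],
                                        [30.0])
        values = [doses[s][0] for s in (40.0, 48.0, 96.0, 200.0)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_kernel_fsf_difference_low_energy(self, kernel_115):
        # 115 MeV, no range shifter: 40 vs 200 mm differ by a few percent
        doses = qa.kernel_central_doses(kernel_115, [40.0, 200.0],
                                        [30.0, 40.0, 50.0])
        rel = 100.0 * (1.0 - doses[40.0] / doses[200.0])
        assert np.all(rel > 1.0)
        assert np.all(rel < 5.0)


class TestLateralProfile:
    def test_error_function_edge_penumbra(self):
        # edge blurred with Gaussian sigma: 20-80% penumbra = 1.683 sigma
        sigma = 4.0
        x = np.linspace(-80, 80, 1601)
        profile = 0.5 * (erf((x + 40) / (sigma * np.sqrt(2)))
                         - erf((x - 40) / (sigma * np.sqrt(2))))
        m = qa.lateral_profile_metrics(x, profile)
        expected = 1.6832 * sigma  # z(0.8) - z(0.2) quantile distance
        assert m.penumbra_20_80_mm == pytest.approx(expected, rel=0.01)

    def test_rectangular_profile(self):
        x = np.linspace(-50, 50, 201)
        profile = np.where(np.abs(x) <= 25, 1.0, 0.0)
        m = qa.lateral_profile_metrics(x, profile)
        assert m.penumbra_20_80_mm < 0.5
        assert m.halfwidth_95_mm == pytest.approx(25.0, abs=0.5)
        assert m.halfwidth_5_mm == pytest.approx(25.0, abs=0.5)

    def test_mid_sobp_penumbra_matches_refined_grid(self, machine, kernel_115):
        # profile metrics are stable under a finer analysis grid (0.5 mm)
        from pbsmc.transport import DoseGrid, Geometry, simulate_spot, water_box

        fine = DoseGrid(
            origin=(-60.0, -60.0, -60.0), shape=(240, 240, 120),
            spacing=(0.5, 0.5, 0.5),
        )
        geom = Geometry([water_box(0.0, 115.0)])
        simulate_spot(machine, 115.0, n=200_000, seed=31, geometry=geom,
                      scorers=(fine,))
        metrics = []
        for grid, depth in ((kernel_115, 50.0), (fine, 50.0)):
            iz = grid.shape[2] - 1 - int(depth / grid.spacing[2])
            yc = np.abs(grid.centers(1)) < 3.0
            prof = grid.energy[:, yc, iz].mean(axis=1)
            metrics.append(qa.lateral_profile_metrics(grid.centers(0), prof))
        assert metrics[0].penumbra_20_80_mm == pytest.approx(
            metrics[1].penumbra_20_80_mm, abs=0.5
        )


class TestGamma:
    def test_identical_grids_pass_fully(self):
        ref = np.random.default_rng(1).random((20, 20)) + 0.5
        assert qa.gamma_index(ref, ref, 3.0, 3.0) == 100.0

    def test_uniform_scaling_criterion_boundary(self):
        ref = np.ones((15, 15))
        assert qa.gamma_index(ref, ref * 1.069, 7.0, 5.0) == 100.0
        assert qa.gamma_index(ref, ref * 1.075, 7.0, 5.0) < 100.0

    def test_rigid_shift_within_dta(self):
        # 4 mm shift of a 10 mm-sigma Gaussian passes 7%/5 mm
        x = np.arange(-40, 41.0)
        xx, yy = np.meshgrid(x, x, indexing="ij")
        ref = np.exp(-(xx**2 + yy**2) / (2 * 10.0**2))
        ev = np.exp(-((xx - 4.0) ** 2 + yy**2) / (2 * 10.0**2))
        assert qa.gamma_index(ref, ev, 7.0, 5.0) == 100.0

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(2)
        base = rng.random((12, 12))
        from scipy.ndimage import gaussian_filter

        ref = gaussian_filter(base, 2.0) + 0.3
        ev = ref * (1 + 0.02 * gaussian_filter(rng.standard_normal((12, 12)), 1.5))
        fast = qa.gamma_index(ref, ev, 2.0, 2.0, subsample=8)
        brute = qa.gamma_index_brute(ref, ev, 2.0, 2.0, upsample=8)
        assert fast == pytest.approx(brute, abs=2.0)

    def test_asymmetry_under_swap(self):
        # gamma is not symmetric: swapping ref and eval can change the rate
        x = np.arange(-30, 31.0)
        xx, yy = np.meshgrid(x, x, indexing="ij")
        ref = np.exp(-(xx**2 + yy**2) / (2 * 6.0**2))
        ev = 1.1 * np.exp(-(xx**2 + yy**2) / (2 * 7.5**2))
        r1 = qa.gamma_index(ref, ev, 3.0, 2.0)
        r2 = qa.gamma_index(ev, ref, 3.0, 2.0)
        assert r1 != r2


class TestDvh:
    def test_uniform_dose(self):
        d = np.full((10, 10, 10), 2.5)
        assert qa.dvh_stat(d, 95) == pytest.approx(2.5)
        assert qa.dvh_stat(d, 2) == pytest.approx(2.5)

    def test_linear_ramp(self):
        d = np.linspace(0, 100, 100_001)
        assert qa.dvh_stat(d, 95) == pytest.approx(5.0, abs=0.01)
        assert qa.dvh_stat(d, 2) == pytest.approx(98.0, abs=0.01)

    def test_endpoints(self):
        d = np.random.default_rng(3).random(1000)
        assert qa.dvh_stat(d, 0) == pytest.approx(d.max())
        assert qa.dvh_stat(d, 100) == pytest.approx(d.min())

    def test_matches_sort_based_brute_force(self):
        rng = np.random.default_rng(4)
        d = rng.random((20, 20, 5))
        mask = rng.random((20, 20, 5)) > 0.4
        for q in (95.0, 50.0, 2.0):
            v = np.sort(d[mask].ravel())
            brute = np.quantile(v, 1 - q / 100.0)
            assert qa.dvh_stat(d, q, mask) == pytest.approx(brute, abs=1e-9)

    def test_cumulative_curve_monotone(self):
        d = np.random.default_rng(5).random(5000)
        levels, frac = qa.dvh(d)
        assert frac[0] == 1.0
        assert np.all(np.diff(frac) <= 1e-12)


class TestRadialHalo:
    def test_pure_gaussian_no_halo(self):
        x = np.arange(-200, 200.5, 1.0)
        xx, yy = np.meshgrid(x, x, indexing="ij")
        spot = np.exp(-(xx**2 + yy**2) / (2 * 5.0**2))
        frac = qa.radial_halo_fraction(spot, x, x, [40.0])
        assert frac[0] == pytest.approx(1.0, abs=1e-8)

    def test_monotone_in_radius(self):
        rng = np.random.default_rng(6)
        x = np.arange(-200, 200.5, 2.0)
        img = rng.random((x.size, x.size))
        frac = qa.radial_halo_fraction(img, x, x, [20, 50, 100, 150, 200])
        assert np.all(np.diff(frac) >= 0)
        assert frac[-1] == pytest.approx(1.0)

    def test_halo_grows_with_air_gap_after_range_shifter(self, machine):
        from pbsmc import materials as M
        from pbsmc import transport as T

        rs_bot = 395.0
        pl = T.PlaneScorer([rs_bot - 5.0, rs_bot - 150.0], halfsize_mm=220.0,
                           bin_mm=1.0)
        geom = T.Geometry([T.Region(460.0, rs_bot, material=M.LEXAN)])
        T.simulate_spot(machine, 115.0, n=100_000, seed=32, geometry=geom,
                        scorers=(pl,))
        ax = pl.axes()
        metric = [
            1.0 - qa.radial_halo_fraction(pl.energy_fluence[i], ax, ax, [40.0])[0]
            for i in (0, 1)
        ]
        assert metric[1] > metric[0]
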