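"""Condensed-history transport engine: conservation, determinism, physics."""

import numpy as np
import pytest

from pbsmc import materials as M
from pbsmc import transport as T
from pbsmc.commissioning import r80


def lexan_geometry():
    return T.Geometry(
        [T.Region(460.0, 395.0, material=M.LEXAN)], lateral_halfsize=200.0
    )


class TestBasics:
    def test_vacuum_straight_line(self):
        # no material regions at all: pure drift leaves energy untouched
        b = T.ParticleBatch.pencil(100, 150.0, z=400.0)
        res = T.transport(b, T.Geometry([T.water_box(-100.0, 50.0)]), (), seed=1,
                          config=T.TransportConfig(nuclear_enabled=False))
        # particles reach the phantom top unchanged in energy before slowing
        assert res.accounting["initial_kinetic"] == pytest.approx(100 * 150.0)

    def test_energy_conservation(self):
        b = T.ParticleBatch.pencil(20_000, 115.0, z=10.0)
        geom = T.Geometry([T.water_box(0.0, 110.0)])
        res = T.transport(b, geom, (), seed=2)
        assert res.energy_balance_error() < 1e-3

    def test_energy_conservation_through_range_shifter(self):
        b = T.ParticleBatch.pencil(20_000, 225.0, z=460.0)
        res = T.transport(b, lexan_geometry(), (), seed=3)
        assert res.energy_balance_error() < 1e-3

    def test_seed_determinism_bit_identical(self):
        def run():
            g = T.DoseGrid.centered(100.0, 0.0, 60.0)
            b = T.ParticleBatch.pencil(5_000, 70.0, z=10.0)
            T.transport(b, T.Geometry([T.water_box(0.0, 60.0)]), (g,), seed=42)
            return g.energy

        a, b = run(), run()
        assert np.array_equal(a, b)

    def test_different_seeds_differ(self):
        def run(seed):
            g = T.DoseGrid.centered(100.0, 0.0, 60.0)
            b = T.ParticleBatch.pencil(5_000, 70.0, z=10.0)
            T.transport(b, T.Geometry([T.water_box(0.0, 60.0)]), (g,), seed=seed)
            return g.energy

        assert not np.array_equal(run(1), run(2))

    def test_nan_energy_rejected(self):
        b = T.ParticleBatch.pencil(10, 100.0)
        b.energy[0] = np.nan
        with pytest.raises(ValueError):
            T.transport(b, lexan_geometry(), (), seed=1)

    def test_batch_validation(self):
        b = T.ParticleBatch.pencil(10, 100.0)
        b.dz[:] = -0.5
        with pytest.raises(ValueError):
            b.validate()


class TestDoseLinearity:
    def test_normalized_idd_independent_of_n(self, machine):
        d1, c1 = T.score_idd(machine, 100.0, n=30_000, seed=5, phantom_depth=110.0)
        d2, c2 = T.score_idd(machine, 100.0, n=60_000, seed=6, phantom_depth=110.0)
        sel = c1 > 0.2 * c1.max()
        assert np.allclose(c1[sel], c2[sel], rtol=0.06)


class TestRangeShifter:
    def test_primary_survival_matches_table(self):
        # MC survival through Lexan vs the deterministic path integral
        n = 400_000
        b = T.ParticleBatch.pencil(n, 115.0, z=460.0)
        res = T.transport(b, lexan_geometry(), (), seed=7)
        wet = M.wet(M.LEXAN, 65.0, 115.0)
        expected = 1.0 - M.nonelastic_probability(M.WATER_REMOVAL_TABLE, wet, 115.0)
        assert res.surviving_primary_fraction() == pytest.approx(expected, abs=0.003)

    def test_primary_loss_and_exit_energy(self):
        n = 200_000
        b = T.ParticleBatch.pencil(n, 115.0, z=460.0)
        res = T.transport(b, lexan_geometry(), (), seed=8)
        loss_pct = 100.0 * (1.0 - res.surviving_primary_fraction())
        assert loss_pct == pytest.approx(8.96, abs=1.5)
        prim = res.exit_batch.species == T.PRIMARY
        mean_e = np.average(res.exit_batch.energy[prim],
                            weights=res.exit_batch.weight[prim])
        assert mean_e == pytest.approx(54.6, abs=3.0)

    def test_secondaries_created(self):
        b = T.ParticleBatch.pencil(50_000, 115.0, z=460.0)
        res = T.transport(b, lexan_geometry(), (), seed=9)
        assert res.accounting["n_secondaries"] > 1000
        assert np.any(res.exit_batch.species == T.SECONDARY)


class TestBraggPeak:
    def test_idd_r80_matches_csda(self, machine, idd_100):
        d, c = idd_100
        assert r80(d, c) == pytest.approx(M.csda_range(M.WATER, 100.0) * 10.0,
                                          abs=1.0)

    def test_peak_ratio_falls_with_spread(self, machine):
        from pbsmc.commissioning import peak_plateau_ratio

        ratios = []
        fwhms = []
        for spread in (0.3, 1.0, 2.0):
            d, c = T.score_idd(machine, 100.0, n=50_000, seed=11,
                               energy_spread_pct=spread, phantom_depth=110.0)
            ratios.append(peak_plateau_ratio(d, c))
            half = c >= 0.5 * c.max()
            fwhms.append(d[half][-1] - d[half][0])
        assert ratios[0] > ratios[1] > ratios[2]
        assert fwhms[0] < fwhms[1] < fwhms[2]


class TestFermiEyges:
    def test_in_water_sigma_matches_quadrature(self):
        """MC lateral spread of a zero-emittance pencil vs deterministic
        Fermi-Eyges accumulation of the same per-step Highland angles."""
        n = 100_000
        depths = [80.0, 100.0, 120.0, 135.0]
        b = T.ParticleBatch.pencil(n, 150.0, z=10.0)
        pl = T.PlaneScorer([-d for d in depths], halfsize_mm=60.0, bin_mm=0.25)
        geom = T.Geometry([T.water_box(0.0, 170.0)])
        T.transport(b, geom, (pl,), seed=12,
                    config=T.TransportConfig(nuclear_enabled=False))
        tab = M.range_table(M.WATER)

        def fe_sigma(depth_mm):
            z, e = 0.0, 150.0
            zs, th2 = [], []
            while z < depth_mm and e > 2.0:
                rres = tab.csda_range(e) * 10.0
                s = min(1.0, max(0.02 * rres, 0.1), depth_mm - z)
                th2.append(M.mcs_sigma(M.WATER, s, e) ** 2)
                zs.append(z + s / 2)
                e -= M.stopping_power(M.WATER, e) * s / 10.0
                z += s
            zs, th2 = np.array(zs), np.array(th2)
            return np.sqrt(np.sum(th2 * (depth_mm - zs) ** 2))

        for i, d in enumerate(depths):
            assert pl.spot_sigma(i) == pytest.approx(fe_sigma(d), rel=0.03)


class TestSpotInMedium:
    def test_spot_sigma_grows_with_depth(self, machine):
        depths = [20.0, 60.0, 90.0]
        pl = T.PlaneScorer([-d for d in depths], halfsize_mm=100.0, bin_mm=0.5)
        geom = T.Geometry([T.water_box(0.0, 120.0)])
        T.simulate_spot(machine, 115.0, n=50_000, seed=13, geometry=geom,
                        scorers=(pl,))
        sig = [pl.spot_sigma(i) for i in range(len(depths))]
        assert sig[0] < sig[1] < sig[2]

    def test_air_gap_broadens_spot_after_range_shifter(self, machine):
        rs_bot = 395.0
        pl = T.PlaneScorer([rs_bot - 5.0, rs_bot - 150.0], halfsize_mm=200.0,
                           bin_mm=0.5)
        geom = T.Geometry([T.Region(460.0, rs_bot, material=M.LEXAN)])
        T.simulate_spot(machine, 115.0, n=50_000, seed=14, geometry=geom,
                        scorers=(pl,))
        assert pl.spot_sigma(1) > pl.spot_sigma(0)

    def test_in_vacuum_planes_match_drift_parabola(self, machine):
        from pbsmc.source import sigma_at

        planes = [300.0, 100.0, 0.0]
        pl = T.PlaneScorer(planes, halfsize_mm=100.0, bin_mm=0.5)
        # phantom far downstream so all planes are in vacuum
        geom = T.Geometry([T.water_box(-150.0, 100.0)])
        T.simulate_spot(machine, 150.0, n=100_000, seed=15, geometry=geom,
                        scorers=(pl,))
        opt = machine.optics[150.0]
        for i, zp in enumerate(planes):
            assert pl.spot_sigma(i) == pytest.approx(
                sigma_at(*opt.axis("x"), zp), rel=0.02
            )


class TestVoxelTransport:
    def test_voxel_water_matches_uniform(self, machine):
        from pbsmc.phantoms import make_slab_phantom

        sc_u = T.IDDScorer(0.0, 120.0)
        sc_v = T.IDDScorer(0.0, 120.0)
        b = T.ParticleBatch.pencil(30_000, 100.0, z=10.0)
        cfg = T.TransportConfig(max_step_mm=0.5)
        T.transport(b, T.Geometry([T.water_box(0.0, 120.0)]), (sc_u,), seed=16,
                    config=cfg)
        vox = make_slab_phantom([(M.WATER, 120.0)], lateral_mm=100.0)
        T.transport(b, T.Geometry(vox.regions), (sc_v,), seed=17, config=cfg)
        du, cu = sc_u.curve()
        dv, cv = sc_v.curve()
        assert r80(du, cu) == pytest.approx(r80(dv, cv), abs=0.5)

    def test_low_density_slab_extends_range(self):
        from pbsmc.phantoms import make_slab_phantom

        b = T.ParticleBatch.pencil(20_000, 100.0, z=10.0)
        cfg = T.TransportConfig(max_step_mm=0.5)
        sc_w = T.IDDScorer(0.0, 140.0)
        T.transport(b, T.Geometry([T.water_box(0.0, 140.0)]), (sc_w,), seed=18,
                    config=cfg)
        sandwich = make_slab_phantom(
            [(M.WATER, 20.0), (M.LUNG, 30.0), (M.WATER, 90.0)], lateral_mm=100.0
        )
        sc_l = T.IDDScorer(0.0, 140.0)
        T.transport(b, T.Geometry(sandwich.regions), (sc_l,), seed=19, config=cfg)
        r_w = r80(*sc_w.curve())
        r_l = r80(*sc_l.curve())
        # 30 mm of RSP-0.31 lung adds ~20.7 mm of range
        assert r_l - r_w == pytest.approx(30.0 * (1 - 0.31), abs=1.5)


class TestFieldSimulation:
    def test_dose_scales_linearly_with_mu(self, machine):
        from pbsmc.plans import make_square_field

        geom = T.Geometry([T.water_box(0.0, 60.0)])

        def run(mu):
            field = make_square_field(100.0, 20.0, mu_per_spot=mu)
            grid = T.DoseGrid.centered(120.0, 0.0, 60.0)
            T.simulate_field(machine, field, n_per_kernel=20_000, seed=20,
                             geometry=geom, grid=grid)
            return grid.energy.sum()

        assert run(2.0) == pytest.approx(2.0 * run(1.0), rel=1e-9)

    def test_kernel_reuse_matches_direct_on_central_dose(self, machine):
        from pbsmc.plans import make_square_field
        from pbsmc.qa import central_axis_dose

        field = make_square_field(100.0, 24.0)
        geom = T.Geometry([T.water_box(0.0, 60.0)])
        doses = []
        for reuse in (True, False):
            grid = T.DoseGrid.centered(150.0, 0.0, 60.0)
            T.simulate_field(machine, field, n_per_kernel=20_000, seed=21,
                            geometry=geom, grid=grid, kernel_reuse=reuse)
            doses.append(central_axis_dose(grid, 30.0))
        assert doses[0] == pytest.approx(doses[1], rel=0.05)


class TestDoseGridIO:
    def test_h5_round_trip(self, tmp_path):
        g = T.DoseGrid.centered(50.0, 0.0, 30.0)
        g.energy[10, 20, 5] = 3.0
        g.n_source_particles = 1000
        path = tmp_path / "dose.h5"
        g.save_h5(path)
        loaded = T.DoseGrid.load_h5(path)
        assert np.array_equal(loaded.energy, g.energy)
        assert loaded.origin == g.origin
        assert loaded.spacing == g.spacing
        assert loaded.n_source_particles == 1000
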