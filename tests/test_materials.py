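"""Single-proton physics: stopping power, ranges, WET, straggling, MCS, removal."""

import numpy as np
import pytest

from pbsmc import materials as M
from pbsmc.constants import PROTON_MASS_MEV

# Published PSTAR values for liquid water: (energy MeV, mass stopping power
# MeV cm^2/g, CSDA range g/cm^2).  Test oracle for the Bethe implementation.
PSTAR_WATER = [
    (50.0, 12.45, 2.227),
    (100.0, 7.289, 7.718),
    (150.0, 5.445, 15.77),
    (200.0, 4.492, 25.96),
    (250.0, 3.911, 37.94),
]


class TestStoppingPower:
    @pytest.mark.parametrize("energy,sp_ref,_", PSTAR_WATER)
    def test_water_matches_pstar(self, energy, sp_ref, _):
        sp = M.mass_stopping_power(M.WATER, energy)
        assert sp == pytest.approx(sp_ref, rel=0.01)

    @pytest.mark.parametrize("material", [M.WATER, M.LEXAN, M.SOLID_WATER, M.AIR])
    def test_decreasing_in_energy(self, material):
        e = np.linspace(10.0, 250.0, 50)
        s = M.mass_stopping_power(material, e)
        assert np.all(np.diff(s) < 0)

    def test_cutoff_violation_raises(self):
        with pytest.raises(M.CutoffError):
            M.stopping_power(M.WATER, 1.0)

    def test_band_violation_raises(self):
        with pytest.raises(ValueError):
            M.stopping_power(M.WATER, 400.0)


class TestRangeEnergy:
    @pytest.mark.parametrize("energy,_,r_ref", PSTAR_WATER)
    def test_water_range_matches_pstar(self, energy, _, r_ref):
        assert M.csda_range(M.WATER, energy) == pytest.approx(r_ref, rel=0.01)

    def test_inverse_identity(self):
        for e in (10.0, 60.0, 100.0, 225.0):
            r = M.csda_range(M.WATER, e)
            assert M.energy_from_range(M.WATER, r) == pytest.approx(e, abs=0.01)

    def test_monotone(self):
        assert M.csda_range(M.WATER, 150.0) > M.csda_range(M.WATER, 100.0)

    def test_range_stopping_consistency(self):
        # dR/dE = 1/S within 0.1%
        for e in (30.0, 100.0, 200.0):
            de = 0.05
            drde = (M.csda_range(M.WATER, e + de)
                    - M.csda_range(M.WATER, e - de)) / (2 * de)
            assert drde == pytest.approx(
                1.0 / M.mass_stopping_power(M.WATER, e), rel=1e-3
            )

    def test_out_of_domain_raises(self):
        with pytest.raises(ValueError):
            M.csda_range(M.WATER, 0.1)


class TestWet:
    def test_lexan_range_shifter(self):
        # 65 mm Lexan range shifter: water-equivalent thickness 74.1 mm
        assert M.wet(M.LEXAN, 65.0, 160.0) == pytest.approx(74.1, abs=0.5)

    def test_water_identity(self):
        for e in (100.0, 200.0):
            assert M.wet(M.WATER, 50.0, e) == pytest.approx(50.0, abs=1e-6)

    def test_lung_surrogate(self):
        # RSP 0.31 surrogate: 10 mm path is 3.1 mm water-equivalent
        assert M.wet(M.LUNG, 10.0, 160.0) == pytest.approx(3.1, abs=0.05)

    def test_additive_over_stacked_slabs(self):
        e = 160.0
        w_full = M.wet(M.LEXAN, 65.0, e)
        w1 = M.wet(M.LEXAN, 30.0, e)
        e_mid = M.slab_exit_energy(M.LEXAN, 30.0, e)
        w2 = M.wet(M.LEXAN, 35.0, e_mid)
        assert w1 + w2 == pytest.approx(w_full, abs=0.1)

    def test_stops_inside_slab(self):
        with pytest.raises(M.StopsInSlabError):
            M.wet(M.LEXAN, 65.0, 50.0)

    def test_zero_thickness(self):
        assert M.wet(M.LEXAN, 0.0, 100.0) == 0.0


class TestExitEnergy:
    def test_range_shifter_exit_energies(self):
        # mean exit energy after the 65 mm Lexan slab (CSDA)
        assert M.slab_exit_energy(M.LEXAN, 65.0, 115.0) == pytest.approx(54.6, abs=3.0)
        assert M.slab_exit_energy(M.LEXAN, 65.0, 225.0) == pytest.approx(193.5, abs=2.0)


class TestStraggling:
    def test_zero_path(self):
        assert M.straggling_sigma(M.WATER, 0.0, 100.0) == 0.0

    def test_variance_additivity(self):
        v1 = M.straggling_sigma(M.WATER, 5.0, 150.0) ** 2
        v2 = M.straggling_sigma(M.WATER, 10.0, 150.0) ** 2
        assert v2 == pytest.approx(2 * v1, rel=0.05)

    def test_bohr_closed_form(self):
        # independent evaluation of the Bohr formula
        x = 1.0 * 74.1 / 10.0  # g/cm^2
        expected = np.sqrt(0.1569 * M.WATER.z_over_a * x)
        assert M.straggling_sigma(M.WATER, 74.1, 115.0) == pytest.approx(
            expected, rel=1e-9
        )


class TestMcs:
    def test_zero_thickness(self):
        assert M.mcs_sigma(M.WATER, 0.0, 150.0) == 0.0

    def test_energy_ordering(self):
        assert M.mcs_sigma(M.WATER, 10.0, 115.0) > M.mcs_sigma(M.WATER, 10.0, 225.0)

    def test_highland_closed_form(self):
        # independent Highland evaluation: 10 mm water at 150 MeV
        t = 150.0
        pc2 = t * (t + 2 * PROTON_MASS_MEV)
        pv = pc2 / (t + PROTON_MASS_MEV)
        x_over_x0 = 1.0 / M.WATER.radiation_length
        expected = 14.1 / pv * np.sqrt(x_over_x0) * (
            1 + np.log10(x_over_x0) / 9
        )
        assert M.mcs_sigma(M.WATER, 10.0, 150.0) == pytest.approx(expected, rel=1e-9)


class TestNuclearRemoval:
    def test_zero_path(self):
        assert M.nonelastic_probability(M.WATER_REMOVAL_TABLE, 0.0, 115.0) == 0.0

    def test_range_shifter_loss(self):
        # ~9% primary loss over the range shifter's water-equivalent path
        p = M.nonelastic_probability(M.WATER_REMOVAL_TABLE, 74.1, 115.0)
        assert p == pytest.approx(0.0896, abs=0.015)

    def test_constant_sigma_exponential(self):
        const = M.NuclearCrossSectionTable(
            energies=(8.0, 300.0), sigma_per_cm=(0.012, 0.012)
        )
        p = M.nonelastic_probability(const, 50.0, 200.0)
        assert p == pytest.approx(1 - np.exp(-0.012 * 5.0), rel=1e-4)

    def test_survival_product_over_split_path(self):
        tab = M.WATER_REMOVAL_TABLE
        e0 = 115.0
        full = 1 - M.nonelastic_probability(tab, 60.0, e0, n_steps=2000)
        p1 = 1 - M.nonelastic_probability(tab, 25.0, e0, n_steps=2000)
        wtab = M.range_table(M.WATER)
        e_mid = wtab.energy_from_range(wtab.csda_range(e0) - 2.5)
        p2 = 1 - M.nonelastic_probability(tab, 35.0, e_mid, n_steps=2000)
        assert full == pytest.approx(p1 * p2, abs=1e-6)

    def test_negative_cross_section_rejected(self):
        with pytest.raises(ValueError):
            M.NuclearCrossSectionTable(energies=(8.0, 300.0),
                                       sigma_per_cm=(-0.01, 0.01))


class TestMaterialDefinition:
    def test_mass_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            M.Material.from_composition("bad", {"H": 0.5, "O": 0.4}, 1.0, 75.0)

    def test_builtin_invariants(self):
        for m in M.BUILTIN_MATERIALS.values():
            assert m.density > 0
            assert m.mean_excitation_energy > 0
            assert sum(w for _, w in m.composition) == pytest.approx(1.0, abs=1e-4)

    def test_bragg_additivity_i_value(self):
        # solid water I derived from composition lands in a physical band
        assert 60.0 < M.SOLID_WATER.mean_excitation_energy < 90.0

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        path = tmp_path / "mat.yaml"
        path.write_text(yaml.safe_dump(M.LEXAN.to_dict()))
        loaded = M.Material.from_yaml(path)
        assert loaded == M.LEXAN
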