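"""Equilibrium constants, Davies model and the speciation solver."""

import dataclasses
import math

import pytest
from hypothesis import given, settings, strategies as st

from methanergy import thermo
from methanergy.fluidchem import SiteSample
from methanergy.speciation import (
    EnergyScenario,
    activity_coefficient,
    davies_A,
    equilibrium_constants,
    o2_air_saturation_uM,
    speciate,
    speciation_oracle,
)
from methanergy.synthetic import FluidSimParams, simulate_fluid_table


def pk(x):
    return -math.log10(x)


class TestEquilibriumConstants:
    def test_carries_its_temperature(self):
        assert equilibrium_constants(300.0).temperature_K == 300.0

    def test_25C_values_match_formation_energy_hand_sums(self):
        """ln K = -dG0/(RT) with dG0 summed by hand over the species table:
        pKw ~ 14.0, pK1 ~ 6.3, pK2 ~ 10.3."""
        t = thermo.species_table()
        K = equilibrium_constants(298.15)
        rt_ln10 = thermo.R_J_MOL_K * 298.15 * math.log(10) / 1000.0

        def hand_pk(stoich):
            return sum(nu * t[n].dGf_25C_kJ_mol for n, nu in stoich.items()) / rt_ln10

        assert pk(K.Kw) == pytest.approx(
            hand_pk({"H2O": -1, "H+": 1, "OH-": 1}), abs=1e-9)
        assert pk(K.Kw) == pytest.approx(14.0, abs=0.15)
        assert pk(K.K1_carbonic) == pytest.approx(6.3, abs=0.15)
        assert pk(K.K2_carbonic) == pytest.approx(10.3, abs=0.15)
        assert pk(K.Ka_ammonium) == pytest.approx(9.25, abs=0.15)
        assert pk(K.Ka_acetate) == pytest.approx(4.76, abs=0.15)

    def test_out_of_range_temperature_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_constants(250.0)


class TestActivityCoefficient:
    def test_neutral_species_and_zero_ionic_strength(self):
        assert activity_coefficient(0, 0.1, 298.15) == 1.0
        for z in (-2, -1, 1, 2):
            assert activity_coefficient(z, 0.0, 298.15) == 1.0

    def test_davies_hand_value_monovalent(self):
        # log10 g = -0.509 * (sqrt(.01)/(1.1) - 0.003) at 25 C
        assert activity_coefficient(1, 0.01, 298.15) == pytest.approx(0.902, abs=0.002)
        assert davies_A(298.15) == pytest.approx(0.509, abs=0.001)

    def test_negative_ionic_strength_rejected(self):
        with pytest.raises(ValueError):
            activity_coefficient(1, -0.1, 298.15)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(ionic=st.floats(min_value=1e-8, max_value=0.3))
    def test_gamma_decreases_with_charge_squared(self, ionic):
        gammas = [activity_coefficient(z, ionic, 298.15) for z in (1, 2, 3)]
        assert gammas[0] > gammas[1] > gammas[2]
        assert all(0 < g <= 1.5 for g in gammas)

    def test_gamma_tends_to_one_as_I_tends_to_zero(self):
        for z in (1, 2, 3, 4):
            assert activity_coefficient(z, 1e-12, 298.15) == pytest.approx(1.0, abs=1e-4)


def test_o2_air_saturation_reference_value():
    assert o2_air_saturation_uM(298.15) == pytest.approx(258.0)
    assert o2_air_saturation_uM(303.15) < o2_air_saturation_uM(298.15)


def _pure_water(pH=7.0, T=25.0):
    return SiteSample(site_id="pure", site_type="spring", temperature_C=T,
                      pH=pH, dic_uM=0.0, doc_uM=0.0, ch4_uM=0.0, h2_uM=0.0)


class TestSpeciate:
    def test_neutral_water_proton_hydroxide_activities(self):
        f = speciate(_pure_water(), filler_na_cl_mM=0.0)
        assert f.activity("H+") == pytest.approx(1e-7, abs=1e-12)
        K = equilibrium_constants(298.15)
        assert f.activity("OH-") == pytest.approx(K.Kw / 1e-7, rel=1e-9)
        # pKw ~ 14.0, so hydroxide sits within ~2e-9 of 1e-7
        assert f.activity("OH-") == pytest.approx(1e-7, abs=2e-9)

    def test_hyperalkaline_spring_is_carbonate_dominated(self, field_sites):
        s8 = next(s for s in field_sites if s.site_id == "Spring 8")
        f = speciate(s8)
        dic = s8.dic_uM * 1e-6
        assert f.molality("CO3--") / dic > 0.9
        assert f.molality("CO2(aq)") / dic < 1e-4

    def test_circumneutral_river_is_bicarbonate_dominated(self, field_sites):
        up = next(s for s in field_sites if s.site_id == "Q. Danta Upstream")
        f = speciate(up)
        assert f.molality("HCO3-") / (up.dic_uM * 1e-6) > 0.9

    def test_carbonate_and_ammonium_mass_balance(self, field_sites):
        for s in field_sites:
            f = speciate(s)
            dic = s.dic_uM * 1e-6
            total = sum(f.molality(n) for n in ("CO2(aq)", "HCO3-", "CO3--"))
            assert abs(total - dic) <= 1e-6 * dic
            if s.nh4_uM:
                n_tot = sum(f.molality(n) for n in ("NH4+", "NH3(aq)"))
                assert abs(n_tot - s.nh4_uM * 1e-6) <= 1e-6 * s.nh4_uM * 1e-6

    def test_every_equilibrium_relation_satisfied(self, field_sites):
        for s in field_sites:
            f = speciate(s)
            assert f.residual <= 1e-8

    def test_scenario_controls_o2_and_acetate(self, field_sites):
        s8 = next(s for s in field_sites if s.site_id == "Spring 8")
        lo = speciate(s8, scenario=EnergyScenario(o2_fraction_air_sat=0.001,
                                                  acetate_fraction_doc=0.01))
        hi = speciate(s8, scenario=EnergyScenario(o2_fraction_air_sat=0.01,
                                                  acetate_fraction_doc=0.10))
        assert hi.molality("O2(aq)") == pytest.approx(10 * lo.molality("O2(aq)"))
        assert hi.molality("CH3COO-") == pytest.approx(10 * lo.molality("CH3COO-"))
        # carbon basis: acetate = fraction * DOC / 2
        assert hi.molality("CH3COO-") == pytest.approx(0.10 * 73.2e-6 / 2, rel=1e-9)
        molar = speciate(s8, scenario=EnergyScenario(acetate_fraction_doc=0.10,
                                                     acetate_basis="molar"))
        assert molar.molality("CH3COO-") == pytest.approx(0.10 * 73.2e-6, rel=1e-9)

    def test_null_required_field_is_named(self, field_sites):
        broken = dataclasses.replace(field_sites[0], dic_uM=None)
        with pytest.raises(ValueError, match="dic_uM"):
            speciate(broken)

    def test_raising_ph_never_increases_dissolved_co2(self, field_sites):
        s = field_sites[1]  # circumneutral river
        previous = None
        for ph in (6.5, 7.5, 8.5, 9.5, 10.5, 11.5):
            m = speciate(dataclasses.replace(s, pH=ph)).molality("CO2(aq)")
            if previous is not None:
                assert m <= previous
            previous = m

    def test_speciate_is_deterministic(self, field_sites):
        a = speciate(field_sites[0])
        b = speciate(field_sites[0])
        assert a.ionic_strength_molal == b.ionic_strength_molal
        assert a.species == b.species


class TestOracleEquivalence:
    @staticmethod
    def max_relative_activity_difference(s, **kw):
        f, g = speciate(s, **kw), speciation_oracle(s, **kw)
        diffs = []
        for name, st_f in f.species.items():
            a_o = g.species[name].activity
            if a_o > 0:
                diffs.append(abs(st_f.activity - a_o) / a_o)
        return max(diffs)

    def test_pure_water_identical(self):
        assert self.max_relative_activity_difference(_pure_water()) <= 1e-10

    def test_spring9_dominant_species_agree(self, field_sites):
        s9 = next(s for s in field_sites if s.site_id == "Spring 9")
        f, g = speciate(s9), speciation_oracle(s9)
        dom_f = max(("CO2(aq)", "HCO3-", "CO3--"), key=lambda n: f.molality(n))
        dom_g = max(("CO2(aq)", "HCO3-", "CO3--"), key=lambda n: g.molality(n))
        assert dom_f == dom_g == "CO3--"
        assert self.max_relative_activity_difference(s9) <= 1e-6

    def test_agreement_on_random_valid_fluids(self):
        samples, _ = simulate_fluid_table(
            FluidSimParams(n_spring=15, n_background=15, seed=2024))
        worst = max(self.max_relative_activity_difference(s) for s in samples)
        assert worst <= 1e-6
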