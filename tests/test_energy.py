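"""Limiting reactants, J/L yields, the scenario grid and pathway ranking."""

import dataclasses

import pytest

from methanergy import thermo
from methanergy.energy import (
    ConfigurationError,
    EnergyScenario,
    MissingMeasurementError,
    default_scenarios,
    energy_per_liter,
    limiting_reactant,
    rank_pathways,
    resolve_limiting_totals,
    results_to_frame,
    scenario_grid,
)
from methanergy.speciation import speciate


def reaction(catalog, rid):
    return next(r for r in catalog if r.reaction_id == rid)


class TestLimitingReactant:
    def test_hydrogen_limits_co2_reduction_at_qdanta(self, catalog):
        # Q. Danta totals: DIC 126.3, H2 38.3 -> min(126.3/1, 38.3/4)
        species, extent = limiting_reactant(
            reaction(catalog, "MG"), {"CO2(aq)": 126.3, "H2(aq)": 38.3})
        assert species == "H2(aq)"
        assert extent == pytest.approx(9.575)

    def test_zero_total_gives_zero_extent(self, catalog):
        _, extent = limiting_reactant(
            reaction(catalog, "MG"), {"CO2(aq)": 0.0, "H2(aq)": 38.3})
        assert extent == 0.0

    def test_single_candidate_identity(self, catalog):
        # 1% of Q. Danta DOC (5.6 uM) on a carbon basis -> 0.028 uM acetate
        species, extent = limiting_reactant(
            reaction(catalog, "AM"), {"CH3COO-": 0.028})
        assert species == "CH3COO-" and extent == pytest.approx(0.028)

    def test_missing_total_is_an_error(self, catalog):
        with pytest.raises(MissingMeasurementError, match="H2"):
            limiting_reactant(reaction(catalog, "MG"), {"CO2(aq)": 126.3})


class TestResolveTotals:
    def test_sulfate_requires_explicit_assumption(self, catalog, field_sites):
        with pytest.raises(ConfigurationError, match="assumed_so4_uM"):
            resolve_limiting_totals(reaction(catalog, "AOM-SO4"),
                                    field_sites[0], EnergyScenario())
        totals = resolve_limiting_totals(
            reaction(catalog, "AOM-SO4"), field_sites[0],
            EnergyScenario(assumed_so4_uM=200.0))
        assert totals["SO4--"] == 200.0

    def test_nitrate_is_nox_minus_nitrite(self, catalog, field_sites):
        up = next(s for s in field_sites if s.site_id == "Q. Danta Upstream")
        totals = resolve_limiting_totals(reaction(catalog, "AOM-NO3"), up,
                                         EnergyScenario())
        assert totals["NO3-"] == pytest.approx(2.5 - 0.1)

    def test_acetate_scales_with_doc_and_basis(self, catalog, field_sites):
        qd = field_sites[0]
        carbon = resolve_limiting_totals(
            reaction(catalog, "AM"), qd, EnergyScenario(acetate_fraction_doc=0.01))
        assert carbon["CH3COO-"] == pytest.approx(0.028)
        molar = resolve_limiting_totals(
            reaction(catalog, "AM"), qd,
            EnergyScenario(acetate_fraction_doc=0.01, acetate_basis="molar"))
        assert molar["CH3COO-"] == pytest.approx(0.056)


class TestEnergyPerLiter:
    def test_yield_is_minus_dg_times_extent(self, field_sites, catalog):
        s8 = next(s for s in field_sites if s.site_id == "Spring 8")
        sc = EnergyScenario()
        r = energy_per_liter(reaction(catalog, "MG"), speciate(s8, scenario=sc), s8, sc)
        assert r.energy_J_L == pytest.approx(-r.dG_kJ_mol * r.extent_umol_L / 1000.0)
        assert r.extent_umol_L == pytest.approx(10.9 / 4)
        assert r.energy_J_L == pytest.approx(0.109, rel=0.25)

    def test_endergonic_reaction_clamps_to_zero(self, field_sites, catalog):
        # reversed CO2 reduction is endergonic in these fluids
        s8 = next(s for s in field_sites if s.site_id == "Spring 8")
        sc = EnergyScenario()
        rev = dataclasses.replace(
            thermo.reverse_reaction(reaction(catalog, "MG")),
            limiting_candidates={"CH4(aq)": "ch4_uM"})
        r = energy_per_liter(rev, speciate(s8, scenario=sc), s8, sc)
        assert r.dG_kJ_mol > 0
        assert r.energy_J_L == 0.0

    def test_linearity_in_limiting_total(self, field_sites, catalog):
        qd = field_sites[0]
        sc = EnergyScenario()
        fluid = speciate(qd, scenario=sc)
        base = energy_per_liter(reaction(catalog, "MG"), fluid, qd, sc)
        doubled_sample = dataclasses.replace(qd, h2_uM=qd.h2_uM * 2)
        doubled = energy_per_liter(reaction(catalog, "MG"), fluid,
                                   doubled_sample, sc)
        assert doubled.energy_J_L == pytest.approx(2 * base.energy_J_L)


class TestScenarioGrid:
    def test_seven_rows_per_spring_site(self, springs, spring_grid):
        # AM x2 acetate cases, MG, AOM-SO4 (skipped: no assumed sulfate),
        # AOM-NO3, AeMO x2 O2 cases
        frame = results_to_frame(spring_grid)
        assert len(frame) == len(springs) * 7
        per_site = frame[frame.site_id == springs[0].site_id]
        assert list(per_site.reaction_id) == [
            "MG", "AM", "AM", "AOM-SO4", "AOM-NO3", "AeMO", "AeMO"]
        skipped = per_site[per_site.status != "ok"]
        assert list(skipped.reaction_id) == ["AOM-SO4"]
        assert "sulfate" in skipped.iloc[0].message

    def test_sulfate_pathway_computed_when_assumed(self, springs):
        results = scenario_grid(springs,
                                scenarios=default_scenarios(assumed_so4_uM=200.0))
        frame = results_to_frame(results)
        assert (frame.status == "ok").all()

    def test_empty_site_list_gives_empty_result(self):
        assert scenario_grid([]) == []

    def test_every_row_satisfies_the_yield_invariant(self, spring_grid):
        for r in spring_grid:
            if r.status != "ok":
                continue
            assert r.energy_J_L == pytest.approx(
                max(0.0, -r.dG_kJ_mol) * r.extent_umol_L / 1000.0)
            assert not (r.energy_J_L > 0 and r.dG_kJ_mol >= 0)

    def test_more_substrate_never_yields_less(self, spring_grid):
        frame = results_to_frame(spring_grid)
        for site in frame.site_id.unique():
            am = frame[(frame.site_id == site) & (frame.reaction_id == "AM")]
            assert (am[am.acetate_fraction_doc == 0.10].energy_J_L.iloc[0]
                    >= am[am.acetate_fraction_doc == 0.01].energy_J_L.iloc[0])
            ae = frame[(frame.site_id == site) & (frame.reaction_id == "AeMO")]
            assert (ae[ae.o2_fraction_air_sat == 0.01].energy_J_L.iloc[0]
                    >= ae[ae.o2_fraction_air_sat == 0.001].energy_J_L.iloc[0])

    def test_nitrate_aom_extent_capped_by_electron_acceptor(self, springs, spring_grid):
        # NOx <= 0.8 uM at the springs -> extent <= 0.2 umol/L, orders of
        # magnitude below methane availability (145-912 uM)
        for r in spring_grid:
            if r.reaction_id == "AOM-NO3" and r.status == "ok":
                assert r.limiting_species == "NO3-"
                assert r.extent_umol_L <= 0.2 + 1e-12

    def test_grid_is_deterministic(self, springs, spring_grid):
        again = scenario_grid(springs)
        assert results_to_frame(again).equals(results_to_frame(spring_grid))


class TestRanking:
    def test_qdanta_co2_reduction_tops_acetoclastic(self, spring_grid):
        ranked = rank_pathways(spring_grid, "Q. Danta")
        ids = [rid for rid, _, _ in ranked]
        assert ids.index("MG") < ids.index("AM")

    def test_spring8_acetoclastic_tops_co2_reduction_at_10pct(self, spring_grid):
        ranked = rank_pathways(spring_grid, "Spring 8")
        am10 = next(e for rid, sc, e in ranked
                    if rid == "AM" and sc.acetate_fraction_doc == 0.10)
        mg = next(e for rid, _, e in ranked if rid == "MG")
        assert am10 > mg

    def test_all_zero_energies_keep_catalog_order(self, catalog):
        from methanergy.energy import EnergyDensityResult
        sc = EnergyScenario()
        rows = [EnergyDensityResult("x", r.reaction_id, sc, None, 0.0, 5.0, 0.0)
                for r in catalog]
        ranked = rank_pathways(rows, "x")
        assert [rid for rid, _, _ in ranked] == [r.reaction_id for r in catalog]

    def test_unknown_site_is_an_error(self, spring_grid):
        with pytest.raises(KeyError):
            rank_pathways(spring_grid, "Atlantis")
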