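"""Free-energy yield per liter of fluid and pathway ranking.

A reaction's per-liter yield combines its in-situ Gibbs energy with the
amount of reaction turnover the fluid can support: the extent (µmol of
reaction per liter) is capped by the limiting reactant, i.e. the minimum
over candidate reactants of (bulk total) / |stoichiometric coefficient|
(McCollom-&-Shock-style accounting on measured bulk totals — DIC for CO2,
NOx-derived nitrate, measured CH4 and H2, scenario-assumed acetate, O2 and
sulfate). The yield is

    energy_J_L = max(0, -dG_kJ_mol) * extent_umol_L / 1000

with endergonic reactions clamped to zero ("energy available" semantics),
the positive dG retained on the result. By default the limiting totals are
the bulk measured pools; ``use_speciated_pools=True`` switches to the
speciated sub-pool (e.g. CO2(aq) only instead of DIC) for sensitivity
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from . import thermo
from .fluidchem import SiteSample
from .speciation import EnergyScenario, SpeciatedFluid, o2_air_saturation_uM, speciate

__all__ = [
    "EnergyScenario",
    "EnergyDensityResult",
    "ConfigurationError",
    "MissingMeasurementError",
    "resolve_limiting_totals",
    "limiting_reactant",
    "energy_per_liter",
    "default_scenarios",
    "scenario_grid",
    "rank_pathways",
    "results_to_frame",
]


class ConfigurationError(ValueError):
    """A scenario assumption required by a reaction was not supplied."""


class MissingMeasurementError(ValueError):
    """A limiting candidate has no measured total."""


@dataclass(frozen=True)
class EnergyDensityResult:
    """Per-liter free-energy yield of one reaction at one site/scenario.

    ``status`` is "ok" for computed cells; reactions that could not be
    evaluated (e.g. sulfate-coupled oxidation with no assumed sulfate) are
    recorded with status "skipped" and a message rather than silently
    dropped.
    """

    site_id: str
    reaction_id: str
    scenario: EnergyScenario
    limiting_species: Optional[str]
    extent_umol_L: Optional[float]
    dG_kJ_mol: Optional[float]
    energy_J_L: Optional[float]
    status: str = "ok"
    message: str = ""


def resolve_limiting_totals(
    r: thermo.Reaction,
    s: SiteSample,
    scenario: EnergyScenario,
    f: SpeciatedFluid | None = None,
    use_speciated_pools: bool = False,
) -> dict[str, float]:
    """Bulk totals (µmol/L) for each limiting candidate of ``r``.

    Raises :class:`ConfigurationError` for an unsupplied scenario assumption
    (sulfate) and :class:`MissingMeasurementError` for a null measurement.
    """
    if use_speciated_pools and f is not None:
        totals = {}
        for species in r.limiting_candidates:
            m = f.molality(species)
            if m is None:
                raise MissingMeasurementError(
                    f"{r.reaction_id}: species {species!r} absent from "
                    f"speciated fluid {f.site_id!r}"
                )
            totals[species] = m * 1e6
        return totals

    T_K = s.temperature_C + 273.15
    totals = {}
    for species, source in r.limiting_candidates.items():
        if source == "acetate_from_doc":
            value: Optional[float] = scenario.acetate_total_uM(s.doc_uM)
        elif source == "o2_air_sat":
            value = scenario.o2_fraction_air_sat * o2_air_saturation_uM(T_K)
        elif source == "so4_assumed":
            if scenario.assumed_so4_uM is None:
                raise ConfigurationError(
                    f"{r.reaction_id}: sulfate was not measured at "
                    f"{s.site_id!r}; supply assumed_so4_uM to evaluate this "
                    f"pathway"
                )
            value = scenario.assumed_so4_uM
        elif source == "no3_from_nox":
            if s.nox_uM is None:
                raise MissingMeasurementError(
                    f"{r.reaction_id}: NOx not measured at {s.site_id!r}"
                )
            value = max(s.nox_uM - (s.no2_uM or 0.0), 0.0)
        else:
            value = getattr(s, source, None)
            if value is None:
                raise MissingMeasurementError(
                    f"{r.reaction_id}: measurement {source!r} (for species "
                    f"{species!r}) is null at {s.site_id!r}"
                )
        totals[species] = float(value)
    return totals


def limiting_reactant(
    r: thermo.Reaction, totals: dict[str, float]
) -> tuple[str, float]:
    """(limiting species, extent µmol/L): extent = min(total / |nu|).

    Ties break in catalog (stoichiometry) order.
    """
    best: tuple[str, float] | None = None
    for species in r.limiting_candidates:
        if species not in totals:
            raise MissingMeasurementError(
                f"{r.reaction_id}: no total supplied for candidate {species!r}"
            )
        nu = abs(r.stoichiometry[species])
        extent = totals[species] / nu
        if best is None or extent < best[1]:
            best = (species, extent)
    if best is None:
        raise ValueError(f"{r.reaction_id}: no limiting candidates")
    return best


def energy_per_liter(
    r: thermo.Reaction,
    f: SpeciatedFluid,
    s: SiteSample,
    scenario: EnergyScenario,
    use_speciated_pools: bool = False,
) -> EnergyDensityResult:
    """Free-energy yield of ``r`` in one liter of the site's fluid (J/L)."""
    totals = resolve_limiting_totals(r, s, scenario, f, use_speciated_pools)
    species, extent = limiting_reactant(r, totals)
    energetics = thermo.delta_g(r, f)
    dg = energetics.dG_kJ_mol
    energy = max(0.0, -dg) * extent / 1000.0
    return EnergyDensityResult(
        site_id=s.site_id,
        reaction_id=r.reaction_id,
        scenario=scenario,
        limiting_species=species,
        extent_umol_L=extent,
        dG_kJ_mol=dg,
        energy_J_L=energy,
    )


def default_scenarios(
    assumed_so4_uM: Optional[float] = None,
    acetate_basis: str = "carbon",
) -> list[EnergyScenario]:
    """The study's scenario grid: O2 at 0.1%/1.0% of air saturation crossed
    with acetate at 1%/10% of DOC."""
    return [
        EnergyScenario(
            o2_fraction_air_sat=o2,
            acetate_fraction_doc=ac,
            assumed_so4_uM=assumed_so4_uM,
            acetate_basis=acetate_basis,
        )
        for o2 in (0.001, 0.01)
        for ac in (0.01, 0.10)
    ]


#: which scenario axis each reaction actually responds to (the per-site
#: report has one bar per acetate case for AM, one per O2 case for AeMO,
#: and a single bar for each scenario-independent reaction)
_SCENARIO_AXIS = {"AM": "acetate_fraction_doc", "AeMO": "o2_fraction_air_sat"}


def _applicable_scenarios(
    r: thermo.Reaction, scenarios: Sequence[EnergyScenario]
) -> list[EnergyScenario]:
    axis = _SCENARIO_AXIS.get(r.reaction_id)
    if axis is None:
        return [scenarios[0]]
    seen: list[EnergyScenario] = []
    for sc in scenarios:
        if all(getattr(sc, axis) != getattr(prev, axis) for prev in seen):
            seen.append(sc)
    return seen


def scenario_grid(
    samples: Iterable[SiteSample],
    catalog: Sequence[thermo.Reaction] | None = None,
    scenarios: Sequence[EnergyScenario] | None = None,
    filler_na_cl_mM: float = 12.5,
    use_speciated_pools: bool = False,
) -> list[EnergyDensityResult]:
    """Site x reaction x applicable-scenario grid of energy densities.

    With the default catalog and scenarios this yields seven rows per site
    (acetoclastic x2 acetate cases, hydrogenotrophic, sulfate-AOM,
    nitrate-AOM, aerobic x2 O2 cases); cells that cannot be evaluated are
    recorded with a "skipped" status. Deterministic and ordered.
    """
    if not scenarios and scenarios is not None:
        raise ValueError("scenarios must be non-empty")
    catalog = list(catalog) if catalog is not None else list(thermo.default_reaction_catalog())
    scenarios = list(scenarios) if scenarios is not None else default_scenarios()

    results: list[EnergyDensityResult] = []
    for s in samples:
        fluid_cache: dict[EnergyScenario, SpeciatedFluid] = {}
        for r in catalog:
            for sc in _applicable_scenarios(r, scenarios):
                try:
                    if sc not in fluid_cache:
                        fluid_cache[sc] = speciate(s, filler_na_cl_mM, sc)
                    results.append(
                        energy_per_liter(r, fluid_cache[sc], s, sc,
                                         use_speciated_pools)
                    )
                except (ConfigurationError, MissingMeasurementError,
                        ValueError) as exc:
                    results.append(EnergyDensityResult(
                        site_id=s.site_id, reaction_id=r.reaction_id,
                        scenario=sc, limiting_species=None,
                        extent_umol_L=None, dG_kJ_mol=None, energy_J_L=None,
                        status="skipped", message=str(exc),
                    ))
    return results


def rank_pathways(
    results: Sequence[EnergyDensityResult], site_id: str
) -> list[tuple[str, EnergyScenario, float]]:
    """Computed cells of one site, descending by energy (stable, so equal
    energies keep catalog order)."""
    rows = [r for r in results if r.site_id == site_id and r.status == "ok"]
    if not any(r.site_id == site_id for r in results):
        raise KeyError(f"no results for site {site_id!r}")
    rows.sort(key=lambda r: -r.energy_J_L)
    return [(r.reaction_id, r.scenario, r.energy_J_L) for r in rows]


def results_to_frame(results: Sequence[EnergyDensityResult]) -> pd.DataFrame:
    """Long-format table of the grid, one row per site/reaction/scenario."""
    rows = []
    for r in results:
        rows.append({
            "site_id": r.site_id,
            "reaction_id": r.reaction_id,
            "o2_fraction_air_sat": r.scenario.o2_fraction_air_sat,
            "acetate_fraction_doc": r.scenario.acetate_fraction_doc,
            "assumed_so4_uM": r.scenario.assumed_so4_uM,
            "acetate_basis": r.scenario.acetate_basis,
            "limiting_species": r.limiting_species,
            "extent_umol_L": r.extent_umol_L,
            "dG_kJ_mol": r.dG_kJ_mol,
            "energy_J_L": r.energy_J_L,
            "status": r.status,
            "message": r.message,
        })
    return pd.DataFrame(rows)
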