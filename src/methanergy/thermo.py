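"""Standard-state thermodynamics of the catabolic reaction catalog.

The in-situ Gibbs energy of a reaction is

    dG = dG0(T) + R*T*ln(Q)

where dG0(T) is the standard Gibbs energy of reaction at the fluid
temperature and Q the activity quotient assembled from the speciated fluid.
dG0 is computed from an embedded table of standard Gibbs energies and
enthalpies of formation of ~20 aqueous species at 25 C (SUPCRT-consistent
compilation, cited per entry in ``data/species.csv``) and corrected to the
fluid temperature with the Gibbs-Helmholtz relation at constant reaction
enthalpy:

    dG0(T) = dG0(T0)*(T/T0) + dH0(T0)*(1 - T/T0),   T0 = 298.15 K

which over the spring-fluid range (24-30 C) is accurate to well under
1 kJ/mol for these reactions. Aqueous standard states are used throughout
(CH4(aq), H2(aq), O2(aq), CO2(aq)); a(H2O) = 1 by the dilute-solution
convention; no pressure correction (1 bar).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .speciation import SpeciatedFluid

__all__ = [
    "R_J_MOL_K",
    "T0_K",
    "ThermoSpecies",
    "Reaction",
    "ReactionEnergetics",
    "species_table",
    "default_reaction_catalog",
    "check_balance",
    "delta_g_standard",
    "delta_g_formation",
    "activity_quotient",
    "delta_g",
    "reverse_reaction",
    "UnknownSpeciesError",
    "TemperatureRangeError",
]

R_J_MOL_K = 8.314  # universal gas constant, J/(mol K)
T0_K = 298.15  # reference temperature, K

#: validity window of the constant-enthalpy temperature correction (K)
T_MIN_K, T_MAX_K = 283.0, 333.0


class UnknownSpeciesError(KeyError):
    pass


class TemperatureRangeError(ValueError):
    pass


@dataclass(frozen=True)
class ThermoSpecies:
    """One aqueous (or liquid water) species of the embedded thermo table."""

    name: str
    formula: dict[str, int]
    charge: int
    dGf_25C_kJ_mol: float
    dHf_25C_kJ_mol: float
    phase: str
    source: str = ""


@dataclass(frozen=True)
class Reaction:
    """A mass- and charge-balanced catabolic stoichiometry.

    ``stoichiometry``: species name -> signed coefficient (reactants
    negative, products positive). ``limiting_candidates``: reactant species
    -> name of the measured/assumed bulk total (µmol/L) that measures its
    availability in a liter of fluid.
    """

    reaction_id: str
    name: str
    category: str
    stoichiometry: dict[str, float]
    limiting_candidates: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class ReactionEnergetics:
    """dG = dG0 + (R*T/1000)*lnQ for one reaction at one site (kJ/mol)."""

    reaction_id: str
    temperature_K: float
    dG0_kJ_mol: float
    lnQ: float
    dG_kJ_mol: float
    gas_constant_J_mol_K: float = R_J_MOL_K


def _parse_pairs(text: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for pair in text.split(";"):
        pair = pair.strip()
        if not pair:
            continue
        key, _, val = pair.rpartition(":")
        out[key.strip()] = float(val)
    return out


def _read_packaged_csv(name: str) -> list[dict[str, str]]:
    ref = resources.files("methanergy.data") / name
    with ref.open("r", encoding="utf-8") as fh:
        rows = [ln for ln in fh if not ln.lstrip().startswith("#")]
    return list(csv.DictReader(rows))


@lru_cache(maxsize=1)
def species_table() -> dict[str, ThermoSpecies]:
    """The embedded species table, keyed by canonical name."""
    table: dict[str, ThermoSpecies] = {}
    for row in _read_packaged_csv("species.csv"):
        formula = {el: int(n) for el, n in
                   ((p.split(":")[0], p.split(":")[1]) for p in row["formula"].split(";"))}
        sp = ThermoSpecies(
            name=row["name"],
            formula=formula,
            charge=int(row["charge"]),
            dGf_25C_kJ_mol=float(row["dGf_25C_kJ_mol"]),
            dHf_25C_kJ_mol=float(row["dHf_25C_kJ_mol"]),
            phase=row["phase"],
            source=row.get("source", ""),
        )
        table[sp.name] = sp
    return table


@lru_cache(maxsize=1)
def default_reaction_catalog() -> tuple[Reaction, ...]:
    """The five methane-cycling catabolisms, in catalog (report) order:

    MG       CO2(aq) + 4 H2(aq) -> CH4(aq) + 2 H2O
    AM       CH3COO- + H2O -> CH4(aq) + HCO3-
    AOM-SO4  CH4(aq) + SO4-- -> HCO3- + HS- + H2O
    AOM-NO3  CH4(aq) + 4 NO3- -> HCO3- + 4 NO2- + H+ + H2O
    AeMO     CH4(aq) + 2 O2(aq) -> HCO3- + H+ + H2O

    Bicarbonate is the inorganic-carbon product of the oxidations (the
    dominant carbonate species at circumneutral-to-alkaline pH); the
    hydrogenotrophic pathway consumes dissolved CO2.
    """
    catalog = []
    for row in _read_packaged_csv("reactions.csv"):
        r = Reaction(
            reaction_id=row["reaction_id"],
            name=row["name"],
            category=row["category"],
            stoichiometry=_parse_pairs(row["stoichiometry"]),
            limiting_candidates={k: v for k, v in
                                 ((p.split(":")[0], p.split(":")[1])
                                  for p in row["limiting"].split(";"))},
        )
        catalog.append(r)
    return tuple(catalog)


def check_balance(r: Reaction) -> list[str]:
    """Element and charge bookkeeping; empty list iff balanced."""
    table = species_table()
    elements: dict[str, float] = {}
    charge = 0.0
    for name, nu in r.stoichiometry.items():
        if name not in table:
            raise UnknownSpeciesError(f"species {name!r} not in thermo table")
        sp = table[name]
        for el, cnt in sp.formula.items():
            elements[el] = elements.get(el, 0.0) + nu * cnt
        charge += nu * sp.charge
    violations = [
        f"element {el} imbalance: {total:+g}"
        for el, total in sorted(elements.items())
        if abs(total) > 1e-9
    ]
    if abs(charge) > 1e-9:
        violations.append(f"charge imbalance: {charge:+g}")
    return violations


def _reaction_sums(r: Reaction) -> tuple[float, float]:
    table = species_table()
    dg0 = dh0 = 0.0
    for name, nu in r.stoichiometry.items():
        if name not in table:
            raise UnknownSpeciesError(f"species {name!r} not in thermo table")
        dg0 += nu * table[name].dGf_25C_kJ_mol
        dh0 += nu * table[name].dHf_25C_kJ_mol
    return dg0, dh0


def delta_g_formation(stoichiometry: dict[str, float], T_K: float) -> float:
    """dG0(T) in kJ/mol for an arbitrary stoichiometry (used for the
    dissociation reactions behind the speciation constants)."""
    return delta_g_standard(
        Reaction("adhoc", "adhoc", "adhoc", dict(stoichiometry)), T_K
    )


def delta_g_standard(r: Reaction, T_K: float) -> float:
    """Standard Gibbs energy of reaction at T (kJ/mol)."""
    if not (T_MIN_K < T_K < T_MAX_K):
        raise TemperatureRangeError(
            f"T = {T_K} K outside the correction window ({T_MIN_K}, {T_MAX_K})"
        )
    dg0, dh0 = _reaction_sums(r)
    ratio = T_K / T0_K
    return dg0 * ratio + dh0 * (1.0 - ratio)


def activity_quotient(r: Reaction, f: "SpeciatedFluid") -> float:
    """ln Q = sum(nu * ln a); a(H2O) = 1, a(H+) = 10**(-pH)."""
    lnq = 0.0
    for name, nu in r.stoichiometry.items():
        if name == "H2O":
            continue  # unit activity by convention
        a = f.activity(name)
        if a is None or a <= 0.0:
            raise ValueError(
                f"activity of {name!r} unavailable or non-positive "
                f"at site {f.site_id!r}"
            )
        lnq += nu * math.log(a)
    return lnq


def delta_g(r: Reaction, f: "SpeciatedFluid") -> ReactionEnergetics:
    """In-situ Gibbs energy: dG = dG0(T) + (R*T/1000) * lnQ (kJ/mol)."""
    T = f.temperature_K
    dg0 = delta_g_standard(r, T)
    lnq = activity_quotient(r, f)
    dg = dg0 + (R_J_MOL_K * T / 1000.0) * lnq
    return ReactionEnergetics(
        reaction_id=r.reaction_id,
        temperature_K=T,
        dG0_kJ_mol=dg0,
        lnQ=lnq,
        dG_kJ_mol=dg,
    )


def reverse_reaction(r: Reaction) -> Reaction:
    """The reaction written backwards (coefficients negated)."""
    return Reaction(
        reaction_id=r.reaction_id + "_rev",
        name=r.name + " (reversed)",
        category=r.category,
        stoichiometry={k: -v for k, v in r.stoichiometry.items()},
        limiting_candidates={},
    )
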