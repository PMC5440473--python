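"""Equilibrium aqueous speciation of a site's fluid at measured pH and T.

The measured pH is taken as fixed (a(H+) = 10**-pH; no charge-balance solve
for H+), and each acid-base system (carbonate, ammonium, phosphate) is
partitioned over its species with equilibrium constants derived from the
embedded thermodynamic table, with Davies-equation activity corrections.
Ionic strength and activity coefficients are solved self-consistently by
fixed-point iteration. A nominal Na+ = Cl- filler (default 12.5 mM, the
midpoint of the 10-15 mM used for these fluids) accounts for the measured
salinity; it affects only the ionic strength.

Conventions and approximations, all logged on the output:

* molality ~ molarity (dilute fluids, density ~ 1 kg/L);
* neutral aqueous species (CH4, H2, O2, NH3, CO2) have gamma = 1
  (no salting-out; negligible at I <~ 0.02 molal);
* dissolved CH4 and H2 are carried at their measured totals;
* O2(aq) is a scenario assumption: a stated fraction of air-saturation
  solubility at T; acetate is a stated fraction of measured DOC
  (carbon basis by default: two carbons per acetate);
* NO3- = max(NOx - NO2, 0);
* species that a reaction requires but whose measured/assumed total is zero
  (NO2- where the table prints 0.0, HS- which was never measured) are
  assigned a nominal trace molality (default 1e-9 mol/kg) so that in-situ
  Gibbs energies remain defined; the substitution is recorded in
  ``assumptions``.

A closed-form re-implementation, :func:`speciation_oracle`, computes the
same state by direct evaluation of ionization-fraction expressions with the
ionic strength found by bracketing + root refinement instead of fixed-point
iteration; it exists for cross-verification in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import thermo
from .fluidchem import SiteSample, validate_sample

__all__ = [
    "EnergyScenario",
    "EquilibriumConstants",
    "SpeciesState",
    "SpeciatedFluid",
    "ConvergenceError",
    "equilibrium_constants",
    "davies_A",
    "activity_coefficient",
    "o2_air_saturation_uM",
    "speciate",
    "speciation_oracle",
]

#: default Na = Cl filler, mM (midpoint of the 10-15 mM used for these fluids)
DEFAULT_FILLER_NA_CL_MM = 12.5

MAX_ITERATIONS = 100
I_RELATIVE_TOL = 1e-10

# Air-saturation O2 solubility (freshwater, 1 atm moist air), umol/L,
# linearly interpolated; anchor values after Benson & Krause (1984),
# with 258 umol/L at 25 C as the reference point.
_O2_SAT_T_C = np.array([20.0, 25.0, 30.0, 35.0])
_O2_SAT_UM = np.array([284.2, 258.0, 236.4, 217.8])


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class EnergyScenario:
    """Scenario assumptions for quantities that were not measured.

    ``o2_fraction_air_sat``: dissolved O2 as a fraction of air-saturation
    solubility (the study's cases: 0.001 and 0.01, i.e. 0.1% and 1.0%).
    ``acetate_fraction_doc``: acetate as a fraction of measured DOC (cases
    0.01 and 0.10); on the default ``carbon`` basis one acetate accounts for
    two DOC carbons, so m(acetate) = fraction * DOC / 2. ``assumed_so4_uM``
    must be supplied for the sulfate-coupled pathway (sulfate was not
    measured); ``None`` means that pathway is skipped. ``trace_floor_molal``
    is the nominal molality assigned to required species with a zero total.
    """

    o2_fraction_air_sat: float = 0.01
    acetate_fraction_doc: float = 0.10
    assumed_so4_uM: Optional[float] = None
    acetate_basis: str = "carbon"
    trace_floor_molal: float = 1e-9

    def __post_init__(self):
        if not (0.0 < self.o2_fraction_air_sat <= 1.0):
            raise ValueError("o2_fraction_air_sat must be in (0, 1]")
        if not (0.0 < self.acetate_fraction_doc <= 1.0):
            raise ValueError("acetate_fraction_doc must be in (0, 1]")
        if self.assumed_so4_uM is not None and self.assumed_so4_uM < 0:
            raise ValueError("assumed_so4_uM must be >= 0 when given")
        if self.acetate_basis not in ("carbon", "molar"):
            raise ValueError("acetate_basis must be 'carbon' or 'molar'")

    def acetate_total_uM(self, doc_uM: Optional[float]) -> float:
        doc = doc_uM or 0.0
        per_molecule = 2.0 if self.acetate_basis == "carbon" else 1.0
        return self.acetate_fraction_doc * doc / per_molecule


@dataclass(frozen=True)
class EquilibriumConstants:
    """Dissociation constants at T, each exp(-dG0(T) / (R*T)) from the
    embedded formation energies (so they are internally consistent with the
    reaction energetics)."""

    temperature_K: float
    Kw: float
    K1_carbonic: float
    K2_carbonic: float
    Ka_ammonium: float
    Ka_acetate: float
    Ka2_phosphoric: float
    Ka3_phosphoric: float


_DISSOCIATIONS = {
    "Kw": {"H2O": -1, "H+": 1, "OH-": 1},
    "K1_carbonic": {"CO2(aq)": -1, "H2O": -1, "H+": 1, "HCO3-": 1},
    "K2_carbonic": {"HCO3-": -1, "H+": 1, "CO3--": 1},
    "Ka_ammonium": {"NH4+": -1, "H+": 1, "NH3(aq)": 1},
    "Ka_acetate": {"CH3COOH(aq)": -1, "H+": 1, "CH3COO-": 1},
    "Ka2_phosphoric": {"H2PO4-": -1, "H+": 1, "HPO4--": 1},
    "Ka3_phosphoric": {"HPO4--": -1, "H+": 1, "PO4---": 1},
}


def equilibrium_constants(T_K: float) -> EquilibriumConstants:
    """Dissociation constants at T from the embedded thermo table."""
    if not (273.15 < T_K < 373.15):
        raise ValueError(f"temperature {T_K} K outside (273.15, 373.15)")
    ks = {
        name: math.exp(-thermo.delta_g_formation(stoich, T_K) * 1000.0
                       / (thermo.R_J_MOL_K * T_K))
        for name, stoich in _DISSOCIATIONS.items()
    }
    return EquilibriumConstants(temperature_K=T_K, **ks)


def davies_A(T_K: float) -> float:
    """Debye-Huckel A parameter (log10 basis); 0.509 at 25 C with a weak
    quadratic temperature dependence fitted to 0-50 C tabulations."""
    t = T_K - 273.15
    return 0.4918 + 6.06e-4 * t + 3.5e-6 * t * t


def activity_coefficient(charge: int, ionic_strength: float, T_K: float) -> float:
    """Davies equation: log10 gamma = -A z^2 (sqrt(I)/(1+sqrt(I)) - 0.3 I).

    Valid to I ~ 0.5 molal; gamma = 1 for neutral species and at I = 0.
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be >= 0")
    if abs(charge) > 4:
        raise ValueError("|charge| must be <= 4")
    if charge == 0 or ionic_strength == 0.0:
        return 1.0
    sqrt_i = math.sqrt(ionic_strength)
    log10_gamma = -davies_A(T_K) * charge * charge * (
        sqrt_i / (1.0 + sqrt_i) - 0.3 * ionic_strength
    )
    return 10.0 ** log10_gamma


def o2_air_saturation_uM(T_K: float) -> float:
    """Air-saturation O2 solubility (µmol/L) at T, freshwater, 1 atm."""
    return float(np.interp(T_K - 273.15, _O2_SAT_T_C, _O2_SAT_UM))


@dataclass(frozen=True)
class SpeciesState:
    molality: float  # mol/kg
    gamma: float
    activity: float


@dataclass
class SpeciatedFluid:
    """Per-species molalities, activity coefficients and activities of one
    site's fluid, with the self-consistent ionic strength."""

    site_id: str
    temperature_K: float
    pH: float
    ionic_strength_molal: float
    species: dict[str, SpeciesState]
    iterations: int
    residual: float
    assumptions: tuple[str, ...] = ()

    def activity(self, name: str) -> Optional[float]:
        st = self.species.get(name)
        return None if st is None else st.activity

    def molality(self, name: str) -> Optional[float]:
        st = self.species.get(name)
        return None if st is None else st.molality

    def to_long_frame(self) -> pd.DataFrame:
        rows = [
            {"site_id": self.site_id, "species": name,
             "molality_mol_kg": st.molality, "gamma": st.gamma,
             "activity": st.activity}
            for name, st in self.species.items()
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "site_id": self.site_id,
            "temperature_K": self.temperature_K,
            "pH": self.pH,
            "ionic_strength_molal": self.ionic_strength_molal,
            "iterations": self.iterations,
            "residual": self.residual,
            "assumptions": list(self.assumptions),
            "species": {
                name: {"molality": st.molality, "gamma": st.gamma,
                       "activity": st.activity}
                for name, st in self.species.items()
            },
        }


def _totals_molal(s: SiteSample, scenario: EnergyScenario) -> tuple[dict[str, float], list[str]]:
    """Bulk totals (mol/kg) of the independently supplied components."""
    assumptions: list[str] = []
    uM = 1e-6

    def nz(v: Optional[float]) -> float:
        return 0.0 if v is None else float(v)

    T_K = s.temperature_C + 273.15
    o2_uM = scenario.o2_fraction_air_sat * o2_air_saturation_uM(T_K)
    assumptions.append(
        f"O2(aq) = {scenario.o2_fraction_air_sat:g} x air saturation "
        f"({o2_uM:.3g} uM)"
    )
    ac_uM = scenario.acetate_total_uM(s.doc_uM)
    assumptions.append(
        f"acetate = {scenario.acetate_fraction_doc:g} x DOC on "
        f"{scenario.acetate_basis} basis ({ac_uM:.3g} uM)"
    )
    no3_uM = max(nz(s.nox_uM) - nz(s.no2_uM), 0.0)
    so4_uM = nz(scenario.assumed_so4_uM)
    if scenario.assumed_so4_uM is not None:
        assumptions.append(f"SO4-- assumed at {so4_uM:g} uM (not measured)")

    totals = {
        "DIC": nz(s.dic_uM) * uM,
        "NH4_total": nz(s.nh4_uM) * uM,
        "PO4_total": nz(s.po4_uM) * uM,
        "CH4": nz(s.ch4_uM) * uM,
        "H2": nz(s.h2_uM) * uM,
        "O2": o2_uM * uM,
        "acetate": ac_uM * uM,
        "NO3": no3_uM * uM,
        "NO2": nz(s.no2_uM) * uM,
        "SO4": so4_uM * uM,
    }
    floor = scenario.trace_floor_molal
    for key, label in (("NO2", "NO2-"), ("HS", "HS-")):
        if totals.get(key, 0.0) <= 0.0:
            totals[key] = floor
            assumptions.append(
                f"{label} assigned nominal trace molality {floor:g} mol/kg "
                f"(zero/absent measurement)"
            )
    totals.setdefault("HS", floor)
    return totals, assumptions


def _check_preconditions(s: SiteSample) -> None:
    violations = validate_sample(s)
    if violations:
        raise ValueError(f"sample {s.site_id!r} invalid: {violations}")
    for name in ("pH", "temperature_C", "dic_uM"):
        if getattr(s, name) is None:
            raise ValueError(f"sample {s.site_id!r}: required field {name!r} is null")


def _assemble(
    s: SiteSample,
    K: EquilibriumConstants,
    totals: dict[str, float],
    filler_molal: float,
    I: float,
    a_h: float,
    T_K: float,
) -> tuple[dict[str, SpeciesState], float]:
    """Species state at a given ionic strength; returns (species, implied I)."""
    g = {z: activity_coefficient(z, I, T_K) for z in (1, 2, 3)}

    # carbonate: m1/m0 = K1 / (aH g1); m2/m1 = K2 g1 / (aH g2)
    r1 = K.K1_carbonic / (a_h * g[1])
    r2 = K.K2_carbonic * g[1] / (a_h * g[2])
    m_co2 = totals["DIC"] / (1.0 + r1 + r1 * r2)
    m_hco3 = m_co2 * r1
    m_co3 = m_hco3 * r2

    # ammonium: m(NH3)/m(NH4+) = Ka g1 / aH   (gamma(NH3) = 1)
    q_n = K.Ka_ammonium * g[1] / a_h
    m_nh4 = totals["NH4_total"] / (1.0 + q_n)
    m_nh3 = totals["NH4_total"] - m_nh4

    # phosphate over H2PO4-/HPO4--/PO4--- (Ka1 irrelevant above pH ~ 4)
    rp2 = K.Ka2_phosphoric * g[1] / (a_h * g[2])
    rp3 = K.Ka3_phosphoric * g[2] / (a_h * g[3])
    m_h2po4 = totals["PO4_total"] / (1.0 + rp2 + rp2 * rp3)
    m_hpo4 = m_h2po4 * rp2
    m_po4 = m_hpo4 * rp3

    m_h = a_h / g[1]
    m_oh = K.Kw / (a_h * g[1])

    sp: dict[str, SpeciesState] = {}

    def put(name, m, z):
        gamma = 1.0 if z == 0 else g[abs(z)]
        sp[name] = SpeciesState(molality=m, gamma=gamma, activity=m * gamma)

    put("H+", m_h, 1)
    put("OH-", m_oh, 1)
    put("CO2(aq)", m_co2, 0)
    put("HCO3-", m_hco3, 1)
    put("CO3--", m_co3, 2)
    put("NH4+", m_nh4, 1)
    put("NH3(aq)", m_nh3, 0)
    put("CH4(aq)", totals["CH4"], 0)
    put("H2(aq)", totals["H2"], 0)
    put("O2(aq)", totals["O2"], 0)
    put("CH3COO-", totals["acetate"], 1)
    put("SO4--", totals["SO4"], 2)
    put("NO3-", totals["NO3"], 1)
    put("NO2-", totals["NO2"], 1)
    put("HS-", totals["HS"], 1)
    put("H2PO4-", m_h2po4, 1)
    put("HPO4--", m_hpo4, 2)
    put("PO4---", m_po4, 3)
    put("Na+", filler_molal, 1)
    put("Cl-", filler_molal, 1)
    # a(H+) is fixed at 10**-pH by construction
    sp["H+"] = SpeciesState(molality=m_h, gamma=g[1], activity=a_h)

    charges = {
        "H+": 1, "OH-": -1, "HCO3-": -1, "CO3--": -2, "NH4+": 1,
        "CH3COO-": -1, "SO4--": -2, "NO3-": -1, "NO2-": -1, "HS-": -1,
        "H2PO4-": -1, "HPO4--": -2, "PO4---": -3, "Na+": 1, "Cl-": -1,
    }
    I_implied = 0.5 * sum(sp[name].molality * z * z for name, z in charges.items())
    return sp, I_implied


def _equilibrium_residual(sp: dict[str, SpeciesState], K: EquilibriumConstants,
                          a_h: float) -> float:
    """Max relative residual over every equilibrium relation used."""
    def a(name):
        return sp[name].activity

    checks = []
    if a("CO2(aq)") > 0:
        checks.append((a_h * a("HCO3-") / a("CO2(aq)"), K.K1_carbonic))
    if a("HCO3-") > 0:
        checks.append((a_h * a("CO3--") / a("HCO3-"), K.K2_carbonic))
    checks.append((a_h * a("OH-"), K.Kw))
    if a("NH4+") > 0:
        checks.append((a_h * a("NH3(aq)") / a("NH4+"), K.Ka_ammonium))
    if a("H2PO4-") > 0:
        checks.append((a_h * a("HPO4--") / a("H2PO4-"), K.Ka2_phosphoric))
    if a("HPO4--") > 0:
        checks.append((a_h * a("PO4---") / a("HPO4--"), K.Ka3_phosphoric))
    return max(abs(q - k) / k for q, k in checks)


def speciate(
    s: SiteSample,
    filler_na_cl_mM: float = DEFAULT_FILLER_NA_CL_MM,
    scenario: EnergyScenario | None = None,
) -> SpeciatedFluid:
    """Equilibrium speciation at the sample's measured pH and temperature.

    Ionic strength and activity coefficients are iterated to a relative
    change of 1e-10 (at most 100 iterations). Pure function of its
    arguments.
    """
    scenario = scenario or EnergyScenario()
    _check_preconditions(s)
    T_K = s.temperature_C + 273.15
    a_h = 10.0 ** (-s.pH)
    K = equilibrium_constants(T_K)
    totals, assumptions = _totals_molal(s, scenario)
    filler_molal = filler_na_cl_mM * 1e-3
    assumptions.append(f"Na+ = Cl- filler at {filler_na_cl_mM:g} mM")
    assumptions.append("molality ~ molarity (dilute fluid, density 1 kg/L)")

    I = filler_molal  # Na+ and Cl- alone give I = m
    sp: dict[str, SpeciesState] = {}
    for iteration in range(1, MAX_ITERATIONS + 1):
        sp, I_new = _assemble(s, K, totals, filler_molal, I, a_h, T_K)
        if abs(I_new - I) <= I_RELATIVE_TOL * max(I_new, 1e-12):
            I = I_new
            break
        I = I_new
    else:
        raise ConvergenceError(
            f"ionic-strength iteration did not converge for {s.site_id!r}; "
            f"last I = {I:g}"
        )
    # one final pass so every gamma is evaluated at the converged I
    sp, _ = _assemble(s, K, totals, filler_molal, I, a_h, T_K)
    residual = _equilibrium_residual(sp, K, a_h)
    return SpeciatedFluid(
        site_id=s.site_id,
        temperature_K=T_K,
        pH=s.pH,
        ionic_strength_molal=I,
        species=sp,
        iterations=iteration,
        residual=residual,
        assumptions=tuple(assumptions),
    )


def speciation_oracle(
    s: SiteSample,
    filler_na_cl_mM: float = DEFAULT_FILLER_NA_CL_MM,
    scenario: EnergyScenario | None = None,
) -> SpeciatedFluid:
    """Closed-form verification path for :func:`speciate`.

    The acid-base systems are evaluated directly through activity-based
    ionization fractions, and the self-consistent ionic strength is located
    by bracketing the fixed-point defect I_implied(I) - I on a grid and
    refining the root with Brent's method — no fixed-point iteration. Used
    in tests only.
    """
    scenario = scenario or EnergyScenario()
    _check_preconditions(s)
    T_K = s.temperature_C + 273.15
    a_h = 10.0 ** (-s.pH)
    K = equilibrium_constants(T_K)
    totals, assumptions = _totals_molal(s, scenario)
    filler_molal = filler_na_cl_mM * 1e-3

    def species_at(I: float) -> dict[str, SpeciesState]:
        g1 = activity_coefficient(1, I, T_K)
        g2 = activity_coefficient(2, I, T_K)
        g3 = activity_coefficient(3, I, T_K)
        # activity-based carbonate fractions:
        # DIC = a0 + a1/g1 + a2/g2 with a1 = K1 a0 / aH, a2 = K1 K2 a0 / aH^2
        denom = 1.0 + K.K1_carbonic / (a_h * g1) \
            + K.K1_carbonic * K.K2_carbonic / (a_h * a_h * g2)
        a0 = totals["DIC"] / denom
        a1 = K.K1_carbonic * a0 / a_h
        a2 = K.K2_carbonic * a1 / a_h
        # ammonium via activities: NH4_total = aN/g1 + aNH3, aNH3 = Ka aN/aH
        aN = totals["NH4_total"] / (1.0 / g1 + K.Ka_ammonium / a_h)
        aNH3 = K.Ka_ammonium * aN / a_h
        # phosphate
        dp = 1.0 / g1 + K.Ka2_phosphoric / (a_h * g2) \
            + K.Ka2_phosphoric * K.Ka3_phosphoric / (a_h * a_h * g3)
        aP1 = totals["PO4_total"] / dp if dp > 0 else 0.0
        aP2 = K.Ka2_phosphoric * aP1 / a_h
        aP3 = K.Ka3_phosphoric * aP2 / a_h

        out: dict[str, SpeciesState] = {}

        def put(name, activity, z):
            gamma = 1.0 if z == 0 else (g1, g2, g3)[abs(z) - 1]
            out[name] = SpeciesState(molality=activity / gamma, gamma=gamma,
                                     activity=activity)

        put("H+", a_h, 1)
        put("OH-", K.Kw / a_h, 1)
        put("CO2(aq)", a0, 0)
        put("HCO3-", a1, 1)
        put("CO3--", a2, 2)
        put("NH4+", aN, 1)
        put("NH3(aq)", aNH3, 0)
        put("CH4(aq)", totals["CH4"], 0)
        put("H2(aq)", totals["H2"], 0)
        put("O2(aq)", totals["O2"], 0)
        put("CH3COO-", totals["acetate"] * g1, 1)
        put("SO4--", totals["SO4"] * g2, 2)
        put("NO3-", totals["NO3"] * g1, 1)
        put("NO2-", totals["NO2"] * g1, 1)
        put("HS-", totals["HS"] * g1, 1)
        put("H2PO4-", aP1, 1)
        put("HPO4--", aP2, 2)
        put("PO4---", aP3, 3)
        put("Na+", filler_molal * g1, 1)
        put("Cl-", filler_molal * g1, 1)
        return out

    charges = {
        "H+": 1, "OH-": -1, "HCO3-": -1, "CO3--": -2, "NH4+": 1,
        "CH3COO-": -1, "SO4--": -2, "NO3-": -1, "NO2-": -1, "HS-": -1,
        "H2PO4-": -1, "HPO4--": -2, "PO4---": -3, "Na+": 1, "Cl-": -1,
    }

    def implied_I(I: float) -> float:
        out = species_at(I)
        return 0.5 * sum(out[n].molality * z * z for n, z in charges.items())

    def defect(I: float) -> float:
        return implied_I(I) - I

    grid = np.concatenate(([0.0], np.logspace(-12, math.log10(0.5), 200)))
    fvals = [defect(x) for x in grid]
    I_star = None
    for lo, hi, flo, fhi in zip(grid[:-1], grid[1:], fvals[:-1], fvals[1:]):
        if flo == 0.0:
            I_star = lo
            break
        if flo * fhi < 0:
            I_star = brentq(defect, lo, hi, xtol=1e-18, rtol=8.9e-16)
            break
    if I_star is None:
        raise ConvergenceError(
            f"oracle found no self-consistent ionic strength for {s.site_id!r}"
        )
    sp = species_at(I_star)
    residual = _equilibrium_residual(sp, K, a_h)
    return SpeciatedFluid(
        site_id=s.site_id,
        temperature_K=T_K,
        pH=s.pH,
        ionic_strength_molal=float(I_star),
        species=sp,
        iterations=0,
        residual=residual,
        assumptions=tuple(assumptions),
    )
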