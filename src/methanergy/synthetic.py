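"""Synthetic fluid-chemistry and taxonomy tables with known ground truth.

The fluid generator emulates the two endmember chemistries of a
serpentinization-influenced watershed: hyperalkaline spring fluids (pH ~
11.5, reducing ORP, CH4 hundreds of µM, H2 tens of µM, DIC ~ 200 µM) versus
circumneutral background surface/ground water (pH ~ 8.2, oxidizing, CH4 <~
0.3 µM, DIC ~ 550 µM). Concentrations get lognormal noise (positive,
spanning orders of magnitude between endmembers); pH, temperature and ORP
get normal noise. These distributions are this module's contract, not a
hydrological model — no mixing, titration or reaction-path simulation.

The taxonomy generator allocates a fixed read depth per sample by a
multinomial draw over guild lineages (taken from the default guild lists)
plus filler lineages, so screen estimates can be compared against exact
target fractions.

All randomness derives from one integer seed through
``numpy.random.SeedSequence(seed).spawn(...)``: child 0 drives the fluid
table, child 1 the taxonomy table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .fluidchem import SiteSample, validate_sample
from .speciation import (
    EnergyScenario,
    activity_coefficient,
    equilibrium_constants,
)
from .taxa import TaxonomyTable, GUILDS
import pandas as pd

__all__ = [
    "AnalyteSpec",
    "FluidSimParams",
    "TaxSimParams",
    "KnownSpeciationCase",
    "simulate_fluid_table",
    "simulate_taxonomy_table",
    "known_speciation_case",
    "default_endmembers",
]


@dataclass(frozen=True)
class AnalyteSpec:
    """One analyte's endmember distribution.

    ``dist`` is "normal" (spread = standard deviation, for pH/temperature/
    ORP) or "lognormal" (spread = coefficient of variation, for
    concentrations).
    """

    dist: str
    mean: float
    spread: float

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.dist == "normal":
            return rng.normal(self.mean, self.spread, size=n)
        if self.dist == "lognormal":
            if self.mean <= 0:
                return np.zeros(n)
            sigma2 = math.log(1.0 + self.spread ** 2)
            mu = math.log(self.mean) - sigma2 / 2.0
            return rng.lognormal(mu, math.sqrt(sigma2), size=n)
        raise ValueError(f"unknown distribution {self.dist!r}")


def default_endmembers() -> dict[str, dict[str, AnalyteSpec]]:
    """Spring vs background endmember settings (means in the field ranges)."""
    return {
        "spring": {
            "pH": AnalyteSpec("normal", 11.5, 0.1),
            "temperature_C": AnalyteSpec("normal", 27.5, 1.5),
            "orp_mV": AnalyteSpec("normal", -310.0, 40.0),
            "conductivity_uS_cm": AnalyteSpec("lognormal", 515.0, 0.08),
            "ch4_uM": AnalyteSpec("lognormal", 500.0, 0.5),
            "h2_uM": AnalyteSpec("lognormal", 30.0, 0.5),
            "dic_uM": AnalyteSpec("lognormal", 200.0, 0.3),
            "doc_uM": AnalyteSpec("lognormal", 30.0, 0.8),
            "nox_uM": AnalyteSpec("lognormal", 0.4, 1.0),
            "nh4_uM": AnalyteSpec("lognormal", 1.2, 0.5),
            "po4_uM": AnalyteSpec("lognormal", 0.2, 0.7),
        },
        "background": {
            "pH": AnalyteSpec("normal", 8.2, 0.4),
            "temperature_C": AnalyteSpec("normal", 26.5, 2.0),
            "orp_mV": AnalyteSpec("normal", 80.0, 40.0),
            "conductivity_uS_cm": AnalyteSpec("lognormal", 560.0, 0.2),
            "ch4_uM": AnalyteSpec("lognormal", 0.3, 1.0),
            "h2_uM": AnalyteSpec("lognormal", 1.0, 1.0),
            "dic_uM": AnalyteSpec("lognormal", 550.0, 0.2),
            "doc_uM": AnalyteSpec("lognormal", 60.0, 0.4),
            "nox_uM": AnalyteSpec("lognormal", 2.0, 1.0),
            "nh4_uM": AnalyteSpec("lognormal", 1.0, 1.0),
            "po4_uM": AnalyteSpec("lognormal", 1.8, 0.5),
        },
    }


@dataclass
class FluidSimParams:
    n_spring: int = 3
    n_background: int = 6
    seed: int = 0
    endmembers: dict[str, dict[str, AnalyteSpec]] = field(
        default_factory=default_endmembers
    )

    def validate(self) -> None:
        if self.n_spring < 0 or self.n_background < 0:
            raise ValueError("site counts must be >= 0")
        for em, specs in self.endmembers.items():
            for name, spec in specs.items():
                if spec.spread < 0:
                    raise ValueError(f"{em}/{name}: spread must be >= 0")
                if name == "pH" and not (6.0 <= spec.mean <= 12.5):
                    raise ValueError(f"{em}/pH mean {spec.mean} outside 6-12.5")
                if name.endswith("_uM") and spec.mean < 0:
                    raise ValueError(f"{em}/{name}: mean must be >= 0")


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_fluid_table(p: FluidSimParams) -> tuple[list[SiteSample], dict]:
    """Synthetic site table + ground truth (the endmember parameters used).

    Deterministic given the seed; every generated sample passes validation.
    """
    p.validate()
    rng = _spawn(p.seed, 2)[0]
    samples: list[SiteSample] = []
    for site_type, em_name, n in (
        ("spring", "spring", p.n_spring),
        ("river", "background", p.n_background),
    ):
        specs = p.endmembers[em_name]
        draws = {name: spec.draw(rng, n) for name, spec in specs.items()}
        for i in range(n):
            values = {name: float(col[i]) for name, col in draws.items()}
            values["pH"] = float(np.clip(values["pH"], 0.01, 13.99))
            values["temperature_C"] = float(
                np.clip(values["temperature_C"], 0.01, 59.99))
            samples.append(SiteSample(
                site_id=f"SYN-{em_name}-{i + 1}",
                site_type=site_type,
                **values,
            ))
    for s in samples:
        violations = validate_sample(s)
        if violations:  # pragma: no cover - guarded by clipping above
            raise AssertionError(f"generated sample invalid: {violations}")
    ground_truth = {
        "seed": p.seed,
        "n_spring": p.n_spring,
        "n_background": p.n_background,
        "endmembers": {
            em: {name: {"dist": sp.dist, "mean": sp.mean, "spread": sp.spread}
                 for name, sp in specs.items()}
            for em, specs in p.endmembers.items()
        },
    }
    return samples, ground_truth


# -- taxonomy tables ---------------------------------------------------------

_GUILD_LINEAGES = {
    "methanogen": (
        "Archaea;Euryarchaeota;Methanobacteria;Methanobacteriales;"
        "Methanobacteriaceae;Methanobacterium",
        "Archaea;Euryarchaeota;Methanomicrobia;Methanomicrobiales;"
        "Methanoregulaceae;Methanoregula",
        "Archaea;Euryarchaeota;Methanomicrobia;Methanosarcinales;"
        "Methanosarcinaceae;Methanosarcina",
    ),
    "ANME": (
        "Archaea;Euryarchaeota;Methanomicrobia;Methanosarcinales;"
        "ANME-1b;ANME-1b_unclassified",
        "Archaea;Euryarchaeota;Methanomicrobia;Methanosarcinales;"
        "ANME-2d;Methanoperedens",
    ),
    "methanotroph_bacteria": (
        "Bacteria;Proteobacteria;Gammaproteobacteria;Methylococcales;"
        "Methylococcaceae;Methylomonas",
        "Bacteria;Proteobacteria;Gammaproteobacteria;Methylococcales;"
        "Methylococcaceae;Methylococcus",
    ),
    "NC10": (
        "Bacteria;NC10;Methylomirabilia;Methylomirabilales;"
        "Methylomirabilaceae;Methylomirabilis",
    ),
}

_FILLER_TEMPLATES = {
    "Archaea": "Archaea;Crenarchaeota;Thermoprotei;Thermoproteales;"
               "Thermoproteaceae;SynthGenusA{i}",
    "Bacteria": "Bacteria;Proteobacteria;Alphaproteobacteria;Rhizobiales;"
                "Rhizobiaceae;SynthGenusB{i}",
}

_DOMAIN_GUILDS = {
    "Archaea": ("methanogen", "ANME"),
    "Bacteria": ("methanotroph_bacteria", "NC10"),
}


@dataclass
class TaxSimParams:
    """Per-sample guild fraction targets for one domain's amplicon table."""

    sample_targets: list[dict[str, float]]
    n_reads: int = 10_000
    n_filler_taxa: int = 20
    domain: str = "Archaea"
    seed: int = 0

    def validate(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be > 0")
        if self.n_filler_taxa <= 0:
            raise ValueError("n_filler_taxa must be > 0")
        if self.domain not in _DOMAIN_GUILDS:
            raise ValueError(f"domain must be one of {list(_DOMAIN_GUILDS)}")
        for i, targets in enumerate(self.sample_targets):
            for guild, frac in targets.items():
                if guild not in _DOMAIN_GUILDS[self.domain]:
                    raise ValueError(
                        f"sample {i}: guild {guild!r} not in domain "
                        f"{self.domain!r} guilds {_DOMAIN_GUILDS[self.domain]}"
                    )
                if frac < 0:
                    raise ValueError(f"sample {i}: fraction {frac} < 0")
            if sum(targets.values()) > 1.0 + 1e-12:
                raise ValueError(f"sample {i}: guild fractions sum > 1")


def simulate_taxonomy_table(p: TaxSimParams) -> tuple[TaxonomyTable, list[dict[str, float]]]:
    """Multinomial taxonomy table + the exact target fractions used."""
    p.validate()
    rng = _spawn(p.seed, 2)[1]
    guilds = _DOMAIN_GUILDS[p.domain]
    lineages: list[str] = []
    lineage_guild: list[Optional[str]] = []
    for guild in guilds:
        for lin in _GUILD_LINEAGES[guild]:
            lineages.append(lin)
            lineage_guild.append(guild)
    for i in range(p.n_filler_taxa):
        lineages.append(_FILLER_TEMPLATES[p.domain].format(i=i + 1))
        lineage_guild.append(None)

    columns = {}
    for j, targets in enumerate(p.sample_targets):
        probs = np.zeros(len(lineages))
        for guild in guilds:
            idx = [k for k, g in enumerate(lineage_guild) if g == guild]
            frac = targets.get(guild, 0.0)
            probs[idx] = frac / len(idx)
        filler_idx = [k for k, g in enumerate(lineage_guild) if g is None]
        remainder = 1.0 - sum(targets.values())
        probs[filler_idx] = remainder / len(filler_idx)
        columns[f"sample_{j + 1}"] = rng.multinomial(p.n_reads, probs)

    table = TaxonomyTable(
        lineages=lineages,
        counts=pd.DataFrame(columns, dtype=int),
    )
    return table, [dict(t) for t in p.sample_targets]


# -- analytic speciation fixtures -------------------------------------------

@dataclass(frozen=True)
class KnownSpeciationCase:
    """A sample engineered so that the solver's self-consistent ionic
    strength equals ``ionic_strength_molal``, plus closed-form activities.

    For the I = 0 (pure-water-like) case the filler is zero and the exact
    ionic strength is the tiny self-ionization value; the expected
    activities listed here are exact only where they are
    gamma-independent (H+, OH-, neutral species) or zero (carbonate with
    DIC = 0) — use DIC ~ 0 with I_target = 0.
    """

    sample: SiteSample
    filler_na_cl_mM: float
    ionic_strength_molal: float
    expected_activities: dict[str, float]
    dominant_carbonate: str


def known_speciation_case(
    pH: float,
    T_K: float,
    dic_uM: float,
    I_target: float,
    ch4_uM: float = 145.0,
    h2_uM: float = 38.3,
    scenario: EnergyScenario | None = None,
) -> KnownSpeciationCase:
    """Oracle fixture: closed-form carbonate activities at fixed pH with
    Davies activity coefficients evaluated at ``I_target``; the Na/Cl filler
    is back-calculated so the solver reproduces ``I_target`` exactly."""
    scenario = scenario or EnergyScenario()
    K = equilibrium_constants(T_K)
    a_h = 10.0 ** (-pH)
    g1 = activity_coefficient(1, I_target, T_K)
    g2 = activity_coefficient(2, I_target, T_K)
    dic = dic_uM * 1e-6

    denom = 1.0 + K.K1_carbonic / (a_h * g1) \
        + K.K1_carbonic * K.K2_carbonic / (a_h * a_h * g2)
    a_co2 = dic / denom
    a_hco3 = K.K1_carbonic * a_co2 / a_h
    a_co3 = K.K2_carbonic * a_hco3 / a_h
    a_oh = K.Kw / a_h

    floor = scenario.trace_floor_molal
    i_nonfiller = 0.5 * (
        a_h / g1 + a_oh / g1 + a_hco3 / g1 + 4.0 * a_co3 / g2
        + floor + floor  # NO2- and HS- trace assignments, |z| = 1
    )
    filler_molal = I_target - i_nonfiller
    if filler_molal < 0:
        if I_target == 0.0:
            filler_molal = 0.0
        else:
            raise ValueError(
                f"I_target {I_target} below the solute-only ionic strength "
                f"{i_nonfiller:.3g}; increase I_target"
            )

    fractions = {
        "CO2(aq)": 1.0 / denom,
        "HCO3-": (K.K1_carbonic / (a_h * g1)) / denom,
        "CO3--": (K.K1_carbonic * K.K2_carbonic / (a_h * a_h * g2)) / denom,
    }
    dominant = max(fractions, key=fractions.get)

    sample = SiteSample(
        site_id=f"case_pH{pH:g}_I{I_target:g}",
        site_type="spring",
        temperature_C=T_K - 273.15,
        pH=pH,
        dic_uM=dic_uM,
        doc_uM=0.0,
        ch4_uM=ch4_uM,
        h2_uM=h2_uM,
    )
    expected = {
        "H+": a_h,
        "OH-": a_oh,
        "CO2(aq)": a_co2,
        "HCO3-": a_hco3,
        "CO3--": a_co3,
        "CH4(aq)": ch4_uM * 1e-6,
        "H2(aq)": h2_uM * 1e-6,
    }
    return KnownSpeciationCase(
        sample=sample,
        filler_na_cl_mM=filler_molal * 1e3,
        ionic_strength_molal=I_target if filler_molal > 0 else i_nonfiller,
        expected_activities=expected,
        dominant_carbonate=dominant,
    )
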