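# Methods

This note documents the models, parameter choices and numerical conventions
behind `methanergy`, and what the synthetic-data tests do and do not
demonstrate.

## Fluid data model

A site record carries the measured physicochemical parameters (pH,
temperature, conductivity, TDS, salinity, ORP), dissolved carbon (DOC, DIC
and δ¹³C-CO₂), nitrogen and phosphorus species, dissolved gases (CH₄ with
δ¹³C-CH₄, H₂) and water isotopes, all concentrations in µmol/L. Cells below
detection are stored as nulls and excluded from summaries; detection limits
(e.g. 0.1 µM for DON) are table metadata, never substituted values —
imputation policy belongs to the analyst, not the reader. Sulfate is an
explicit nullable field even though the packaged field table has no sulfate
column, because the sulfate-coupled methane-oxidation reaction needs it;
downstream code must be handed an assumed value explicitly.

The packaged fixture transcribes the nine-site Santa Elena Ophiolite table
verbatim. The source's narrative ranges occasionally disagree with its own
table (text pH "11.2–11.6" vs table minimum 11.54; text ORP "−380" vs table
−348); the fixture follows the table and the discrepancy is simply noted
here, not resolved.

## Speciation

**Fixed-pH partitioning.** pH was measured in the field, so a(H⁺) is fixed
at 10^(−pH) and no charge-balance solve for H⁺ is attempted. The Na⁺ = Cl⁻
filler (default 12.5 mM, the midpoint of the 10–15 mM appropriate for these
fluids' salinity) only contributes ionic strength. The carbonate system is
partitioned over CO₂(aq)/HCO₃⁻/CO₃²⁻ by K₁ and K₂ at the fluid temperature
with activity corrections, constrained to sum to measured DIC; ammonium and
phosphate are handled identically. Whether the original speciation honored
measured pH exactly or re-equilibrated with the atmosphere is not
documented anywhere we can check; fixed-pH partitioning is the defensible
choice for field-measured pH and is what this package does.

**Equilibrium constants.** All constants are derived from the same embedded
formation-energy table used for reaction energetics, via
ln K = −ΔG°(T)/(RT). This guarantees internal consistency: the pK values
the speciation uses (pK_w = 14.00, pK₁ = 6.35, pK₂ = 10.33 at 25 °C) are
exactly what the reaction catalog implies. Computing Ka₂/Ka₃ of phosphoric
acid and Ka of acetic acid requires H₂PO₄⁻ and CH₃COOH(aq) entries, so the
species table carries them even though they matter little at pH 11.5.

**Activity model.** Davies equation,
log₁₀ γ = −A z² (√I/(1+√I) − 0.3 I), with A = 0.509 at 25 °C and a weak
quadratic temperature dependence. The fluids are dilute (EC ≤ 700 µS/cm,
I ≈ 0.01–0.02 molal with the filler), far inside the Davies validity range
(I ≲ 0.5), so differences against B-dot-style models are negligible;
documented so results can be compared against B-dot implementations.
Neutral species get γ = 1 (no Setchenow salting-out). Molality ≈ molarity
(density 1 kg/L). a(H₂O) = 1.

**Scenario species.** Dissolved O₂ was not measured: it enters as a stated
fraction of air-saturation solubility (anchors 284.2/258.0/236.4/217.8 µM
at 20/25/30/35 °C after Benson & Krause 1984, linear interpolation).
Acetate enters as a stated fraction of measured DOC; on the default
*carbon* basis one acetate accounts for two DOC carbons
(m = fraction × DOC/2), with a *molar* basis (m = fraction × DOC)
selectable. NO₃⁻ = max(NOx − NO₂, 0). Measured ORP is carried as data but
does not enter the speciation — no redox re-speciation is attempted.

**Trace floor for unmeasured products.** In-situ ΔG of the anaerobic
oxidation pathways requires activities for NO₂⁻ (printed as 0.0 µM at the
springs) and HS⁻ (never measured). Species whose measured/assumed total is
zero are assigned a nominal trace molality, default 10⁻⁹ mol/kg (1 nM), in
the spirit of the nominal-product-concentration convention of
hydrothermal-bioenergetics calculations; every such substitution is
recorded in the output's assumptions list, and the floor is a scenario
parameter. Because ΔG depends logarithmically on the floor, ΔG of AOM-NO₃
shifts by only ~2.3 kJ/mol per 10× change in the floor against a ~−600
kJ/mol total — orderings reported here are insensitive to it.

**Numerics.** Ionic strength and activity coefficients are iterated to a
relative change of 10⁻¹⁰ (typically 5–7 iterations; hard cap 100 with a
convergence error). After convergence every equilibrium relation is
re-checked; the reported residual is ≤ 10⁻⁸ relative by contract and
~10⁻¹⁶ in practice. A closed-form re-implementation (ionization fractions
in activity space, ionic strength located by grid bracketing plus Brent
root refinement, no fixed-point iteration) serves as an independent
verification path in the tests; the two agree to better than 10⁻¹² relative
on random valid fluids.

## Reaction energetics

ΔG = ΔG° + RT ln Q with R = 8.314 J/(mol·K). ΔG°(25 °C) is the
stoichiometric sum of standard Gibbs energies of formation from a curated
~20-species aqueous table (SUPCRT-lineage compilation, source cited per
entry in `data/species.csv`); the temperature correction is
Gibbs–Helmholtz at constant reaction enthalpy,
ΔG°(T) = ΔG°(T₀)·T/T₀ + ΔH°(T₀)·(1 − T/T₀), valid here for 283–333 K. Over
the spring range (24–30 °C) the error of this correction is well under
1 kJ/mol, which does not justify implementing a full revised-HKF equation
of state. Aqueous standard states are used throughout, 1 bar, no pressure
correction.

The catalog (editable CSV) holds five reactions:

| id | reaction | ΔG°₂₅ (kJ/mol) |
|----|----------|-----------------|
| MG | CO₂(aq) + 4 H₂(aq) → CH₄(aq) + 2 H₂O | −193.7 |
| AM | CH₃COO⁻ + H₂O → CH₄(aq) + HCO₃⁻ | −14.9 |
| AOM-SO₄ | CH₄(aq) + SO₄²⁻ → HCO₃⁻ + HS⁻ + H₂O | −33.2 |
| AOM-NO₃ | CH₄(aq) + 4 NO₃⁻ → HCO₃⁻ + 4 NO₂⁻ + H⁺ + H₂O | −474.9 |
| AeMO | CH₄(aq) + 2 O₂(aq) → HCO₃⁻ + H⁺ + H₂O | −822.8 |

Bicarbonate is the inorganic-carbon product of the oxidations (the dominant
carbonate species from circumneutral to alkaline pH); the hydrogenotrophic
pathway consumes dissolved CO₂ explicitly. Nitrate-AOM is written to
nitrite (the ANME-2d/Methanoperedens partial denitrification); a variant to
N₂ would be more exergonic per mole of CH₄ but needs an N₂ activity
assumption — since the catalog is a data file, substituting electron
acceptor products requires no code change. Methylotrophic methanogenesis is
deliberately absent (no genomic support in these systems). Element and
charge balance of every catalog entry is enforced by a bookkeeping check.

## Energy density and ranking

The extent of reaction per liter is min over candidate reactants of
(bulk total)/|ν|, using measured bulk totals: DIC for CO₂, measured CH₄ and
H₂, NOx-derived nitrate, and the scenario-assumed acetate, O₂ and sulfate.
Bulk totals (not speciated sub-pools) follow the established
limiting-component convention for such calculations; a
`use_speciated_pools` flag switches to the speciated pool (e.g. CO₂(aq)
instead of DIC) for sensitivity analysis. Yield is
E = max(0, −ΔG) × extent / 1000 (J/L); endergonic reactions clamp to zero
yield ("energy available" semantics) with the positive ΔG retained. J/L is
the base unit because typical values are ≪ 1 kJ/L.

The default scenario grid crosses O₂ ∈ {0.1 %, 1.0 %} of air saturation
with acetate ∈ {1 %, 10 %} of DOC. In reports each reaction varies only
along the axis it responds to — two acetate bars for AM, two O₂ bars for
AeMO, one bar each for MG, AOM-SO₄ and AOM-NO₃ — giving seven rows per
site. Cells that cannot be computed (AOM-SO₄ without an assumed sulfate)
are emitted as "skipped" rows with a message, never silently dropped:
default assumed sulfate is *none*, because the field table has no sulfate
and silently inventing one would corrupt comparisons. Ranking sorts
computed cells by yield, descending, with a stable sort so ties keep
catalog order.

**A sensitivity note on orderings.** On the packaged springs the pipeline
reproduces: hydrogenotrophic > acetoclastic at Q. Danta (by ~60×; DOC there
is only 5.6 µM), acetoclastic > hydrogenotrophic at Spring 8 under the 10 %
acetate case (by ~5 %; this ordering hinges entirely on the
DOC-composition assumption), and nitrate-AOM capped at ≤ 0.2 µmol/L extent
by electron-acceptor scarcity, far below both methanogenic substrates.
Note that electron-acceptor *limitation* (tiny extent) does not force
nitrate-AOM below acetoclastic methanogenesis in J/L everywhere: at
Q. Danta the acetate pool is so small that AOM-NO₃'s ~−600 kJ/mol makes it
the larger per-liter yield of the two. Per-mole favorability and per-liter
yield answer different questions; both are reported.

## Taxonomy screen

Input is an already-classified table (OTU/ASV processing is upstream and
out of scope). Guilds: aerobic methanotrophic bacteria (17 genera of
Methylococcaceae, Methylocystaceae, Beijerinckiaceae and Verrucomicrobia —
the list keeps the legacy transcription "Methyothermus" *and* the standard
"Methylothermus" for recall), NC10 (Ca. Methylomirabilis / phylum NC10),
methanogens (seven orders: Methanopyrales, Methanococcales,
Methanobacteriales, Methanomicrobiales, Methanocellales,
Methanoplasmatales, Methanosarcinales), and ANME (clade labels ANME-1
through ANME-3 at any rank). Matching is exact-token per rank after
stripping quotes, mothur confidence suffixes and "Candidatus" prefixes:
genera at the genus rank, orders at the order rank. Methanoperedens
(ANME-2d) overrides its parent order Methanosarcinales into ANME, so a
lineage contributes to exactly one guild.

Relative abundance = matched counts / total counts of the lineage's domain
per sample (archaeal fractions over archaeal reads — bacterial and archaeal
amplicon sets are separate surveys). "Domain total" means all reads whose
first rank is that domain, including unclassified-below-domain reads; this
is a convention, stated here because the alternative (excluding
unclassified) inflates fractions. Samples with zero reads in the domain
report null, not zero.

## Synthetic data

The fluid generator draws spring and background endmembers with lognormal
noise on concentrations (positive, order-of-magnitude spread) and normal
noise on pH/temperature/ORP. Defaults: springs pH N(11.5, 0.1), CH₄
lognormal about 500 µM, H₂ about 30 µM, DIC about 200 µM, ORP about
−310 mV; background pH N(8.2, 0.4), CH₄ about 0.3 µM, DIC about 550 µM,
oxidizing ORP — i.e. the contrast between serpentinized and meteoric
endmember chemistry. These distributions are the generator's contract, not
a hydrological claim: there is no mixing, titration or reaction-path model,
no covariance between analytes, and no seasonality. Tests passing on this
generator therefore demonstrate numerical correctness and statistical
calibration of the pipeline, not geochemical realism of any particular
watershed.

The taxonomy generator allocates a fixed read depth per sample
multinomially over guild lineages plus filler lineages, so screen estimates
have exact targets; recovery is asserted within the 4·√(f(1−f)/n) binomial
band (coverage ≥ 95 % over 1000 replicates at 10⁴ reads). One global
integer seed drives everything through `numpy.random.SeedSequence.spawn`,
so every draw is reproducible.

`known_speciation_case` builds solver fixtures with closed-form expected
activities: carbonate ionization fractions at fixed pH with Davies γ at a
target ionic strength, and a back-calculated Na/Cl filler that makes the
solver's self-consistent ionic strength land exactly on the target. For the
I = 0 (pure-water-like) case only γ-independent activities (H⁺, OH⁻,
neutral species) are exact, so that case is used with DIC ≈ 0.

## Problem sizes used in the shipped checks

The packaged field table (9 sites, 3 springs), 100 random synthetic fluids
for solver/oracle equivalence, and 1000 multinomial replicates at 10⁴ reads
for screen calibration; the whole suite and the acceptance script each run
in seconds.

## Known limitations

- No mineral saturation indices, CO₂ in/degassing, Pitzer or revised-HKF
  models; no pressure correction.
- ΔG° correction assumes constant reaction enthalpy — adequate for
  24–30 °C, not for hydrothermal temperatures.
- Measured ORP is not used to re-speciate redox couples.
- Per-liter yields ignore kinetics, growth yields and power supply
  (kJ/kg/yr); they bound what catabolism could harvest, not what organisms
  do harvest.
- The sulfate pathway's yield is only as good as the assumed sulfate and
  the 1 nM sulfide floor.
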