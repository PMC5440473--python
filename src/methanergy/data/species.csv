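# Standard-state thermodynamic properties of aqueous species at 25 C, 1 bar.
# dGf/dHf in kJ/mol, converted (1 cal = 4.184 J) from the SUPCRT92 "slop"
# compilation (Johnson/Oelkers/Helgeson lineage; Shock & Helgeson 1988,
# Shock et al. 1989/1997 for the aqueous ions and neutral gases).
# formula syntax: Element:count pairs joined by ';'.
name,formula,charge,dGf_25C_kJ_mol,dHf_25C_kJ_mol,phase,source
H2O,H:2;O:1,0,-237.183,-285.830,liquid,SUPCRT92 (-56688/-68317 cal)
H+,H:1,1,0.0,0.0,aqueous,convention
OH-,H:1;O:1,-1,-157.297,-230.024,aqueous,SUPCRT92 (-37595/-54977 cal)
CO2(aq),C:1;O:2,0,-385.974,-413.798,aqueous,SUPCRT92 (-92250/-98900 cal)
HCO3-,C:1;H:1;O:3,-1,-586.940,-689.933,aqueous,SUPCRT92 (-140282/-164898 cal)
CO3--,C:1;O:3,-2,-527.983,-675.234,aqueous,SUPCRT92 (-126191/-161385 cal)
CH4(aq),C:1;H:4,0,-34.451,-87.906,aqueous,SUPCRT92 (-8234/-21010 cal)
H2(aq),H:2,0,17.723,-4.184,aqueous,SUPCRT92 (4236/-1000 cal)
O2(aq),O:2,0,16.544,-12.134,aqueous,SUPCRT92 (3954/-2900 cal)
CH3COO-,C:2;H:3;O:2,-1,-369.322,-486.010,aqueous,SUPCRT92 (-88270/-116180 cal)
CH3COOH(aq),C:2;H:4;O:2,0,-396.476,-485.760,aqueous,SUPCRT92 (-94760/-116100 cal)
SO4--,S:1;O:4,-2,-744.459,-909.602,aqueous,SUPCRT92 (-177930/-217400 cal)
HS-,H:1;S:1,-1,11.966,-16.108,aqueous,SUPCRT92 (2860/-3850 cal)
NO3-,N:1;O:3,-1,-110.905,-206.811,aqueous,SUPCRT92 (-26507/-49429 cal)
NO2-,N:1;O:2,-1,-32.217,-104.600,aqueous,SUPCRT92 (-7700/-25000 cal)
NH4+,N:1;H:4,1,-79.454,-133.260,aqueous,SUPCRT92 (-18990/-31850 cal)
NH3(aq),N:1;H:3,0,-26.706,-81.170,aqueous,SUPCRT92 (-6383/-19400 cal)
H2PO4-,H:2;P:1;O:4,-1,-1130.266,-1296.287,aqueous,SUPCRT92 (-270140/-309820 cal)
HPO4--,H:1;P:1;O:4,-2,-1089.137,-1292.081,aqueous,SUPCRT92 (-260310/-308815 cal)
PO4---,P:1;O:4,-3,-1018.804,-1277.379,aqueous,SUPCRT92 (-243500/-305300 cal)
Na+,Na:1,1,-261.881,-240.300,aqueous,SUPCRT92 (-62591/-57433 cal)
Cl-,Cl:1,-1,-131.290,-167.080,aqueous,SUPCRT92 (-31379/-39933 cal)
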