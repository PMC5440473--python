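# Catabolic reaction catalog: methane-cycling metabolisms considered for the
# hyperalkaline-spring fluids. Stoichiometry: species:coefficient pairs,
# reactants negative, products positive. limiting: reactant species mapped to
# the measured/assumed bulk total (in umol/L) that caps its availability.
reaction_id,name,category,stoichiometry,limiting
MG,Hydrogenotrophic methanogenesis,methanogenesis,CO2(aq):-1;H2(aq):-4;CH4(aq):1;H2O:2,CO2(aq):dic_uM;H2(aq):h2_uM
AM,Acetoclastic methanogenesis,methanogenesis,CH3COO-:-1;H2O:-1;CH4(aq):1;HCO3-:1,CH3COO-:acetate_from_doc
AOM-SO4,Anaerobic methane oxidation (sulfate),anaerobic_methanotrophy,CH4(aq):-1;SO4--:-1;HCO3-:1;HS-:1;H2O:1,CH4(aq):ch4_uM;SO4--:so4_assumed
AOM-NO3,Anaerobic methane oxidation (nitrate),anaerobic_methanotrophy,CH4(aq):-1;NO3-:-4;HCO3-:1;NO2-:4;H+:1;H2O:1,CH4(aq):ch4_uM;NO3-:no3_from_nox
AeMO,Aerobic methane oxidation,aerobic_methanotrophy,CH4(aq):-1;O2(aq):-2;HCO3-:1;H+:1;H2O:1,CH4(aq):ch4_uM;O2(aq):o2_air_sat
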