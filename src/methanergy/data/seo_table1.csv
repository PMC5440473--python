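site_id,site_type,temperature_C,pH,conductivity_uS_cm,tds_ppm,salinity_ppm,orp_mV,doc_uM,dic_uM,d13C_CO2_permil,tdn_uM,nox_uM,no2_uM,nh4_uM,don_uM,po4_uM,tdp_uM,ch4_uM,d13C_CH4_permil,h2_uM,d18O_permil,d2H_permil,so4_uM
Q. Danta,spring,29.2,11.59,542,358,412,-251,5.6,126.3,-20.1,0.4,0.8,0.0,1.3,bdl,0.1,0.1,145.0,-44.0,38.3,-7.18,-50.0,
Q. Danta Upstream,river,27.9,8.42,470,334,357,66,103.0,597.3,-17.9,6.6,2.5,0.1,0.6,3.5,1.6,0.2,0.3,bdl,9.2,-4.33,-33.4,
Spring 8,spring,26.1,11.54,543,386,414,-331,73.2,227.0,-17.9,14.2,0.3,0.0,1.7,12.2,0.2,0.1,870.7,-0.9,10.9,-7.22,-50.4,
Spring 9,spring,26.4,11.54,466,333,351,-348,41.2,254.3,-20.8,1.7,0.2,0.0,0.8,1.1,0.3,0.1,912.3,-2.2,53.1,-7.18,-50.4,
Murciélago Upstream,river,24,8.9,492,306,326,35,67.1,533.7,-19.8,1.7,0.3,0.1,0.1,1.3,1.6,0.2,14.3,1.3,0.8,-7.02,-45.7,
R. Calera,river,25.3,8.61,493,349,372,148,59.5,663.3,-18.6,2.6,1.8,0.0,0.1,0.7,1.9,0.2,0.3,bdl,23.7,-6.65,-45.1,
P. Murciélago,well,28,7.54,700,498,535,97,11.6,748.0,-19.5,62.4,58.3,0.0,2.1,2.0,2.7,0.4,0.3,bdl,1.0,-7.12,-47.6,
P. Nuevo,well,30.2,8.3,696,535,496,76,20.2,417.7,-18.6,3.5,0.2,0.0,4.1,bdl,1.7,0.6,0.3,bdl,0.8,-6.84,-48.9,
P. Aguas Calientes,well,30.2,7.26,603,428,459,70,25.9,644.3,-18.7,39.2,36.8,0.0,1.5,0.9,2.7,1.1,0.2,bdl,1.0,-6.65,-45.1,
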