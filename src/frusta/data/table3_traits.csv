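taxon,specimen,group,ilium_area_cm2,mass_kg,log10_mass,iy_body,iy_leg,iy_body_leg,agility_force_planted,agility_moment_planted,agility_force_pointe,agility_moment_pointe
Dilophosaurus_wetherelli,UCMP 37302,other,380.16,372.07,2.571,213,0.279,218,1.78,2.57,1.75,2.51
Ceratosaurus_nasicornis,USNM 4735,other,903.83,678.26,2.831,546,1.093,559,1.60,2.21891,1.57,2.61
Eustreptospondylus_oxoniensis,OUM J13558,other,280,206.26,2.314,70.45,0.098,73.26,3.97,4.70,3.82,4.52
Allosaurus_fragilis_USNM,USNM 4734,other,1131.5,1512.10,3.180,2303.25,2.405,2344.62,0.49,1.13,0.48,1.11
Allosaurus_fragilis_UUVP,UUVP 6000,other,1228.06,1683.33,3.226,2036.81,2.121,2078.55,0.60,1.43,0.59,1.41
Acrocanthosaurus_atokensis,NCSM 14345,other,2551.25,5474.1,3.738,14979,19.718,15377.24,0.17,0.60,0.17,0.58
Giganotosaurus_carolinii,MUCPv-CH-1,other,3540.64,6907.6,3.839,35821,23.731,26593.36,0.10,0.511,0.13,0.507
Sinraptor_hepingensis,ZDM 0024,other,1268.9,2373.5,3.430,3530.7,4.929,3740.32,0.343,0.93,0.339,0.91
Yangchuanosaurus_shangyouensis,CV 00215,other,992.4,2176.4,3.173,2836.7,3.365,1672.88,0.61,1.36,0.59,1.31
Raptorex_kriegsteini,LH PV18,tyrannosaurid_juvenile,179.7,47.07,1.673,4.65,0.0205,4.68,43.96,31.74,43.60,31.49
Tarbosaurus_bataar_juvenile,ZPAL MgD-I/3,tyrannosaurid_juvenile,1455.2,727.45,2.861,535,1.437,548,2.72,2.39,2.65,4.77
Tarbosaurus_bataar_adult_ZPAL,ZPAL MgD-I/4,tyrannosaurid_adult,2800,2249.1,3.352,3069.9,5.586,3126.17,0.912,2.39,0.905,2.37
Tarbosaurus_bataar_adult_PIN,PIN 552-1,tyrannosaurid_adult,2977,2816.3,3.450,4486,10.049,4515.1,0.664,1.87,0.659,1.86
Tyrannosaurus_rex_juvenile,BMRP 2002.4.1,tyrannosaurid_juvenile,1107.41,660.23,2.820,344.83,0.683,347,3.21,5.59,3.19,5.56
Tyrannosaurus_rex_adult_AMNH,AMNH 5027,tyrannosaurid_adult,4786.49,6986.6,3.844,18175,34.067,18276.08,0.263,1.01,0.262,1.00
Tyrannosaurus_rex_adult_FMNH,FMNH PR 2081,tyrannosaurid_adult,6661.8,9130.87,3.963,28847,51.205,29297,0.231,0.97,0.227,0.95
Gorgosaurus_libratus_adult,AMNH 5458,tyrannosaurid_adult,2358,2427.3,3.385,3219,9.79,3312,0.73,1.97,0.70,1.67
Gorgosaurus_libratus_juvenile_AMNH,AMNH 5664,tyrannosaurid_juvenile,1040.56,687.7,2.837,402,1.087,420.14,2.59,4.56,2.48,4.37
Gorgosaurus_libratus_juvenile_TMP,TMP 91.36.500,tyrannosaurid_juvenile,1060.93,496.1,2.70,251.95,0.660,265.29,4.21,6.67,4.00,6.33
Daspletosaurus_torosus,CMN 8506,tyrannosaurid_adult,3209.77,3084.8,3.489,5338,9.665,5586,0.60,1.75,0.58,1.67
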