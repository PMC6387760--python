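scenario,response,comparison,F,p,alpha_printed
planted,force,among_groups,10.2,0.0014,0.0244
planted,force,juvenile_vs_adult,0.0054,0.9421,0.1325
planted,force,tyrannosaurs_vs_others,19.45,0.0004,0.0084
planted,moment,among_groups,6.71,0.077,0.3492
planted,moment,juvenile_vs_adult,0.008,0.9301,0.1548
planted,moment,tyrannosaurs_vs_others,12.91,0.0024,0.0379
pointe,force,among_groups,10.44,0.0013,0.0229
pointe,force,juvenile_vs_adult,0.149,0.7044,0.4015
pointe,force,tyrannosaurs_vs_others,19.21,0.0005,0.0102
pointe,moment,among_groups,10.69,0.0011,0.0200
pointe,moment,juvenile_vs_adult,0.160,0.6938,0.4081
pointe,moment,tyrannosaurs_vs_others,19.61,0.0004,0.0084
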