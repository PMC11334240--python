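name,category,density_g_cm3,provenance,H,C,N,O,Na,Mg,P,S,Cl,K,Ca,Fe,Ar
water,soft,1.000,base-set,0.1119,0,0,0.8881,0,0,0,0,0,0,0,0,0
air,low_density,0.001205,base-set,0,0,0.755,0.232,0,0,0,0,0,0,0,0,0.013
lung,low_density,0.26,base-set,0.103,0.105,0.031,0.749,0.002,0,0.002,0.003,0.003,0.002,0,0,0
adipose,soft,0.95,base-set,0.114,0.598,0.007,0.278,0.001,0,0,0.001,0.001,0,0,0,0
muscle,soft,1.05,base-set,0.102,0.143,0.034,0.710,0.001,0,0.002,0.003,0.001,0.004,0,0,0
liver,soft,1.06,base-set,0.102,0.139,0.030,0.716,0.002,0,0.003,0.003,0.002,0.003,0,0,0
brain,soft,1.04,base-set,0.107,0.145,0.022,0.712,0.002,0,0.004,0.002,0.003,0.003,0,0,0
blood,soft,1.06,base-set,0.102,0.110,0.033,0.745,0.001,0,0.001,0.002,0.003,0.002,0,0.001,0
skin,soft,1.09,base-set,0.100,0.204,0.042,0.645,0.002,0,0.001,0.002,0.003,0.001,0,0,0
red_marrow,soft,1.03,base-set,0.105,0.414,0.034,0.439,0,0,0.001,0.002,0.002,0.002,0,0.001,0
yellow_marrow,soft,0.98,base-set,0.115,0.644,0.007,0.231,0.001,0,0,0.001,0.001,0,0,0,0
cortical_bone,bone,1.92,base-set,0.034,0.155,0.042,0.435,0.001,0.002,0.103,0.003,0,0,0.225,0,0
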