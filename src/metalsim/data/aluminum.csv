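energy_keV,mu_over_rho_cm2_g
10,26.23
15,7.955
20,3.441
30,1.128
40,0.5685
50,0.3681
60,0.2778
80,0.2018
100,0.1704
150,0.1378
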