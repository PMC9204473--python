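energy_keV,mu_over_rho_cm2_g
10,5.356
15,1.693
20,0.8205
30,0.3793
40,0.2685
50,0.2262
60,0.2048
80,0.1823
100,0.1693
150,0.1492
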