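# Mass attenuation coefficient of bismuth, Z=83 (total, with coherent scattering)
# K edge at 90.526 keV; stored as two nodes 1 eV either side
# energy_keV	mu_over_rho_cm2_g
30	31.80
40	15.10
50	8.463
60	5.292
80	2.552
90.525	1.894
90.527	7.300
100	5.739
150	2.082
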