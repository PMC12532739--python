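# Mass attenuation coefficient of lead, Z=82 (total, with coherent scattering)
# K edge at 88.005 keV; stored as two nodes 1 eV either side
# energy_keV	mu_over_rho_cm2_g
30	30.32
40	14.36
50	8.041
60	5.021
80	2.419
88.004	1.910
88.006	7.683
100	5.549
150	2.014
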