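# Mass attenuation coefficient of copper, Z=29 (total, with coherent scattering)
# energy_keV	mu_over_rho_cm2_g
30	10.92
40	4.862
50	2.613
60	1.593
80	0.7630
100	0.4584
150	0.2217
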