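# Mass attenuation coefficient of liquid water (total, with coherent scattering)
# energy_keV	mu_over_rho_cm2_g
30	0.3756
40	0.2683
50	0.2269
60	0.2059
80	0.1837
100	0.1707
150	0.1505
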