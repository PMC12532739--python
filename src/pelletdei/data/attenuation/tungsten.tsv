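# Mass attenuation coefficient of tungsten, Z=74 (total, with coherent scattering)
# K edge at 69.525 keV; the edge is stored as two nodes 1 eV either side so
# that energies remain strictly increasing
# energy_keV	mu_over_rho_cm2_g
30	22.73
40	10.67
50	5.949
60	3.713
69.524	2.552
69.526	11.23
80	7.810
100	4.438
150	1.581
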