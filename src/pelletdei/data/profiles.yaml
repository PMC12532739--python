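# Calibration profiles for the synthetic DECT phantom generator.
#
# Each material entry gives the target per-pellet dual-energy-index (DEI)
# distribution (mean, SD) measured on a clinical dual-source scanner, the
# pellet count per gelatine block, and the pellet diameter.  The generator
# inverts the DEI formula to obtain the low-kVp interior HU from the
# high-kVp anchor, so the simulated blocks reproduce these distributions by
# construction.
#
# Classification boundaries are protocol specific (they shift with the kVp
# pair), so they live here with the profile they were calibrated for.

paper-100-140:
  kvp: [100, 140]
  hu_high_anchor: 8000.0        # interior high-kVp HU, extended scale
  gelatine_hu: [60.0, 50.0]     # background HU at (low, high) kVp
  noise_sd: 15.0                # additive Gaussian noise, HU
  block_size_mm: [70.0, 70.0, 150.0]
  spacing_mm: [0.504, 0.504, 1.0]
  depth_range_mm: [20.0, 120.0] # axial pellet depth band
  min_separation_mm: 10.0
  materials:
    steel:    {dei_mean: 0.212, dei_sd: 0.006, n_pellets: 5,  diameter_mm: 3.0}
    lead:     {dei_mean: 0.008, dei_sd: 0.001, n_pellets: 4,  diameter_mm: 3.0}
    copper:   {dei_mean: 0.187, dei_sd: 0.002, n_pellets: 13, diameter_mm: 3.0}
    tungsten: {dei_mean: 0.012, dei_sd: 0.004, n_pellets: 6,  diameter_mm: 3.0}
    bismuth:  {dei_mean: 0.008, dei_sd: 0.002, n_pellets: 8,  diameter_mm: 3.0}
  classification:
    steel_min: 0.1995           # midpoint of the copper and steel means
    copper_min: 0.1
    ambiguous_halfwidth: 0.0

# Size-robustness protocol: steel pellets at a lower low-kV tube voltage
# (maximises beam hardening), one block of 3 mm and one of 4 mm pellets.
# The two DEI means differ by 0.0024 units (0.8 %); stated to three decimals
# they round to 0.300 and 0.297.
paper-80-140-steel:
  kvp: [80, 140]
  hu_high_anchor: 8000.0
  gelatine_hu: [60.0, 50.0]
  noise_sd: 15.0
  block_size_mm: [70.0, 70.0, 150.0]
  spacing_mm: [0.504, 0.504, 1.0]
  depth_range_mm: [20.0, 120.0]
  min_separation_mm: 10.0
  materials:
    steel-3mm: {dei_mean: 0.2996, dei_sd: 0.002, n_pellets: 20, diameter_mm: 3.0}
    steel-4mm: {dei_mean: 0.2972, dei_sd: 0.002, n_pellets: 20, diameter_mm: 4.0}
  classification:
    steel_min: 0.25
    copper_min: 0.1
    ambiguous_halfwidth: 0.0
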