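# pelletdei

Dual-energy CT (DECT) material analysis of shotgun pellets.

Retained shotgun pellets are common in both trauma care and forensic
casework, and their material matters: lead is toxic, and steel (soft iron)
pellets are ferromagnetic and can rule out MRI. Conventional CT cannot tell
the metals apart — their Hounsfield units saturate and overlap — but a
dual-energy acquisition carries spectral information. `pelletdei`
implements the complete analysis chain for this problem:

- **DEI volumes** — the dual-energy index of co-registered low/high-kVp
  volumes `I_low`, `I_high` on the extended HU scale,

  ```
  DEI = (I_low − I_high) / (I_low + I_high + 2000)
  ```

  which is 0 for water and material specific otherwise.
- **Automated pellet segmentation** — fixed 2000 HU threshold on the
  high-kVp image (strictly above = pellet), slicewise erosion by a
  4-pixel-diameter disk to strip the partial-volume shell, 26-connected
  component labelling, and per-pellet mean/SD DEI.
- **Material discrimination** — per-material summaries, a pairwise
  two-sided Wilcoxon rank-sum p-value matrix (exact null for small tie-free
  samples, tie-corrected normal approximation otherwise), and a
  category classifier (steel / copper / high-Z indeterminate) that surfaces
  the ferromagnetic flag.
- **Attenuation physics** — packaged elemental mass-attenuation tables
  (30–150 keV, K edges included) for Fe, Cu, W, Pb, Bi and water, with
  log-log interpolation, theoretical HU, and the closed-form monochromatic
  DEI prediction `(r_L − r_H)/(r_L + r_H)` where `r_E = μ_material(E)/μ_water(E)`.
- **Synthetic phantoms** — a seeded generator of gelatine blocks
  (70 × 70 × 150 mm, 0.504 × 0.504 × 1.0 mm voxels) containing spherical
  pellets whose two-energy HU values are inverted from target per-material
  DEI distributions, with supersampled partial-volume blending, Gaussian
  noise, and ground-truth sidecars. Every pipeline stage is testable
  without any scanner data.

## Worked example

Run the full pipeline on the packaged five-block phantom (one block per
pellet material, with the study's pellet counts):

```sh
pelletdei pipeline --profile paper-100-140 --seed 2 --outdir full --no-volumes
```

prints

```
36 pellets detected; artifacts in full
material  n  mean_dei   sd_dei   ...             category  ferromagnetic
   steel  5  0.216887 0.006397   ...                steel           True
    lead  4  0.008196 0.000662   ... high-Z indeterminate          False
  copper 13  0.186855 0.002367   ...               copper          False
tungsten  6  0.011729 0.005158   ... high-Z indeterminate          False
 bismuth  8  0.007920 0.001754   ... high-Z indeterminate          False
```

All 36 pellets are found; the recovered per-material means sit within
±0.01 of the calibration targets (steel 0.212, lead 0.008, copper 0.187,
tungsten 0.012, bismuth 0.008). The pairwise rank-sum matrix
(`full/pvalues.csv`) shows the expected pattern — steel and copper separate
from everything (p < 0.05), while lead vs bismuth is far from significant
(p = 0.93 here): those high-Z metals cannot be told apart, which is why the
classifier pools them. The steel row carries `ferromagnetic=True`, the
clinically actionable output.

Other subcommands: `simulate` (generate blocks + truth sidecars), `dei`,
`segment`, `analyze` (group statistics from a per-pellet CSV); the same
functionality is available as a library (`pelletdei.run_pipeline`,
`pelletdei.compute_dei_volume`, …).

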