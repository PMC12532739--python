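# Methods

## The measurement model

A dual-source DECT acquisition yields two co-registered reconstructions of
the same object at different tube voltages (here nominally 100/140 kVp or
80/140 kVp with tin filtration on the high-energy tube). For a voxel with
values `I_low`, `I_high` in Hounsfield units the dual-energy index is

    DEI = (I_low − I_high) / (I_low + I_high + 2000).

Since HU + 1000 is proportional to linear attenuation, the +2000 offset
rewrites the index as a normalized contrast of attenuation ratios: with
`r_E = μ_material(E) / μ_water(E)`,

    DEI = (r_low − r_high) / (r_low + r_high)

for a monochromatic acquisition. Water is identically 0; materials whose
attenuation falls faster with energy than water's (low-Z metals in the
photoelectric regime) have positive DEI. The package computes both sides of
this identity — the voxelwise formula in `dei.py` and the closed form from
packaged attenuation tables in `physics.py` — and the test suite asserts
their equivalence to 1e−9 across all packaged materials and 30–150 keV
energy pairs.

The monochromatic prediction explains the *direction* of the effect (iron
and copper separate strongly from the K-edge metals) but deliberately does
not reproduce measured values for tungsten, lead and bismuth: a real
scanner integrates a polychromatic spectrum, and at these extreme
attenuations the measured DEI collapses toward zero through saturation and
beam hardening. No spectrum model is attempted; the synthetic phantoms
reproduce measured statistics by construction instead (below).

## Attenuation tables

`data/attenuation/` ships two-column (keV, cm²/g) text tables for Fe, Cu,
W, Pb, Bi and liquid water over 30–150 keV, transcribed from the standard
elemental mass-attenuation tabulations, with standard elemental densities
(Fe 7.87, Cu 8.96, W 19.30, Pb 11.35, Bi 9.78, water 1.00 g/cm³) in a
manifest. Interpolation is linear in (log E, log μ/ρ) — attenuation is near
power-law between edges — and returns tabulated values exactly at nodes.
K edges (W 69.525, Pb 88.005, Bi 90.526 keV) are stored as two nodes 1 eV
apart so the energy grid stays strictly increasing and interpolation is
well defined across the edge. Ballistic gelatine is modelled as water: it
is a soft-tissue surrogate and no composition-resolved table is warranted.
"Steel" resolves to iron — steel shot is soft iron, radiologically
indistinguishable.

## Segmentation

The pellet pipeline follows the fully automated scheme: threshold the
high-kVp volume at a fixed 2000 HU (strictly greater than; metals on the
extended HU scale sit far above, soft tissue far below), erode, label
26-connected components, and summarise DEI per component.

Erosion removes the partial-volume shell, whose blended voxels would bias
mean DEI toward the background. It is applied *per axial slice* with a
disk structuring element of 4-pixel diameter: voxels are strongly
anisotropic (0.504 mm in plane, 1.0 mm between slices), so an in-plane
disk is the only unambiguous reading of a disk element. The footprint is
the 13-pixel set at Euclidean distance ≤ 2.0 from the centre pixel (a 5×5
box minus the corners and (±2, ±1) pixels — identical to
`skimage.morphology.disk(2)`), shipped as a text fixture so the operation
is bit-reproducible; out-of-image pixels count as background. This
convention is declared, not inferred: 2D-vs-3D and the exact footprint are
free choices, and the tests pin this one against a brute-force
min-over-translated-footprint oracle.

Component labelling uses the most permissive 26-neighbourhood so an eroded
core that survives in two adjacent slices is never double-counted.
Components erased entirely by erosion simply produce no record;
`min_core_voxels` (default 1) and an optional min/max voxel-count hook
(default off, for rejecting non-pellet dense objects like dental work) are
exposed in `SegmentationConfig`. Per-pellet mean and SD (n−1) are taken
over the component's valid-DEI voxels after sorting, so results are
independent of voxel traversal order — permuting the volume axes (with the
slice axis tracked through the permutation) changes nothing, not even the
last bit; a component with no valid voxels is logged and excluded.
Centroids are voxel-index means × spacing, in mm.

## Group statistics and classification

Per-material groups of per-pellet mean DEI are summarised (mean, n−1 SD —
undefined and reported missing for n = 1 — and box-plot quartiles) and
compared pairwise with the two-sided Wilcoxon rank-sum test: the exact
enumeration null when n_a + n_b ≤ 20 and the pooled sample is tie free,
otherwise the midrank normal approximation with tie-corrected variance.
The matrix diagonal is fixed at 1.000 and raw p-values are reported;
a Holm step-down option exists but is off by default, matching the raw
pairwise reporting convention. Significance is flagged at α = 0.05.

Classification maps a mean DEI to steel (≥ 0.1995, the midpoint of the
copper 0.187 and steel 0.212 calibration means), copper (0.1–0.1995) or
"high-Z indeterminate" (< 0.1). Lead, tungsten and bismuth are never
separated — their measured DEI distributions overlap almost completely —
and steel alone carries the ferromagnetic flag. Boundaries are
protocol-specific configuration, not code: at 80/140 kVp steel shifts to
≈ 0.30, so each phantom profile carries its own boundaries.

## Synthetic phantoms

The generator emulates the study's gelatine blocks: 70 × 70 × 150 mm at
0.504 × 0.504 × 1.0 mm voxels (139 × 139 × 150 grid), spherical pellets of
3–4 mm diameter at seeded uniform positions 20–120 mm deep with ≥ 10 mm
pairwise separation. Per-material calibration inverts the DEI formula:
a pellet's DEI is drawn from Normal(mean, SD) of its material profile, and
with high-kVp interior anchor `H2` the low-kVp interior is

    H1 = (H2 (1 + d) + 2000 d) / (1 − d),

the unique solution of the DEI equation, so noise-free interiors
round-trip their drawn DEI exactly. Defaults, chosen once as the study
conditions: anchor `H2` = 8000 HU for all materials (metals only need to
exceed the 2000 HU threshold; a common anchor isolates DEI as the
discriminating quantity, and per-material anchors/jitter remain
configurable), gelatine background (60, 50) HU at (low, high) energy —
slightly denser than water — and additive Gaussian noise of SD 15 HU,
independent between energies, the simplest model consistent with a
well-dosed reconstruction. Partial volume is modelled by supersampling
each voxel 4× per axis and blending `f·H_material + (1−f)·H_gelatine`; at
that factor a 3 mm sphere's rasterised volume matches the analytic volume
to well under 2 %. Draw order per block is documented and fixed (per-pellet
DEI and anchor jitter in pellet order, then the two noise fields), so a
(spec, seed) pair is bit-reproducible and a truth sidecar (centre,
diameter, material, drawn DEI, H1/H2, merge flags) accompanies every block.

The packaged profiles carry the calibration targets: `paper-100-140` with
per-material means/SDs 0.212 ± 0.006 (steel, 5 pellets), 0.008 ± 0.001
(lead, 4), 0.187 ± 0.002 (copper, 13), 0.012 ± 0.004 (tungsten, 6),
0.008 ± 0.002 (bismuth, 8); and `paper-80-140-steel` with two 20-pellet
steel blocks. The 3 mm and 4 mm entries of the latter are calibrated to
0.2996 and 0.2972: the two means are stated as 0.300/0.297 at three
decimals but their difference as 0.0024 DEI units (0.8 %), and
0.2996/0.2972 is the unrounded pair consistent with both statements.

What the phantoms do *not* emulate: polychromatic spectra, beam-hardening
streaks (an optional subtractive streak overlay is cosmetic only and off
by default), scatter, reconstruction blur, wound tracks, correlated noise.
Passing recovery tests therefore demonstrates that the *pipeline* is
unbiased and size/orientation invariant under the stated geometry and
noise — not that a scanner will reproduce the calibration values; those
are themselves measured inputs.

## Numerical and design choices

- DEI volumes are float64; voxels where |I_low + I_high + 2000| < 1 HU
  (impossible for tissue/metal, possible for synthetic input) are masked
  invalid and set to 0 so downstream statistics never see NaN.
- The threshold comparison is strict (`>`), so a voxel at exactly 2000 HU
  is background.
- Exact rank-sum p-values are defined as 2·min(P(W ≤ w), P(W ≥ w)) capped
  at 1, matching exhaustive enumeration over all rank assignments.
- Pellet placement is rejection sampling; an unplaceable layout (too many
  pellets for the separation constraint) raises rather than degrades.
- Overlapping pellets are allowed but warn and are flagged `merged` in the
  truth sidecar; a pellet protruding outside the block is an error.
- Validation problem sizes: the five-block study phantom (~139² × 150
  voxels × 2 energies per block) runs the full pipeline in a few seconds;
  the detection-fidelity sweep uses 100 compact 40 mm blocks with four
  well-separated pellets each, which exercises the identical code path at
  a fraction of the cost.

## Known limitations

- The high-Z calibration values are *measured* statistics; the physics
  module intentionally predicts much larger monochromatic DEI for W/Pb/Bi
  and should not be used as a quantitative forward model for them.
- Segmentation assumes pellets are the only objects above 2000 HU; in
  clinical data dental work or implants require the size-filter hook or
  manual review.
- Touching pellets merge into one component (no watershed splitting), as
  flagged in the truth sidecar.
- The DICOM pathway is out of scope; volumes travel as NIfTI plus JSON
  sidecar.
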