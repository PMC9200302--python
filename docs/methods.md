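# Methods

## Densitometric model

All quantitative readouts derive from the Hounsfield scale anchored at the
density of air (−1000 HU) and water (0 HU). Raw scanner grey levels `g` are
rescaled by the exact linear map

    HU(g) = −1000 + (g − g_air) · 1000 / (g_water − g_air)

where `g_air` and `g_water` are measured anchor grey levels supplied by the
caller; no native grey range is assumed, and calibrated values are never
clipped (clipping would bias the mean lung attenuation, from which
everything else follows).

Within the segmented parenchyma mask (V_exp, the total lung volume at
end-expiration) voxels are binned into aeration compartments:

| compartment  | HU band        | convention        |
|--------------|----------------|-------------------|
| hyper        | < −860         | tracked separately|
| normo-aerated| [−860, −435)   | half-open         |
| hypo-aerated | [−435, −121)   | half-open         |
| non-aerated  | [−121, 121]    | closed            |
| dense-out    | > 121          | tracked separately|

The boundary values −435 and −121 appear in two adjacent published ranges;
a deterministic rule is required, and each shared edge is assigned to the
denser band. Hyper and dense-out voxels are counted in V_exp so the five
compartments always partition the mask exactly; compartment percentages are
normalised to the full mask volume (an alternative — normalising to the sum
of the three named bands — differs only by the hyper/dense-out fraction and
can be computed from the reported volumes).

Functional readouts from the mean lung attenuation MLA (arithmetic mean HU
over the mask):

    FRC    = V_exp · MLA / (−1000)     clamped to [0, V_exp], clamps logged
    Tissue = V_exp − FRC
    A/T    = FRC / Tissue              undefined (NaN + warning) at Tissue=0

The algebraic identity A/T = (FRC/V_exp) / (1 − FRC/V_exp) holds whenever
tissue is positive and is asserted in the tests. Raising any in-mask
voxel's HU can only raise MLA, so FRC is non-increasing and Tissue
non-decreasing in every voxel's HU — a monotonicity property the tests
check directly.

## Segmentation

The automatic path reproduces standard rodent-CT practice: threshold at an
aeration cutoff (default −300 HU, between the parenchyma and soft-tissue
modes), label connected components (26-connectivity by default), discard
the ambient-air component touching the volume border and components below
100 voxels, then spherical closing (radius 2) followed by hole filling per
axial slice and in 3D so dense interior lesions are recaptured into the
mask. The mask is covariant with intensity shifts: adding a constant to the
volume and to the threshold leaves it unchanged.

Conducting airways are removed by seeded region growing restricted to
sub-threshold voxels. The leak guard aborts a wavefront generation whose
voxel count exceeds twice the running total; it is armed only after 50
voxels, because the first shells around a single seed always violate that
ratio. Note the guard's reach: a breadth-first front in a lattice grows at
most polynomially while the running total grows one power faster, so the
rule only catches *immediate* explosions (a front bursting from a short
tube into open space). It is a safety net, not a substitute for sensible
seed placement. Airway removal is optional — whether V_exp should include
the conducting-airway lumen is a convention choice; the default excludes
it whenever a seed is given.

Severely consolidated lungs defeat any threshold rule (the reason manual
segmentation exists in this field); manually drawn masks are accepted as
files and either unioned with or substituted for the automatic mask.

## Synthetic phantom

The phantom emulates an expiratory-phase mouse chest on a 96³ grid at
0.05 mm isotropic spacing (configurable; geometry scales with the grid):
ambient air, an ellipsoidal soft-tissue body (40 ± 15 HU), two ellipsoidal
lungs (~46 k voxels combined), and a sealed tracheal air tube between them.
The clean scene defines the ground truth: per-voxel labels, the true air
fraction clip(HU/−1000, 0, 1), and the achieved lesion fraction (within
±0.01 of target). Measurement is then emulated by a Gaussian
partial-volume blur (σ = 1 voxel), additive Gaussian HU noise (sd 25 HU),
and an affine encoding into grey levels whose calibration pair is returned
— consumers must run the grey→HU step themselves, so every recovery test
exercises the full pipeline. Identical spec and seed give bit-identical
phantoms.

Design choices that matter, and why:

- **Correlated parenchyma texture.** Healthy parenchyma HU is a Gaussian
  field with a 2.5-voxel correlation length rather than iid voxel noise.
  Real parenchymal texture (vessels, alveolar clustering) varies on a
  supra-voxel scale; iid noise would be annihilated by the partial-volume
  blur and the healthy lung would show an unrealistically narrow HU
  distribution with almost no hypo-aerated tail.
- **Calibrated healthy distribution.** The parenchyma mean and sd are not
  hand-picked: `calibrate_healthy(78.5, 21.5)` grid-searches mean ∈
  [−750, −550] (step 25), sd ∈ [60, 160] (step 20) HU and accepts the first
  candidate whose *pipeline-measured* normo/hypo fractions (averaged over
  seeds 1–5) land within ±2 points of the targets — the normo/hypo split
  reported for healthy (saline-treated) animals. The persisted result is
  mean −575, sd 160 HU, giving 78.3% normo / 20.8% hypo on the calibration
  seeds. Seed-to-seed spread of the normo fraction is roughly ±1.5 points.
- **Clustered lesions with a collapsed-parenchyma halo.** Fibrotic lesions
  are spheres (radius U(2, 6) voxels, HU U(−100, 60)) placed by
  preferential attachment (each new lesion lands near an existing one with
  probability 0.7), yielding the patchy, confluent foci seen
  histologically. Each lesion union is wrapped in a 2-voxel halo of
  partially collapsed parenchyma (−140 ± 20 HU). The halo is physiology
  (peri-lesional atelectasis) and measurement necessity at once: a bare
  −20 HU lesion bordered by −575 HU parenchyma loses a ~0.9-voxel rim
  below −121 HU to the blur, and a 5% inserted fraction would read back as
  only ~2.5–3.5% non-aerated; the halo's inner shell absorbs that rim loss
  so the measured non-aerated fraction tracks the inserted fraction
  (5% inserted → 4.8% measured, seed-averaged).
- **Interior placement.** Lesion centres keep a Euclidean-distance margin
  (halo width + 3 voxels) from the pleura. Subpleural dense tissue merges
  with the chest wall and no threshold-based mask can retain it — the very
  failure mode that forces manual segmentation on real severe lungs — so
  the phantom tests the automatic pipeline on lesions it is designed to
  capture.
- **Lesion-stream prefix property.** Lesion draws (centre, radius, HU)
  come from a dedicated RNG stream that never depends on the target
  fraction; a larger target simply extends the same sequence. Longitudinal
  series built from one base seed therefore have nested lesions whenever
  the schedule is non-decreasing, giving monotone non-aerated fractions
  and air/tissue ratios across time-points. Non-monotone (resolution)
  schedules are allowed and flagged in the series metadata.

What the phantom does *not* emulate: anatomically realistic airway trees
(the trachea is sealed and disconnected from the lungs — with a connected
tree the running-total leak guard could not stop parenchyma flooding),
cardiac/respiratory motion, beam hardening, or scanner-specific noise
spectra. Passing recovery tests therefore demonstrates correctness of the
densitometric bookkeeping and robustness to partial volume and additive
noise, not performance on real scanner artefacts.

## Histology and statistics

Ashcroft scores (integers 0–8 per microscopic field) aggregate per animal
as the mean across fields and as a frequency distribution over mild
(≤ 3), moderate (4) and severe (≥ 5) classes; the class rule is defined on
reals (3 < s < 5 → moderate) so averaged scores grade deterministically.
With two raters the per-field score defaults to the rater mean rounded
half-up before grading — the reconciliation rule is an assumption and can
be disabled.

Spearman correlation uses mid-rank ties and the two-sided t approximation
on n − 2 df (the common software default), with exact permutation
enumeration available for n ≤ 9. Group comparisons fit one-way or
day×group factorial OLS ANOVA (type-II sums of squares) with Tukey
all-pairs or Dunnett many-to-one (reference "saline") post-hoc contrasts;
for the factorial design the post-hoc runs within each day and empty
design cells are reported, never silently dropped. The factorial model
treats the long table as printed; a repeated-measures error structure
(animals as their own controls across days) is a known alternative not
modelled here. Body weight is tracked as percent change from day 0, with
the humane-endpoint flag at −20%. Under a permuted-labels null with five
animals per group the ANOVA's empirical type-I error is calibrated (checked
at α = 0.05 over 1000 simulations).

## Numerical and scale choices

Phantom-based checks use 96³ grids (the default study condition) with 5-
or 20-seed averages; unit tests use 48³–64³ grids, the smallest at which
the scaled anatomy retains a lung depth able to host interior lesions.
Profiles report volumes in mm³ and fractions in percent of V_exp;
conservation of compartment volumes is exact (integer voxel counts), the
A/T identity is asserted to 1e-9 relative tolerance, and FRC/V_exp
recovery against phantom truth is required to a mean absolute error of
0.05 under default blur and noise (measured ≈ 0.031). Degenerate inputs
fail loudly: empty masks, zero tissue volume, constant rank vectors,
coincident calibration anchors and infeasible lesion loads all raise
typed exceptions rather than returning silent NaNs or infinities.
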