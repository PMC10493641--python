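# Methods

This note documents the models behind `fogmap`, the choices made where the
design was genuinely open, and what the synthetic validation does and does
not establish.

## Volume of tissue activated

Stimulation is modelled as monopolar and quasi-static: the active contact
is a Dirichlet electrode held at the stimulation amplitude, the boundary
of the solver grid is ground (standing in for the distant implanted
case), and the potential solves `∇·(σ∇φ) = 0`. The discretization is a
7-point finite-difference stencil with harmonic-mean face conductivities
on a regular voxel grid — the same physics as a tetrahedral FEM, chosen
because it is compact, fast, and testable against a closed form. The
linear system is solved by Jacobi-preconditioned conjugate gradients
(sparse-direct fallback) to a relative residual of 1e-8; the
unit-amplitude problem is solved once and scaled, so the potential is
exactly linear in amplitude and identically zero at 0 V.

Conductivities (S/m): grey matter 0.33, white matter 0.14, contacts 1e6,
insulated shaft 1e-6. The conductor/insulator values are limiting values,
not tissue measurements; 1e6/1e-6 (twelve orders of magnitude apart) keep
the system well-conditioned enough for the stated residual tolerance in
double precision, which more extreme values do not.

Each hemisphere is solved on a local 0.5 mm subgrid (half-width 8 mm)
centred on the active contact — amply larger than any VTA at therapeutic
amplitudes, where the 0.2 V/mm threshold radius is ~3 mm. The e-field
magnitude is the central-difference gradient in V/mm; voxels inside the
electrode body are zeroed (they are not tissue); the binary VTA is
`|E| ≥ 0.2 V/mm`. Pulse width and frequency are carried as metadata but do
not enter the field model, which is amplitude-driven at a fixed threshold.

**Solver oracle.** In a homogeneous medium, a point-like source inside a
concentric grounded sphere of radius R has `φ(r) = c (1/r − 1/R)` — the
monopole `c/r` corrected for the finite ground, reducing to `c/r` as
R → ∞. The test fits `c` at r ≈ 2 mm and requires the FD solution to track
the curve within 5 % for r ∈ [2, 6] mm on a 0.5 mm grid (measured: ~2.6 %).
A pure `c/r` comparison is not meaningful at desk scale: with any
tractable grounded box the boundary term alone exceeds 5 % at r = 6 mm
(the ground would need to sit ≥ ~80 mm away), so the oracle compares
against the exact solution of the boundary-value problem actually solved.
The VTA boundary is additionally checked against the analytic radius where
the field crosses 0.2 V/mm (within one voxel), and the solver obeys
nestedness in amplitude, exact mirror symmetry, and < 10 % volume change
under voxel-size halving.

## Analysis space and atlas

Everything lives in a single RAS millimetre space on a 61×71×61 grid at
1 mm (x ∈ [−30, 30], y ∈ [−40, 30], z ∈ [−30, 30]), loosely shaped like
template coordinates around the midbrain. The toy atlas places two
mirror-symmetric ellipsoidal STNs (semi-axes 5.5 × 2.5 × 3.5 mm, long axis
tilted dorsolateral→ventromedial) centred at (±12, −13, −7), partitioned
along the long axis into sensorimotor (dorsolateral 50 %), associative
(30 %) and limbic (ventromedial 20 %) subregions, plus two midline
spherical parcels standing in for SMA/pre-SMA (0, −8, 24) and prefrontal
cortex (0, 18, 6). STN and parcels are grey matter; everything else is
white matter. The left STN is the mirrored label block of the right, so
left/right voxel counts match exactly (the grid must be symmetric about
x = 0).

Clinical workflows compute VTAs in native space and analyse groups in
template space; the synthetic pipeline has one space by construction, so
no normalization step is modelled.

## Synthetic cohort and planted truth

The generator's defaults are the study conditions:

- **n = 76 bilateral patients.** Stimulation settings per hemisphere from
  truncated normals matching published STN-DBS cohort moments (amplitude
  2.36 ± 0.56 V right / 2.41 ± 0.52 V left; pulse width 67.6 ± 11.3 /
  70.0 ± 11.4 µs; frequency 131.3 ± 21.2 / 130.9 ± 19.9 Hz, truncated at
  the ≥ 90 Hz high-frequency inclusion criterion). Baseline FOG-Q is an
  integer from N(16.89, 5.46) clipped to 10–24 (the questionnaire is
  modelled as a 0–24 total, six items × 0–4).
- **Lead placement.** Tips are aimed so the *expected* active contact
  (contacts drawn with probabilities 0.2/0.35/0.35/0.1 from tip-most up)
  sits at the STN centre, then jittered with SD 2 mm per axis. The jitter
  has a patient-level component shared by both hemispheres (60 % of the
  variance, mirrored in x) plus independent per-side noise: bilateral
  placement within one operation is correlated (same surgeon, protocol and
  anatomy), and this correlation is what lets one outcome number per
  patient constrain maps on both sides.
- **Planted effects.** A sweet sphere (radius 3 mm, +1.2 % per mm³ of VTA
  overlap) at the dorsolateral sensorimotor pole of each STN
  (±13.1, −12.4, −4.9) and a sour sphere (radius 3 mm, −1.5 %/mm³) at the
  ventromedial limbic pole (±10.2, −14.0, −10.4); ±15 % offsets for
  engaging the positive/negative fibre bundle (a patient "engages" a
  bundle when the bilateral VTA union touches the majority of its
  fibres); Gaussian noise with SD 40 on the percent scale. The latent
  change is clipped to [−100, 100] and the post-operative score is
  `round(pre·(1 − change/100))` clipped to 0–24, so realized changes are
  discretized — tests that need the exact linear formula use the stored
  latent value. The noise SD mimics the dispersion reported for real
  cohorts; with the planted signal on top, the realized outcome SD lands
  somewhat above it.
- **Streamlines.** 20 000 total: 1 000 fibres per planted bundle and
  18 000 correlated-random-walk distractors (persistence 0.85, 1.5 mm
  steps, 30 steps, clipped to the grid). The planted bundles are
  *bilateral arches*, the way merged hemispheric pathways appear in
  group-level tractograms: each positive-bundle fibre runs from the right
  sensorimotor pole over the midline SMA-like parcel into the left pole
  (quadratic Bézier with apex at the parcel), and the negative bundle
  arches between the limbic poles through the prefrontal parcel. The
  bilateral geometry matters: a one-sided bundle's connected patients form
  a compact spatial set that retained random-walk distractors can mimic,
  whereas no local random walk reproduces an either-pole set spanning
  hemispheres 26 mm apart — so the planted bundle, and only the planted
  bundle, captures the bilaterally-summed outcome.
- **Functional connectome.** 20 synthetic subjects × 200 time points on a
  2 mm grid. Each subject is white noise plus two shared low-rank
  networks: one loading on the SMA-like parcel + sensorimotor STN, one on
  the prefrontal parcel + limbic STN (within-network pairwise r ≈ 0.5,
  across ≈ 0). Series are standardized per voxel. 2 mm (not the 1 mm
  analysis grid) keeps memory modest and is the resolution class of real
  normative fMRI; a coarser grid blurs the two STN subregions into the
  same voxels and destroys the planted network distinction.

All randomness derives from one master seed via independent child
sequences; the whole study is bit-reproducible.

## Mapping statistics

- **Coverage rule:** a voxel enters the PSM when covered by at least
  ⌈0.2 · n⌉ patients (16 of 76); the usual phrasing of the rule ("a minimum of 20 %") is ambiguous
  about rounding and the ceiling is the conservative reading. A patient's coverage is the union of both hemispheres' VTAs.
- **Per-voxel test:** this step is conventionally described as a "Wilcoxon signed
  rank" test between connected and disconnected VTAs — a paired test
  named for an unpaired design; the default here is the unpaired Mann–Whitney rank-sum
  (exact distribution for combined n ≤ 20, tie-corrected normal
  approximation with continuity correction otherwise), with a one-sample
  signed-rank-versus-grand-mean variant available behind
  `voxel_test="signed_rank_vs_mean"`. No voxel-wise multiple-testing
  correction is applied, matching the uncorrected P < 0.05 masking of the
  original maps.
- **Cluster summaries:** centroids are |mean-effect|-weighted means of
  voxel coordinates per sign and side; peaks are the extreme voxel, ties
  broken by first position in C voxel order.
- **Patient scoring:** the PSM score is the sum of significant weighted
  voxels under the patient's VTAs; the fibre-model prediction is the mean
  T of retained fibres the patient connects to (no single aggregation is standard;
  the mean is scale-stable under refiltering); the R-map
  prediction is the Pearson spatial correlation between the patient map
  and the R-map over valid voxels.
- **Fibre statistics:** pooled-variance (not Welch) two-sample t, matching
  the era's toolbox convention; Welch is a switch away. Degenerate
  variance with equal means scores 0; with unequal means the statistic is
  capped at ±1e6 with a warning. Streamline–VTA intersection uses 0.5 mm
  arc-length resampling rather than exact segment–voxel clipping; halving
  the step changes < 1 % of connectivity entries.
- **Correlations:** Spearman throughout, exact permutation P for n ≤ 10
  and the t approximation above. Covariate adjustment residualizes both
  variables on the covariates by least squares and rank-correlates the
  residuals — covariate-adjusted analyses in this literature fit a GLM yet
  report Spearman effect sizes, and double residualization is the
  composition that honors both. LOOCV significance is one-sided positive by default (a predictive
  map should predict in the stated direction); two-sided is available.
- **Group boundaries:** %change exactly 0 or 30 falls in the "minor"
  class; deterioration is strictly below 0, alleviation strictly above 30.

## Null calibration

With outcomes permuted (20 replicates), the mean fraction of covered
voxels significant at α = 0.05 must lie in [0.02, 0.10] — the
continuity-corrected normal approximation is slightly conservative, so the
mean sits near 0.035; individual replicates scatter more widely, which is
why the band is checked on the mean — and the PSM and fibre LOOCV P-values
must exceed 0.05 in at least 17 of 20 replicates.

## What the synthetic validation shows — and does not

Passing tests establish that the pipeline recovers *planted* spatial and
network effects at realistic cohort size, settings and noise: sweet/sour
centroids within 2 mm, cross-validated predictions far from chance, bundle
T-scores above the distractor tail, and correct R-map signs. They do not
show that real FOG outcomes behave this way: the generator's effects are
exactly spherical, its placement errors Gaussian, its fibres noiseless
polylines, and its connectome low-rank — no registration error,
partial-volume effects, item-level questionnaire structure, disease
progression, or stimulation-parameter interactions. Cross-validated
correlations on the synthetic cohort (~0.6–0.8) are therefore much larger
than anything expected clinically; they are detection checks, not effect
estimates.

## Problem sizes

Defaults were chosen so the full study (76 patients × 2 field solves at
0.5 mm, 20 000 fibres, 20-subject connectome, three 76-fold LOOCVs) runs
in a few minutes on one CPU; the test suite adds permutation nulls and a
0.25 mm discretization check and stays within ordinary laptop budgets.
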