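# Methods

`hydroquant` re-implements, as a tested library, a volumetric pipeline for
quantifying endolymphatic hydrops (EH) from delayed gadolinium-enhanced
inner-ear MRI, together with the semi-quantitative grading, the derived
neurotologic measures, and the cohort association statistics. Because no
patient images are distributed, every imaging stage is validated against a
synthetic labyrinth phantom with known ground truth. This note records the
models, the tunable parameters, and the design choices made where the
procedure left room for interpretation.

## Image model and contrast construction

Three co-registered acquisitions drive the analysis: MR cisternography
(MRC; all inner-ear fluid bright), a positive perilymph image (PPI;
perilymph bright, endolymph dark) and a positive endolymph image (PEI; the
reverse). The subtraction image

    HYDROPS = PPI − PEI

is positive in perilymph and negative in endolymph; multiplying by the MRC,

    Mi2 = HYDROPS × MRC,

suppresses the (MRC-dark) background and boosts fluid contrast-to-noise.
HYDROPS is kept signed through the multiplication; quantization to 8-bit is
applied to the Mi2 volume that feeds the thresholding ensemble. Whether the
scanner console clips negatives before quantization is not documented
anywhere we could rely on; keeping the signed product and quantizing once
is our choice, and a constant volume quantizes to all-zero rather than
mid-gray (no contrast should be invented where none exists).

Preprocessing follows the pipeline order: crop a 30 × 30 × 52 mm cuboid
around the two inner ears, convert to 8-bit (linear min–max map, rounded
half-to-even so repeated runs are bit-stable), upsample by an integer
factor (default 2) with quintic B-spline interpolation, and, on the MRC
branch only, clip the histogram at the (0.5, 99.5) percentiles and
re-stretch — a cheap noise floor/outlier reduction that stabilizes
registration.

## Total-fluid-space segmentation

A probabilistic occupancy atlas is the mean of binarized fluid masks,
averaged with its left–right mirror image to make it side-independent. It
is registered to the subject MRC with a 12-parameter affine (3
translations, 3 rotations, 3 scales, 3 shears, composed about the fixed
volume center; the transform maps atlas coordinates into subject
coordinates). The optimizer is a multiresolution regular-step gradient
descent on the mean-squared difference of min–max normalized intensities,
evaluated on a random half of the voxels per resolution level (capped at
50 000 samples at the finest level), with the descent step bounded by 0.5
and halved whenever the cost rises or the gradient direction reverses.
Rotations, scales and shears are scaled by a 20 mm lever arm so one step
unit moves a peripheral point about 1 mm regardless of parameter type.
Initialization aligns intensity centers of mass. The procedure is
deterministic for a fixed seed. On noise-free phantoms random affines
(|t| ≤ 2 mm, scale 0.95–1.05) are recovered to ~0.01 voxel; the acceptance
bound is 0.5 voxel.

Within the registered atlas region (binarized at occupancy 0.5 and dilated
by 2 voxels) the MRC is thresholded with Otsu's method computed on the
in-ROI histogram only — the inner ear occupies a meaningful fraction of the
ROI, so the in-ROI histogram is bimodal and the threshold parameter-free.
The largest connected component per side is kept, internal holes are
filled, and the result is the binary hull of the total fluid space (TFS).
A 1-voxel ball dilation of the hull masks the Mi2 image into the fusion
volume; voxels outside carry NaN and are excluded from every statistic
downstream.

## VOLT: the local-threshold ensemble

Endolymph classification uses 12 slicewise local-threshold classifiers:
three orthogonal slice orientations × two algorithms × two window radii.
For a voxel with intensity x and a (2r+1)² in-slice window with masked mean
μ and standard deviation σ:

* Niblack: vote when x < μ + kσ (k = −0.2, the classical dark-foreground
  setting),
* local mean: vote when x < μ + c (c = 0).

The two radii are 6 and 10 voxels at the upsampled (factor-2) resolution —
window edges of 3.25 mm and 5.25 mm. Window statistics ignore NaN voxels
and windows are clipped at slice borders; no padding values are invented.
Votes require the intensity to fall below the threshold by more than 1e-6:
this breaks the tie on constant windows toward background (a flat region
must never be classified endolymph) and makes the ensemble insensitive to
the order of floating-point summation, so the production implementation
agrees voxel-exactly with a brute-force reference that recomputes every
window from scratch. Votes are summed (0–12) and voxels with ≥ 11 votes
inside the (undilated) hull are endolymph. The published cut-off of 11 is
read as a vote count of the 12-member ensemble; restriction to the hull is
applied at classification. A cubic-window (3D) variant exists behind a
config flag but is not the default.

The compartment split (cochlea vs vestibule), done manually on patient
data, is performed with the phantom's ground-truth compartment labels or
with user-supplied crop boxes; voxels in neither region stay in the
whole-ear totals.

## Derived parameters and grading

Per side and per scope (inner ear, cochlea c, vestibule v): ELS volume in
mm³ (voxel count × voxel volume), ELS/TFS ratio in %, the between-side
difference Diff = |ipsi − contra|, Diff/TFS (relative to the mean TFS of
the two sides), and the asymmetry index AI = 100·(R − L)/(R + L). The AI
is signed right-minus-left by its printed formula even though usage is
often ipsi/contra; both sides' values are exposed so either convention can
be formed. AI is defined 0 when both sides are 0.

Grading uses single reference slices along the inferior–superior axis:

* cochlear slice — the slice maximizing the cochlear fluid cross-section
  (mid-modiolar surrogate); grade 0 when the endolymph-classified (duct)
  area is below a detection floor of 5 % of the slice's fluid area, grade 1
  while the duct area does not exceed the remaining (scala-vestibuli) area,
  grade 2 beyond. Reissner's-membrane displacement is not resolvable in a
  phantom, so area dominance is the operational criterion.
* vestibular slice — the lowest slice whose vestibular fluid cross-section
  exceeds half its maximum; this canal-free surrogate stands in for "lowest
  slice where the lateral semicircular canal is still visible", since the
  phantom omits the canals. Grade 0 below an area ratio of 1/3, grade 1 up
  to and including 50 % ("exceeds 50 %" is read strictly), grade 2 above.
  The published grade-0 wording ("not < 33.3 %") contradicts the grade-1
  definition; ratio < 1/3 ⇒ grade 0 is the only reading consistent with
  the other two grades and is what we implement.

Ties in slice selection break toward the lower slice index.

## Neurotology

Caloric asymmetry follows the Jongkees formula on slow-phase velocities,
100·[(R30+R44) − (L30+L44)] / [(R30+R44) + (L30+L44)]; the printed formula
contains an "R33 °C" term that can only be a typo for the 30 °C irrigation.
Asymmetry strictly above 35 % defines vestibular paresis. VEMP amplitude
asymmetry is 100·(larger − smaller)/(larger + smaller). Both ratios are
invariant to scaling all responses, which is asserted as a property test.

The deficit categories feeding the association tables are reconstructed as:
cochlear deficit when either side's pure-tone average is ≥ 25 dB;
vestibular deficit when |caloric AR| > 35 %, any VEMP amplitude AR ≥ 40 %,
or the vHIT gain falls below a reference band (default lower bound 0.80,
standing in for a 2-SD age-matched range that is not published); both at
once give a vestibulocochlear deficit. Laterality is the implicated side,
bilateral when both. VEMP latencies are recorded but excluded from the
classification by default (no group effect was reported for them). Every
threshold is independently configurable.

## Cohort statistics

Pearson chi-square without continuity correction (printed statistics match
the uncorrected values); the effect size is reported as φ = sqrt(χ²/N) for
every table — for the 3×3 tables this is the only convention that
reproduces the printed effect sizes, and it is labeled "phi (paper
convention)" advisedly since Cramér's V would divide by min(r−1, c−1).

The exact r×c Fisher test (Freeman–Halton) sums, under the multivariate
hypergeometric with fixed margins, the probabilities of all tables no more
probable than the observed (tolerance 1e-7 on log-probabilities for the
tie). It is computed by exhaustive enumeration of fixed-margin tables,
vectorized row-by-row with column-cap pruning; the 4×4, N = 62 laterality
table enumerates 2.7 million tables in ~15 s. Enumeration is limited to
5×5 tables with N ≤ 100 and a bounded candidate count; beyond that a
seeded Monte-Carlo version samples fixed-margin tables by permutation and
reports the add-one-corrected proportion with its standard error.

Spearman correlation uses tie-corrected ranks with a two-sided p — exact
by permutation for n ≤ 9, t-approximation otherwise. One-way ANOVA is
followed by pairwise comparisons using the pooled within-group variance,
Bonferroni-multiplied and capped at 1.

The package ships the published categorical counts (diagnosis groups ×
EH/symptom codings, and the EH-location / EH-laterality by deficit tables)
as a CSV with a per-cell transcription note. Two caveats are carried as
printed: the "no EH" row sums to 35 in the location table but 34 in the
laterality table (used as printed, no reconciliation), and the
probable-subgroup statistics printed as χ²(2) = 9.2 (EH) and 11.1
(headache) are not recoverable from the printed counts (recomputation
gives ≈ 7.1 and ≈ 7.2); those two are therefore reported but not used as
reference values anywhere. The exact p of the location table computes to
0.0026 — smaller than the χ² approximation (≈ 0.01, df 9) suggests.

## The phantom: what it emulates, and what it does not

Each subject is a pair of mirrored stylized labyrinths on a 0.5 mm grid:
a cochlea as an Archimedean-spiral tube (base radius 3 mm tapering by 75 %
over 2.25 turns, tube radius 0.9 mm, small helical rise) and a vestibule as
an ellipsoid (semi-axes 2.5 × 3.0 × 2.5 mm), 26 mm between ear centers.
Semicircular canals are omitted — they are excluded from grading anyway.
Within each compartment an endolymph sub-region is selected by ranking
voxels on a normalized in-slice radial coordinate and taking the innermost
quantile; this makes both the volume fraction and the per-slice area
fraction equal the requested fraction (to within one voxel), which is
exactly the quantity the grading measures. Intensities are
piecewise-constant per tissue class (8-bit scale: background/bone 5;
perilymph MRC 220 / PPI 200 / PEI 60; endolymph MRC 220 / PPI 40 / PEI
180) plus i.i.d. Gaussian noise (default sd 5), chosen so the subtraction
polarity matches the dark-ELS / bright-PLS appearance. There is no MR
physics: no relaxation modeling, no bias fields, no motion, and noise is
white rather than spatially correlated. Passing tests therefore demonstrate
the correctness and stability of the computational pipeline, not clinical
segmentation accuracy on patient data.

Every subject carries one seed; geometry, per-sequence noise and
neurotology draw from named sub-streams of it, so stages are independently
reproducible.

The cohort generator draws a severity scalar u ~ U(0, 1) per subject and
maps it linearly to endolymph fractions within group-specific ranges
(clinically leading side: MD vestibule 0.35–0.65 and cochlea 0.25–0.55;
VM 0.05–0.18 / 0.02–0.06 symmetric; the VM–MD overlap group straddles the
cochlear detection floor at 0.03–0.20 so its EH prevalence is
intermediate; contralateral ears are healthy, cochlea 0.02–0.06). Healthy
cochlear fractions are deliberately near the detection limit — the normal
scala media is a sub-voxel structure — so normal ears grade 0 through the
5 % floor. The same severity drives PTA upward (12 + 55·f dB), caloric
slow-phase velocity downward (26 − 28·f °/s per ear), VEMP amplitudes and
vHIT gain downward, each with configurable Gaussian measurement noise;
with noise at zero the links are strictly monotone and rank correlations
are exactly ±1, with the default noise they are recoverable but imperfect,
which is what the cohort-level Spearman checks exercise.

## Problem sizes used in tests and the acceptance script

The default analysis grid is 120 × 120 × 208 voxels at 0.25 mm (the
30 × 30 × 52 mm crop, upsampled ×2); a full subject runs in ~30 s. The
recovery experiments (fraction/grade recovery across 30 seeded runs, hull
accuracy, registration accuracy, determinism) run on a reduced
configuration — 0.5 mm voxels, no upsampling, window radii 3 and 5 —
that keeps every physical length of the default pipeline (same crop
semantics, same mm window edges) while running a subject in about a
second. The acceptance script additionally executes one subject at the
full default grid and reports its runtime, ipsilateral ELS/TFS ratio and
EH detection.

## Known limitations

* At the upsampled 0.25 mm resolution, B-spline interpolation spreads thin
  dark structures and softens boundaries. Two consequences, both measured:
  thin endolymph structures *bloom* (a sub-voxel healthy scala media can
  exceed the 5 % cochlear floor and read grade 1), and the small low
  vestibular grading slice *erodes* under noise (a 0.40 area ratio can read
  ~0.29–0.36 at the reference slice, i.e. a borderline mild hydrops can
  grade 0 in some seeds). Volumetric ratios stay within ±0.04 of truth;
  single-slice area ratios are the sensitive quantity. The reduced 0.5 mm
  configuration does not upsample and shows neither artifact.
* The registration cost is unimodal only for overlapping fields of view;
  initialization is by centers of mass and no exhaustive search is
  attempted. This matches its use (atlas and subject already roughly
  framed) but would fail on grossly mis-framed inputs.
* The Monte-Carlo Fisher fallback conditions on both margins, like the
  exact test; tables whose margins are themselves random are outside its
  scope.
* Patient-level volumetric reference values (per-group means of ELS, TFS,
  Diff, AI) cannot be reproduced without the original images; the pipeline
  reports these quantities for synthetic cohorts only.
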