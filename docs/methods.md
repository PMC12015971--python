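# Methods

This note documents the models, parameter choices and numerical
conventions behind `pt2nerve`, and what the synthetic cohorts do and do
not establish about real data.

## Two-point pseudo-T2* estimation

The acquisition model is a mono-exponential transverse decay per tissue
compartment, S(t) = A · exp(−t/T2*), sampled at two echo times
(defaults TE1 = 1.05 ms, TE2 = 5.37 ms, the vTE protocol). The voxelwise
estimator is pT2* = −ΔTE / ln(iTE2/iTE1). Properties that the test suite
asserts exactly: the estimator inverts the forward model to machine
precision; it is invariant to common scaling of the echoes (so TR, flip
angle, T1 weighting and proton density — absorbed into A — never enter);
it is strictly increasing in iTE2 for fixed iTE1.

**Validity policy.** A voxel has a defined pT2* only when iTE1 > 0 and
0 < iTE2 < iTE1. Other voxels (noise floor, non-decaying signal) are
excluded from ROI means rather than clipped to a ceiling: clipping would
bias group means, and exclusion is made visible by reporting the valid
fraction in every ROI summary. There is no upper cap on pT2*.

**Reduction.** ROI summaries average voxelwise estimates over the valid
voxels of a structure on the analysis slices (the first and last slices
of the slab are always excluded, generalising the 12 → 10 rule to any
slice count ≥ 3). An alternative reduction — a single estimate from the
ROI-averaged echo intensities — is provided
(`roi_pt2star_from_mean_signal`); the two agree exactly on noiseless
uniform ROIs (tested) and the voxelwise route is the default.

**Noise bias.** The voxelwise estimator is a convex function of the log
echo ratio, so noise inflates its expectation by a factor of roughly
1 + Var(ln iTE2 − ln iTE1)/L0², L0 = −ΔTE/T2*. Rician magnitude bias
itself cancels in the log to second order; the convexity term does not
average away over the ROI. At SNR 50 (sigma defined at the fascicle TE1
signal) this is ≈ +1.5% at T2* = 15 ms (asserted below 2% by simulation
on a 500-voxel ROI) and ≈ +2.1% at T2* = 18.35 ms (≈ +0.4 ms); at
SNR 100 it falls below 0.6%. For this reason the cohort-recovery test,
which demands agreement with the configured group means within two
standard errors (±0.32 ms at n = 500), runs at SNR 100; the acceptance
script reports the study condition SNR 50, where the residual +2% offset
is part of the method's honest operating characteristics, not a defect
of the simulation.

## Phantom and cohort generator

The generator emulates the study conditions so the downstream stages can
be validated by parameter recovery.

**Geometry.** Default grid 96 × 96 × 12 voxels at 0.6 × 0.6 × 5.0 mm (a
reduced field of view around the nerve; the slab covers 6 cm). Each
slice holds one elliptical nerve cross-section (random axis ratio
1–1.5, random orientation, ±1 mm centre jitter plus smaller per-slice
jitter). The whole-nerve voxel set per slice is the N voxels of smallest
elliptical radius with N = round(CSA/(dx·dy)), so the pixel-counting CSA
matches the subject's true CSA to within one voxel.

**Fascicle/epineurium partition.** Published fascicular fractions are
high (≈ 0.76–0.84 of the nerve area), which rules out rendering
fascicles as non-overlapping packed discs (random disc packings saturate
near 55% coverage). Instead, fascicle *territories* are grown around
randomly packed seed points (4–9 per nerve, rejection-sampled with a
separation that shrinks for small nerves; deterministic failure when a
requested minimum cannot be placed), and the epineurium budget
N_epi = N − round(fraction·N) is assigned to the voxels closest to
territory boundaries or to the nerve rim. This reproduces the visual
structure of hyperintense fascicles separated and surrounded by
hypointense epineurium, guarantees the exact partition
fascicle + epineurium = nerve, and hits the true fascicular fraction to
within one voxel. The labels are 0 background/muscle, 1 epineurium,
2 fascicle.

**Signal and noise.** Per-compartment amplitudes default to fascicle
1.0, epineurium 0.55, muscle 0.35 (arbitrary units; fat is treated as
suppressed by the sequence's binomial excitation and not simulated), and
the generator refuses configurations in which fascicles would not be
hyperintense at TE1. Noise is Rician by default — two independent
Gaussian draws per voxel per echo — with sigma = fascicle TE1 signal /
SNR (default SNR 50); Gaussian noise is available for analytic checks
and `snr: inf` disables noise.

**Subject truth.** Per-group distributions (means ± SD):

| quantity | ATTRv | HC | floor/ceil |
|---|---|---|---|
| fascicle pT2* (ms) | 18.35 ± 3.48 | 14.74 ± 3.21 | ≥ 1 |
| epineurium pT2* (ms) | 9 ± 2 | 9 ± 2 | ≥ 1 |
| CSA (mm²) | 49.32 ± 19.63 | 37.89 ± 12.92 | ≥ 10 |
| fascicular fraction | 0.842 ± 0.05 | 0.763 ± 0.05 | [0.05, 0.95] |

Fascicle pT2* and CSA use published group values. The fraction means are
the published fascicular-area/CSA ratios, so that with independent draws
the expected fascicular area equals the published group mean
(49.32 × 0.842 = 41.53 mm²; the implied epineurium areas, 7.8/9.0 mm²,
and fascicular-area SDs, ≈ 16.7/10.0 mm², also land close to the
published 7.79/9.34 and 16.27/8.44). The fraction SD of 0.05 is the one
free choice and was fixed by that SD match. Epineurium pT2* is N(9, 2²)
in both groups: no group effect was reported there and no epineurium
means were published; with the area fractions above this puts simulated
whole-nerve means near (within ~1 ms of) the published 15.65/12.64 ms.
All truths are drawn from normals truncated **symmetrically** about the
mean (half-width min(mean − floor, ceil − mean)), so configured means
are exact expectations — a one-sided floor would bias CSA upward by
about 1 mm². A floor above mean + 6 SD is rejected as infeasible.

**Covariates.** Clinical scores and nerve-conduction values share a
Gaussian copula with the fascicle-pT2* latent normal: a target Spearman
ρ_s maps to the latent correlation r = 2·sin(π·ρ_s/6), exact for
bivariate normals, and each covariate applies its inverse marginal CDF
to the correlated latent. Patient targets: NIS 0.544, NIS-LL 0.545, PND
0.592, peroneal CMAP −0.592, tibial CMAP −0.715, sural SNAP −0.552,
peroneal/tibial NCV −0.519/−0.531; age and sex are uncorrelated
(matched design), and controls have uncorrelated, healthier NCS
marginals and zero clinical scores. Marginals: NIS and NIS-LL are
lognormals with medians 18 and 11 clipped to their scale bounds (0–244,
0–88) — the published medians constrain the location, the lognormal
shape and log-SD 0.9 are modelling choices since the true marginal shape
is unknowable from group summaries; PND is ordinal 1/2/3 with
probabilities 10/18, 6/18, 2/18; CMAP/SNAP are lognormals; NCV normals.
Discrete marginals (sex, PND) attenuate the realised Spearman through
ties; continuous ones reproduce it within ±0.03 at n = 5000 (tested).

**Determinism.** Per-subject seeds are spawned from the master seed
(`numpy.random.SeedSequence`), so cohorts are reproducible byte-for-byte
(truth CSVs, label maps and — because nibabel writes gzip with a fixed
mtime — the NIfTI files themselves; run manifests record SHA-256
checksums per file).

**What the generator does not emulate.** No Bloch/extended-phase-graph
simulation, k-space sampling, asymmetric-echo reconstruction, partial
voluming at nerve boundaries, B0/B1 inhomogeneity (the motivation for
the edge-slice exclusion is asserted as a rule, not simulated), fat
signal, or bi-exponential tissue behaviour. On that last point: myelin
water and free water give real nerves a multi-compartment decay, but no
compartment fractions or short-T2* values are available to calibrate
one, so compartments stay mono-exponential and passing recovery tests
shows estimator correctness under the stated model, not robustness to
multi-exponential tissue. Real manual segmentations also overlap
structures ambiguously (fascicle ROIs reportedly include some inner
epineurium); ground-truth masks here are clean partitions, and the
boundary-flip rater perturbation (`perturb_mask`, default rate 0.2) is
the mechanism for studying segmentation disagreement.

## Reliability

Dice is computed over a structure's voxel sets, with the convention
Dice = 1 when both sets are empty (raters agree the structure is
absent); the alternative — undefined — would crash on structures missing
from a slice. The ICC is computed from the two-way ANOVA mean squares
and returned with them for audit. ICC(2,1) (absolute agreement) is the
default because the scientific question is whether raters' absolute
measurements are interchangeable; ICC(3,1) (consistency, insensitive to
a fixed rater bias) is available. A constant measurement table has no
defined ICC and is returned flagged degenerate rather than raising.

## Statistics

- **Adjusted group comparison:** OLS of measure ~ group + age + sex;
  reports the group coefficient, its p-value, and the model's multiple
  correlation R = √R². Whether a published "R" is a multiple R or a
  partial correlation is ambiguous; both are computable here (the
  partial correlation via `correlate(..., covariates=...)`). Singular
  designs (e.g. single-sex cohorts) are rejected explicitly. A
  mixed-effects model was considered and rejected: with one observation
  per subject there is no identifiable random effect.
- **Two-sample tests:** Welch t (no equal-variance assumption stated
  anywhere, so the safer default) plus Mann-Whitney U, both always
  reported; CSA uses a one-tailed larger-in-patients alternative by
  default, configurable.
- **Severity analysis:** strata from NIS-LL (mild 1–20, moderate 21–61,
  severe 62–88; moderate and severe pooled; controls their own
  stratum). The omnibus is a one-way ANOVA F; post hoc pairs use Dunn's
  rank-based z with tie correction. Pairing a parametric omnibus with a
  rank-based post hoc is heterodox (Dunn conventionally follows
  Kruskal-Wallis) but mirrors the analysis structure this package
  reproduces; both are reported side by side. Post hoc p-values are
  unadjusted by default with Holm always included in the output table.
- **Correlations:** Pearson or Spearman; "controlling for sex and age"
  is implemented as partial correlation by residualisation (ranks first
  for the Spearman flavour), p from t with n − 2 − k df.
- Type-I error of every test is verified by null simulation (1000
  replicates); the exact Mann-Whitney test is discrete, so its rejection
  rate is compared against its exactly attainable level below α rather
  than nominal α.

## Problem sizes and tolerances

Cohort-recovery runs use 500 subjects per group on the default
96 × 96 × 12 grid (≈ 25 s per 1000 subjects); recovery bands are two
standard errors of the configured group SDs. Copula fidelity: ±0.05 at
n = 500–2000, ±0.03 at n = 5000. Noiseless end-to-end identity is
asserted at 10⁻⁹ relative error; closed-form worked cases at 10⁻¹².
Monte-Carlo calibration tolerance is ±1.5 percentage points around
α = 0.05 at 1000 replicates (≈ 2 binomial SD).

## Known limitations

- The two-point estimator's noise bias (above) is inherent; a multi-echo
  least-squares fit would reduce it but is out of scope.
- Rendered geometry is voxel-exact in area but has no sub-voxel
  boundaries, so Dice values between simulated raters are optimistic
  relative to manual segmentation of smooth anatomy.
- Published patient-derived numbers that depend on the original scans
  (real-segmentation ICC/Dice, specific small-sample p-values) are not
  reproducible and are not targeted; the package validates the defined
  computations and the calibrated-recovery surface instead.
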