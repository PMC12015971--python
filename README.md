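# pt2nerve

Quantitative MR-neurography of the sciatic nerve with a dual-echo
variable-echo-time (vTE) gradient-echo acquisition: pseudo-T2*
relaxometry, sub-structure morphometry, inter-rater reliability, and
group/correlation statistics — driven end to end by a synthetic
phantom-and-cohort generator, so every stage is testable without any
scanner data.

## Who this is for

Hereditary transthyretin amyloidosis (ATTRv) causes a progressive
polyneuropathy in which amyloid deposition and myelin loss change the
microstructure of peripheral nerves. On vTE images of the sciatic nerve
the endoneurial fascicles appear hyperintense and the inner epineurium
hypointense, and both the effective transverse decay time and the nerve
caliber shift with disease severity. This package is for imaging
scientists who want a reproducible, scriptable implementation of that
analysis — either on their own NIfTI data (each pipeline stage runs
standalone on files) or on simulated cohorts calibrated to published
group-level distributions.

## The model

A dual-echo acquisition (TE1/TE2 = 1.05/5.37 ms by default) samples a
mono-exponential decay S(t) = S0 · exp(−t/T2*). The two-point
**pseudo-T2*** estimate at each voxel is

```
pT2* = −ΔTE / ln(iTE2 / iTE1),   ΔTE = TE2 − TE1
```

which is invariant to any common scaling of the two echoes (proton
density and T1/TR/flip-angle weighting cancel). Voxels without a valid
decay (iTE2 ≥ iTE1, or non-positive signal) are flagged invalid and
excluded from ROI means, with the valid fraction always reported. The
first and last slices of the slab are excluded from analysis (12
acquired → 10 analyzed). Areas are pixel-counting areas per axial slice;
per-subject values are means over the analysis slices.

The cohort generator draws subject-level truth (fascicle/epineurium
pT2*, whole-nerve cross-sectional area, fascicular area fraction) from
per-group truncated normals, ties clinical scores (NIS, NIS-LL, PND) and
nerve-conduction values (CMAP, SNAP, NCV) to fascicle pT2* through a
Gaussian copula (latent correlation r = 2·sin(π·ρ_s/6) for a target
Spearman ρ_s), renders one elliptical nerve cross-section per slice with
fascicle territories separated by epineurium, and adds Rician noise.

Reliability is quantified with the Dice coefficient
2|A∩B|/(|A|+|B|) and the two-way random-effects absolute-agreement ICC,
ICC(2,1). The statistics layer provides covariate-adjusted group
comparisons (OLS: measure ~ group + age + sex), Welch t / Mann-Whitney U
tests, a three-stratum severity analysis (one-way ANOVA omnibus with
Dunn rank-based pairwise post hoc), and Pearson/Spearman correlations
with optional partial correlation by residualisation.

## Worked example

```python
import numpy as np
from pt2nerve import RunConfig, analyze_subject
from pt2nerve.simulate import simulate_subject

cfg = RunConfig(master_seed=7)                       # protocol defaults
truth, vol, mask = simulate_subject("ATTRv", cfg, np.random.default_rng(7), "ATTRV-001")
m = analyze_subject(vol, mask, "ATTRV-001")
print(f"true fascicle pT2* = {truth.fascicle_t2star_ms:.2f} ms")
print(f"measured fascicle pT2* = {m.fascicle_pt2star_ms:.2f} ms")
print(f"true CSA = {truth.csa_mm2:.2f} mm^2 | measured CSA = {m.csa_mm2:.2f} mm^2")
```

prints

```
true fascicle pT2* = 18.35 ms
measured fascicle pT2* = 18.82 ms
true CSA = 44.19 mm^2 | measured CSA = 44.28 mm^2
```

The measured fascicle pT2* sits ~0.5 ms above truth because the
voxelwise two-point estimator carries a small positive noise bias at
SNR 50 (see `docs/methods.md`); the rendered CSA matches the subject's
truth to within one voxel.

A whole cohort, from simulation through statistics:

```
pt2nerve run-all --config examples/cohort.yaml --seed 7 --out run/
```

where the YAML config needs only `master_seed` (all other keys override
defaults). The run directory contains per-subject NIfTI images and label
maps, `truth.csv`, `cohort.csv` (truth joined to derived measures),
`reliability.json` (Dice/ICC against a simulated second rater),
`stats_results.csv`, a Markdown report, and a `manifest.json` with
SHA-256 checksums — identical configs reproduce identical checksums.

Stage subcommands (`simulate`, `map`, `morph`, `reliability`, `stats`)
operate on explicit file paths, so real acquisitions can replace the
simulated ones at any point. Conventions: arrays are (x, y, slice) with
the 0-based slice index on the third NIfTI axis; labels are 0 background,
1 inner epineurium, 2 fascicles (whole nerve = {1, 2}).

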