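# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic test surface does and does not
establish about real data.

## Signal model and tensor estimation

Diffusion is modeled per voxel by a symmetric positive semi-definite tensor
`D` (10⁻³ mm²/s) under the monoexponential model
`S(b, g) = S0 · exp(−b gᵀDg)` with `b` in s/mm². The default acquisition
scheme mirrors a clinical single-shell protocol: 30 noncolinear directions
at b = 1000 s/mm² plus one b = 0 volume, 2 mm isotropic voxels. Directions
are generated by antipodal electrostatic repulsion from a seeded random
start (300 fixed iterations, step 0.05), which is deterministic and keeps
the worst pair of directions well away from colinearity.

Fitting is log-linear least squares on `log S` with the seven-column design
`(1, −b gx², −b gy², −b gz², −2b gx gy, −2b gx gz, −2b gy gz)`; the
intercept provides the per-voxel `S0` estimate, which is more robust than a
mean-b0 estimate when only a single b = 0 volume exists. Unweighted least
squares is the default; signal-magnitude-weighted least squares is
available (`weighted=True`) for noisy data where the log transform
inflates low-signal variance. Nonpositive signals are excluded from the
affected voxel's fit; a voxel with fewer than 7 usable volumes is dropped
from the mask. Tensors with negative eigenvalues are reconstructed with
those eigenvalues clamped to zero; the count is reported, not fatal, and no
refit is attempted.

Eigenvalues are sorted descending; fractional anisotropy uses
`FA = sqrt(3/2)·sqrt(Σ(λi−MD)²)/sqrt(Σλi²)` with FA of the zero tensor
defined as 0. The principal eigenvector is reported as componentwise
absolute values `|V1|`: eigenvector sign is arbitrary, and the magnitude
maps are exactly what the ROI scoring consumes. For degenerate (tied)
eigenvalues the eigenvector basis is arbitrary but stable; such voxels have
low FA and are therefore down-weighted to irrelevance by the scoring.
Scanner-axis diffusivities (Dxx, Dyy, Dzz) are the diagonal tensor elements
`eᵀDe` — not sorted eigenvalues — which is what makes the ALPS contrast
orientation-specific.

## ROI selection

Axes follow the RAS convention: projection fibers (CST) run along z,
association fibers (SLF) along y, perivascular flow along x. Each in-label
voxel is scored `(|V1_axis| − |V1_other| − |V1_other|) · FA` with the
desired axis z for projection and y for association labels; the subtraction
precedes the FA multiplication. In-mask scores lie in `[−√2·FA, FA]` (the
lower extreme is a principal direction fully in the nuisance plane at 45°).
The top `ceil(f·N)` voxels per label are kept, `f = 0.87` by default,
reading "the 87% highest-value voxels" as a retained fraction rather than a
score cutoff — scores are not bounded below by zero, so a value cutoff at
0.87 would be ill-posed. Ties at the cutoff break by ascending linearized
voxel index, making selection fully deterministic. The fraction applies per
hemisphere-label; hemispheres are processed independently and combined only
by averaging the two ALPS indices (an arithmetic mean of indices, not an
index of averaged diffusivities).

Atlas-to-subject registration is deliberately out of scope: the pipeline
takes label masks, and optional restriction masks (the ventricle-body-level
crop), already in subject diffusion space.

## The phantom

The phantom realizes the minimal geometry the index depends on: two
hemispheres, each with one projection box carrying `diag(base+g, base,
fiber)` and one association box carrying `diag(base+g, fiber, base)`, in an
isotropic background. Defaults: 32×32×20 voxels at 2 mm, 6×6×8-voxel boxes,
`base = 0.4`, `fiber = 1.7`, background 0.8 (all 10⁻³ mm²/s), S0 = 1000.
The boost `g` on the x axis is the planted perivascular component, giving
the closed-form ground truth `ALPS = (base+g)/base`. Labels handed to the
ROI stage are the boxes dilated by one voxel — emulating atlas labels that
leak past the tract — while the exact boxes serve as restriction masks.
An `impurity_fraction` of in-box voxels receives the fiber tensor under a
seeded uniform random rotation, standing in for CSF/cortex contamination;
`floor(f·N)` impurities per box complement the `ceil((1−f)·N)` keep rule
exactly. Noise is Rician, `sqrt((S+e1)² + e2²)` with iid Gaussian `e1, e2`
(the magnitude-MRI noise law); additive Gaussian noise exists as a debug
option.

What the phantom does *not* emulate: anatomy, partial-volume gradients,
crossing-fiber fanning, motion, eddy currents, susceptibility distortion.
Passing phantom tests therefore establishes correctness of the measurement
chain given well-posed inputs, not robustness to acquisition artifacts —
those corrections are upstream of this pipeline by design.

## The cohort simulator

Per-subject covariates emulate a de novo Parkinson's disease cohort (n=54)
with matched controls (n=32): ages ≈59 ± 12/8 years, ~68% male, AHI with
gamma marginals (mean/sd 16.0/19.9 patients, 18.5/15.8 controls), and ODI,
stage-N1 ratio and arousal index tied to AHI through a Gaussian copula with
rank correlations 0.8/0.4/0.5 (package choices; only marginals are known
for the emulated cohort). Sleep-stage percentages are gamma draws
rescaled so wake+N1+N2+N3+R = 100 exactly per subject. The patients-only
TST standard deviation was reduced to 90 min: the printed 255 min is
implausible beside a 334-min mean on an 8-hour recording.

Ground-truth ALPS is linear: `baseline + β_age·age + β_sex·male +
β_AHI·AHI·1[patient] + ε`, with `β_age = −0.005`, `β_sex = −0.116`,
`β_AHI = −0.004` (the regression-scale effects of the emulated study) and
baseline 1.72, which reproduces group means ≈1.28/1.34. The residual sd
(0.10) was calibrated once, by simulation, so the patient-group rank
correlation of ALPS with AHI is ≈ −0.40 — the coupling the study design
targets — yielding an ALPS sd ≈ 0.15. Optional comorbidity flags (RBD, RLS,
PLMS) are generated in the patient group with fixed prevalences; planted
confounding (an RBD effect on both ALPS and AHI) is available for testing
the adjusted model. The simulator can also emit one phantom spec per
subject whose boost reproduces that subject's ALPS under the noiseless
forward model (`g = base·(ALPS−1)`).

## Statistics

Group comparisons use the Mann–Whitney U test: the exact null distribution
when `n1+n2 ≤ 12` with no ties, otherwise the normal approximation with tie
and continuity corrections (mode recorded; the approximation agrees with
exact enumeration to < 0.016 at n1=n2=6). The sex split uses the two-sided
exact test on the 2×2 table. Degenerate all-identical data returns p = 1
with a flag.

Spearman correlations use ranked Pearson with average ranks. The p-value
defaults to the Fieller-corrected Fisher-z statistic
`z = atanh(ρ)·sqrt((n−3)/1.06)`: at the study's sample sizes the classical
t approximation is slightly anti-conservative in the far tail (measured
size 0.0039 at the 0.05/14 cutoff for n=54), enough to push Bonferroni
familywise error past its nominal bound, while the Fieller form stays at or
below nominal (0.0032–0.0034); the t approximation remains available via
`p_method="t"`. Confidence intervals use the plain Fisher z transform,
`tanh(atanh ρ ± z_{1−α/2}/sqrt(n−3))`. Bonferroni families default to the
14 covariates per group for the correlation battery and the number of
continuous variables for the comparison table; both are parameters, since
family definitions are a reporting choice.

Regressions are OLS with intercept; group (patient=1) and sex (male=1)
codings are recorded in every output, without which coefficient signs are
uninterpretable. The interaction column is `AHI · group`, so its
coefficient is the patient-group excess AHI slope. Standardized
coefficients are `Beta = B · sd(x)/sd(y)`. Singular designs raise an error
naming the collinear terms; in the comorbidity-adjusted model,
zero-variance flags are dropped and listed so the exposure coefficient
degrades gracefully to the simple regression. A generic permutation
`monte_carlo_p_interval` (add-one-corrected `(k+1)/(B+1)` with a
Clopper–Pearson interval) mirrors Monte-Carlo p reporting; no claim is made
that it reproduces any specific software's interval construction.

## Problem sizes and determinism

Every stochastic component takes an explicit seed and is bit-reproducible;
pipeline reruns with the same configuration produce identical output
checksums for deterministic stages. The validation battery uses problem
sizes chosen to make Monte-Carlo bounds tight at desk scale: 1000 random
tensors for fit exactness, 500 cohort replicates for effect recovery, 2000
for familywise error, 50 noisy phantom realizations for robustness.

## Known limitations

- The tensor model is single-shell DTI: no kurtosis, free water, or
  crossing-fiber modeling; the ALPS construction itself assumes the
  canonical fiber geometry holds at the ROI level.
- The 87% retention fraction is a convention of the emulated protocol, not
  an optimized value; it is exposed as a parameter.
- The cohort simulator's copula correlations and comorbidity prevalences
  are plausible package choices, not estimates from data.
- Real-data mode expects fully preprocessed inputs (distortion/motion
  corrected, masks in subject space); no registration is performed.
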