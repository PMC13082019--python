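# Methods

## The operational model of allosterism

The effect surface implemented in `allofit.operational` is

E = E_max·N/(D + N), with
N = (τ_A[A]/K_A + τ_B[B]/K_B + αβ·τ_A[A][B]/(K_A K_B))ⁿ and
D = (1 + [A]/K_A + [B]/K_B + α[A][B]/(K_A K_B))ⁿ.

The leading unity term in D is required: without it the expression is 0/0
at [A] = [B] = 0, whereas the model must give zero basal effect. Note the
αβ numerator term carries τ_A specifically — the surface describes
modulation *of the orthosteric agonist* — so the model is **not** symmetric
under swapping (A, τ_A, K_A) ↔ (B, τ_B, K_B) unless τ_A = τ_B; the test
suite asserts the swap-invariance only in that regime.

Useful exact reductions (used as test oracles):

* [B] = 0, n = 1: a three-parameter logistic with
  EC₅₀ = K_A/(1+τ_A) and Top = E_max·τ_A/(1+τ_A);
* τ_B = 0, n = 1: the observed EC₅₀ at fixed b is
  K_A(K_B+b) / (K_B + αb + τ_A(K_B + αβb));
* α = β = 1, τ_B = 0: the surface is independent of [B].

### Fitting conventions

* **Constraints.** E_max is fixed — either supplied, or "auto": the
  smallest multiple of 10 (on the normalized % scale) at or above the
  maximum observed cell mean; a plain-ceiling variant is available. The
  transducer slope n is fixed at 1.
* **Scales and bounds.** K_A, K_B, α, β are estimated as log₁₀ values with
  logK ∈ [−14, −3] and logα, logβ ∈ [−4, 4]; τ_A, τ_B on the natural scale
  with lower bound 0. These bounds are numerical-conditioning guards at the
  edge of pharmacological plausibility, not priors.
* **Optimization.** Trust-region-reflective least squares
  (`scipy.optimize.least_squares`) from 8 deterministic-plus-jittered
  starts (seed recorded in the fit report); ties between equal-loss starts
  break toward the lower Jacobian condition number. Convergence: relative
  loss change below 1e-12 or the iteration cap (both configurable).
* **Uncertainty.** Standard errors come from the Gauss–Newton curvature,
  cov = s²(JᵀJ)⁻¹ with s² = RSS/(n−p). This is a local approximation; the
  simulation harness checks that ±2·SE intervals for logα cover the truth
  in ≥80 % of noisy-surface replicates, which is what those SEs are good
  for. Profile-likelihood intervals are out of scope.
* **Identifiability.** With only one nonzero modulator concentration, α
  and β cannot be separated; the fitter emits a warning naming the flat
  parameter combination (detected from the curvature eigenspectrum,
  eigenvalue ratio < 1e-10) instead of silently returning point estimates.
  Because only logα is conventionally tabulated while both α and β enter
  the surface, fit reports carry logα, logβ and their sum log(αβ).
* **Gain in potency** uses b_ref = 1 µM. Each EC₅₀ is the agonist
  concentration at the midpoint between E(0, b) and the analytic a→∞
  asymptote at that b — the way an EC₅₀ is read off a fixed-modulator
  curve — solved by bracketed monotone root-finding on log[A] (Brent,
  relative tolerance 1e-10), not as half of E_max.

## Single-ligand models

Three-parameter forms throughout (Hill slope fixed at 1; a free-slope
logistic exists but is off by default). Concentration parameters are fitted
on the log₁₀ scale so back-transforms are strictly positive; vehicle wells
(concentration exactly 0, explicitly flagged) enter the logistic fit at
Bottom by the continuity convention. Fits are unweighted least squares —
replicates are stored raw, never pre-averaged, so per-point SEM weighting
remains possible — with the same multi-start machinery as above.

The printed form of the competition relation in common use,
"IC₅₀ = 1 + [L]/K_d", is dimensionally inconsistent; the package implements
the canonical Cheng–Prusoff-type correction IC₅₀ = K_i(1 + [L]/K_d), which
is the only form consistent with using the measured radioligand
concentration and its K_d to obtain a K_i. Whether Bottom is floated or
fixed (e.g. to nonspecific binding) is a user choice; floating is the
default.

## Normalization and BRET

Signals are mapped affinely so the vehicle mean is 0 % and the mean at the
highest reference-agonist concentration (modulator-free column, for a
surface) is 100 %. Mutant data can instead be anchored on the paired
wild-type vehicle/maximum, in which case mutant maxima legitimately fall
below 100 % (low-expressing mutants) or above. mBRET is
(sample 535/475 ratio − mean control ratio)·1000, with the control mean
taken per experiment (the averaging window is not standardized in the
literature; per-experiment is this package's choice) over records flagged
as acceptor-free controls.

## Trajectory statistics

* A **polar contact** between two residues in a frame is a minimum N/O–N/O
  distance below 4.0 Å. "Sidechain" scope (the default) excludes backbone
  N/O (PDB v3 names N, O, OXT); an all-atom scope covers backbone-mediated
  contacts. Strict "<" is the default; an inclusive "≤" flag exists — at
  continuous coordinates the two differ on a measure-zero set.
* **Occupancy** is the fraction of frames in contact, reported per
  replicate with the across-replicate SD; pooled occupancy is the
  frame-count-weighted mean of per-replicate values (an exact identity,
  tested).
* **Helix position** is the distance between the unweighted Cα centroid of
  a residue window (e.g. a TM6 cytoplasmic stretch) and the Cα centroid of
  the union of bundle segments. The seven bundle ranges are
  config-supplied: residue numbering is structure-specific, so the package
  ships no default ranges and refuses to guess.
* **Occupancy grids** count, per 1 Å voxel, the fraction of frames with at
  least one selected atom (default main-chain N/Cα/C) in the voxel, with a
  0.5 iso-threshold export (plain text + OpenDX header). Alignment is the
  caller's responsibility; a Cα Kabsch aligner is provided.
* **Replicate-level inference** uses per-replicate means with n = number of
  replicates, never per-frame n — frames within a replicate are
  autocorrelated and pooling them would be pseudoreplication. Whether
  published per-condition tests used frames or replicate means is usually
  unstated; this package takes the conservative reading.

Densities of displacement series use a Gaussian KDE with Silverman
bandwidth (configurable), renormalized on the evaluation grid; below 50
frames per replicate a histogram fallback is used with a warning.

## Replicate statistics

Welch's t (two-sided, Welch–Satterthwaite df) via `scipy.stats.ttest_ind`;
one-way ANOVA F plus Dunnett two-sided many-to-one adjusted p-values via
`scipy.stats.dunnett` (equicorrelated multivariate-t; integration seeded,
reproducible to ~1e-4). Seeded Monte-Carlo calibration in the test suite
checks a per-test and familywise type-I error of 0.05 within [0.035,
0.065]; with n = 3 per group Welch runs slightly conservative (~0.04),
which is expected for the Satterthwaite approximation at minimal df.

## Synthetic data: what it emulates, and what not

Generators draw additive homoscedastic Gaussian noise around exact forward
-model means (constant absolute spread matches how SEM bars behave on a
normalized % scale; a multiplicative lognormal option exists for raw
counts). The default study conditions are: operational surfaces on an 8 × 5
grid (vehicle + 7 agonist levels, half-log spacing over the potency window;
modulator 0–3.16 µM), 3 replicates, SD 5 % points, truth logK_A −8.6,
logK_B −6.2, τ_A 5, τ_B 0.3, logα 1.6, logβ 0.3, E_max 110; single-agonist
curves at logEC₅₀ −9.83; saturation binding at K_d 4.74 nM; competition at
logK_i −8.20 with [L] = K_d. Shipped presets ("wildtype_gtpgammaS",
"mutant_N362S", …) carry magnitudes inspired by published wild-type/mutant
regimes — they are generator parameters, not experimental data.

Trajectory stacks are a template scaffold plus isotropic per-atom Gaussian
jitter, optional rigid segment displacements over frame windows, and
optional forced contact schedules (contact "in" placed at exactly 3.5 Å,
"out" at 6.0 Å), so occupancies and displacement steps are exact by
construction. None of this reproduces real assay or MD physics: no
plate/position effects, no heteroscedastic counting noise, no correlated
frames, no force fields. Passing recovery tests therefore demonstrate that
the estimators are correct and calibrated *under the stated noise model*,
not that any particular experimental dataset would be recovered.

Problem sizes in the recovery harnesses (200 surfaces in the test suite,
60 in the acceptance script; 10⁴/5·10³ and 10⁴/2·10³ calibration draws)
were chosen so Monte-Carlo error is small against the assertion widths
while the default run stays fast.

## Known limitations

* No global/shared-parameter fitting across receptor variants, no Schild
  analysis, no kinetic binding models.
* SEs are curvature-based; strongly correlated parameters (τ_B with logβ at
  weak direct agonism) can have optimistic SEs — the coverage harness
  bounds this for logα only.
* The trajectory reader handles multi-model PDB and plain XYZ tables only;
  binary trajectory formats are deliberately outside the core.
* The pipeline executes stages sequentially on one process; there is no
  caching or partial re-execution.
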