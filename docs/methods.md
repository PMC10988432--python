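# Methods

`myoquant` re-implements, as a tested pipeline, the derived-measure and
statistical machinery of a deep muscle-phenotyping comparison between
patients with end-stage liver disease (ESLD, n = 39) and age/sex-matched
healthy controls (HC, n = 18). Because no subject-level data are
deposited for such studies — only group summaries — the package pairs
every computation with a synthetic cohort generator whose defaults
encode the published group means/SDs and medians/IQRs, so that each
stage can be verified end to end: the generator plants known
ground-truth values in raw records, and the pipeline must recover them.

## Derived measures

**Anthropometry.** Mid-arm muscle circumference
`MAMC = MAC − π·TSF/10` (MAC in cm, triceps skinfold TSF in mm; the /10
converts mm→cm — the standard calliper convention, since the source
leaves TSF units implicit). Dry weight subtracts clinically graded fluid
percentages from measured weight — ascites mild/moderate/severe
5/10/15 %, peripheral oedema mild/moderate 5/10 % — combined
*additively* (the grading is phrased "and/or"; a multiplicative
combination has no support and differs only in the second decimal).
Possible total corrections are therefore {0, 5, 10, 15, 20, 25} %.

**Muscle volume.** Sparse serial cross-sections (≈7 slices, 4 cm apart,
within a restricted thigh ROI running from the lesser trochanter to 20 %
above the proximal patella) are integrated as truncated-cone segments:

    MV = Σ (t/3)·(Aₙ + √(Aₙ·Aₙ₊₁) + Aₙ₊₁)

The printed rendering of this formula in the source lost its grouping
and radical in typesetting; the frustum series is the only reading that
is dimensionally consistent and matches the cited methodology, and it is
exact for any linearly tapering radius. A trapezoidal variant
(`method="trapezoid"`) is provided for sensitivity analysis; by AM–GM it
is never smaller than the frustum estimate. Volume index = MV/height²
(cm³/m²). L3 SMI = summed L3-level muscle CSA/height², reported in
cm²/m² (an area over m² — the source's cm³/m² unit label is treated as a
typo). Mid-thigh ACSA is the slice nearest 50 % femur length; in vivo
this slice is identified with an oil-capsule marker, so the pipeline's
nearest-slice rule is the digital analogue.

**Myosteatosis.** Two-point Dixon intermuscular adipose tissue:
`IMAT% = 100·SI_fat/(SI_fat + SI_water)` over the muscle ROI mask. The
ratio is invariant to any common positive rescaling of both channels
(to floating-point rounding), and reaches 0/100 only at zero fat/water
signal.

**Architecture and strength.** VL PCSA = VL volume / fascicle length;
PCSA_eff = PCSA·cos(pennation), the component transmitted along the
tendon line. Peak torque and grip are the maximum over 5 (resp. 3)
maximal attempts; fewer completed trials produce a warning, not an
error. Specific force = torque / (mid-ACSA·(1 − IMAT%/100)): "1 − IMAT%"
is read as the non-fat *fraction* of area, the only dimensionally
sensible interpretation. The pipeline pairs each subject's (non-dominant
limb) torque with that subject's mid-ACSA and IMAT% — retaining the
source protocol's cross-limb pairing.

**Accelerometry.** Epoch-level ENMO-style magnitudes (mg). A calendar
day is valid at ≥ 16 h wear; a recording (capped at 14 days) is excluded
if post-calibration error > 0.01 g, valid days < 3, or any of the 96
quarter-hour bins of the aggregated 24-h clock cycle never sees wear —
the referenced processing suite's convention for diurnal coverage.
Average acceleration and MVPA minutes (epochs strictly > 100 mg) are
computed per valid day over wear epochs only and averaged, *unweighted*,
across valid days (whether the original processing weighted by wear time
is unstated; unweighted is the simpler contract and is what the rules
text suggests). Exclusion decisions depend only on wear flags, the
calibration error and day counts, never on magnitudes.

## Statistics

Each sample passes a D'Agostino–Pearson omnibus gate at α = 0.05
(n < 8 is forced non-normal, the statistic being undefined there). Both
arms normal → unpaired pooled-variance Student's t with mean ± SD
summaries; otherwise two-sided Mann–Whitney U with median (IQR)
summaries. The Mann–Whitney p is an exact permutation enumeration when
min(n₁,n₂) ≤ 8 (correct under ties via mid-ranks) and the
continuity/tie-corrected normal approximation otherwise. Correlations
are Pearson when both variables pass the gate, Spearman otherwise
("adjusted if non-parametric" is interpreted as rank substitution).
No multiple-testing correction is applied (none is in the source).

**Cohen's d** uses the unweighted mean of the two SDs:
`d = |m₁ − m₂| / ((s₁ + s₂)/2)`, reported unsigned with direction
carried by the percent difference. This denominator — rather than the
n-weighted pooled SD — is the one that reproduces the published effect
sizes from the published summaries (e.g. torque 43/43 = 1.0, IMAT
5.3/2.6 = 2.04); it is documented as inferred from the outputs. d is
computed from sample means/SDs even for median-summarised variables,
since the source prints d for those too. Two published values (mid-ACSA
d = 0.79, L3 SMI d = 0.26) recompute to 0.796/0.268 from the rounded
summaries; they were evidently computed from unrounded data, so
reproduction is asserted to within one unit in the last printed digit.

## Synthetic cohort generator

The generator is the package's test instrument: it emulates the *study
conditions*, not any individual patient.

- **Marginals.** Normally reported variables are truncated normals at
  the published mean ± SD; median (IQR) variables (grip, chair-stand,
  PCSA_eff, MVPA) are lognormal with (μ, σ) matched in closed form to
  the printed median and IQR (σ = asinh(IQR/2·median)/z₀.₇₅).
- **Correlation structure.** One standard-normal latent "muscle size"
  factor per subject; size-linked variables use
  z = λ·L + √(1−λ²)·ε with λ = 0.825 for mid-ACSA, volume index and
  torque (λ² ≈ 0.68 reproduces the published mass–strength r) and
  λ = 0.68 for VL thickness (product ≈ 0.56, the published
  thickness–ACSA r). Ultrasound ACSA is the MRI value times 2 % CV
  multiplicative noise, reproducing the near-unity US↔MRI agreement
  without modelling imaging physics.
- **Raw records.** Slice stacks are synthesised so the *derived*
  quantities equal the subject's true draws: 6–8 slices at exactly 4 cm
  spacing with one slice at 50 % femur length (femur = 26 % of stature);
  a one-parameter unimodal area profile pinned to the true mid-slice
  area is root-solved so the frustum volume matches the true volume
  index·height². When a draw demands more volume than a mid-peaked
  profile can hold, the profile's peak shifts proximally of the
  mid-femur slice — anatomically the quadriceps peak usually lies
  proximal to mid-thigh, so this branch stays realistic. VL stacks span
  the full muscle and are scaled linearly to the true VL volume
  (back-computed from the true PCSA_eff, fascicle length and pennation);
  L3 is a single 1 cm slice. Dixon ROIs are 12×12 fat/water maps with
  Gaussian noise (SD 2 on an S₀ = 100 scale) around (f·S₀, (1−f)·S₀) —
  the fat fraction being scale-free, S₀ is arbitrary. Strength trials
  place the true peak among sub-maximal attempts at 80–98 %.
  Accelerometer series (60 s epochs, 7 days, full wear) plant per-day
  above-threshold bouts (gamma-distributed excess over 100 mg) matching
  the subject's true MVPA and solve the background level so the day's
  wear-mean matches the true average acceleration; bout minutes are
  capped by the day's magnitude budget, so physically inconsistent
  (high-MVPA, low-average) tail draws are reconciled in favour of
  average acceleration.
- **Fluid overload.** ESLD ascites/oedema grades are sampled with
  probabilities (none/mild/moderate/severe = .30/.45/.18/.07;
  oedema .95/.04/.01), giving ≈70 % ascites prevalence and an expected
  dry-weight correction ≈5.4 %, matching the published measured→dry
  weight drop. Controls carry no fluid overload.

**Determinism.** All draws flow from one `numpy` PCG64 generator seeded
from the config; identical (config, seed) yields identical cohorts, and
the CSV writer (17-significant-digit floats, round-trip parsing) makes
write→read an exact identity and repeated writes byte-identical.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: segmentation error and inter-rater
variability, non-Gaussian Dixon noise and partial-volume effects,
diurnal activity structure (bouts are placed uniformly at random),
missing data, and any causal link between fluid grades and the muscle
variables. Recovery tests demonstrate the pipeline inverts its own
generative model, plus the published summary statistics; they cannot
validate the measures against patients.

## Numerical choices and problem sizes

- Slice-spacing uniformity tolerance 1e-6 (relative); profile
  root-solves use Brent's method at xtol = 1e-12, falling back to the
  nearest bracket endpoint for (never observed in 1200 simulated
  subjects) unattainable draws.
- Monte-Carlo test sizes: distributional recovery at n = 500/arm;
  latent-factor monotonicity at 3 loadings × 200 subjects; statistical
  calibration at 1000 null replicates (n = 39/18); these sizes put the
  checks' own sampling error well inside the asserted bands while
  keeping the default test run around a minute.
- Large simulated cohorts in tests use a thinned accelerometer profile
  (1 day, 10-min epochs); the wear rules are epoch-length agnostic, and
  the 60 s default is exercised by the study-sized cohort.

## Known limitations

- The generator draws each variable's marginal independently of sex and
  age (the source reports pooled summaries only), so sex-stratified
  analyses of synthetic cohorts are not meaningful.
- IMAT carries no latent-size loading: the within-arm covariance of
  myosteatosis with size/strength is unreported in the source, so none
  is assumed.
- The chair-stand abstract-level percent difference in the source
  (+56 %) is not recoverable from its printed medians (+43 %); the
  pipeline reports what it computes.
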