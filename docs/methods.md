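# Methods

## The fingerprinting model

For each of Ns subjects, two resting-state runs yield parcelled time
series `X ∈ R^{T×N}` (T time points, N ROIs). Static FC is the Pearson
correlation matrix of the columns; its strict upper triangle, unfolded
row-major into `c_i(r) ∈ R^M` with `M = N(N−1)/2`, is the subject's FC
profile for run r. The identifiability matrix
`I[i,j] = corr(c_i(1), c_j(2))` is asymmetric because the two run sets
are ordered. Derived statistics:

- `Iself` = mean diagonal, `Iothers` = mean over *all* off-diagonal
  entries. Since I is asymmetric, both triangles are pooled — a choice
  this package fixes explicitly.
- `Idiff = Iself − Iothers`; Cohen's
  `d = Idiff / sqrt((σ²self + σ²others)/2)` with sample variances
  (ddof=1) over the diagonal and off-diagonal sets.
- Identification accuracy: a subject counts as identified when the
  strict maximum of their row lies on the diagonal. An exact tie at the
  maximum involving the diagonal counts as a failure and emits a
  warning — ties have measure zero for float data, but the rule must be
  deterministic. Reported percentages are rounded to one decimal for
  display; full precision is retained internally.
- Top-K accuracy ranks each row descending (ties broken toward the
  lower column index) and asks whether the diagonal is within the K
  best. It is non-decreasing in K by construction and reaches 100% at
  K = Ns.
- Chance level is 100/Ns percent: under exchangeable subjects the row
  argmax is uniform over the Ns columns.

A symmetric identification variant (averaging row-wise and column-wise
success) exists behind a flag and is off by default; the ordered
run1→run2 definition is the primary one. An optional Fisher z-transform
of FC values before vectorization likewise defaults off — fingerprints
correlate raw FC profiles.

## Parcellation

The spinal cross-section is fixed at 14 bilateral ROIs — GM: dh, iz, vh;
WM: cst, fc, fg, sl — so a parcellation over L levels has N = 14·L
(42, 70, 98 for C4–C6, C4–C8, C2–C8). The within-level ordering
(GM dorsal→ventral, then WM, L before R) is a package convention chosen
for deterministic matrix layouts; anatomical atlases do not dictate a
serialization order. The brain block has 119 ROIs (100 cortical tagged
by seven canonical resting-state networks, 19 subcortical).

Voxel-to-parcel reduction uses a robust mean: at each time point, voxels
of an ROI outside that time point's [5th, 95th] percentile band (linear
interpolation between order statistics) are discarded before averaging;
if trimming would empty the set (tiny ROIs), the untrimmed mean is used.
Trimming across voxels within a time point — rather than across time
within a voxel — is the reading implemented; both interpretations exist
in the wild, and the percentile bounds are exposed as parameters. tSNR
is temporal mean over temporal SD (population, ddof=0), with NaN marking
zero-variance voxels.

## Edge reliability: ICC(1,1)

Per edge, the Ns×2 table of run values enters a one-way random-effects
ANOVA: MSR = between-subject mean square (df Ns−1), MSW = within-subject
mean square (df Ns·(k−1), k=2), and
`ICC(1,1) = (MSR − MSW)/(MSR + (k−1)·MSW)`, bounded in [−1, 1] for k=2.
Negative values are retained — the estimator admits them and flooring
would bias summaries. The cross-sectional average extracts each map's
within-level 14×14 blocks and averages them elementwise (cross-level
edges excluded; undefined entries left out of each mean). Percentile
thresholding computes its cutoff over the strict upper triangle only
(each edge once); entries below the cutoff become 0. Nodal strength sums
each ROI's row of the thresholded map by default; a mean-based reduction
is available (`mode="mean"`) since both conventions appear in reliability
summaries.

## PCA-based Idiff maximization

All 2·Ns FC profiles are stacked as columns of an M×2Ns matrix; each
edge (row) is centered across observations; principal components come
from one SVD of the centered matrix, with a deterministic sign
convention (largest-magnitude loading of each component non-negative).
For each m in 2..2·Ns, every profile is reconstructed from its top-m
components plus the mean, the identifiability matrix is recomputed, and
the m maximizing Idiff is selected, ties toward the smallest m. At
m = 2·Ns reconstruction is exact, so the selected optimum can never fall
below the unreconstructed Idiff. Run-specific noise concentrates in
late, low-variance components, which is why truncation typically helps
when run noise is strong.

## Brain↔spine residualization

For a combined run, the target block Y (spine or brain) is regressed on
the predictor block X sharing the time axis: both are column-demeaned
(no intercept; preprocessed fMRI series are mean-free, and demeaning
keeps the formulation symmetric), β is the minimum-norm least-squares
solution (well-defined even for rank-deficient X), and the residuals
ε = Y − Ŷ are fingerprinted. The fit asserts the exact decomposition and
residual–predictor orthogonality. When the predictor count reaches T the
fit is perfect and residuals vanish; the package warns in this regime
and raises if residuals are identically zero (e.g. predictor = target).
Regression is fitted per subject and per run independently; no pooling
across runs is attempted.

## Synthetic cohort generator

The generator emulates the statistical skeleton of a two-run test-retest
cohort, not spinal physiology:

- **Subject fingerprint.** Loadings `A_i = A_group + λ·B_i` (entries
  standard normal, N×k) give `C_i = A_iA_iᵀ + σ_obs²·I_N` — positive
  definite by construction, shared across a subject's runs.
  `lambda_subject` (λ) scales how far each subject departs from the
  group pattern.
- **Run noise.** Per run, `C_i` is perturbed by `σ_run·(S+Sᵀ)/2`
  (S standard normal) and projected back to positive definite by
  flooring eigenvalues at 1e−6 of the leading one. T rows are then drawn
  from the zero-mean Gaussian.
- **Coupling.** With a combined parcellation and coupling c > 0, spinal
  series are `sqrt(1−c)·intrinsic + sqrt(c)·(brain @ W_i)` with a
  variance-normalized, subject-specific mixing matrix W_i. The
  brain-driven share of the spinal signal is then removable by the
  residualization stage, which measurably lowers spinal Idiff — the
  directional effect the pipeline must expose.
- **Determinism.** Every draw comes from a substream keyed by
  (seed, purpose, subject, run), so a spec reproduces its cohort
  byte-for-byte and adding subjects leaves existing subjects' data
  untouched.

Defaults — Ns=15, C4–C6 (N=42), T=300, k=5, λ=0.2, σ_run=3.0, σ_obs=1.0,
c=0 — were calibrated once, by a coarse grid probe, to place the default
cohort in the regime cervical-cord fingerprinting studies report:
Idiff of a few hundredths, identification around 50–70% against a ~7%
chance level, Cohen's d near 1.5. Stronger subject effects saturate
accuracy at 100%, which real spinal data do not show. What the generator
deliberately omits: physiological noise spectra (cardiac/respiratory
aliasing, CSF pulsatility), motion artefacts, spatial autocorrelation of
ROIs, non-Gaussian BOLD features, and any session/day structure beyond
two runs. Passing tests therefore demonstrate correctness of the
*estimators and their directional behavior*, not expected effect sizes
on real acquisitions.

## Numerical choices and degenerate inputs

- Pearson FC requires T ≥ 3 and rejects constant columns by ROI name;
  matrices are symmetrized, clipped to [−1, 1], unit diagonal.
- Vectorization rejects asymmetry beyond 1e−10; the edge order is
  row-major over the strict upper triangle, and devectorization is its
  exact inverse.
- Cohen's d returns NaN with a warning when both similarity sets are
  degenerate (zero variance).
- ICC returns NaN when its denominator vanishes; the matrix diagonal is
  NaN (self-edges are undefined).
- Percentiles use linear interpolation between order statistics
  throughout.
- Analysis problem sizes (15 subjects × 42 ROIs × 300 time points for
  the main cohort; 10 × 48 × 250 over 20–50 seeds for residualization
  grids) were chosen so each driver completes in seconds while leaving
  Monte-Carlo error well inside the tested tolerances.

## Known limitations

- The identifiability framework cannot separate neural individuality
  from individually stable artefacts; on synthetic data this is moot,
  on real data it is the central caveat.
- Residualization is linear and instantaneous; lagged or nonlinear
  brain–spine dependencies pass through untouched.
- The PCA sweep selects m on the same cohort it evaluates — no held-out
  validation of m* is attempted.
- Only two runs (k=2) are supported for ICC; other ICC variants
  ((2,1), (3,1)) are out of scope.
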