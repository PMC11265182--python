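# Methods

## Signal model and tensor estimation

Per voxel, the diffusion-weighted signal is modelled by the fourth-order
cumulant expansion

    ln S(b, n) = ln S0 − b Σᵢⱼ nᵢnⱼ Dᵢⱼ + (b²/6) Σᵢⱼₖₗ nᵢnⱼnₖnₗ Uᵢⱼₖₗ ,

with D the symmetric diffusion tensor (6 unique components, mm²/s) and
U = MD²·W, where W is the fully symmetric dimensionless kurtosis tensor
(15 unique components) and MD = trace(D)/3. The 22 unknowns
`[ln S0 | Dxx Dyy Dzz Dxy Dxz Dyz | U...]` are linear in the log-signal;
cross terms carry their symmetry multiplicities (2 for the rank-2 tensor;
1/4/6/12 for the aaaa/aaab/aabb/aabc rank-4 classes). W is recovered post
hoc as U/MD². Fitting U rather than W keeps the problem linear; the cost is
that W is undefined when MD² < 1e-12 mm⁴/s² (voxel flagged).

Two estimators are provided. OLS solves the log-linear system directly.
The default WLS re-solves with weights equal to the squared OLS-predicted
signals — the first-order variance model for log-transformed data with
additive noise. Numerics: the design-matrix columns span ~7 orders of
magnitude (1 vs b²/6), so the matrix is equilibrated to unit column norm,
and the weighted pass is solved by batched QR rather than normal equations
(which would square a ~5e6 condition number). On noiseless model-generated
signals both estimators recover all 22 parameters to ~1e-12 relative.

Voxels containing non-positive signals are flagged invalid, not clamped:
flooring the log systematically biases kurtosis. Further QC flags mark
MD ≤ 0 and directional (apparent) kurtosis outside [−3, 10], a conventional
physical-plausibility window. Flagged voxels become NaN in the metric maps
and are excluded from ROI means; an ROI that loses more than half of its
voxels flags the subject.

### Kurtosis axis conventions

The literature phrase "diffusivities of the kurtosis tensor" is ambiguous,
so both readings are implemented for the diagonal kurtosis maps:

- `tensor` (default): the raw components W_iiii, matching what
  kurtosis-tensor output files of standard estimators contain;
- `apparent`: K_app(eᵢ) = (MD²/Dᵢᵢ²)·W_iiii, the directional excess
  kurtosis along the axis.

The ALPS ratio is scale-free, so the two conventions give different DKI-ALPS
values only when the MD²/Dᵢᵢ² factors differ between numerator and
denominator axes — which they do in anisotropic tissue. Results should be
reported with the convention named; the CLI records it in every sidecar.

## ALPS geometry

Four spheres of 5 mm diameter, a projection-fibre and an association-fibre
ROI per hemisphere. Voxel membership is by voxel-centre distance (simple and
reproducible; no partial-volume weighting). On a 1 mm grid a 5 mm sphere
holds 81 voxels, on the 2 mm acquisition grid 7 voxels. Inputs must be in an
axis-aligned space (right-left x, anterior-posterior y, inferior-superior
z); the affine's rotation is checked to be within 5° of axis-aligned and a
warning is raised otherwise, because the construction reads single tensor
components off the grid axes. Default template-space sphere centres are
package-editable values on the lateral-ventricle-body plane (projection
medial, association lateral, mirrored across x=0); user-supplied mask files
override them and are the authoritative route for real data. The whole-brain
index is the mean of the two hemispheric indices; pooling the four ROIs
before the ratio is available as an option.

## Phantom

The phantom realizes the geometry the index assumes: mirrored 3-voxel boxes
for projection regions (diffusion diag (1.0, 0.6, 1.6)×10⁻³ mm²/s, kurtosis
diag (1.0, 0.65, 0.7)) and association regions ((1.1, 1.6, 0.55)×10⁻³;
(1.0, 0.7, 0.6)) in an isotropic background (0.8×10⁻³, W = 0), on a
16×16×10 grid of 2 mm voxels by default (a desk-scale volume: the full
pipeline runs in well under a second). These diagonals give analytic indices
DTI-ALPS = 1.05/0.575 ≈ 1.826 and DKI-ALPS (tensor convention) = 1.6,
deliberately in the range reported for human readings. The acquisition
mirrors the study protocol: one b=0 plus 56 directions at each of
b = 1000 and 2000 s/mm². Direction sets are generated deterministically by
electrostatic repulsion (Fibonacci-spiral start, antipodally symmetric
Coulomb descent; minimum angular separation ≈ 18° for 56 directions).

Crossing-fibre regions are Gaussian-compartment mixtures
S = S0 Σ f_c exp(−b nᵀD_c n). Their effective tensors follow from the
cumulant expansion: D_eff = Σ f_c D_c and
W = 3·sym(Cov_f[D_ij, D_kl])/MD², so K_app(n) = 3·Var_f(nᵀD_c n)/E_f(nᵀD_c n)².
For the 50/50 mixture of fibres along z and y with diffusivities
{0.3, 1.7}×10⁻³, this gives K_app(z) = 3·0.49/1 = 1.47 and K_app(x) = 0.

**Finite-b truncation.** Signals are generated from the exact compartment
sum, but the fitted model truncates the cumulant series at b². For the
strong two-point mixture above, the neglected fourth cumulant contributes
≈ −0.21 to the log-signal at b = 2000 along z, so the fitted apparent
kurtosis underestimates the analytic value by ≈ 18% at the study's shells
(and misfit leakage produces K_app(x) ≈ 0.2 instead of 0). The fit converges
to the cumulant oracle as b shrinks — within 2% with shells at one-eighth of
the study's — and the test suite asserts exactly this convergence rather
than pretending the full-b fit is unbiased. This is a property of the
kurtosis signal model at clinical b-values, not of the estimator.

Noise is Gaussian or Rician (magnitude of two Gaussian channels), with
σ = S0/SNR. At SNR 30 the Rician floor matters for the lowest-signal
measurements (b = 2000 along the fibre axis drops to single-digit local
SNR). Measured over 20 seeds, the pipeline's DTI indices are accurate to
well under 1%, and the global DKI index to ~1%; the hemispheric DKI indices
carry a 5–8% per-seed spread (7-voxel ROIs averaging noisy kurtosis
estimates), so short seed averages fluctuate by 1–2%.

## Cohort simulation

Each simulated subject draws region diffusion and kurtosis diagonals
log-normally around group means (between-subject CV 8% by default, mean
preserved), with multiplicative group effects per region/axis — the default
effect is +7% x-axis kurtosis in the right hemisphere of the migraine
group, the direction and laterality of the finding the package is built
around. Subjects then get a small phantom (12×12×8 grid), Rician noise at
SNR 30, the full WLS fit, and ALPS extraction. Covariates (age, sex,
education, disease duration, attack frequency, PHQ-9, GAD-7, MIDAS, HIT-6)
are drawn from distributions matching the study's demographics table;
clinical scores are missing for controls, as in such tables. Everything is
reproducible from one seed.

What the simulation does *not* emulate: real anatomy and registration error,
eddy/motion/susceptibility artifacts, CSF partial volume, spatially
correlated noise, and manual-ROI placement variability. Passing tests
therefore demonstrate correctness of the estimator and index machinery under
the stated generative model, not clinical accuracy.

## Statistical battery

- **Lilliefors**: D = sup|F̂(x) − Φ((x−x̄)/s)| with the Monte-Carlo null
  (default 5000 reps, cached per sample size; add-one-corrected p). KS-type
  tests have only moderate power against light-tailed alternatives: at
  n = 100 roughly half of Uniform(0,1) samples are *not* rejected — matching
  statsmodels decision-for-decision.
- **t-tests**: classical pooled (default — the plain reading of
  "two-sample t-test") and Welch; both available from raw samples or from
  printed mean ± SD summaries, which makes published group tables
  recomputable.
- **Mann-Whitney U**: midrank ties; exact p by enumeration of all
  C(n₁+n₂, n₁) assignments for ≤ 20 observations (two-sided p = 2·min tail,
  capped at 1), tie-corrected continuity-corrected normal otherwise. On
  tie-free 8+8 data exact and normal p agree within 0.011 over every
  achievable U; heavily tied small samples can disagree by up to ~0.07 near
  p ≈ 1 — inherent discreteness, not an implementation artifact.
- **Chi-square** (2×2, df = 1): uncorrected by default (the convention that
  makes a printed (statistic, p) = (2, 0.1573) pair self-consistent); Yates
  optional.
- **Correlations**: Pearson, or Spearman via midranks, two-sided p from the
  t-transform, listwise deletion. No multiple-testing correction anywhere:
  α = 0.05 throughout, matching how such studies report.
- **Group report**: mean ± SD per group, Mann-Whitney for demographics,
  chi-square for sex, Lilliefors screening then t-test for the six indices,
  stars at α. Calibration: over 2000 null cohorts (n = 30 per group) the
  starred fraction sits within [0.03, 0.07].

## Design notes

- Default fit is WLS (heteroscedastic log-signals); OLS is one flag away.
- No positivity or kurtosis constraints are imposed in the fit; implausible
  voxels are flagged and excluded transparently rather than projected.
- b0 threshold 50 s/mm² and shell rounding to the nearest 50 s/mm² absorb
  vendor b-value jitter.
- Signals are stored as floating point regardless of on-disk dtype; gradient
  directions are taken in the image frame (preprocessed data assumed, no
  re-orientation).
- Simulation problem sizes (16×16×10 phantom; 12×12×8 cohort subjects;
  20-seed noise averages; 100-seed power runs; 2000-rep calibrations) are
  chosen so the entire suite runs on a laptop in a few minutes while keeping
  Monte-Carlo error well below the tolerances being asserted.

## Known limitations

- The kurtosis-model truncation bias at b = 2000 in strong crossing
  configurations (above) is the dominant systematic error of DKI-ALPS here.
- Hemispheric DKI indices from 5 mm ROIs on a 2 mm grid average only 7
  voxels; at SNR 30 their per-acquisition spread is 5–8%.
- The exact Mann-Whitney is limited to 20 observations (combinatorial
  enumeration); larger samples use the normal approximation.
- ROI placement for real data is the user's responsibility (masks in the
  map space); the shipped template-space centres are editable defaults, not
  validated coordinates.
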