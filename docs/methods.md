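# Methods

## The measurement model

The pipeline quantifies how "young-like" a subject's memory-encoding
brain activity is, and relates that to behaviour and traits.

**Recognition performance (A′).** In the recognition test each of 88
old and 44 new images receives a rating from 1 ("definitely new") to 5
("definitely old"). With oᵢ and nᵢ the counts of old and new items at
rating i, hit and false-alarm rates at threshold t ∈ {0,…,5} are the
proportions rated strictly above t; A′ is the trapezoidal area under
the six-point polygon (FA(t), H(t)). This equals the rank-sum quantity
P(old rating > new rating) + ½·P(tie) — an identity verified
exhaustively in the tests for all count vectors with up to six items
per side. No parametric (d′/criterion) model is fitted to the
behavioural data; A′ is distribution-free.

**First-level GLM.** Each condition (novel, master) is a boxcar of the
2.5 s presentation convolved with a canonical double-gamma HRF
(peak delay 6, undershoot delay 16, dispersions 1, peak:undershoot
ratio 6:1; peak ≈ 5 s). The subsequent-memory regressor weights each
novel trial by arcsin((r − 3)/2) — an odd-symmetric map of the rating
scale onto [−π/2, π/2] — mean-centred across novel trials *before*
convolution, which (i) decorrelates it from the novelty main effect and
(ii) makes the memory contrast invariant to constant shifts of the
modulator (a tested invariance). The affine pre-map inside the arcsine
is a package choice (the transform itself is standard for this task)
and can be replaced via the `modulator` argument of
`build_design_matrix`. Drift is modelled by a linear term plus a
DCT cosine set below 1/128 Hz. Fits are voxel-wise OLS; no
autocorrelation modelling, motion regressors or HRF derivatives — the
scores are defined on contrast estimates and group-level t maps, which
these refinements do not redefine.

**Reference maps.** J⁺/J⁻ are the voxels whose young-group one-sample
t is significant at one-sided p < α/V (Bonferroni over the V mask
voxels, α = 0.05) after removing connected components smaller than
k = 10 voxels (18-connectivity by default; 6/26 available). Bonferroni
replaces random-field-theory FWE deliberately: it requires no
smoothness estimation and is conservative, and the method is recorded
in the reference's parameter sidecar. β̂ⱼ and σ̂ⱼ (n−1 denominator) are
taken over the full mask. Degenerate voxels (σ̂ⱼ < 1e−12) are excluded
from SAME sums with a warning. An empty J⁺ aborts (the scores are
undefined); an empty J⁻ yields activation-term-only SAME scores with a
flag. "Outside J⁺" in the FADE definition means mask∖J⁺, not the whole
volume.

**Scores.** FADE is linear in the t map and shift-invariant; SAME is
linear in γ, zero for a subject identical to the young voxel-wise mean,
and halves when the young s.d. doubles — all asserted as tests. Young
subjects are scored against the reference that includes them
(`in_sample`, the default) or with a leave-one-out reference; older
subjects always use the full young reference.

**Association statistics.** All regression estimates are fully
standardized: every variable, including 0/1 gender and education, is
z-scored before OLS, so coefficients are comparable across predictors.
Mediation uses the two-regression product of coefficients (a from
m~x; b, c′ from y~x+m; c from y~x), which on one sample satisfies
c = c′ + a·b to machine precision. For a saturated three-variable
linear model these point estimates coincide with a fully standardized
SEM fit; standard errors are delta-method (Sobel) by default, with a
percentile bootstrap (seeded) optional — the two conventions can
differ slightly in small samples. Group t tests default to pooled
variance (Welch by flag). No multiple-testing correction is applied to
the correlation tables; the report tables carry unadjusted p values.

**Voxel-wise inference.** Cluster-level FWE uses permutation of the
maximum supra-threshold cluster size at a one-sided cluster-forming
threshold of p < 0.001. With covariates, Freedman–Lane permutation
(residuals of the covariates-only model are permuted and added back to
its fitted values) preserves nuisance structure under the null; with
none it reduces to exchanging rows. Corrected p values are
(1 + #{perm max ≥ s})/(n_perm + 1) ∈ [1/(n_perm+1), 1], monotone in
cluster size, and the familywise false-positive rate on null
simulations is verified ≤ 5% within Monte-Carlo error. This replaces
random-field cluster correction: exact under exchangeability, no
smoothness or stationarity assumptions, at the cost of runtime and of
giving no closed-form p. Only positive predictor effects form
clusters (test the negated predictor for the other direction).

## The synthetic cohort generator

Because the motivating dataset is access-restricted, the generator is
a first-class module that emulates the statistical structure the
analysis assumes, with defaults chosen once to resemble a published
two-group encoding cohort:

* sample sizes 209 young / 143 older; 88 old / 44 new recognition
  items; demographic and Big Five means/s.d. set to realistic
  group-level values (cosmetic, not fitted);
* a latent *network integrity* per subject: fixed at the ceiling 1.0
  for young adults, Normal(0.8, 0.12²) for older adults. The group
  coupling is by construction: trait–integrity correlation exists only
  in the older group (planted r = 0.3, matching the observed
  trait–SAME correlation magnitude), because the analysis this
  supports reports trait coupling in older adults only;
* contrast maps: compact blobs (+1 activation, −1 deactivation;
  nearest-neighbour balls, so extent thresholds behave as on smoothed
  group maps) scaled by integrity, plus i.i.d. Gaussian voxel noise
  (s.d. 0.5). A flag adds Gaussian-smoothed noise for cluster-inference
  simulations; score unit tests do not need smoothness because the
  scores are voxel averages. Synthetic t maps are γ/noise-s.d. — the
  nominal first-level t under a unit-variance design — since cohort
  maps are planted at the contrast level; full BOLD-level generation
  exists separately (`generate_subject_bold`) for GLM recovery tests;
* recognition ratings from an equal-variance signal-detection model
  with d′ = −0.2 + 1.5·integrity and symmetric criteria at
  d′/2 + (−1.5, −0.5, 0.5, 1.5), giving A′ ≈ 0.80 (young) and ≈ 0.76
  (older).

With these defaults the simulated cohort reproduces the qualitative
target pattern: young SAME scores centre on zero, older SAME ≈ −0.8
(s.d. ≈ 0.5), trait–SAME correlation ≈ 0.3 in older adults and ≈ 0 in
young adults.

**What the generator does not emulate.** Scanner artefacts, motion,
physiological noise, site differences, spatial autocorrelation of
signal, realistic anatomy, and — importantly — any *direct*
trait→behaviour path: the trait affects behaviour only through
integrity, so planted mediation is complete (proportion ≈ 100%),
whereas real cohorts show partial mediation. Passing recovery tests
therefore demonstrates estimator correctness under the assumed
linear-Gaussian structure, not robustness to real-data violations.
The linear-Gaussian trait–integrity coupling itself is an assumption;
no generative model for it is established in the literature.

## Numerical choices

* One-sample t at zero-variance voxels: 0/0 → t = 0 with a warning;
  zero variance with nonzero mean is an error.
* First-level t with zero residual variance is reported as 0 (the γ
  estimate is exact there).
* Regression designs are guarded by a condition-number limit (1e8) and
  explicit zero-variance checks; rank-deficient designs raise.
* Proportion mediated is undefined (error) when |c| < 1e−10.
* The pipeline's global seed fans out to per-stage seeds through
  `numpy.random.SeedSequence(seed, spawn_key=(stage,))`, so stages are
  independently reproducible and two runs with the same configuration
  produce byte-identical summary JSON.

## Problem sizes

Default simulated grids are 16×16×12 voxels (pipeline) down to 8×8×4
(unit fixtures) — large enough for non-trivial cluster topology and
extent filtering while keeping the full test suite in tens of seconds.
Permutation counts default to 500 in the pipeline (100–200 in tests);
the type-I-error calibration uses 200 null replicates. The mediation
recovery checks use n = 200,000 (point accuracy) and 100 seeds at
n = 10,000 (bias).

## Known limitations

* Bonferroni is conservative relative to RFT on smooth maps; J⁺/J⁻ are
  smaller than an SPM-style reference would give.
* Sobel SEs are anti-conservative for small n; use the bootstrap for
  n ≲ 100.
* Cluster inference reports positive effects only, and no anatomical
  labelling is attempted.
* Ingest mode expects maps already normalized to a common space; no
  preprocessing (realignment, normalization, smoothing) is provided.
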