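# Methods

`gfconn` implements an analysis stack for *general functional connectivity*
(GFC): estimating a subject's intrinsic connectome by aggregating frames
across task and resting-state fMRI scans, and quantifying what that
aggregation buys in test-retest reliability, twin-based heritability and
out-of-sample behavioral prediction. Because the studies this methodology
targets cannot redistribute their imaging data, the package ships a synthetic
twin-cohort generator whose statistical structure matches the assumptions of
the downstream analyses; every claim the package makes is demonstrated as a
parameter-recovery experiment on that generator.

## The latent model behind the generator

Each subject *i* carries a latent trait connectome on the Fisher-z scale,
one value per edge *e* of an R-region parcellation (R = 44 by default,
E = R(R−1)/2 = 946 edges):

    z_ie = m_e + a_ie + c_fe + t_pe + u_ie

with per-edge variances (σ²_A, σ²_C, σ²_T, σ²_E) for the additive-genetic,
shared-environment, twin-specific and unique components. The additive part
uses the shared/unique Gaussian decomposition a = √.5·a_family +
√.5·a_individual, exact for the 0.5 kinship coefficient of DZ co-twins and
full siblings; MZ co-twins copy a single draw. C is shared by the whole
family; T is shared only within a twin pair and contributes variance only to
twins (siblings carry no T). The implied familial correlations of
standardized shares are cor(MZ) = a²+c²+t², cor(DZ) = ½a²+c²+t² and
cor(twin–sib) = ½a²+c², which the property tests verify empirically.

A scan of type *s* realizes the trait as i.i.d. multivariate-normal frames
whose target correlation matrix is

    R_ise = tanh(z_ie + δ_se + ε_ise),

where δ_se is a task-state offset shared by all subjects and
ε ~ N(0, σ²_sess) is drawn once per subject × scan (the session/state
fluctuation). The matrix is made positive definite by eigenvalue clipping at
0.01 followed by diagonal renormalization; matrices already clear of the
floor pass through untouched. A censor mask marks ⌊censor_frac·n⌋ uniform
random frames.

A behavioral phenotype is y_i = Σ_e w_e z_ie + η_i with sparse weights; the
noise is scaled so the squared correlation between the noiseless predictor
and y equals a target R² (using the cohort's empirical predictor variance,
so very small cohorts wobble around the target).

### Default parameters and why

| Parameter | Default | Rationale |
|---|---|---|
| total trait variance / edge (z-scale) | 0.002 | places 5-min single-scan reliability near ICC 0.22 and 40-min near 0.66, the range reported for short vs. aggregated scans |
| shares (a², c², t², e²) | (0.285, 0.045, 0.045, 0.625) | implied observed heritability ≈ 0.10 at 5 min rising to ≈ 0.20 at 40 min with small, stable C and T — the pattern twin-imaging studies report |
| session-noise variance σ²_sess | 0.0005 | a per-scan state fluctuation small relative to sampling noise at short budgets; a single free knob, since day-to-day state variance is not separately characterized in the literature this emulates |
| task state offsets δ | N(0, 0.05²) per edge | distinct but modest task signatures; large enough to matter for task regression, small enough that implied matrices stay near positive definite |
| mean connectome m | low-rank factor model (3 factors, loadings N(0, 0.3²)) | a valid correlation matrix with min eigenvalue ≈ 0.6; an i.i.d. mean profile is far from positive definite and the repair would distort edges |
| scan menu | 4 rest (330 frames) + 7 task scans (88–203 frames) per session, TR 2 s, LR/RL alternating | the shape of a two-session multi-task protocol at quarter length, so full sweeps run in minutes |
| censor fraction | 0.05 | typical post-scrubbing frame loss |
| behavior | 3 signal edges, target R² = 0.10 | sparse signal at the effect size connectome-wide prediction studies report |

The choice of a **positive-definite mean connectome** is load-bearing: with
per-edge perturbation sd ≈ 0.05 (trait + session) around a base with
eigenvalue margin ≈ 0.6, the clipping repair is inactive for rest scans and
negligible (<1% edge-variance change) for task scans, so the generator's
analytic variance bookkeeping stays valid. Larger perturbations or an
unstructured mean profile would push substantial variance through the
nonlinear repair and silently attenuate between-subject differences.

## Cleaning and connectome estimation

Confound removal is a single projection: censored frames are deleted, then
each region's series is projected onto the orthogonal complement of
[nuisance | out-of-band trig basis], where the trig basis holds sine/cosine
pairs at Fourier frequencies k/(N·TR) outside the requested band, evaluated
on the kept frames' original (irregular) time grid. One projection cannot
reintroduce variance another step removed, and it is idempotent; both are
tested. Nuisance columns follow the common recipe: intercept, 6 motion
parameters plus backward-difference derivatives (first element 0), 5
tissue-compartment components, optional global signal, and per-condition
boxcar ⊗ double-gamma HRF task regressors. Cleaned scans keep their original
frame times and Fourier grid so repeated cleaning is exactly idempotent.
Subjects whose kept-frame count does not exceed the regressor count raise an
exclusion error, mirroring how studies drop such subjects.

Time-point selection converts a budget in minutes to frames
(round(min·60/TR)) and takes an equal share per scan type while every type
has frames (LR-labelled scans first, in acquisition order, then RL); once a
type is exhausted — or the budget is not divisible by the type count — the
shortfall is drawn uniformly at random with a caller-supplied seed. Edge
matrices are plain Pearson correlations of the concatenated kept frames,
vectorized in canonical row-major upper-triangle order.

## Reliability

ICC(3,1) — two-way mixed, consistency, single measurement — is computed per
edge from the two-session ANOVA, vectorized across edges, with pairwise
deletion for missing edges. Bins are left-closed ([0,.4) poor, [.4,.6)
moderate, [.6,.75) good, [.75,1] excellent; negatives clamp to poor).

The scan-length mechanism has a closed form the sweep is checked against: on
the z scale an edge estimate is trait + state fluctuation + sampling noise,
so

    ICC_e ≈ σ²_B / (σ²_B + σ²_sess·Σ_s w_s² + 1/(T−3)),

where w_s are the frame shares of the scans a budget spans (state
fluctuations average across scans) and 1/(T−3) is the Fisher-z sampling
variance. The per-edge tanh scale factor (1−ρ²)² multiplies numerator and
denominator alike and cancels. ICC itself is computed on raw r (an option
exists for the z scale); the cancellation is why that choice is benign. The
observed sweep matches this prediction within 0.05 at 60 subjects.

## Heritability (extended-twin ACTE)

Each edge is fit independently by maximum likelihood on family blocks
y_f ~ N(X_f β, σ²_A K + σ²_C J + σ²_T Tm + σ²_E I), with kinship K (MZ 1,
DZ/sib 0.5), J all ones, and Tm equal to 1 between co-twins and on their
diagonal entries — T adds variance only to twins, the convention adopted
here from the extended-twin literature and isolated behind
`family_covariance`. The mean model carries intercept, age and sex
(constant covariates are dropped with a warning). β is profiled out by GLS,
families are grouped by role pattern so the likelihood vectorizes, and
nonnegativity comes from parameterizing each component as the square of an
unconstrained scalar, optimized by Nelder-Mead from 3 seeded starts.

Profile-likelihood CIs are computed directly on the standardized-share
scale: the share of interest is fixed by the ratio reparameterization
σ²_comp = v/(1−v)·(sum of the others), the remaining parameters are
re-maximized, and Brent's method locates the crossing of the deviance with
χ²₁(0.95) to 1e−4. "Significant heritability" is deviance at a² = 0
exceeding the critical value — identical to the CI lower bound being
positive. Coverage is verified by simulation (95% ± 4% at 500 families, 200
replicates).

Finite-sample behavior worth knowing: at a few hundred families the
per-edge share estimates are noisy (sd ≈ 0.1 for a²) and the nonnegativity
boundary shifts mass from A into C; recovery within ±0.05 per component
needs on the order of 2000 families, which is what the recovery experiment
uses. The scan-length experiment therefore runs at 1200 families so the
qualitative pattern — observed a² rising and e² falling with frames per
subject, C and T nearly flat — is not swamped by that bias. The drift in
standardized C and T across budgets is not exactly zero even in expectation
(shrinking measurement noise inflates every non-E share); the defaults keep
it within 0.03.

## Prediction (CPM)

Connectome-based predictive modeling: edges pass a p < .01 two-tailed filter
on their Pearson correlation with the phenotype (exact t transform), split
by sign; subjects are summarized by the positive and negative sums; linear
models are fit on the positive sum, the negative sum, and both jointly (the
combined model, the default — two slopes plus intercept, which nests the
difference-score variant). `CPMRegressor` follows the scikit-learn estimator
protocol and composes with its model selection tools. Leave-one-out CV
re-runs selection and fitting inside every fold; folds with empty masks
predict the training mean and are counted. Effect size is the Spearman
correlation between predicted and observed scores (ρ² reported as %
variance explained); transfer applies frozen masks and coefficients to an
independent cohort. Steiger's test for two dependent correlations sharing
one variable uses the Z̄*-type statistic with the averaged-correlation
factor, validated by Monte-Carlo type-I calibration rather than formula
transcription; multiple comparisons use Benjamini-Hochberg FDR; CIs come
from seeded paired percentile bootstrap.

Two structural facts the experiments respect. First, with ~950 independent
edges the p < .01 filter admits ~9 noise edges, and a sparse true signal is
diluted by √(selected count) in the summary sum: the best achievable
LOO/transfer effect size at a latent R² of 0.10 is ρ ≈ 0.16 (ρ² ≈ 0.025)
regardless of how the signal is spread over 1–10 edges. Real connectomes,
whose signal spreads over many mutually correlated edges, are friendlier to
CPM, which is why published effect sizes in the 4–10% range exceed what this
independent-edge generator can produce at the same latent R². Second, the
leave-one-out correlation itself is a poorly behaved statistic at small n:
even with fixed a-priori masks and a pure-noise phenotype, LOO predictions
at n = 100 correlate with the outcome at mean ρ ≈ −0.12 with sd ≈ 0.2,
because every fold shares the training mean and coefficient noise (and the
empty-mask fallback predicts the training mean, which is exactly
anti-correlated with the held-out value). Null LOO distributions are
therefore centered near zero but wide; permutation tests, not analytic
p-values, are the honest inference route for LOO-CPM. The GFC-vs-rest
comparison mirrors the motivating use case — a short (5-min) rest scan
against aggregation of everything available (40 min) — and is scored as the
fraction of seeded replicates in which GFC transfers at least as well as
rest.

## Experiment scales and numerical choices

Problem sizes were chosen so the full suite runs on one CPU in well under
half an hour: reliability sweeps use 60 unrelated subjects × 2 sessions;
ACTE recovery 2000 families; CI coverage 200 replicates × 500 families;
the heritability-vs-length sweep 1200 families × 24 edges × 3 budgets;
CPM calibration 200 permutations at n = 100 plus 2000 Steiger replicates;
the transfer comparison 50 replicates at 400 training / 600 test subjects.

Numerical conventions: projections use SVD with a relative singular-value
threshold of 1e−10; ICC denominators ≤ 0 yield missing edges; the ACTE
optimizer converges at 1e−8 on the log-likelihood; profile bounds are
floored at 0 and capped at 1; ties in time-point selection are resolved by
acquisition order, and the random remainder is drawn without replacement
from the stated seed. The profiled deviance is evaluated with solution
continuation: each fixed-share optimization warm-starts from the nearest
previously solved share, stepping through intermediates on large jumps, with
an additional start that spreads the removed component's variance over the
free ones — a direct jump from a fitted a² of 0.15–0.2 to a² = 0 otherwise
stalls in a local optimum and inflates the deviance (observed before this
safeguard was added; the inner optimizations use a loosened tolerance since
deviances are only compared at ~1e−3 precision). The likelihood itself is
evaluated from padded, batched sufficient statistics so its cost is
independent of the number of families. All generators and experiments are pure functions of
(arguments, seed); experiment outputs embed a config hash and seed.

## What passing these tests does and does not show

The generator realizes exactly the variance structure the analyses assume:
Gaussian edges, i.i.d. frames, exchangeable sessions, linear behavior
links. Passing therefore demonstrates that the implementations are correct
and that the scan-length mechanisms follow from sampling variance — not that
real fMRI satisfies these assumptions. Autocorrelated BOLD noise (which
lowers the effective T per minute), motion artifacts correlated across
sessions, non-Gaussian edge distributions, and cross-edge correlation of
traits and noise are all outside the generator; the absolute ICC and
heritability values here should be read as qualitative analogues of
published values, not calibrated predictions.

## Known limitations

- Volumetric preprocessing, FD/DVARS computation and parcellation from
  images are out of scope; censor masks and nuisance series are inputs.
- Only ACTE (no dominance, no GxE, no multivariate genetic models); ML, not
  REML, so variance components carry the usual small-sample downward bias.
- Burst (contiguous) censoring and boundary-aware correlation estimators are
  not implemented; censoring is uniform-random frames.
- The spatial-smoothing step of volumetric pipelines does not apply to
  parcel-level series and is omitted.
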