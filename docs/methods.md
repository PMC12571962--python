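# Methods

`emofmri` re-implements, as a reusable and fully tested pipeline, a
Bayesian group analysis of emotion processing in task fMRI: first-level
general linear models for picture-category, rating-modulated, and
psychophysiological-interaction (PPI) effects; parcel-wise median
extraction with covariate adjustment; and Bayes-factor group inference
with a dual-threshold region-selection rule.  Because the original imaging
data are not public, the package ships a synthetic cohort generator that
emulates the study design, and the pipeline's correctness is established
through closed-form anchors, independent numerical oracles, and
operating-characteristic (recovery/calibration) experiments on planted
ground truth.

## Experimental design being modeled

Two groups (patients with early multiple sclerosis or clinically isolated
syndrome, and matched healthy controls; 16 subjects each) view 54
affective pictures — 18 negative, 18 neutral, 18 positive, crossed with 27
low- and 27 high-arousal items.  Each picture is shown for 6 s, followed
by a self-paced rating period of up to 8 s in which valence and arousal
are rated on 9-level SAM scales; successive picture onsets are 10–14 s
apart.  One functional run comprises 470 volumes at TR = 2 s.  Brain
signals are analyzed in 246 atlas parcels; the left and right amygdala
parcels serve as connectivity seeds.

## First-level models

**HRF.** The canonical double-gamma impulse response (peak delay 6 s,
undershoot delay 16 s, unit dispersions, peak:undershoot 6:1, 32 s
support), scaled so its positive lobe sums to one; convolution is carried
out on a microtime grid of 16 bins per TR and sampled at each volume's
middle bin.

**Model 1 (category).** One 6 s boxcar regressor per category (NEG, NEU,
POS) with uniform amplitude, plus one stick regressor per button press,
six motion regressors and a constant (K = 11).  The contrasts
dBR_N = BR_NEG − BR_NEU and dBR_P = BR_POS − BR_NEU are the endpoints.

**Model 2 (parametric).** A mean picture boxcar plus valence- and
arousal-modulated boxcars whose per-trial amplitudes are the subject's
mean-centered ratings.  The two modulators are *not* orthogonalized
against each other; centering is per run.  The endpoints are the slopes of
brain response on rated valence/arousal.

**Model 3 (PPI).** Per seed: the first eigenvariate of the seed parcel
(SVD of the centered time × voxel matrix, sign-aligned with the parcel
mean, rescaled to the mean voxel SD) is deconvolved to a microtime neural
estimate; the estimate is multiplied by centered ±1 psychological vectors
for NEG−NEU and POS−NEU and reconvolved with the HRF.  The design holds
three task regressors, the observed seed eigenvariate, the two PPI
regressors, press sticks, motion, and a constant (K = 14).  dFC, the
connectivity modulation, is the PPI beta.  Forming the interaction at the
neural level before convolution is the defining feature of deconvolution
PPI; the observed (not reconvolved) eigenvariate is used for the seed
column.

**Deconvolution.** Ridge regression on a discrete-cosine basis with one
coefficient per volume: minimize ‖Bz − y‖² + λ·z'Pz, where B is
HRF-convolution-plus-volume-sampling.  The penalty P is zero for basis
frequencies up to the HRF's −3 dB cutoff (≈0.072 Hz) and grows as the
squared excess frequency above it; λ defaults to 10% of the data-term
curvature at the cutoff column.  This band-limited profile keeps the
noise-free deconvolve→reconvolve round trip below 2% relative RMS error on
boxcar designs while still suppressing out-of-band noise; penalizing all
frequencies uniformly (the more common textbook form) degraded the round
trip past 5% and was rejected.

**High-pass filter.** An orthonormal DCT basis spanning frequencies up to
the 1/128 Hz cutoff is projected out of data and design alike.  The basis
extends one frequency step *beyond* the cutoff: a drift at exactly the
cutoff frequency (the generator's default) otherwise leaks 30–80% of its
amplitude through the filter, because a truncated cosine basis cannot
represent an arbitrary-phase sinusoid at its own edge frequency.  With the
extra column the refitted residual drift amplitude stays below 5% for
every phase.

**Noise model.** AR(1) serial correlation with a single coefficient per
parcel, estimated by restricted maximum likelihood jointly over the
parcel's voxels (each voxel keeps its own residual variance), followed by
prewhitening and generalized least squares.  If the ReML optimization
fails, the lag-1 autocorrelation of OLS residuals is used and the fit is
flagged.  Estimates of ρ are mildly attenuated (≈0.05) by the preceding
high-pass projection; this is inherent to filtering and shared by standard
packages.

## Group level

For each endpoint, every subject contributes the median voxel contrast per
parcel.  The 32 × 246 matrix is adjusted for sex, age and depression
severity by pooled least squares *without* a group term (centered
covariates; the intercept is restored), so genuine group differences
survive adjustment.  Each parcel is then tested with a two-sided JZS
independent-samples t-test between groups and four one-sided one-sample
tests (each group × each sign).

**Dual-threshold rule.** A parcel is a *difference* when the
group-difference log10 BF10 > 1.0, a *similarity* when it is < −0.5, and
*undecided* otherwise; difference parcels are *reported* only when at
least one group also shows one-sided main-effect evidence log10 BF > 0.5.
Clause two is evaluated as the maximum over the two directions within each
group.  No multiplicity correction is applied across the 246 parcels; the
evidence thresholds are the only filter, and single-parcel findings should
be read accordingly.  Note a structural limit: with the pooled-variance
JZS test at n = 16 + 16 and prior scale √2/2, the strongest attainable
evidence for the null is log10 BF10 ≈ −0.473 (at t = 0), so the similarity
class is empty at the study's own sample size and only populates for
larger cohorts or wider prior scales.

## Bayes factors

**JZS t-tests.** Cauchy(0, r) prior on the standardized effect
(r = √2/2 by default).  The Bayes factor is computed by adaptive
quadrature of the noncentral-t likelihood over the prior, using the
substitution δ = r·tan θ which turns the Cauchy weight into a constant on
(−π/2, π/2); relative tolerance 1e-8.  One-sided factors truncate and
renormalize the prior, so the prior-splitting identity
BF10 = (BF+0 + BF−0)/2 holds by construction and is verified to 1e-6 over
1000 random datasets.  Two-sample tests from summary statistics use the
pooled-variance Student t, consistent with the equal-variance assumption
of the JZS derivation.

**Binomial test.** Closed form: BF10 = B(k+a, n−k+b) / [B(a, b)·p0^k
(1−p0)^(n−k)] with a uniform Beta(1,1) prior by default; the binomial
coefficient is common to both marginal likelihoods and cancels.

**Contingency tables.** Gunel–Dickey independent-multinomial sampling with
the group margins fixed: each row has its own Dirichlet(a) cell-probability
prior under H1; all rows share a single Dirichlet(a) vector under H0.  The
Bayes factor is a ratio of Dirichlet normalizers, evaluated with log-gamma
functions.

**Correlation.** Stretched-beta prior on ρ (width 1 = uniform on (−1, 1));
the marginal likelihood is integrated numerically through the exact
sampling density of the Pearson r (Gaussian hypergeometric form).

**Repeated-measures ANCOVA inclusion BFs.**  The mixed model
y = μ + subject + category + group + category×group + covariates + ε uses
orthonormal sum-to-zero codes per effect and g-priors
β_e | g_e ~ N(0, σ²g_e I), g_e ~ InvGamma(1/2, r_e²/2), with scales √2/2
for fixed effects, 1 for subject random intercepts and √2/4 for
standardized covariate slopes, and p(μ, σ²) ∝ 1/σ².  Conditional on the
g-scales, all coefficients and (μ, σ²) integrate in closed form (a Woodbury
identity keeps the cost at the total-column dimension), leaving a 5–8
dimensional integral over log g.  That integral is estimated by
importance sampling: a Laplace mode search seeds a multivariate-t proposal
(df 6) which is refined once on a pilot batch of weighted draws before the
final `mcmc_passes` draws (default 5000); the Monte-Carlo SE of each
log-marginal is reported and a low effective sample size flags the result.
This sampler replaces the power-posterior/bridge MCMC sometimes used for
the same estimand because the analytic reduction makes the remaining
integral low-dimensional, where adaptive importance sampling is both
cheaper and easier to audit (a brute-force quadrature oracle on a tiny
two-subject design agrees within the Monte-Carlo error).

The model space is {null, W, B, W+B, W+B+W×B} with equal prior odds — all
additive/interaction models respecting marginality; the null always keeps
the intercept, subject intercepts and covariates.  Inclusion Bayes factors
are posterior over prior inclusion-odds ratios averaged across all models;
a matched-models variant is exposed but off by default.

**Evidence grades.** |log10 BF| ≥ 1.0 is strong (≥10:1), ≥ 0.5 moderate
(≥10^0.5 ≈ 3.16:1), below that anecdotal, with the sign selecting the
favored hypothesis.

## Synthetic cohorts

The generator reproduces the design above exactly (trial counts, timing,
run length, parcel count) and plants three kinds of ground-truth group
effect: `category_amplitude` (extra neural amplitude for one category),
`valence_slope` (per-rating-point amplitude modulation), and `ppi_gain`
(seed-by-condition product added to target parcels at the neural level —
the same structure the PPI estimator assumes).  Seed parcels additionally
carry a smooth intrinsic neural fluctuation (SD 1.0, ≈2 s Gaussian
autocorrelation): connectivity is coupling of stochastic fluctuations, and
without it a planted interaction would be exactly collinear with the task
regressors and unidentifiable for any estimator.

SAM ratings follow an ordinal-probit-style model: latent = category mean
(NEG 2.5 / NEU 5.0 / POS 7.5; arousal LOW 3.5 / HIGH 6.5) + subject offset
(SD 0.5) + Gaussian noise (SD 1.0), rounded and clipped to 1..9.  Patient
category means are shifted 1.5 rating points toward the neutral midpoint
(and high-arousal means 0.5 points downward), emulating the blunted
emotional experience of the patient group.  Voxel noise is AR(1) Gaussian
(innovation SD 1.0, ρ = 0.3, stationary start) plus a sinusoidal drift
(amplitude 1.0, period 128 s, random phase per voxel).  Covariates mimic
the cohort table: age ~ N(30.5, 8.5²) truncated to 18–65, balanced sex,
BDI-2 ~ N(4, 4²) truncated at 0.  Randomness descends from a single root
seed through `SeedSequence` spawning in subject order, so cohorts are
bit-reproducible.

What the generator does **not** emulate: spatial voxel correlation and
smoothing, realistic physiological noise spectra, motion-correlated
artifacts, or the recognition-memory paradigm's internal structure
(recognition performance and speed are plain Gaussian outcome columns).
Passing recovery tests therefore demonstrate the estimators' correctness
under the model's own assumptions, not robustness to every property of
real BOLD data.

## Verification strategy and problem sizes

* Closed-form anchors: the binomial and contingency Bayes factors and the
  four two-sample tests recompute the published cohort-table values from
  the printed inputs.
* Independent oracles: brute-force convolution, Monte-Carlo
  prior-averaging for the quadrature Bayes factors (10^6 draws),
  a dense-quadrature check of the rmANCOVA marginal likelihood on a tiny
  design, SVD identities for the eigenvariate, and an established external
  implementation for the t-test and correlation factors.
* Operating characteristics (chosen to keep the default suite fast while
  leaving the conclusions stable): rmANCOVA null calibration over 200
  simulated cohorts at 1000 importance draws each (median interaction BF
  < 0, < 5% above +0.5) and power over 30 planted-flattening cohorts
  (≥ 80% above +1.0); PPI sign recovery over 100 runs; and one full-scale
  end-to-end pass (32 subjects × 246 parcels × 470 volumes) for both a
  null cohort (≤ 5 false difference verdicts) and a cohort with five
  planted patient-only amplitude effects of 0.8 noise SD (≥ 3 recovered).

## Known limitations

* AR order is fixed at 1 and pooled within parcel; no voxel-wise
  whitening, FIR or derivative HRF bases.
* The deconvolution approximates the empirical-Bayes PPI deconvolution
  with a fixed frequency-weighted ridge; it is not a bit-for-bit
  replication of any particular package.
* Two-sample tests from summaries assume equal variances (pooled t).
* The similarity verdict cannot occur at n = 16/16 with the default prior
  scale (see above); this mirrors a genuine property of the decision rule,
  not an implementation gap.
* Recognition endpoints are generated without category structure, so the
  behavioral ANCOVA is exercised on the rating endpoints only.
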