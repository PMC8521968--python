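# Methods

This note documents the probabilistic model behind `bayespta`, the learning
and inference algorithms, the numerical choices, and the synthetic populations
used for testing — including what those tests do and do not demonstrate about
real audiometric data.

## Model

### Response model

A pure-tone trial presents a stimulus of frequency `f` (Hz) and intensity `h`
(dB-HL) and records a binary response `y ∈ {−1, +1}` (+1 = audible).  The
subject is assumed to compare `h` against their hearing threshold `t` at that
frequency under additive Gaussian perceptual noise:

    P(y | h, t) = Φ( y (h − t) / σ_p ),

a probit psychometric function.  `σ_p` (dB) is a single frequency-independent
scalar.  It cannot be identified from a data set of audiograms (which contain
no individual responses), so it is a configuration parameter; the package
default is **5 dB**, matching the resolution at which clinical audiograms are
recorded.  All simulation results depend quantitatively on this choice.

### Threshold prior

Thresholds are modeled as smooth functions of *perceptual* frequency.  All GP
computation happens on the Bark scale `x = bark(f) = 6 asinh(f/600)`, which is
invertible in closed form; Hz appears only at I/O boundaries.

The population prior is a finite mixture of `C` Gaussian processes:

    c ~ Categorical(α(I)),      t | c ~ GP(m_c, k_c),

where the side information `I` is an optional age (0–120) and gender.  Each
component has a cubic-polynomial mean and a squared-exponential kernel

    m_c(x) = a₀ + a₁u + a₂u² + a₃u³,   u = x − x₀,
    k_c(x, x′) = v_c exp(−(x − x′)² / (2 ℓ_c²)),

with `v_c` in dB² and `ℓ_c` in Bark.  The polynomial is expressed in powers of
the *centered* Bark coordinate (`x₀` = midpoint of the standard audiometric
grid in Bark, ≈ 10.47) so that its coefficients stay well-scaled during
optimization.  The mixture captures the observation that thresholds cluster
into archetypal shapes (flat mild loss, high-frequency sloping loss,
mid-frequency "cookie-bite" loss) whose prevalence varies with age and gender.

α(I) is a lookup table keyed by (5-year age bucket, gender).  Queries resolve
by nearest neighbor: exact-key space for fully specified info (age distance in
buckets; a gender mismatch costs 1000 buckets), an age-marginal table when
only age is given, a gender-marginal table when only gender is given, and the
population-marginal weights when nothing is given.  The marginal tables are
stored explicitly so that partially specified queries are deterministic.

## Learning

On a fixed frequency grid F the GP mixture restricts to an ordinary Gaussian
mixture, so maximum-likelihood fitting proceeds in three steps.

**Step 1 — EM.**  A full-covariance Gaussian mixture is fitted to the
complete-case records on F (scikit-learn's EM, k-means++ initialization, best
of 4 restarts, tolerance 1e-6, ≤500 iterations).  Full covariances are
essential: step 2 must see cross-frequency correlation to identify the kernel.
The covariance floor (`reg_covar`) deserves care on quantized data: audiogram
thresholds are recorded in 5 dB steps, and with a near-zero floor EM reliably
finds higher-likelihood *degenerate* solutions in which one component's
covariance collapses (an eigenvalue → 0) onto the discretization lattice,
destroying the cluster structure.  `fit_model` therefore floors the
covariances at the uniform-quantization variance `step²/12 ≈ 2.08 dB²`.

**Step 2 — KL matching.**  Each fitted Gaussian `N(μ, Σ)` is matched by a GP
component by minimizing `KL(N(μ, Σ) ‖ N(m_θ, K_θ + σ_obs² I))` over the mean
coefficients and kernel hyperparameters.  Choices made here:

* *Direction*: the target leads the KL (mass-covering), so the constrained GP
  cannot ignore regions where the data put mass.
* *Observation noise*: the target covariance was estimated from quantized
  observations, so it contains ~`step²/12` of noise per frequency (plus the EM
  floor) that the smooth SE kernel cannot and should not absorb.  The matching
  covariance is therefore `K_θ + σ_obs² I` with
  `σ_obs² = step²/12 + reg_covar`; the returned component keeps only the SE
  hyperparameters.  Without this term the optimizer shortens the lengthscale
  drastically to cover the nugget, and hyperparameter recovery fails.
* *Optimization*: for fixed hyperparameters the KL is a generalized
  least-squares quadratic in the mean coefficients, which are solved in closed
  form; only (log v, log ℓ) are optimized numerically (L-BFGS-B, gradient
  tolerance 1e-6).  This profiled problem has the same optimum as the joint
  one and is far better conditioned.
* *Jitter symmetry*: SE covariances on the 11-point grid are numerically
  near-singular, so a shared jitter (1e-8 × mean diagonal) is added to both
  target and model; an exact-SE target then has KL exactly 0.

**Step 3 — α table.**  For every record, component responsibilities
`r_c ∝ w_c N(t_obs | m_c, K_c + (step²/12) I)` are computed on the record's
own defined frequencies (missing entries marginalize trivially, so incomplete
records contribute here even though they are dropped in step 1).  The
responsibilities are averaged within each (age-bucket, gender) stratum, and
within each marginal stratum.  Two robustness measures:

* the *observation-noise term* again: without it, quantized records evaluated
  under near-singular GP covariances all collapse onto the component with the
  shortest lengthscale;
* *Dirichlet smoothing*: responsibilities of full audiograms are nearly hard
  assignments, so a thin stratum can store an exact zero for a component that
  merely happened not to occur there — ruinous when the table later weights
  log-densities.  Each stratum average is shrunk toward the marginal weights
  with a pseudo-count of 5 records.  The unsmoothed average remains available
  (`smoothing=0`).

The unconditional α entry is the EM mixture weight vector itself, keeping
steps 1 and 3 consistent at zero side information.

## Inference

Given trials D, per-component inference is a GP probit classifier.  The
posterior over the latent thresholds at the *distinct* trial frequencies
(duplicate-frequency trials share a latent value) is approximated by the
Laplace method: Newton iteration with backtracking finds the mode (log Φ is
concave, so the log-posterior is strictly concave and the mode is global;
convergence at gradient norm < 1e-8, ≤100 iterations, non-convergence raises
an error carrying the last iterate), and the covariance is the inverse
negative Hessian `(K⁻¹ + W)⁻¹`.  Predictions at other frequencies use
standard GP conditioning of the Laplace posterior; with no trials the
posterior is the prior.

The mixture posterior reweights components by their evidence:

    p(t | D) = Σ_c π_c p_c(t | D),    π_c ∝ α_c(I) Z_c,
    Z_c = ∫ p(D | t) p_c(t) dt,

normalized in log space.  **The evidence is computed exactly, not by the
Laplace expansion.**  For a probit likelihood, a trial is audible iff
`t(x) + ε < h` with independent `ε ~ N(0, σ_p²)`, so `Z_c` is a Gaussian
orthant probability under `N(m, K + σ_p² I)` in trial space — closed form for
one trial, and evaluated by Genz quasi-Monte-Carlo (seeded, hence
deterministic) otherwise.  The classical Laplace evidence is also computed
and stored for reference, but its log error at audiometric prior scales
(kernel SD ~8–12 dB against σ_p = 5 dB) was measured at 0.02–0.11 for 1–3
trials — enough to distort early mixing weights, which drive both component
identification and stimulus selection.  The exact value agrees with
tensor-grid quadrature to ~1e-5.

Posterior summaries are closed-form: the predictive response probability is
`Σ_c π_c Φ((h − μ_c)/√(σ_p² + σ_c²))`; the threshold estimate uses the
mixture mean and the law of total variance (computed in the centered form
`Σπσ² + Σπ(μ − mean)²`, which is exact under ties); the predictive score of
a held-out audiogram is the sum over its frequencies of the log *marginal*
mixture density — a per-frequency quantity, not a joint multivariate density.

## Stimulus selection

The next tone maximizes the mutual information between the response and the
threshold (BALD), evaluated in bits:

    I(y; t | x, h) ≈ h(Σ_c π_c Φ((h−μ_c)/√(σ_p²+σ_c²)))
                     − Σ_c π_c (K/√(σ_c²+K²)) exp(−(h−μ_c)²/(2(σ_c²+K²))),

with `K = σ_p √(π ln2 / 2)`.  The second term replaces the binary entropy of
the probit by a squared-exponential function, whose Gaussian convolution is
then exact.  That approximation *underestimates* the entropy pointwise, and
the binary entropy is concave, so the objective is provably non-negative.
The default feasible grid is the 11 standard audiometric frequencies ×
intensities −20…120 dB-HL in 5 dB steps; selection is an exhaustive grid
search (≤ 11×29 cheap evaluations) with ties resolved to the lowest
frequency, then the lowest intensity.  A faster variant first moment-matches
the mixture to a single Gaussian per frequency, picks the frequency with the
largest variance, and sets the intensity to the posterior mean there (snapped
to the grid).

## Synthetic populations

The default population has three prototypes, chosen for the archetypal shapes
above and deliberately separable:

| prototype | mean shape | v (dB²) | ℓ (Bark) |
|---|---|---|---|
| flat-mild | 20 dB at all frequencies | 64 | 6 |
| sloping-old-age | 20 dB at 125 Hz → 70 dB at 8 kHz, linear in Bark | 100 | 4 |
| cookie-bite | quadratic bump peaking ≈50 dB near 1–2 kHz | 64 | 3 |

The sloping prototype's weight grows with age (0.05 + 0.008/year, capped at
0.85; men +0.05 at the flat prototype's expense), the cookie-bite holds a
constant 0.15 share, and the flat prototype takes the remainder.  Ages follow
a clinic-like distribution concentrated around the late 60s; genders are
balanced.  Generated thresholds are drawn on the standard grid and quantized
to 5 dB (round half away from zero).  An optional missingness mask blanks
non-anchor frequencies independently; 250/1000/4000/8000 Hz are never
blanked, so every record keeps ≥4 defined thresholds.

What this emulates: the grid, the 5 dB resolution, cluster structure, and
age/gender-dependent prevalence.  What it does not: real audiograms are not
exact GP draws (asymmetries, notches at single frequencies, measurement
artifacts), prevalences are stylized rather than epidemiological, the two
ears are not correlated, and responses in simulation follow the model's own
probit — so passing tests demonstrate internal correctness and the *relative*
benefits of mixtures, side information, and information-gain selection, not
clinical performance.

## Simulation protocol

A session targets one audiogram: the tabulated thresholds are interpolated
piecewise-linearly in Hz (constant extrapolation outside the defined range),
and the loop select → respond → refit runs for a fixed number of responses
(25 by default).  The simulated subject uses the model's σ_p unless
overridden.  The tracked error is the mean absolute difference between the
posterior mean threshold and the interpolated target over all 11 standard
frequencies, recorded before the first trial and after every response, along
with the mixing-weight trajectory.  The experiment harness crosses models ×
selectors (exhaustive BALD, moment-matched, uniform-random baseline) ×
side-information usage over an audiogram set, pairing all conditions on a
per-audiogram seed.

## Problem sizes and numerical defaults

Default test-scale study conditions: populations of 3000 training / 1000
held-out audiograms for model comparison, 5000 for parameter recovery, 50
paired held-out sessions of 25 trials for protocol comparisons, Monte-Carlo
checks at 10⁶ samples, quadrature oracles at 200 Gauss-Hermite nodes.
Numerical constants: covariance jitter 1e-8×variance; Newton tolerance 1e-8;
KL-matching gradient tolerance 1e-6; evidence QMC with 20 000 points and a
fixed seed; mixing weights normalized by log-sum-exp.

## Known limitations

* σ_p is frequency-independent and fixed; no lapse/corruption model.
* Posterior refits are from scratch at every trial (O(C n³) per step); no
  incremental updates.
* The α table is tabular; it cannot extrapolate trends in age beyond nearest
  neighbor, and needs smoothing in thin strata.
* The Laplace posterior slightly underestimates skewness of the per-component
  posterior after very few trials; only the evidence is computed exactly.
* Absolute error magnitudes in the simulations depend on σ_p and the stimulus
  grid and are not comparable across data sets; only relative comparisons
  (mixture vs single GP, informed vs random selection) transfer.
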