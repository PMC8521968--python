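# bayespta

Bayesian pure-tone audiometry with learnable Gaussian-process mixture priors
and information-optimal tone selection.

Pure-tone audiometry estimates a subject's hearing threshold — the quietest
audible intensity, in dB-HL, as a function of frequency — from a sequence of
"audible"/"inaudible" responses to pure tones.  `bayespta` treats the whole
procedure probabilistically: a population prior over threshold curves, a
probit response model, Bayesian posterior inference after every response, and
greedy expected-information-gain selection of the next tone.  It is intended
for researchers in computational audiology and adaptive psychophysics who
want a complete, testable reference implementation of mixture-prior
audiometry, including model learning from annotated audiogram datasets and a
simulation harness.

## Model

A response `y ∈ {−1, +1}` to a tone of intensity `h` at Bark-transformed
frequency `x = 6 asinh(f/600)` follows a probit psychometric function around
the latent threshold `t(x)`:

    P(y | h, t) = Φ( y (h − t(x)) / σ_p ).

The prior over threshold curves is a mixture of `C` Gaussian processes with
cubic-polynomial means and squared-exponential kernels, with mixing weights
conditioned on optional side information `I` (age, gender):

    c ~ Categorical(α(I)),    t | c ~ GP(m_c, k_c).

After trials `D` the posterior stays a mixture, `p(t|D) = Σ_c π_c p_c(t|D)`,
with `π_c ∝ α_c(I) Z_c`: per-component posteriors come from a Laplace
approximation of the GP probit classifier, and the evidence `Z_c` is computed
exactly as a Gaussian orthant probability.  The next stimulus maximizes the
mutual information between response and threshold (BALD), which is closed
form under the mixture posterior.  Model parameters (`m_c`, `k_c`, `α(I)`)
are learned from audiogram tables by EM on the induced finite-dimensional
Gaussian mixture, KL-matching of GP components, and nearest-neighbor
responsibility tables.  See `docs/methods.md` for the full treatment.

## Worked example

```python
import numpy as np
from bayespta import (
    default_population, generate_dataset, fit_model,
    average_posterior_log_likelihood, run_pta_simulation, StimulusGrid,
)

rng = np.random.default_rng(0)
population = default_population()          # 3 archetypal threshold shapes
train, _ = generate_dataset(population, 3000, rng)
test, _ = generate_dataset(population, 200, rng)

model = fit_model(train, 3, sigma_p=5.0, rng=np.random.default_rng(1))
model_c1 = fit_model(train, 1, sigma_p=5.0, rng=np.random.default_rng(1))

print(average_posterior_log_likelihood(model_c1, test))          # -47.45
print(average_posterior_log_likelihood(model, test))             # -44.75
print(average_posterior_log_likelihood(model, test, use_age=True))  # -44.45

record = test.records[0]                   # age 51, female
trace = run_pta_simulation(model, record, record.info, n_trials=25,
                           grid=StimulusGrid.default(),
                           rng=np.random.default_rng(7))
print([round(e, 1) for e in trace.errors[[0, 5, 10, 25]]])  # [28.0, 7.3, 4.2, 2.5]
print(trace.pi_history[-1].round(3))                        # [0. 1. 0.]
```

The held-out average posterior log-likelihood (sum over the 11 standard
frequencies of the log mixture density) improves from −47.45 with a single GP
to −44.75 with a three-component mixture, and to −44.45 when the prior is
additionally conditioned on the subject's age.  The simulated 25-response
session starts at 28.0 dB mean absolute error under the prior alone and ends
at 2.5 dB; the posterior mixing weights converge onto the single component
that generated the target (here the sloping prototype), which is the
mechanism that lets the mixture beat a single GP.

A command-line interface wraps the same pipeline:

```sh
bayespta generate --default --n 3000 --seed 1 --out audiograms.csv
bayespta fit --audiograms audiograms.csv --components 3 --out model.json
bayespta select --model model.json --age 70          # next most informative tone
bayespta simulate --model c3 model.json --audiograms audiograms.csv \
    --n-trials 25 --selector full --out runs.csv
```

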