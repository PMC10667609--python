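# medaka-ipm

Life-history-to-fitness inference for size-structured fish cohorts.

Warming typically makes ectotherms grow faster early in life but reach a
smaller adult size (the temperature–size rule), while food limitation
lowers fecundity yet often lengthens lifespan. Whether such trait shifts
are adaptive cannot be read off any single trait: it depends on how
growth, survival and reproduction combine into population-level fitness.
This package implements the full inference chain for a 2×2 temperature
(20 °C / 30 °C) × feeding-frequency (continuous / intermittent) medaka
(*Oryzias latipes*) rearing experiment, from tidy per-tank measurement
tables to the asymptotic population growth rate λ and generation time T
of each treatment — together with a synthetic-data generator so every
stage is testable without any experimental download.

It is aimed at population ecologists and biostatisticians who want a
reproducible, fully scriptable version of this analysis, or a tested
scaffold for similar size-structured demographic pipelines.

## The model

**Growth.** Total length follows the Von Bertalanffy curve
L(t) = L∞(1 − e^(−K(t − t₀))), fitted hierarchically by MCMC: four
treatment-level parameter triples with vague Normal priors (precision
0.001), correlated tank-level random effects ε ~ MVN(0, Σ) with uniform
priors on the standard deviations and correlations of Σ, and Normal
observation error σ ~ U(0, 10). Treatment curves are compared by overlap
of their pointwise 95% credibility bands.

**Vital rates.** On the state variable z = log length (mm), per day:
survival s(z) (Kaplan–Meier survival mapped through the fitted age–size
relationship, then a weighted binomial-logistic fit), growth g(z′|z)
(the one-day update L_{t+1} = L_t e^(−K) + L∞(1 − e^(−K)) with a
posterior-propagated residual sd), reproduction probability f_p(z) (a
steep logistic at the size reached at maturity age), daily fecundity
f_n(z) (Poisson regression with log link), egg-to-recruit survival f_g
and a Normal juvenile size distribution f_d.

**Demography.** The kernel K(z′, z) = P + F with P = s·g and
F = f_p·f_n·f_g·ρ·f_d is discretised by the midpoint rule on 400 mesh
cells over [L, U] (predicted 30-day log size to the largest observed
log size). λ is the dominant eigenvalue of K (power iteration), R₀ the
dominant eigenvalue of F(I − P)⁻¹, and T = log R₀ / log λ. Uncertainty
comes from a bootstrap that pairs posterior growth draws with
case-resampled survival and clutch tables and refits every vital rate
per replicate; a finite-difference sensitivity analysis reports
∂λ/∂θ, ∂T/∂θ and elasticities for every scalar vital-rate parameter.

## Worked example

```python
import medaka_ipm as m

result = m.run_pipeline(seed=1, mcmc=m.McmcConfig.test_scale(seed=3), n_mesh=400)
print(result.summary().round(4).to_string(index=False))
```

```
        treatment  lambda       R0        T  converged
  cold_continuous  1.0357 151.2742 143.0738       True
cold_intermittent  1.0375 199.2775 143.8022       True
  warm_continuous  1.0605 151.4320  85.5025       True
warm_intermittent  1.0667 156.7830  78.3417       True
```

Each λ is the per-day population growth factor (λ > 1: growing), R₀ the
expected lifetime recruit production per recruit, T the generation time
in days. The life-history structure encoded in the generator — faster
early growth, earlier maturity and higher mortality in the warm
treatments — transfers to the demography: warming roughly halves the
generation time and raises mean fitness at both feeding levels.

The scripts in `examples/` walk through each capability (simulating a
cohort, fitting and comparing growth curves, building the projection
model, bootstrap intervals, sensitivity analysis); each prints the
numbers it computes with a line on what they mean. The same stages are
available from the shell via the `medaka-ipm` command (see
`medaka-ipm --help`).

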