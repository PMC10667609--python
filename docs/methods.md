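# Methods

This note documents the statistical models, the numerical choices and
the synthetic-data design behind `medaka_ipm`, and what the package's
tests do and do not establish about real experimental data.

## 1. Hierarchical Von Bertalanffy growth model

Observed total lengths L_ftj (fish f, tank t, age j, in mm) follow

    L_ftj ~ Normal(L∞_t (1 − exp(−K_t (j − t0_t))), σ)

with tank-level parameters equal to a treatment-level triple plus a
correlated random effect:

    (L∞_t, K_t, t0_t) = (L∞_CT, K_CT, t0_CT) + ε_t,   ε_t ~ MVN(0, Σ).

Priors: each treatment-level component Normal(0, precision 0.001)
(unconstrained, so negative draws are possible a priori); Σ is assembled
from standard deviations (σ_L∞, σ_K, σ_t0) with Uniform(0, 10) priors
and correlations (r1, r2, r3) with Uniform(−1, 1) priors, subject to
positive definiteness of the correlation matrix (checked via the closed
form det R = 1 + 2 r1 r2 r3 − r1² − r2² − r3² > 0); σ ~ Uniform(0, 10) mm.

### Sampler

The posterior is sampled with an adaptive blockwise random-walk
Metropolis sampler written for this package (`_mcmc.py`). The posterior,
not the sampler, defines the model, and a blockwise scheme has two
practical advantages here: every update block touches only a small part
of the likelihood (cached per-tank sums of squares make treatment, tank
and σ updates cheap), and the chain/retention bookkeeping is exact —
n_chains × n_iterations / thin draws are kept, by construction.

Blocks per sweep: one 3-vector update per treatment, one per tank
random effect, one *translation* move per treatment that shifts the
treatment triple and its tanks' effects in opposite directions (the
likelihood is invariant along this ridge, so the move decorrelates the
hierarchy's location; only the priors enter its acceptance ratio), six
scalar updates for the components of Σ, and one for σ. Step sizes adapt
per chain and per block during burn-in (Robbins–Monro on the log scale,
targets 0.44 scalar / 0.30 vector) and are frozen afterwards. Chains
start from least-squares fits (pooled per treatment; the spread of
per-tank fits initialises the random-effect scales) with multiplicative
jitter. Split-R̂ is computed with arviz for all treatment-level and
variance parameters; any R̂ > 1.1 flags the fit as non-converged with a
warning rather than an exception, since downstream stages remain
well-defined.

Schedules: the reference schedule is 5 chains × 400,000 iterations
after 50,000 burn-in, thinned by 200 (10,000 retained draws). The
desk-scale default used throughout the test suite, the examples and the
acceptance script is 4 chains × 5,000 after 2,000 burn-in, thinned by
10 (2,000 draws); on the default synthetic cohort it converges
(all R̂ ≤ 1.1) and recovers all twelve generating treatment-level
parameters within three posterior standard deviations.

### Curve comparison

Treatment curves are compared pointwise: at each age the 95% credibility
intervals (2.5%/97.5% quantiles of the curve evaluated per retained
draw) either overlap or not; disjoint ages are merged into intervals.
Closed intervals are used, so bands that merely touch count as
overlapping (the conservative reading).

## 2. Vital rates

The IPM state is z = natural log of total length in mm and the time
step is **one day** — the growth recursion advances exactly one unit of
K's time base, clutches are daily counts, and mortality is monitored
daily, so every rate is naturally a per-day quantity.

* **Survival s(z).** Kaplan–Meier from day 60 (lifelines, with
  left-truncation at entry) gives S(t); the default *per_step* mode
  converts to daily survival p_t = S(t)/S(t−1) on the daily grid, maps
  ages to sizes through the fitted growth curve, and fits a binomial
  logistic regression weighted by numbers at risk. A *cumulative* mode
  that regresses S(t) itself on z is retained behind a flag: it is the
  literal reading of fitting "the survival curve", but it conflates
  cumulative with per-step survival and would not compose correctly in
  a daily-step kernel, hence per_step is the prominent default. Fits
  with no information (no deaths, constant p) fall back to a flat curve
  at the observed mean, flagged `degenerate`.
* **Growth g.** Deterministic one-day step
  μ(z) = log(e^z e^{−K} + L∞(1 − e^{−K})) plus Normal residual. The
  residual sd is obtained by propagating every posterior draw through
  the curve and the one-day update at each age, taking the across-draw
  sd of log size at t+1, and averaging over ages 30–350 (ages with
  non-positive predicted lengths are skipped). Computing it on the log
  scale makes it directly the kernel sd on the z-domain; a raw-mm
  option exists.
* **Reproduction probability f_p.** All fish reproduce once past their
  treatment's maturity age; the maturity age is mapped to a size z_mat
  through the fitted curve and f_p(z) = expit(steepness·(z − z_mat)).
  Steepness defaults to 50 per log-length unit — effectively a step
  (the transition spans ~±0.09 log units ≈ ±2 mm at 25 mm) while
  staying differentiable for the sensitivity analysis; it is
  config-exposed.
* **Fecundity f_n.** Poisson regression (log link) of daily egg count
  on log female length, maximum likelihood via statsmodels.
* **Recruits.** f_g (egg hatching × juvenile survival to the 30-day
  recruit stage) and the juvenile log-size Normal (f_d) are inputs, not
  fits — the corresponding data are not part of the measurement tables.
  The egg-and-larval lag is absorbed into f_g: spawning produces
  30-day-sized recruits one step later, with no explicit delay.
* **Sex structure.** A female fraction ρ = 0.5 multiplies recruitment;
  ρ = 1 reproduces an all-female accounting. Config-exposed.

## 3. Integral projection model

n(z′, t+1) = ∫ [P(z′,z) + F(z′,z)] n(z,t) dz with P = s·g and
F = f_p·f_n·f_g·ρ·f_d, discretised by the midpoint rule on n_mesh = 400
uniform cells over [L, U]; L is the predicted log size at 30 days
(recruit size) and U the maximum observed log size, per treatment by
default (a global-U flag exists; at 400 cells λ differences between the
two conventions are far below the bootstrap uncertainty).

**Eviction.** Normal growth mass falling outside [L, U] is returned to
its column by renormalisation (default), so column j of P sums exactly
to s(z_j) — survival is conserved. A *truncate* mode (mass lost, the
literal midpoint rule) is available. If a column's density underflows
entirely (sd_g → 0), the renormalisation limit is a point mass in the
cell containing the deterministic destination; sd_g below 1e−12 is
treated as exactly that point mass.

**λ, R₀, T.** λ, the stable size distribution w and the reproductive
value v come from power iteration (convergence: relative change of the
total-mass ratio below 1e−10 over 50 consecutive steps, config-exposed;
the non-converged case returns the best estimate with a flag). R₀ is
the dominant eigenvalue of F N with N = (I − P)⁻¹ computed via LU
factorisation; the iteration for R₀ reuses the factorisation. T =
log R₀ / log λ. The spectral radius condition ρ(P) < 1 is certified by
the column-sum bound (max column sum of P equals max survival < 1);
power iteration is only invoked for the check if that bound fails.
Exactly at λ = 1 the ratio is indeterminate; the documented fallback
evaluates T with F scaled by (1 ± 1e−6) and averages — a package
choice, since the R₀-based definition has no value there. Mesh
stability: on the default synthetic configuration λ changes by less
than 0.1% between 200 and 800 cells.

## 4. Bootstrap and sensitivity

Each bootstrap replicate draws one (L∞, K, t0) triple from the retained
posterior (with replacement), case-resamples the survival and clutch
tables at the record level (a tank-level block bootstrap is available
behind a flag), refits s, f_p's midpoint, f_n and the growth residual
sd (the latter from a with-replacement subsample of up to 500 posterior
draws), rebuilds the grid (L moves with the sampled parameters, U stays
at the observed maximum) and solves the IPM. Replicates whose refits
degenerate are dropped and counted; more than 10% failures is a hard
error. 95% intervals are percentile (2.5/97.5); treatments are compared
by closed-interval overlap, mirroring the growth-band convention. No
BCa or studentised correction is attempted.

Sensitivities are central finite differences at θ(1 ± δ), δ = 0.01
relative (absolute when θ = 0), over the scalar parameters {survival
intercept/slope, f_p midpoint/steepness, fecundity a/b, f_g, ρ,
juvenile mean/sd, growth residual sd, L∞, K}, with the grid held fixed;
probability parameters pushed outside [0, 1] are clamped and flagged.
Elasticities (θ/λ)∂λ/∂θ are reported alongside. The per-kernel-entry
adjoint formula ∂λ/∂K_ij = v_i w_j/(v·w) serves as an independent test
oracle, not as the reported sensitivity.

## 5. Synthetic experiment design

The generator reproduces the experiment's layout exactly: four
treatments (20/30 °C × continuous/intermittent), tanks 3/3/3 and 2 for
the cold-intermittent treatment, 27 fish per tank (297 fish total),
measurements at days {30, 45, 60, 100, 150, 200, 300, 350} of 12–17
fish per tank (or all survivors), lengths recorded to 0.5 mm after
Normal(0, 1 mm) measurement noise, survival monitored daily from day
60, clutches daily after each treatment's maturity age. Growth tables
are cross-sectional (fish are not individually identified — the curve
belongs to the population); survival records carry ids because the
product-limit estimator needs event times. Clutch rows use a female
reference length from the treatment curve at the observation day (plus
measurement noise), since female identity was not tracked; a per-female
row layout is the default with a tank-day aggregate layout behind a
flag.

Generating values, chosen once as a realistic parameterisation of the
2×2 design and documented here:

| treatment | L∞ (mm) | K (/day) | t0 (d) | maturity (d / mm) | hazard (/day) |
|---|---|---|---|---|---|
| cold, continuous | 32.0 | 0.0100 | −12 | 169.7 / 26.3 | 0.0020 |
| cold, intermittent | 31.0 | 0.0095 | −10 | 186.5 / 25.7 | 0.0015 |
| warm, continuous | 25.0 | 0.0170 | −6 | 67.3 / 16.8 | 0.0040 |
| warm, intermittent | 24.0 | 0.0170 | −5 | 60.0 / 17.2 | 0.0030 |

Maturity ages and lengths are the observed experimental values; the
growth triples are chosen so each curve passes close to its maturity
size, warm curves cross cold ones (faster early growth, smaller
asymptote — the temperature–size rule) and intermittent curves nest
below their continuous counterparts. Mortality is a single constant
daily hazard per treatment from day 60 (the simplest generator whose
Kaplan–Meier estimate is analytically known), higher under warming and
lower under intermittent feeding; negative t0 values give realistic
positive hatch sizes. Random-effect sds (0.8 mm, 8e−4 /day, 2 d) with
common correlation 0.3 produce visible but modest between-tank spread.
Fecundity uses log mean eggs = −3 + 1.5·log length (≈ 5–8 eggs per
female per day at adult sizes), a single size-mediated law across
treatments; 80% of females spawn on a given day. Recruit parameters
default to f_g = 0.2 and juvenile log-size Normal(log 8 mm, 0.15) —
documented constants, as the corresponding data are external to the
measurement tables.

**What the generator does not emulate:** individual growth
trajectories (no fish-level autocorrelation), density dependence,
sex-specific growth or survival, temporal variation in hazards or
fecundity beyond the size trend, non-Poisson clutch overdispersion,
egg-stage dynamics, or husbandry covariates. Passing tests therefore
show that the pipeline recovers the structures it models from data
that contain exactly those structures (plus realistic noise); they do
not certify behaviour under misspecification of these omitted
features.

## 6. Problem sizes and determinism

The test suite and the acceptance script use the desk-scale MCMC
schedule, 400 mesh cells (200/800 for the refinement check), 1000
bootstrap replicates for the bookkeeping check and 200 for the
reported intervals, and a 10-replication scaled-down coverage
experiment at 60 bootstrap replicates — sizes chosen so the whole chain
runs comfortably on a single CPU while keeping every statistical check
meaningful. Every stochastic component (generator, sampler, bootstrap)
is driven by an explicit integer seed and is exactly reproducible;
per-treatment bootstrap streams are derived from the user seed via
`numpy.random.SeedSequence`.

## 7. Known limitations

* The growth-residual sd reflects posterior parameter spread, not
  individual growth variability; with little posterior uncertainty the
  growth kernel approaches a deterministic map. λ is moderately
  sensitive to this spread, which is why the bootstrap refits it per
  replicate.
* The survival logistic inherits any bias in the age→size mapping near
  the entry day, where the curve is steep.
* The λ = 1 generation-time fallback is a numerical stabilisation, not
  a limit theorem; values within 1e−8 of λ = 1 should be interpreted
  with the bootstrap interval in hand.
* Non-convergence of the MCMC is flagged, not fatal; consumers should
  check `PosteriorDraws.converged` before trusting tail quantities.
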