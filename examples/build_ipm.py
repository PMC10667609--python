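"""From raw tables to population fitness: run the whole chain and read
off lambda, R0 and generation time for each treatment.

lambda > 1 means the population grows (lambda is the per-day factor);
R0 is lifetime offspring per recruit; T = log(R0)/log(lambda) is the
generation time in days."""

import medaka_ipm as m

result = m.run_pipeline(seed=1, mcmc=m.McmcConfig.test_scale(seed=3), n_mesh=400)

print(result.summary().round(4).to_string(index=False), "\n")

# warming shortens the generation time and raises mean fitness within
# each feeding level - the life-history structure (faster early growth,
# earlier maturity, higher mortality) transfers through the kernel
for food in ("continuous", "intermittent"):
    warm = result.treatments[f"warm_{food}"].estimates
    cold = result.treatments[f"cold_{food}"].estimates
    print(
        f"{food:12s}: T {cold.T:6.1f} -> {warm.T:6.1f} days under warming; "
        f"lambda {cold.lam:.4f} -> {warm.lam:.4f}"
    )
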