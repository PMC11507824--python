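"""Compare the two marginal families with a nested-sampling Bayes factor.

Each family's evidence integrates its iid likelihood over normal priors
centered on the family's own least-squares fit (sd = 10% of the mean).
ln B = ln e1 - ln e2 is graded on the Jeffreys scale (|ln B| <= 1
inconclusive, then weak / moderate / strong at 2.5 and 5).
"""

from qexon import (
    SyntheticConfig,
    bayes_factor,
    binned_density,
    compute_evidence,
    fit_marginal,
    generate_series,
    priors_from_fit,
)

series, truth = generate_series(SyntheticConfig(seed=0, n=30_000))
density = binned_density(series)
fit_g = fit_marginal(density, "q_gamma")
fit_ig = fit_marginal(density, "inv_q_gamma")

e1 = compute_evidence(series, "q_gamma", seed=0, max_points=1000,
                      priors=priors_from_fit(fit_g.params, "q_gamma"))
e2 = compute_evidence(series, "inv_q_gamma", seed=1, max_points=1000,
                      priors=priors_from_fit(fit_ig.params, "inv_q_gamma"))
cmp_ = bayes_factor(e1, e2)

print(f"ln evidence q-Gamma        : {e1.log_evidence:.2f} +- {e1.log_evidence_err:.3f}")
print(f"ln evidence inverse q-Gamma: {e2.log_evidence:.2f} +- {e2.log_evidence_err:.3f}")
print(f"ln Bayes factor            : {cmp_.ln_B12:.2f} +- {cmp_.ln_B12_err:.3f}")
print(f"Jeffreys grade             : {cmp_.label}")
# Positive ln B favors the q-Gamma; on data generated from a q-Gamma mixture
# the pointwise likelihood separates the families even when their binned
# histograms look alike.
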