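# qexon — superstatistics of exon-length series

`qexon` analyses the ordered exon lengths along a chromosome as a discrete
"time series" l(t) and asks whether their distribution is the stationary
mixture predicted by superstatistics: a system that equilibrates locally on a
fast scale γ⁻¹ while a local intensive parameter ξ (the local mean/variance
scale of exon lengths) drifts on a much slower persistence scale T. It is a
library for genome scientists and statistical physicists studying length
statistics of coding regions; annotation in (GFF3 or a plain series TSV),
per-chromosome reports out.

## The model

With a conditional local law f(l|ξ) and a mixing law p(ξ), the marginal is

```
p(l) = ∫ f(l|ξ) p(ξ) dξ .
```

Two dual cases are implemented exactly:

* **gamma local × inverse-gamma mixing → q-Gamma marginal**

  `p_G(l) = A_G (l/σ)^a exp_q(−l/σ)`, with
  `a = k−1`, `q = 1 + 1/(k+μ)`, `σ = ω(q−1)/k`;

* **inverse-gamma local × gamma mixing → inverse q-Gamma marginal**

  `p_IG(l) = A_IG (l/σ)^(−α−2) exp_q(−σ/l)`, with
  `q = 1 + 1/(α+δ+1)`, `σ = αω/(q−1)`,

where `exp_q(−u) = [1+(q−1)u]^(−1/(q−1))` is the q-exponential and the
entropic index q → 1 recovers the classical gamma / inverse-gamma laws.
Normalizations A are available in closed form, and the mappings are verified
against numerical quadrature of the mixture integral to ≤ 10⁻⁸ relative.

The pipeline per chromosome: series → binned density (linear-box bins of
width 25·i bp) → autocorrelation → double-exponential fit
`C(τ) = a e^(−τ/t1) + b e^(−τ/t2)` giving (t1 ≈ γ⁻¹, t2 ≈ T) → windows of
length T → per-window ξ from the local variance → mixing-law fits →
Levenberg–Marquardt fits of both q-families to the binned density →
nested-sampling evidences and the Bayes factor
`ln B₁₂ = ln ε₁ − ln ε₂`, graded on the Jeffreys scale.

## Worked example

```python
from qexon import (SyntheticConfig, generate_series, autocorrelation,
                   fit_two_exponential, binned_density, fit_marginal)

series, truth = generate_series(SyntheticConfig(seed=0))   # n = 100000
fit = fit_two_exponential(autocorrelation(series, tau_max=800))
print(f"t1 = {fit.t1:.2f}, t2 = {fit.t2:.1f}, ratio = {fit.ratio:.0f}")
# t1 = 1.13, t2 = 73.3, ratio = 65   (generator truth: t1 = 1.3, T = 121)

qfit = fit_marginal(binned_density(series), "q_gamma")
print(f"fitted q = {qfit.params.q:.4f}  (mixture-implied {truth.marginal.q:.4f})")
# fitted q = 1.0843  (mixture-implied 1.0645)
```

The ratio t2/t1 ≫ 10 confirms the timescale separation the mixture
construction assumes, and the fitted entropic index lands within ±0.05 of the
value implied by the generator's local shape and mixing law. The
`examples/` directory has one short script per capability (series
extraction, timescales, local/mixing fits, marginal fits, Bayesian
comparison, full pipeline); each prints the numbers it computes and what they
mean. A thin CLI mirrors the pipeline:
`qexon simulate /tmp/syn.gff3 && qexon chromosome /tmp/syn.gff3 --no-evidence`.

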