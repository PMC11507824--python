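# Methods

## Model and assumptions

The package treats the ordered exon lengths of one chromosome as a discrete
stationary series l(t), t = 1..n, generated by a superstatistical mechanism:
the series is locally equilibrated at a slowly drifting intensive parameter ξ.
Formally, a conditional local law f(l|ξ) with mean ξ holds within stretches of
length ~T (the persistence scale), while serial dependence inside a stretch
relaxes on a much shorter scale t1 = γ⁻¹; the marginal length distribution is
the mixture ∫ f(l|ξ) p(ξ) dξ. The analysis assumes T ≫ t1 (checked via the
fitted ratio, flagged below 10) and positive integer lengths in base pairs.

Two dual local/mixing pairs are supported, both mean-parametrized:

* local gamma with shape k and mean ξ, ξ ~ inverse gamma(μ, ω)
  ⇒ marginal q-Gamma with a = k−1, q = 1+1/(k+μ), σ = ω(q−1)/k;
* local inverse gamma with shape α and mean ξ (finite for α > 0),
  ξ ~ gamma(δ, ω) ⇒ marginal inverse q-Gamma with q = 1+1/(α+δ+1),
  σ = αω/(q−1).

These closed-form mappings were derived by direct integration (both marginals
are generalized beta-prime densities; the CDFs reduce to regularized
incomplete beta functions, which the package uses for exact CDFs and for
bin-averaged model densities). The normalization of the inverse q-Gamma is
A_IG = (q−1)^(α+1) Γ(1/(q−1)) / [σ Γ(α+1) Γ(1/(q−1)−α−1)]; it is the unique
constant making the density integrate to one, and both mappings and
normalizations are validated in the test suite against numerical quadrature
of the mixture integral (≤ 10⁻⁸ relative) rather than trusted.

Validity constraints: σ > 0, q > 1 (q = 1 handled as the exact classical
limit), a > −1 or α > 0, and normalizability 1/(q−1) − shape − 1 > 0. The
q < 1 compact-support regime is out of scope.

## Pipeline stages and parameter conventions

1. **Series construction.** GFF3 (1-based inclusive; length = end−start+1)
   or NCBI-style feature tables, ordered by genomic start with a
   deterministic tie-break (smaller end, then input order). Strand is kept
   for provenance but ignored for ordering. Duplicate isoform-shared
   intervals are kept by default (`dedup` collapses exact duplicates): the
   convention is undocumented in typical upstream analyses, and keeping all
   records is the conservative choice.
2. **Binned density.** "Linear box" bins with width 25·i bp for the i-th
   bin (edges 25·i(i+1)/2 starting at 0), covering the maximum length;
   density = count / (N · width). A uniform-width alternative exists because
   the linear-box wording is ambiguous; the growing-width reading smooths the
   sparse tail while resolving the ~10² bp peak, which is the behaviour the
   method needs.
3. **Timescales.** Biased (1/n) sample autocorrelation (statsmodels, FFT),
   default max lag min(n/10, 2000), fit from lag 1 by least squares to
   a·e^(−τ/t1) + b·e^(−τ/t2) with log-parametrized timescales (positivity),
   a 3×4 multistart grid over initial decades, and the convention t2 ≥ t1.
   A second stage refits restricted to lags where the first-stage model
   exceeds the sampling noise floor 2/√n: with a piecewise-constant ξ the
   slow component decays triangularly rather than exponentially, and
   including long noise-dominated lags biases t2 low by roughly a factor two.
   Ratios t2/t1 < 10 set `scale_separated = False`.
4. **Windows and ξ(t).** Non-overlapping windows of round(T) points,
   trailing remainder dropped. Per window the biased variance v gives
   ξ = 1/v (gamma flavour, units bp⁻²) or ξ = v (inverse-gamma flavour,
   bp²); the free proportionality constant is fixed to 1 because the mixing
   shapes (δ, μ) are scale-invariant — only ω absorbs the constant.
   Zero-variance or sub-4-point windows are skipped, never imputed. Local
   fits are maximum likelihood (scipy, location pinned at 0); a mixing fit
   requires ≥ 20 windows.
5. **Marginal fits.** Levenberg–Marquardt least squares against the binned
   density, default on linear density (log-residual option for tail
   emphasis). Parameters are optimized in an unconstrained transform
   (log σ; shape via log(1+a) or log α; tail index m = 1/(q−1) =
   shape + 1 + e^u) so every iterate is valid by construction, with a
   multistart grid seeded from the data mean. The model value per bin is the
   bin-averaged density from exact CDF differences rather than the pdf at
   the bin center: with steep densities and narrow first bins, center
   evaluation is measurably biased. `A_constrained` (default) enforces the
   closed-form normalization (3 free parameters); `A_free` reproduces the
   four-parameter treatment with A independent.
6. **Evidence and Bayes factor.** Likelihood is the iid product of pointwise
   densities. Priors are independent normals truncated at each parameter's
   hard bound (0 for A, σ, α; −1 for a; 1 for q). The documented default
   table (A_G 6.05×10⁻⁷ ± 7×10⁻⁸, a_G 2.99 ± 0.30, σ_G 12.29 ± 1.23,
   q_G 1.17 ± 0.12; A_IG 3.25×10³ ± 3.25×10², α_IG 0.52 ± 0.05,
   σ_IG 222.67 ± 22.30, q_IG 1.12 ± 0.13) encodes a ~10% relative width
   around values typical of real chromosome-scale exon data;
   `priors_from_fit` applies the same recipe around the chromosome's own LM
   fit, which is what the pipeline uses so the priors match the data scale.
   Default evidence mode is `A_constrained`: with A free and priors that are
   not narrow, the unnormalized-density likelihood is unbounded in the shape
   direction (raising A and the shape together increases every factor), so
   the four-parameter mode is only meaningful with tight priors and is kept
   for parity. ln B₁₂ = ln ε₁ − ln ε₂ with quadrature-summed uncertainty;
   Jeffreys bands at |ln B| = 1, 2.5, 5 with boundaries closed toward
   "inconclusive", and labels name the favored model explicitly.

## Nested sampler

Evidence is computed by a compact nested sampler written for this package:
live points in a unit cube with inverse-CDF prior transforms, deterministic
volume shrinkage X_i = e^(−i/nlive), and likelihood-constrained replacement
by a random walk whose proposal covariance is the live-point sample
covariance (Cholesky-scaled), with an acceptance-targeted step scale.
Termination when the maximum possible remaining contribution falls below
10⁻³ of the accumulated evidence; the final live points are added with
volume X/nlive each. The reported uncertainty is the information-based
estimate √(H/nlive). The sampler is validated against numerical quadrature
on a one-parameter conjugate model (agreement within 3 reported σ across
seeds). Default nlive = 200, walk length max(20, 8·ndim). On long
chromosomes the likelihood uses a seeded subsample (default ≤ 2000 lengths)
to bound cost; the subsample size is recorded in the report.

## Synthetic generator

`generate_series` emulates exactly the structure the analysis assumes:
ξ redrawn per window of T_true points from the mixing law; conditional
lengths with mean ξ; within-series serial dependence by a Gaussian-copula
AR(1) with coefficient e^(−1/t1_true) (rank-preserving, so the marginal is
exact); integer rounding with a floor at 1 bp. Defaults are the study
conditions: gamma local k = 0.5, inverse-gamma mixing μ = 15, ω = 4000 bp
(mean local scale ≈ 285 bp, heavy-tailed lengths peaking near 10² bp),
T_true = 121, t1_true = 1.3, n = 10⁵ — the window and relaxation scales
measured on real chromosome-scale exon series and a local/mixing pair that
implies a constrained q-Gamma marginal with q ≈ 1.0645.

What the generator does **not** emulate: isoform structure and overlapping
transcripts, chromosome-length and GC heterogeneity, annotation errors, and
regime switching at random (rather than fixed-length) boundaries. Passing
tests therefore demonstrate correctness of the estimators under the model's
own assumptions, not that real genomes satisfy those assumptions.

Known small biases, by construction: integer rounding with floor-at-1
shifts the fitted q upward by ~0.02–0.04 at these conditions (visible
because k = 0.5 puts ~6% of the mass below 1.5 bp); the block-constant ξ
makes the slow autocorrelation component triangular, so even the two-stage
fit recovers t2 below T_true by a factor ~1.5; and the Gaussian-copula
transform attenuates the Pearson lag-1 correlation relative to the latent
AR(1), biasing t1 slightly low. The end-to-end tolerances (±0.05 on q,
factor 2 on the timescale ratio) reflect these, and q is intrinsically
weakly identified from binned densities as q → 1 (the families become
indistinguishable from their classical limits).

## Numerical choices

Densities are evaluated in log space (no overflow for extreme q);
q − 1 < 10⁻¹² is treated as the exact classical limit. The quadrature oracle
integrates over log ξ and splits the range at ξ = l to capture both the
mixing bulk and the conditional's peak. Exact marginal CDFs use the beta
representation (betainc), also used by the exact mixture sampler's
goodness-of-fit tests. Chi-square marginal checks on generated integer
series use rounding-aware bin probabilities (CDF at edges −0.5) and a
one-point-per-window subsample so the iid multinomial null applies.

## Reporting

Per-chromosome reports carry every stage's parameters, warnings and
failures, plus provenance (input hash, full config, package version, seed);
identical config + seed reproduces byte-identical numeric fields. Genome
aggregation reports the unweighted mean of fitted q across chromosomes with
its standard error (reported as absent for a single chromosome); failed or
skipped chromosomes are listed, not silently dropped.
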