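import numpy as np
import pytest
from scipy import integrate, stats

from qexon import (
    InvQGammaParams,
    MixingGammaParams,
    MixingInvGammaParams,
    QGammaParams,
    binned_density,
    fit_marginal,
    inv_qgamma_cdf,
    inv_qgamma_pdf,
    invqgamma_from_mixture,
    marginal_pdf_quadrature,
    mixture_from_invqgamma,
    mixture_from_qgamma,
    q_exponential,
    qgamma_cdf,
    qgamma_from_mixture,
    qgamma_pdf,
    sample_marginal,
)
from qexon.errors import ValidationError, ValidityError


class TestQExponential:
    def test_zero_argument(self):
        for q in (1.0, 1.2, 2.0):
            assert q_exponential(0.0, q) == pytest.approx(1.0)

    def test_closed_form_value(self):
        assert q_exponential(-1.0, 1.5) == pytest.approx(1.5 ** -2)

    def test_classical_limit(self):
        assert q_exponential(-2.0, 1 + 1e-8) == pytest.approx(np.exp(-2), abs=1e-6)

    def test_q_below_one_unsupported(self):
        with pytest.raises(ValidityError):
            q_exponential(-1.0, 0.9)

    def test_positive_argument_rejected(self):
        with pytest.raises(ValidationError):
            q_exponential(0.5, 1.2)


VALID_GRID = [(2.0, 50.0, 1.15), (0.5, 200.0, 1.05), (-0.5, 500.0, 1.07),
              (3.0, 12.0, 1.17)]


class TestPdfsAndCdfs:
    @pytest.mark.parametrize("a,sigma,q", VALID_GRID)
    def test_qgamma_normalization(self, a, sigma, q):
        p = QGammaParams.constrained(a, sigma, q)
        val, _ = integrate.quad(lambda l: qgamma_pdf(l, p), 0, np.inf, limit=500)
        assert val == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("alpha,sigma,q", [(0.52, 222.67, 1.12),
                                               (1.2, 400.0, 1.05),
                                               (2.5, 80.0, 1.15)])
    def test_inv_qgamma_normalization(self, alpha, sigma, q):
        p = InvQGammaParams.constrained(alpha, sigma, q)
        val, _ = integrate.quad(lambda l: inv_qgamma_pdf(l, p), 0, np.inf,
                                limit=500)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_cdfs_match_pdf_quadrature(self):
        p = QGammaParams.constrained(1.5, 100.0, 1.1)
        pi = InvQGammaParams.constrained(0.8, 300.0, 1.08)
        for l in (30.0, 300.0, 3000.0):
            c, _ = integrate.quad(lambda x: qgamma_pdf(x, p), 0, l, limit=500)
            assert qgamma_cdf(l, p) == pytest.approx(c, abs=1e-10)
            c, _ = integrate.quad(lambda x: inv_qgamma_pdf(x, pi), 0, l, limit=500)
            assert inv_qgamma_cdf(l, pi) == pytest.approx(c, abs=1e-10)

    def test_normalizability_violation_raises(self):
        # 1/(q-1) - a - 1 = -0.1  for q = 1.5, a = 1.1
        with pytest.raises(ValidityError):
            QGammaParams.constrained(1.1, 50.0, 1.5)

    def test_q_to_one_recovers_classical_families(self):
        l = np.linspace(1, 2000, 400)
        a, sigma = 2.0, 80.0
        sup_prev = np.inf
        for q in (1.05, 1.005, 1.0005):
            p = QGammaParams.constrained(a, sigma, q)
            sup = np.max(np.abs(qgamma_pdf(l, p)
                                - stats.gamma.pdf(l, a + 1, scale=sigma)))
            assert sup < sup_prev
            sup_prev = sup
        assert sup_prev < 1e-5
        sup_prev = np.inf
        alpha = 1.5
        for q in (1.05, 1.005, 1.0005, 1.00005):
            p = InvQGammaParams.constrained(alpha, sigma, q)
            sup = np.max(np.abs(inv_qgamma_pdf(l, p)
                                - stats.invgamma.pdf(l, alpha + 1, scale=sigma)))
            assert sup < sup_prev
            sup_prev = sup
        assert sup_prev < 1e-5

    def test_tail_behavior(self):
        # q-Gamma tail is heavier than the matching classical gamma
        p = QGammaParams.constrained(2.0, 50.0, 1.15)
        l = 5000.0
        assert qgamma_pdf(l, p) > stats.gamma.pdf(l, 3.0, scale=50.0)
        # inverse q-Gamma is eventually decreasing with a power-law tail
        pi = InvQGammaParams.constrained(1.2, 400.0, 1.05)
        ls = np.array([1e5, 1e6, 1e7])
        vals = inv_qgamma_pdf(ls, pi)
        assert np.all(np.diff(vals) < 0)
        slopes = np.diff(np.log(vals)) / np.diff(np.log(ls))
        assert slopes[0] == pytest.approx(slopes[1], abs=0.05)  # power law
        assert slopes[0] == pytest.approx(-(pi.alpha + 2), abs=0.05)


class TestMixtureMapping:
    def test_qgamma_mapping_matches_quadrature(self):
        mixing = MixingInvGammaParams(mu=15.0, omega=4000.0)
        p = qgamma_from_mixture(0.5, mixing)
        l = np.logspace(0, 4.2, 50)
        closed = qgamma_pdf(l, p)
        quad = marginal_pdf_quadrature(l, "gamma", 0.5, mixing)
        assert np.max(np.abs(closed / quad - 1)) < 1e-8

    def test_invqgamma_mapping_matches_quadrature(self):
        mixing = MixingGammaParams(delta=18.0, omega=18.0)
        p = invqgamma_from_mixture(1.2, mixing)
        l = np.logspace(0, 4.2, 50)
        closed = inv_qgamma_pdf(l, p)
        quad = marginal_pdf_quadrature(l, "inverse_gamma", 1.2, mixing)
        assert np.max(np.abs(closed / quad - 1)) < 1e-8

    def test_mixing_shape_to_infinity_recovers_local_family(self):
        # inverse-gamma mixing with huge shape concentrates at its mean
        k, mean_xi = 1.5, 300.0
        l = np.linspace(1, 3000, 300)
        target = stats.gamma.pdf(l, k, scale=mean_xi / k)
        sup_prev = np.inf
        for mu in (50.0, 500.0, 5000.0):
            p = qgamma_from_mixture(k, MixingInvGammaParams(mu=mu,
                                                            omega=(mu - 1) * mean_xi))
            sup = np.max(np.abs(qgamma_pdf(l, p) - target))
            assert sup < sup_prev
            sup_prev = sup
        assert p.q == pytest.approx(1.0, abs=1e-3)

    def test_mapping_round_trip(self):
        p = QGammaParams.constrained(1.2, 90.0, 1.12)
        k, mixing = mixture_from_qgamma(p)
        p2 = qgamma_from_mixture(k, mixing)
        assert (p2.a, p2.sigma, p2.q) == pytest.approx((p.a, p.sigma, p.q))
        pi = InvQGammaParams.constrained(0.7, 250.0, 1.09)
        alpha, mixing = mixture_from_invqgamma(pi)
        pi2 = invqgamma_from_mixture(alpha, mixing)
        assert (pi2.alpha, pi2.sigma, pi2.q) == pytest.approx(
            (pi.alpha, pi.sigma, pi.q))


class TestSampler:
    def test_reproducible(self):
        p = QGammaParams.constrained(2.0, 50.0, 1.15)
        a = sample_marginal(p, 1000, seed=9)
        b = sample_marginal(p, 1000, seed=9)
        assert np.array_equal(a, b)

    def test_zero_draws_rejected(self):
        p = QGammaParams.constrained(2.0, 50.0, 1.15)
        with pytest.raises(ValidationError):
            sample_marginal(p, 0, seed=1)

    def test_qgamma_sample_matches_analytic_cdf(self):
        p = QGammaParams.constrained(2.0, 50.0, 1.17)
        x = sample_marginal(p, 100_000, seed=21)
        res = stats.kstest(x, lambda v: qgamma_cdf(v, p))
        assert res.pvalue > 0.01

    def test_inv_qgamma_sample_matches_analytic_cdf(self):
        p = InvQGammaParams.constrained(0.52, 222.67, 1.10)
        x = sample_marginal(p, 100_000, seed=22)
        res = stats.kstest(x, lambda v: inv_qgamma_cdf(v, p))
        assert res.pvalue > 0.01


class TestFitMarginal:
    def test_qgamma_recovery(self):
        p = QGammaParams.constrained(2.0, 50.0, 1.17)
        x = sample_marginal(p, 100_000, seed=30)
        fit = fit_marginal(binned_density(x), "q_gamma")
        assert fit.params.q == pytest.approx(1.17, abs=0.02)
        assert fit.mode == "A_constrained"

    def test_inv_qgamma_recovery(self):
        p = InvQGammaParams.constrained(0.52, 222.67, 1.10)
        x = sample_marginal(p, 100_000, seed=31)
        fit = fit_marginal(binned_density(x), "inv_q_gamma")
        assert fit.params.q == pytest.approx(1.10, abs=0.02)

    def test_a_free_mode_recovers_amplitude(self):
        p = QGammaParams.constrained(2.0, 50.0, 1.17)
        x = sample_marginal(p, 100_000, seed=32)
        fit = fit_marginal(binned_density(x), "q_gamma", mode="A_free")
        assert fit.params.A == pytest.approx(p.A, rel=0.15)
        assert fit.params.q == pytest.approx(1.17, abs=0.05)

    def test_log_residuals_mode(self):
        p = QGammaParams.constrained(2.0, 50.0, 1.17)
        x = sample_marginal(p, 100_000, seed=33)
        fit = fit_marginal(binned_density(x), "q_gamma", residual_scale="log")
        assert fit.params.q == pytest.approx(1.17, abs=0.03)

    def test_too_few_occupied_bins(self):
        d = binned_density(np.array([10.0, 30.0, 30.0, 80.0]))
        with pytest.raises(ValidationError):
            fit_marginal(d, "q_gamma")
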