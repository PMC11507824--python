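import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from qexon import (
    QGammaParams,
    bayes_factor,
    compute_evidence,
    default_priors,
    jeffreys_label,
    log_likelihood,
    priors_from_fit,
    sample_marginal,
)
from qexon.bayes_compare import PriorParam, PriorSpec
from qexon.errors import EmptyInputError, ValidationError
from qexon.nested import nested_sample
from qexon.qdistributions import qgamma_logpdf


class TestPriors:
    def test_documented_default_values(self):
        g = default_priors("q_gamma")
        means = {p.name: (p.mean, p.sd) for p in g.params}
        assert means == {"A": (6.05e-7, 7e-8), "a": (2.99, 0.30),
                         "sigma": (12.29, 1.23), "q": (1.17, 0.12)}
        ig = default_priors("inv_q_gamma")
        means = {p.name: (p.mean, p.sd) for p in ig.params}
        assert means == {"A": (3.25e3, 3.25e2), "alpha": (0.52, 0.05),
                         "sigma": (222.67, 22.30), "q": (1.12, 0.13)}

    def test_transform_respects_truncation(self):
        pri = PriorSpec((PriorParam("x", 1.0, 5.0, lower=0.0),))
        u = np.linspace(1e-6, 1 - 1e-6, 101)
        vals = np.array([pri.transform(np.array([ui]))[0] for ui in u])
        assert np.all(vals > 0)
        assert np.all(np.diff(vals) > 0)

    def test_priors_from_fit_centers_on_fit(self):
        p = QGammaParams.constrained(-0.5, 500.0, 1.06)
        pri = priors_from_fit(p, "q_gamma")
        byname = {pp.name: pp for pp in pri.params}
        assert byname["a"].mean == pytest.approx(-0.5)
        assert byname["a"].lower == -1.0
        assert byname["q"].lower == 1.0
        assert byname["sigma"].sd == pytest.approx(50.0)


class TestLogLikelihood:
    def test_single_point_equals_logpdf(self):
        p = QGammaParams.constrained(2.0, 50.0, 1.15)
        x = np.array([123.0])
        assert log_likelihood(x, "q_gamma", p) == pytest.approx(
            float(qgamma_logpdf(123.0, p)))

    def test_concatenation_adds(self):
        p = QGammaParams.constrained(2.0, 50.0, 1.15)
        a = sample_marginal(p, 100, seed=1)
        b = sample_marginal(p, 150, seed=2)
        assert log_likelihood(np.concatenate([a, b]), "q_gamma", p) == \
            pytest.approx(log_likelihood(a, "q_gamma", p)
                          + log_likelihood(b, "q_gamma", p))

    def test_truth_beats_perturbation(self):
        p = QGammaParams.constrained(2.0, 50.0, 1.15)
        worse = QGammaParams.constrained(2.0, 65.0, 1.15)
        wins = 0
        for seed in range(100):
            x = sample_marginal(p, 1000, seed=1000 + seed)
            wins += (log_likelihood(x, "q_gamma", p)
                     > log_likelihood(x, "q_gamma", worse))
        assert wins >= 99

    def test_empty_data(self):
        p = QGammaParams.constrained(2.0, 50.0, 1.15)
        with pytest.raises(EmptyInputError):
            log_likelihood(np.array([]), "q_gamma", p)


class TestJeffreys:
    @pytest.mark.parametrize("lnb,expect", [
        (-0.065, "Inconclusive"),
        (-1.0, "Inconclusive"),
        (1.0, "Inconclusive"),
        (5.0001, "Strong evidence for q-Gamma"),
        (2.0, "Weak evidence for q-Gamma"),
        (-3.0, "Moderate evidence for inverse q-Gamma"),
        (-7.0, "Strong evidence for inverse q-Gamma"),
    ])
    def test_bands(self, lnb, expect):
        assert jeffreys_label(lnb) == expect

    @settings(deadline=None, max_examples=50)
    @given(st.floats(-20, 20, allow_nan=False))
    def test_antisymmetry(self, lnb):
        fwd = jeffreys_label(lnb, "M1", "M2")
        rev = jeffreys_label(-lnb, "M2", "M1")
        assert fwd == rev


class TestBayesFactor:
    def test_difference_of_log_evidences(self):
        cmp_ = bayes_factor(-0.085, -0.020, err1=0.019, err2=0.010)
        assert cmp_.ln_B12 == pytest.approx(-0.065)
        assert cmp_.ln_B12_err == pytest.approx(np.hypot(0.019, 0.010))
        assert cmp_.ln_B12_err == pytest.approx(0.0215, abs=5e-4)
        assert cmp_.label == "Inconclusive"

    def test_equal_evidence_is_inconclusive(self):
        cmp_ = bayes_factor(-3.0, -3.0)
        assert cmp_.ln_B12 == 0.0
        assert cmp_.label == "Inconclusive"

    def test_swap_antisymmetry(self):
        cmp_ = bayes_factor(1.4, -0.3, err1=0.1, err2=0.2)
        sw = cmp_.swapped()
        assert sw.ln_B12 == -cmp_.ln_B12
        assert sw.ln_B12_err == cmp_.ln_B12_err

    def test_requires_finite(self):
        with pytest.raises(ValidationError):
            bayes_factor(-np.inf, 0.0)


def _conjugate_toy():
    rng = np.random.default_rng(1)
    y = rng.exponential(2.0, size=50)
    pri = PriorSpec((PriorParam("theta", 2.0, 0.5),))

    def loglike(th):
        t = th[0]
        return float(-y.size * np.log(t) - y.sum() / t)

    a = (0 - 2.0) / 0.5

    def integrand(t):
        return np.exp(-y.size * np.log(t) - y.sum() / t) * \
            stats.truncnorm.pdf(t, a, np.inf, loc=2, scale=0.5)

    lnz_true = np.log(integrate.quad(integrand, 1e-6, 12, limit=400)[0])
    return loglike, pri, lnz_true


class TestEvidence:
    def test_toy_matches_quadrature(self):
        loglike, pri, lnz_true = _conjugate_toy()
        r = nested_sample(loglike, pri.transform, 1, nlive=200, seed=0)
        assert abs(r.logz - lnz_true) < 3 * r.logzerr

    def test_seed_to_seed_consistency(self):
        loglike, pri, _ = _conjugate_toy()
        r1 = nested_sample(loglike, pri.transform, 1, nlive=200, seed=1)
        r2 = nested_sample(loglike, pri.transform, 1, nlive=200, seed=2)
        assert abs(r1.logz - r2.logz) < 3 * np.hypot(r1.logzerr, r2.logzerr)

    def test_compute_evidence_reports_settings(self):
        p = QGammaParams.constrained(2.0, 50.0, 1.15)
        x = sample_marginal(p, 400, seed=5)
        pri = priors_from_fit(p, "q_gamma")
        e = compute_evidence(x, "q_gamma", priors=pri, nlive=100, seed=0)
        assert e.log_evidence_err >= 0
        assert e.sampler_settings["mode"] == "A_constrained"
        assert e.n_likelihood_calls > 0

    def test_empty_data_rejected(self):
        with pytest.raises(EmptyInputError):
            compute_evidence(np.array([]), "q_gamma")
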