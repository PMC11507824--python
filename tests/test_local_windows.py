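import numpy as np
import pytest
from scipy import stats

from qexon import (
    ExonSeries,
    LocalGammaParams,
    LocalInvGammaParams,
    MixingGammaParams,
    MixingInvGammaParams,
    XiSeries,
    fit_local,
    fit_mixing,
    segment,
    xi_series,
)
from qexon.errors import InsufficientDataError, SkipWindow, ValidationError, WindowError


class TestSegment:
    def test_window_arithmetic(self):
        s = ExonSeries("c", np.arange(1, 1001))
        windows = segment(s, 121)
        assert len(windows) == 8
        assert all(w.lengths.size == 121 for w in windows)
        assert windows[0].start == 1 and windows[1].start == 122

    def test_exact_fit_single_window(self):
        s = ExonSeries("c", np.arange(1, 122))
        assert len(segment(s, 121)) == 1

    @pytest.mark.parametrize("T", [0, 1, 2000])
    def test_bad_window_sizes(self, T):
        s = ExonSeries("c", np.arange(1, 1001))
        with pytest.raises(WindowError):
            segment(s, T)


class TestFitLocal:
    def test_gamma_mle_recovery(self):
        x = stats.gamma.rvs(0.5, scale=700 / 0.5, size=100_000,
                            random_state=np.random.default_rng(10))
        p = fit_local(x, "gamma")
        assert p.k == pytest.approx(0.5, abs=0.02)
        assert p.xi == pytest.approx(700.0, rel=0.02)

    def test_inverse_gamma_mle_recovery(self):
        x = stats.invgamma.rvs(2.2, scale=1.2 * 260, size=100_000,
                               random_state=np.random.default_rng(11))
        p = fit_local(x, "inverse_gamma")
        assert p.alpha == pytest.approx(1.2, abs=0.05)
        assert p.xi == pytest.approx(260.0, rel=0.03)

    def test_mean_parametrization(self):
        # for the gamma family the MLE of xi is exactly the sample mean
        x = stats.gamma.rvs(1.5, scale=100, size=50_000,
                            random_state=np.random.default_rng(12))
        p = fit_local(x, "gamma")
        assert p.xi == pytest.approx(float(np.mean(x)), rel=1e-6)

    def test_constant_window_skipped(self):
        with pytest.raises(SkipWindow):
            fit_local(np.full(10, 5.0), "gamma")

    def test_tiny_window_skipped(self):
        with pytest.raises(SkipWindow):
            fit_local(np.array([1.0, 2.0, 3.0]), "gamma")


class TestXiSeries:
    def test_two_point_window_example(self):
        s = ExonSeries("c", np.array([10, 14]))
        g = xi_series(s, 2, "gamma")
        ig = xi_series(s, 2, "inverse_gamma")
        assert g.xi_values[0] == pytest.approx(0.25)
        assert ig.xi_values[0] == pytest.approx(4.0)

    def test_flavors_are_reciprocal(self, rng):
        s = ExonSeries("c", rng.integers(1, 1000, size=2000))
        g = xi_series(s, 50, "gamma")
        ig = xi_series(s, 50, "inverse_gamma")
        assert np.allclose(g.xi_values * ig.xi_values, 1.0)

    def test_variance_shrinks_with_window_size(self):
        x = stats.gamma.rvs(2.0, scale=100, size=120_000,
                            random_state=np.random.default_rng(13))
        s = ExonSeries("c", np.maximum(1, np.rint(x)))
        v_small = np.var(np.log(xi_series(s, 50, "gamma").xi_values))
        v_large = np.var(np.log(xi_series(s, 400, "gamma").xi_values))
        assert v_large < v_small

    def test_two_regime_series_is_bimodal(self):
        g = np.random.default_rng(14)
        lo = g.normal(100, 2, size=5000)
        hi = g.normal(100, 60, size=5000)
        s = ExonSeries("c", np.maximum(1, np.rint(np.concatenate([lo, hi]))))
        xi = xi_series(s, 100, "inverse_gamma")
        logxi = np.sort(np.log(xi.xi_values))
        gaps = np.diff(logxi)
        # the two variance regimes leave a gap much larger than typical spacing
        assert gaps.max() > 10 * np.median(gaps)


class TestFitMixing:
    def test_gamma_mixing_recovery(self):
        vals = stats.gamma.rvs(18.0, scale=18.0, size=10_000,
                               random_state=np.random.default_rng(15))
        xi = XiSeries(np.arange(vals.size), vals, "inverse_gamma")
        p = fit_mixing(xi, "gamma")
        assert p.delta == pytest.approx(18.0, rel=0.05)
        assert p.omega == pytest.approx(18.0, rel=0.05)

    def test_inverse_gamma_mixing_recovery(self):
        vals = stats.invgamma.rvs(15.0, scale=4000.0, size=10_000,
                                  random_state=np.random.default_rng(16))
        xi = XiSeries(np.arange(vals.size), vals, "gamma")
        p = fit_mixing(xi, "inverse_gamma")
        assert p.mu == pytest.approx(15.0, rel=0.05)
        assert p.omega == pytest.approx(4000.0, rel=0.05)

    def test_too_few_windows(self):
        xi = XiSeries(np.arange(5), np.ones(5) * 2.0, "gamma")
        with pytest.raises(InsufficientDataError):
            fit_mixing(xi, "gamma")


class TestParamValidation:
    @pytest.mark.parametrize("cls,kwargs", [
        (LocalGammaParams, dict(k=-1, xi=10)),
        (LocalInvGammaParams, dict(alpha=0, xi=10)),
        (MixingGammaParams, dict(delta=1, omega=0)),
        (MixingInvGammaParams, dict(mu=-2, omega=5)),
    ])
    def test_positivity(self, cls, kwargs):
        with pytest.raises(ValidationError):
            cls(**kwargs)

    def test_local_mean_matches_xi(self):
        assert LocalGammaParams(k=0.7, xi=300).dist().mean() == pytest.approx(300)
        assert LocalInvGammaParams(alpha=1.5, xi=200).dist().mean() == pytest.approx(200)
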