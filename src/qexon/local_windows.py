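"""Windowing at the persistence scale T, local fits and the xi(t) series.

Within a window of length ~T the series is treated as locally equilibrated:
lengths follow either a gamma law with shape k and mean xi,

    f_G(l) = (k/xi)^k l^(k-1) exp(-k l / xi) / Gamma(k),

or an inverse-gamma law with shape alpha and mean xi,

    f_IG(l) = (alpha xi)^(alpha+1) l^(-alpha-2) exp(-alpha xi / l) / Gamma(alpha+1).

The slowly varying intensive parameter xi(t) is tracked per window through the
local variance v = <l^2> - <l>^2: the gamma flavour uses xi = 1/v, the
inverse-gamma flavour xi = v (proportionality constant fixed to 1; the shape
of the mixing law is invariant under rescaling of xi, only its scale omega
absorbs the constant).  Across windows xi is then itself modelled by a gamma
mixing law p(xi; delta, omega) or an inverse-gamma mixing law p(xi; mu, omega).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .annotation_io import ExonSeries
from .errors import (
    InsufficientDataError,
    SkipWindow,
    ValidationError,
    WindowError,
)

__all__ = [
    "LocalGammaParams",
    "LocalInvGammaParams",
    "XiSeries",
    "MixingGammaParams",
    "MixingInvGammaParams",
    "Window",
    "segment",
    "fit_local",
    "xi_series",
    "fit_mixing",
]


@dataclass(frozen=True)
class LocalGammaParams:
    """Gamma local law: shape k, mean xi (bp)."""

    k: float
    xi: float

    def __post_init__(self):
        if not (self.k > 0 and self.xi > 0):
            raise ValidationError("local gamma requires k > 0 and xi > 0")

    def dist(self):
        return stats.gamma(self.k, scale=self.xi / self.k)


@dataclass(frozen=True)
class LocalInvGammaParams:
    """Inverse-gamma local law: shape alpha, mean xi (bp)."""

    alpha: float
    xi: float

    def __post_init__(self):
        if not (self.alpha > 0 and self.xi > 0):
            raise ValidationError("local inverse gamma requires alpha > 0, xi > 0")

    def dist(self):
        # shape alpha+1, scale alpha*xi  =>  mean = alpha*xi / alpha = xi
        return stats.invgamma(self.alpha + 1.0, scale=self.alpha * self.xi)


@dataclass(frozen=True)
class MixingGammaParams:
    """Gamma mixing law for xi: shape delta, scale omega."""

    delta: float
    omega: float

    def __post_init__(self):
        if not (self.delta > 0 and self.omega > 0):
            raise ValidationError("mixing gamma requires delta > 0, omega > 0")

    def dist(self):
        return stats.gamma(self.delta, scale=self.omega)


@dataclass(frozen=True)
class MixingInvGammaParams:
    """Inverse-gamma mixing law for xi: shape mu, scale omega."""

    mu: float
    omega: float

    def __post_init__(self):
        if not (self.mu > 0 and self.omega > 0):
            raise ValidationError("mixing inverse gamma requires mu > 0, omega > 0")

    def dist(self):
        return stats.invgamma(self.mu, scale=self.omega)


@dataclass(frozen=True)
class Window:
    start: int           # 1-based index of the first element
    lengths: np.ndarray


@dataclass(frozen=True)
class XiSeries:
    """Per-window xi estimates for one local family.

    Units: 1/bp^2 for the gamma flavour (xi = 1/variance), bp^2 for the
    inverse-gamma flavour (xi = variance).
    """

    window_starts: np.ndarray
    xi_values: np.ndarray
    family: str  # "gamma" | "inverse_gamma"

    def __post_init__(self):
        if self.family not in ("gamma", "inverse_gamma"):
            raise ValidationError(f"unknown family {self.family!r}")
        if np.any(np.asarray(self.xi_values) <= 0):
            raise ValidationError("xi values must be positive")

    @property
    def n_windows(self) -> int:
        return int(len(self.xi_values))


def segment(series: ExonSeries | np.ndarray, T: float) -> list[Window]:
    """Split into consecutive non-overlapping windows of length round(T).

    The trailing remainder shorter than round(T) is discarded.
    """
    x = series.lengths if isinstance(series, ExonSeries) else np.asarray(series)
    w = int(round(float(T)))
    if w < 2:
        raise WindowError(f"window size round(T)={w} must be >= 2")
    n = x.size
    if w > n:
        raise WindowError(f"window size {w} exceeds series length {n}")
    k = n // w
    return [Window(start=i * w + 1, lengths=x[i * w:(i + 1) * w]) for i in range(k)]


def fit_local(window: np.ndarray | Window, family: str):
    """Maximum-likelihood fit of the local gamma / inverse-gamma law.

    Both families are mean-parametrized: the returned ``xi`` is the
    distribution mean.  Degenerate windows (size < 4, zero variance,
    or an inverse-gamma fit with infinite mean) raise :class:`SkipWindow`.
    """
    x = np.asarray(window.lengths if isinstance(window, Window) else window, float)
    if x.size < 4:
        raise SkipWindow(f"window size {x.size} < 4")
    if np.any(x <= 0):
        raise ValidationError("lengths must be positive")
    if np.var(x) == 0:
        raise SkipWindow("zero-variance window")
    if family == "gamma":
        k, _loc, scale = stats.gamma.fit(x, floc=0)
        return LocalGammaParams(k=float(k), xi=float(k * scale))
    if family == "inverse_gamma":
        shape, _loc, scale = stats.invgamma.fit(x, floc=0)
        alpha = shape - 1.0
        if alpha <= 0:
            raise SkipWindow("inverse-gamma fit has no finite mean (shape <= 1)")
        return LocalInvGammaParams(alpha=float(alpha), xi=float(scale / alpha))
    raise ValidationError(f"unknown family {family!r}")


def xi_series(series: ExonSeries | np.ndarray, T: float, family: str) -> XiSeries:
    """Per-window local-variance xi(t) under the chosen family.

    gamma flavour: xi = 1/v; inverse-gamma flavour: xi = v, where v is the
    biased sample variance of the window.  Zero-variance windows are skipped.
    """
    if family not in ("gamma", "inverse_gamma"):
        raise ValidationError(f"unknown family {family!r}")
    starts, xis = [], []
    for w in segment(series, T):
        v = float(np.var(w.lengths.astype(float)))
        if v == 0.0:
            continue
        starts.append(w.start)
        xis.append(1.0 / v if family == "gamma" else v)
    if not xis:
        raise InsufficientDataError("all windows degenerate")
    return XiSeries(window_starts=np.array(starts), xi_values=np.array(xis),
                    family=family)


#: minimum number of windows for a mixing-law fit.
MIN_MIXING_WINDOWS = 20


def fit_mixing(xi: XiSeries, family: str):
    """Maximum-likelihood fit of the mixing law to the per-window xi values.

    ``family`` is the mixing family: ``gamma`` -> (delta, omega) law,
    ``inverse_gamma`` -> (mu, omega) law.
    """
    vals = np.asarray(xi.xi_values, float)
    if vals.size < MIN_MIXING_WINDOWS:
        raise InsufficientDataError(
            f"{vals.size} windows < required {MIN_MIXING_WINDOWS}")
    if family == "gamma":
        delta, _loc, omega = stats.gamma.fit(vals, floc=0)
        return MixingGammaParams(delta=float(delta), omega=float(omega))
    if family == "inverse_gamma":
        mu, _loc, omega = stats.invgamma.fit(vals, floc=0)
        return MixingInvGammaParams(mu=float(mu), omega=float(omega))
    raise ValidationError(f"unknown family {family!r}")
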