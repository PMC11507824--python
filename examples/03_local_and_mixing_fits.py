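"""Window the series at scale T, estimate xi(t) and fit the mixing law.

Within windows of length T the series is locally stationary; the local
variance v gives the intensive parameter xi per window (gamma flavour
xi = 1/v, inverse-gamma flavour xi = v).  Across windows xi fluctuates, and
its distribution is fit by an inverse-gamma (for the gamma flavour) or gamma
(for the inverse-gamma flavour) mixing law.
"""

from qexon import SyntheticConfig, fit_local, fit_mixing, generate_series, segment, xi_series

series, truth = generate_series(SyntheticConfig(seed=0))
T = truth.config.T_true

window = segment(series, T)[0]
local = fit_local(window, "gamma")
print(f"first window local gamma fit: k = {local.k:.3f}, xi = {local.xi:.1f} bp")

xi = xi_series(series, T, "gamma")
print(f"windows with usable variance: {xi.n_windows}")

mixing = fit_mixing(xi, "inverse_gamma")
print(f"mixing law for xi (inverse gamma): mu = {mixing.mu:.2f}, "
      f"omega = {mixing.omega:.3g}")
# mu is the shape of the fluctuation law of 1/variance across windows; its
# scale omega absorbs the flavour's units (1/bp^2 here).
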