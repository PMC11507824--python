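"""A compact nested sampler for Bayesian evidence estimation.

Implements the classic scheme: ``nlive`` live points are drawn from the prior
(via a unit-cube prior transform, as in modern nested-sampling packages); at
each iteration the worst live point is replaced by a new prior draw subject to
the hard likelihood constraint L > L*, obtained by a random walk in the unit
cube started from a randomly chosen surviving live point.  Prior volumes
shrink deterministically, X_i = exp(-i / nlive); the evidence accumulates as

    Z = sum_i (X_{i-1} - X_i) * L_i  +  (final live-point contribution)

and the reported uncertainty is the information-based estimate
sqrt(H / nlive) on ln Z.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import EvidenceError

__all__ = ["NestedResult", "nested_sample"]


@dataclass(frozen=True)
class NestedResult:
    logz: float
    logzerr: float
    h: float                       # information (nats)
    niter: int
    ncall: int
    nlive: int
    settings: dict = field(default_factory=dict)


def _logaddexp(a, b):
    return np.logaddexp(a, b)


def _constrained_step(u0, logl0, loglike_u, lstar, rng, scale, nsteps, chol):
    """Random walk in the unit cube under the constraint L > L*.

    Proposals follow the live-point covariance (Cholesky factor ``chol``) so
    the walk tracks the shrinking, generally anisotropic constrained region.
    """
    u, logl = u0.copy(), logl0
    naccept = ncall = 0
    for _ in range(nsteps):
        prop = u + scale * (chol @ rng.standard_normal(u.size))
        prop = np.abs(prop)                      # reflect at 0
        prop = np.where(prop > 1.0, 2.0 - prop, prop)  # reflect at 1
        prop = np.clip(prop, 1e-12, 1.0 - 1e-12)
        ll = loglike_u(prop)
        ncall += 1
        if ll > lstar:
            u, logl = prop, ll
            naccept += 1
    return u, logl, naccept, ncall


def _live_cholesky(u_live):
    """Cholesky factor of the live-point covariance (regularized)."""
    cov = np.cov(u_live, rowvar=False)
    cov = np.atleast_2d(cov)
    d = cov.shape[0]
    cov += np.eye(d) * (1e-10 + 1e-4 * np.trace(cov) / d)
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:  # pragma: no cover
        return np.diag(np.sqrt(np.maximum(np.diag(cov), 1e-12)))


def nested_sample(
    loglike: Callable[[np.ndarray], float],
    prior_transform: Callable[[np.ndarray], np.ndarray],
    ndim: int,
    nlive: int = 400,
    seed: int = 0,
    frac_remain: float = 1e-3,
    max_iter: int = 200_000,
    walk_steps: int | None = None,
) -> NestedResult:
    """Estimate ln Z = ln integral L(theta) pi(theta) dtheta.

    ``loglike`` maps a parameter vector to a log-likelihood; ``prior_transform``
    maps a point of the unit cube to parameter space (inverse-CDF transform of
    the prior).  Terminates when the maximum possible remaining contribution
    drops below ``frac_remain`` of the accumulated evidence.
    """
    rng = np.random.default_rng(seed)
    nsteps = walk_steps or max(20, 8 * ndim)

    def loglike_u(u):
        return float(loglike(prior_transform(u)))

    u_live = rng.uniform(1e-12, 1.0 - 1e-12, size=(nlive, ndim))
    logl_live = np.array([loglike_u(u) for u in u_live])
    ncall = nlive
    if not np.any(np.isfinite(logl_live)):
        raise EvidenceError("no live point has finite likelihood")

    logz = -np.inf
    h = 0.0
    logx = 0.0           # current log prior volume
    dlogx = -1.0 / nlive
    log_shrink = np.log1p(-np.exp(dlogx))  # ln(1 - e^{-1/nlive})
    scale = 2.0
    niter = 0

    while niter < max_iter:
        worst = int(np.argmin(logl_live))
        lstar = logl_live[worst]
        logw = logx + log_shrink
        logz_new = _logaddexp(logz, logw + lstar)
        if np.isfinite(lstar):
            h = (np.exp(logw + lstar - logz_new) * lstar
                 + np.exp(logz - logz_new) * (h + logz)
                 - logz_new) if np.isfinite(logz) else lstar - logz_new
        logz = logz_new
        logx += dlogx
        niter += 1

        # replace worst from a random surviving point
        chol = _live_cholesky(u_live)
        attempt_scale = scale
        for _attempt in range(15):
            j = int(rng.integers(nlive))
            if j == worst and nlive > 1:
                continue
            u_new, logl_new, nacc, nc = _constrained_step(
                u_live[j], logl_live[j], loglike_u, lstar, rng,
                attempt_scale, nsteps, chol)
            ncall += nc
            if nacc > 0 and logl_new > lstar:
                break
            attempt_scale *= 0.5
        else:
            raise EvidenceError(
                f"constrained replacement failed at iteration {niter}")
        # adapt walk scale toward ~35% acceptance
        frac = nacc / nsteps
        scale = attempt_scale * np.exp((frac - 0.35) / 2.0)
        scale = float(np.clip(scale, 1e-3, 10.0))
        u_live[worst] = u_new
        logl_live[worst] = logl_new

        logz_remain = logx + np.max(logl_live)
        if np.isfinite(logz) and logz_remain - logz < np.log(frac_remain):
            break
    else:
        raise EvidenceError(f"no convergence within {max_iter} iterations")

    # add the final live points, each with volume X/nlive
    logw_live = logx - np.log(nlive)
    for ll in logl_live:
        logz_new = _logaddexp(logz, logw_live + ll)
        h = (np.exp(logw_live + ll - logz_new) * ll
             + np.exp(logz - logz_new) * (h + logz) - logz_new)
        logz = logz_new

    logzerr = float(np.sqrt(max(h, 0.0) / nlive))
    return NestedResult(logz=float(logz), logzerr=logzerr, h=float(max(h, 0.0)),
                        niter=niter, ncall=ncall, nlive=nlive,
                        settings={"frac_remain": frac_remain,
                                  "walk_steps": nsteps, "seed": seed})
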