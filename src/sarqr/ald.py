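"""Check loss, asymmetric Laplace working likelihood, and special samplers.

Quantile regression at level tau minimizes the check loss
rho_tau(eps) = eps * (tau - 1{eps < 0}).  Treating the errors as asymmetric
Laplace ALD(0, delta0, tau) makes check-loss minimization a maximum-likelihood
problem, and the ALD admits the exponential-normal location-scale mixture

    eps = m1 * e + sqrt(m2 * delta0 * e) * nu,    e ~ Exp(mean delta0),

with m1 = (1 - 2 tau)/(tau (1 - tau)) and m2 = 2/(tau (1 - tau)).  The latent
e_i then have generalized inverse Gaussian (GIG) full conditionals, sampled
here exactly; a truncated-Cauchy proposal generator supports the
Metropolis-Hastings updates of bounded parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import kv

__all__ = [
    "QuantileConstants",
    "check_loss",
    "ald_loglik",
    "sample_gig",
    "gig_moment",
    "trunc_cauchy_rvs",
    "trunc_cauchy_weight",
]

#: floor applied to latent draws before forming 1/e (the likelihood divides by e)
LATENT_FLOOR = 1e-12


@dataclass(frozen=True)
class QuantileConstants:
    """Mixture constants of the ALD at quantile level tau."""

    tau: float
    m1: float
    m2: float

    @classmethod
    def from_tau(cls, tau):
        if not 0 < tau < 1:
            raise ValueError(f"tau must lie in (0, 1), got {tau}")
        denom = tau * (1.0 - tau)
        return cls(tau=tau, m1=(1.0 - 2.0 * tau) / denom, m2=2.0 / denom)


def check_loss(eps, tau):
    """Quantile check loss eps * (tau - 1{eps < 0}); vectorized in eps."""
    if not 0 < tau < 1:
        raise ValueError(f"tau must lie in (0, 1), got {tau}")
    eps = np.asarray(eps, dtype=float)
    return eps * (tau - (eps < 0))


def ald_loglik(residuals, tau, delta0):
    """Log-likelihood of i.i.d. ALD(0, delta0, tau) residuals.

    n * log(tau (1 - tau) / delta0) - sum_i rho_tau(eps_i) / delta0.
    """
    if delta0 <= 0:
        raise ValueError(f"delta0 must be positive, got {delta0}")
    residuals = np.atleast_1d(np.asarray(residuals, dtype=float))
    n = residuals.size
    return n * np.log(tau * (1.0 - tau) / delta0) - check_loss(residuals, tau).sum() / delta0


# ---------------------------------------------------------------------------
# Generalized inverse Gaussian sampling
# ---------------------------------------------------------------------------

def _invgauss_rvs(mu, lam, rng):
    """Vectorized inverse-Gaussian draws, Michael–Schucany–Haas transform."""
    mu = np.asarray(mu, dtype=float)
    y = rng.standard_normal(mu.shape) ** 2
    w = mu * y / lam
    x = mu * (1.0 + 0.5 * w - 0.5 * np.sqrt(w * (4.0 + w)))
    x = np.maximum(x, LATENT_FLOOR * mu)
    flip = rng.random(mu.shape) > mu / (mu + x)
    return np.where(flip, mu * mu / x, x)


def sample_gig(nu, a, b, rng, size=None):
    """Draw from GIG(nu, a, b) with density ~ x^(nu-1) exp(-(a^2/x + b^2 x)/2).

    The latent-variable hot path nu = 1/2 uses the exact inverse-Gaussian
    transform (1/X is inverse Gaussian with mean b/a and shape b^2), vectorized
    over (a, b).  The degenerate kernels a = 0 (Gamma) and b = 0 (inverse
    Gamma) are handled explicitly; other nu go through scipy's geninvgauss.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("GIG parameters a, b must be nonnegative")
    if size is None:
        shape = np.broadcast_shapes(a.shape, b.shape)
    else:
        shape = (size,) if np.isscalar(size) else tuple(size)
    a = np.broadcast_to(a, shape).astype(float)
    b = np.broadcast_to(b, shape).astype(float)
    if np.any((a == 0) & (b == 0)):
        raise ValueError("GIG requires a > 0 or b > 0")
    out = np.empty(shape, dtype=float)

    zero_a = a == 0
    zero_b = b == 0
    general = ~(zero_a | zero_b)
    if np.any(zero_a):  # Gamma(nu, rate b^2/2); needs nu > 0
        if nu <= 0:
            raise ValueError("a = 0 requires nu > 0 (Gamma limit)")
        out[zero_a] = rng.gamma(nu, 2.0 / b[zero_a] ** 2)
    if np.any(zero_b):  # inverse Gamma(-nu, a^2/2); needs nu < 0
        if nu >= 0:
            raise ValueError("b = 0 requires nu < 0 (inverse-Gamma limit)")
        out[zero_b] = (a[zero_b] ** 2 / 2.0) / rng.gamma(-nu, 1.0, size=int(zero_b.sum()))
    if np.any(general):
        ag, bg = a[general], b[general]
        if nu == 0.5:
            y = _invgauss_rvs(bg / ag, bg**2, rng)
            out[general] = 1.0 / y
        elif nu == -0.5:
            out[general] = _invgauss_rvs(ag / bg, ag**2, rng)
        else:
            # scipy parameterization: geninvgauss(p, c) ~ w^(p-1) exp(-c (w + 1/w)/2),
            # x = (a/b) w  =>  x ~ GIG(nu, a, b) with c = a b.
            w = stats.geninvgauss.rvs(nu, ag * bg, random_state=rng)
            out[general] = (ag / bg) * w
    out = np.maximum(out, LATENT_FLOOR)
    if size is None and shape == ():
        return float(out)
    return out


def gig_moment(nu, a, b, order=1):
    """E[X^order] of GIG(nu, a, b) via the Bessel-ratio closed form."""
    if a <= 0 or b <= 0:
        raise ValueError("closed-form moments require a > 0 and b > 0")
    return (a / b) ** order * kv(nu + order, a * b) / kv(nu, a * b)


# ---------------------------------------------------------------------------
# Truncated Cauchy
# ---------------------------------------------------------------------------

def trunc_cauchy_weight(center, scale, lower, upper):
    """arctan((upper-c)/s) - arctan((lower-c)/s): the (unnormalized) mass of a
    Cauchy(center, scale) on (lower, upper).  Building block of the MH
    truncation corrections."""
    return np.arctan((upper - center) / scale) - np.arctan((lower - center) / scale)


def trunc_cauchy_rvs(center, scale, lower, upper, rng):
    """Inverse-CDF draw from a Cauchy(center, scale) truncated to (lower, upper)."""
    if not lower < upper:
        raise ValueError(f"empty truncation interval ({lower}, {upper})")
    if scale <= 0:
        raise ValueError("scale must be positive")
    flo = np.arctan((lower - center) / scale)
    fhi = np.arctan((upper - center) / scale)
    u = rng.uniform(flo, fhi)
    return center + scale * np.tan(u)
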