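"""Ex-Wald and Wald first-passage-time distributions.

The Wald (inverse-Gaussian) law is the first-passage time of a drift
diffusion with drift ``v``, noise scale ``s`` and absorbing threshold
``theta``.  The ex-Wald adds an independent exponential stage with rate
``gamma``, modelling a residual (non-decisional) component of the
response time.  Only the CDF is needed downstream: layer fitting matches
the model CDF against the empirical interpulse-interval CDF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import log_ndtr, ndtr

__all__ = ["ExWaldParams", "wald_cdf", "exwald_cdf", "exwald_sample"]


@dataclass(frozen=True)
class ExWaldParams:
    """Parameters of the ex-Wald response-time law.

    Attributes
    ----------
    v : float
        Drift rate (evidence units per sample).
    s : float
        Diffusion noise scale (evidence per sqrt-sample).
    theta : float
        Absorbing threshold (evidence units).
    gamma : float
        Rate of the exponential stage (per sample).
    """

    v: float
    s: float
    theta: float
    gamma: float

    def __post_init__(self) -> None:
        if not (self.s > 0 and self.theta > 0 and self.gamma > 0 and self.v > 0):
            raise ValueError(
                "ex-Wald parameters require v > 0, s > 0, theta > 0, gamma > 0; "
                f"got v={self.v}, s={self.s}, theta={self.theta}, gamma={self.gamma}"
            )
        if self.v**2 < 2.0 * self.gamma * self.s**2:
            raise ValueError(
                "imaginary-k regime: v^2 < 2*gamma*s^2 "
                f"(v={self.v}, s={self.s}, gamma={self.gamma}); only the real-k "
                "branch of the ex-Wald CDF is supported"
            )

    @property
    def k(self) -> float:
        """Reduced drift ``sqrt(v^2 - 2*gamma*s^2)``, always in [0, v]."""
        return float(np.sqrt(self.v**2 - 2.0 * self.gamma * self.s**2))

    @property
    def mean(self) -> float:
        """Analytic mean theta/v + 1/gamma of the convolution."""
        return self.theta / self.v + 1.0 / self.gamma


def _check_t(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("first-passage times are nonnegative; got negative t")
    return t


def wald_cdf(t, v: float, s: float, theta: float):
    """Wald (inverse-Gaussian) CDF of a drift-diffusion first-passage time.

    F(t) = Phi((v*t - theta)/(s*sqrt(t))) + exp(2*theta*v/s^2) * Phi(-(v*t + theta)/(s*sqrt(t)))

    The second term is evaluated in log-space: for large ``theta*v/s^2``
    the exponential overflows while the Gaussian tail underflows, but
    their product is bounded by 1.
    """
    if not (s > 0 and theta > 0 and v > 0):
        raise ValueError(f"wald_cdf requires v > 0, s > 0, theta > 0; got v={v}, s={s}, theta={theta}")
    t = _check_t(t)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    sq = s * np.sqrt(tp)
    with np.errstate(over="ignore", under="ignore"):
        first = ndtr((v * tp - theta) / sq)
        log_second = 2.0 * theta * v / s**2 + log_ndtr(-(v * tp + theta) / sq)
    out[pos] = first + np.exp(log_second)
    np.clip(out, 0.0, 1.0, out=out)
    return float(out[0]) if scalar else out


def exwald_cdf(t, p: ExWaldParams):
    """Ex-Wald CDF: Wald first-passage plus an independent exponential stage.

    H(t) = F(t | v, s, theta) - F(t | k, s, theta) * exp(-gamma*t + theta*(v - k)/s^2)

    with ``k = sqrt(v^2 - 2*gamma*s^2)``.  At the boundary of the real-k
    domain (k = 0) the second Wald factor degenerates: a zero-drift
    diffusion still crosses the threshold with probability one, and the
    k=0 limit of the formula remains finite.
    """
    t = _check_t(t)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    k = p.k
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    first = wald_cdf(tp, p.v, p.s, p.theta)
    # F(t|k,s,theta) * exp(-gamma t + theta (v-k)/s^2), log-space for the
    # same overflow reason as in wald_cdf; k = 0 needs the zero-drift CDF
    # 2*Phi(-theta/(s sqrt(t))) handled as a limit.
    sq = p.s * np.sqrt(tp)
    with np.errstate(over="ignore", under="ignore"):
        if k > 0:
            a = ndtr((k * tp - p.theta) / sq)
            log_b = 2.0 * p.theta * k / p.s**2 + log_ndtr(-(k * tp + p.theta) / sq)
            fk = a + np.exp(log_b)
        else:
            fk = 2.0 * ndtr(-p.theta / sq)
        log_fac = -p.gamma * tp + p.theta * (p.v - k) / p.s**2
        second = np.exp(np.log(np.maximum(fk, 1e-300)) + log_fac)
    out[pos] = first - second
    np.clip(out, 0.0, 1.0, out=out)
    return float(out[0]) if scalar else out


def exwald_sample(p: ExWaldParams, n: int, seed) -> np.ndarray:
    """Draw ``n`` ex-Wald variates: inverse-Gaussian + exponential.

    The inverse-Gaussian component has mean theta/v and shape theta^2/s^2,
    matching the Wald first-passage time; the exponential has rate gamma.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    mean = p.theta / p.v
    lam = p.theta**2 / p.s**2
    ig = stats.invgauss.rvs(mu=mean / lam, scale=lam, size=n, random_state=rng)
    exp = rng.exponential(scale=1.0 / p.gamma, size=n)
    return ig + exp
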