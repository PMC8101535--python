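"""Moment-matched log-normal sampling.

Daily PM2.5 concentrations are right-skewed, so both the synthetic monitor
generator and the Monte Carlo exposure sensitivity draw from a log-normal
parameterized by its arithmetic mean m and relative standard deviation r
(RSD = SD/mean) via the method of moments:

    sigma^2 = ln(1 + r^2)
    mu      = ln(m) - sigma^2 / 2

so the configured (mean, RSD) are exactly recoverable from the draws.
"""

from __future__ import annotations

import numpy as np


def lognormal_params(mean, rsd):
    """Return (mu, sigma) of ln X for a log-normal with arithmetic mean and RSD.

    Parameters
    ----------
    mean : array-like, > 0
        Arithmetic mean of the distribution (concentration units).
    rsd : array-like, >= 0
        Relative standard deviation, SD/mean (dimensionless).
    """
    mean = np.asarray(mean, dtype=float)
    rsd = np.asarray(rsd, dtype=float)
    if np.any(mean <= 0):
        raise ValueError("log-normal mean must be strictly positive")
    if np.any(rsd < 0):
        raise ValueError("RSD must be non-negative")
    sigma2 = np.log1p(np.square(rsd))
    sigma = np.sqrt(sigma2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, sigma


def draw_lognormal(rng, mean, rsd, size=None):
    """Draw from the moment-matched log-normal.

    Degenerate cases are exact: rsd == 0 returns the mean itself (no
    round-trip through exp/log), and mean == 0 returns 0.
    """
    mean = np.asarray(mean, dtype=float)
    rsd = np.broadcast_to(np.asarray(rsd, dtype=float), mean.shape).copy()
    out_shape = mean.shape if size is None else size
    zero_mean = mean == 0
    degenerate = (rsd == 0) | zero_mean
    if np.all(degenerate):
        return np.broadcast_to(mean, out_shape).copy()
    safe_mean = np.where(zero_mean, 1.0, mean)
    mu, sigma = lognormal_params(safe_mean, rsd)
    draws = rng.lognormal(mean=mu, sigma=sigma, size=out_shape)
    return np.where(degenerate, np.broadcast_to(mean, out_shape), draws)
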