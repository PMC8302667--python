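"""Tracy-Widom test for the number of significant eigenvalues.

The largest eigenvalue of a sample covariance/correlation matrix of pure
noise, suitably centered and scaled, follows the Tracy-Widom distribution of
order 1 (TW1).  Eigenvalues are tested sequentially from the top: at each
step the leading remaining eigenvalue is normalized against the
Marchenko-Pastur edge for the remaining dimensions (Patterson-style moment
normalization, effective sample size n - 1) and compared with the TW1
critical value; testing stops at the first non-significant eigenvalue.

The TW1 distribution function is evaluated with the shifted-gamma
approximation TW1 ~ Gamma(k, theta) - alpha (k ~ 46.446, theta ~ 0.18605,
alpha ~ 9.84801), accurate to about 1e-3 in probability across the support —
far below the Monte-Carlo noise of any eigenvalue-count decision.
"""

from __future__ import annotations

import numpy as np
from scipy import special

__all__ = ["tw1_cdf", "tw1_critical_value", "tracy_widom_k"]

# shifted-gamma parameters matching the first three TW1 cumulants
_K = 46.44604884387787
_THETA = 0.18605402228279682
_ALPHA = 9.848007781128567


def tw1_cdf(x) -> np.ndarray:
    """Cumulative distribution function of the Tracy-Widom law of order 1."""
    x = np.asarray(x, dtype=float)
    return special.gammainc(_K, np.maximum(x + _ALPHA, 0.0) / _THETA)


def tw1_critical_value(alpha: float) -> float:
    """Upper-tail critical value: P(TW1 > c) = alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return _THETA * special.gammainccinv(_K, alpha) - _ALPHA


def _tw_statistic(lead: float, total: float, m: int, n_eff: float) -> float:
    """Patterson normalization of the leading of m eigenvalues summing to total."""
    l1 = m * lead / total
    sq_n = np.sqrt(n_eff - 1.0)
    sq_m = np.sqrt(float(m))
    mu = (sq_n + sq_m) ** 2 / n_eff
    sigma = (sq_n + sq_m) / n_eff * (1.0 / sq_n + 1.0 / sq_m) ** (1.0 / 3.0)
    return (l1 - mu) / sigma


def tracy_widom_k(eigenvalues, n: int, alpha: float = 0.05) -> int:
    """Number of significant leading eigenvalues by sequential TW1 testing.

    Parameters
    ----------
    eigenvalues
        Non-increasing, non-negative eigenvalues of a sample correlation (or
        covariance) matrix.
    n
        Number of samples the matrix was estimated from.
    alpha
        Per-eigenvalue significance level (default 0.05).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    ev = np.asarray(list(eigenvalues), dtype=float)
    if ev.size == 0:
        return 0
    if (ev < -1e-12).any():
        raise ValueError("eigenvalues must be non-negative")
    ev = np.maximum(ev, 0.0)
    if (np.diff(ev) > 1e-8).any():
        raise ValueError("eigenvalues must be non-increasing")
    crit = tw1_critical_value(alpha)
    n_eff = float(n - 1)
    if n_eff <= 1:
        return 0
    k = 0
    J = ev.size
    for i in range(J):
        m = J - i
        total = ev[i:].sum()
        if m < 2 or total <= 0 or ev[i] <= 0:
            break
        stat = _tw_statistic(ev[i], total, m, n_eff)
        if stat > crit:
            k += 1
        else:
            break
    return k
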