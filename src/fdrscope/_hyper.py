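"""Exact vectorized hypergeometric upper tails in log space.

``log P(X >= x)`` for X ~ Hypergeometric(N population, K marked, n drawn)
is computed as ``log pmf(x) + log sum_{i>=x} pmf(i)/pmf(x)`` using the pmf
ratio recurrence

    pmf(i+1)/pmf(i) = (K - i)(n - i) / ((i + 1)(N - K - n + i + 1)),

with the running sum accumulated by ``logaddexp``.  The summation is exact
up to float rounding (it is the same finite sum an enumeration performs) and
runs in O(tail length) vectorized steps, which keeps large-population
contrast scoring and permutation tables fast.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln


def _log_comb(n, k):
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def log_hypergeom_sf(x, N, K, n) -> np.ndarray:
    """log P(X >= x) for X ~ Hypergeom(N, K, n); broadcasts all arguments.

    ``x <= max(0, K + n - N)`` gives 0.0 (probability one); ``x`` beyond
    ``min(K, n)`` gives ``-inf``.
    """
    x, N, K, n = np.broadcast_arrays(
        *(np.asarray(a, dtype=np.int64) for a in (x, N, K, n))
    )
    shape = x.shape
    x = x.ravel().copy()
    N, K, n = N.ravel(), K.ravel(), n.ravel()
    lb = np.maximum(0, K + n - N)  # smallest possible draw count
    ub = np.minimum(K, n)
    out = np.full(x.shape, -np.inf)
    certain = x <= lb
    out[certain] = 0.0
    todo = (~certain) & (x <= ub)
    if todo.any():
        xi = x[todo]
        Ni, Ki, ni, ubi = N[todo], K[todo], n[todo], ub[todo]
        lpmf = (
            _log_comb(Ki, xi)
            + _log_comb(Ni - Ki, ni - xi)
            - _log_comb(Ni, ni)
        )
        log_s = np.zeros(xi.shape)  # running log of sum(pmf(i)/pmf(x))
        log_term = np.zeros(xi.shape)
        i = xi.astype(np.float64)
        active = i < ubi
        while active.any():
            ratio = np.zeros(xi.shape)
            a = active
            ratio[a] = (
                np.log(Ki[a] - i[a])
                + np.log(ni[a] - i[a])
                - np.log(i[a] + 1.0)
                - np.log(Ni[a] - Ki[a] - ni[a] + i[a] + 1.0)
            )
            log_term = np.where(a, log_term + ratio, log_term)
            log_s = np.where(a, np.logaddexp(log_s, log_term), log_s)
            i = np.where(a, i + 1.0, i)
            # stop once further terms cannot move the sum at float precision
            active = a & (i < ubi) & (log_term - log_s > -45.0)
        out[todo] = np.minimum(0.0, lpmf + log_s)
    return out.reshape(shape)


def hypergeom_sf(x, N, K, n) -> np.ndarray:
    """P(X >= x); see :func:`log_hypergeom_sf`."""
    return np.exp(log_hypergeom_sf(x, N, K, n))
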