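"""Closed-form Poisson–Gamma marginal likelihoods.

The workhorse identity used throughout: for independent counts
``y_i ~ Poisson(r_i * lam)`` with ``lam ~ Gamma(shape a, rate b)``,

    log P(y) = sum_i [ y_i log r_i - log y_i! ]
             + a log b - log G(a) + log G(a + y+) - (a + y+) log(b + R)

where ``y+ = sum y_i`` and ``R = sum r_i``.  With ``a = b = alpha`` this is
the synonymous-data marginal of the background model; with ``(a, b)`` set to
a gene's synonymous posterior it is the conditional non-synonymous marginal.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, xlogy

__all__ = [
    "poisson_gamma_loglik",
    "poisson_gamma_loglik_by_group",
]


def poisson_gamma_loglik(counts, rates, shape: float, rate: float) -> float:
    """log of the Gamma-mixed Poisson marginal for one group of sites.

    Parameters
    ----------
    counts, rates
        Aligned 1-D arrays: observed counts ``y_i`` and per-site rate
        multipliers ``r_i`` (``r_i >= 0``).
    shape, rate
        Parameters of the Gamma mixing distribution over the shared
        multiplier ``lam`` (shape/rate parameterisation; both > 0).
    """
    if shape <= 0 or rate <= 0:
        raise ValueError("Gamma shape and rate must be positive")
    y = np.asarray(counts, dtype=float)
    r = np.asarray(rates, dtype=float)
    if y.shape != r.shape:
        raise ValueError("counts and rates must be aligned")
    y_plus = y.sum()
    R = r.sum()
    site_term = float(np.sum(xlogy(y, r) - gammaln(y + 1.0)))
    return (
        site_term
        + shape * np.log(rate)
        - gammaln(shape)
        + gammaln(shape + y_plus)
        - (shape + y_plus) * np.log(rate + R)
    )


def poisson_gamma_loglik_by_group(counts, rates, group_idx, n_groups: int,
                                  shape, rate) -> np.ndarray:
    """Vectorised per-group Poisson–Gamma marginal log-likelihoods.

    ``shape`` and ``rate`` may be scalars (shared prior) or arrays of length
    ``n_groups`` (per-group posteriors).  Returns an array of length
    ``n_groups``; groups with no sites get the empty-product value 0 when
    their net Gamma normaliser cancels (shape==..., y+=0, R=0 gives 0).
    """
    y = np.asarray(counts, dtype=float)
    r = np.asarray(rates, dtype=float)
    g = np.asarray(group_idx)
    y_plus = np.bincount(g, weights=y, minlength=n_groups)
    R = np.bincount(g, weights=r, minlength=n_groups)
    site = np.bincount(g, weights=xlogy(y, r) - gammaln(y + 1.0),
                       minlength=n_groups)
    a = np.broadcast_to(np.asarray(shape, dtype=float), (n_groups,))
    b = np.broadcast_to(np.asarray(rate, dtype=float), (n_groups,))
    return (
        site
        + a * np.log(b)
        - gammaln(a)
        + gammaln(a + y_plus)
        - (a + y_plus) * np.log(b + R)
    )
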