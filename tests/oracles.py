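"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's closed forms and forward recursions:
the Poisson–Gamma marginals are computed by adaptive quadrature over the
gene effect, and the spatial likelihood by exhaustive enumeration of hidden
state paths (with the gene effect integrated on the same generalized
Gauss–Laguerre rule the package documents, derived here independently via
the change-of-variables identity for integrals against a Gamma weight).
"""

import itertools

import numpy as np
from scipy.integrate import quad
from scipy.special import gammaln, logsumexp, roots_genlaguerre, xlogy
from scipy.stats import gamma as gamma_dist


def quadrature_poisson_gamma_loglik(counts, rates, shape, rate):
    """log integral of prod Poisson(y_i; r_i lam) against Gamma(lam; a, b)
    by adaptive quadrature (small instances only)."""
    y = np.asarray(counts, dtype=float)
    r = np.asarray(rates, dtype=float)

    def integrand(lam):
        logp = np.sum(xlogy(y, r * lam) - r * lam - gammaln(y + 1.0))
        return np.exp(logp) * gamma_dist.pdf(lam, shape, scale=1.0 / rate)

    # the integrand is proportional to a Gamma(shape + y+, rate + R) density
    post = gamma_dist(shape + y.sum(), scale=1.0 / (rate + r.sum()))
    hi = float(post.ppf(1 - 1e-16)) * 4 + 10.0
    mode = (shape + y.sum()) / (rate + r.sum())
    val, _ = quad(integrand, 0, hi, points=[mode / 4, mode, mode * 4],
                  limit=400, epsabs=0, epsrel=1e-12)
    return np.log(val)


def enumerate_spatial_loglik(S, C, D_total, a, b, q_enter, mean_len, rho,
                             n_nodes=16):
    """Brute-force spatial marginal likelihood for a short gene.

    For each quadrature node of the gene effect, sums over all 2^L hidden
    state paths of the two-state hotspot chain (background/hotspot), with
    the chain started at stationarity and the hotspot state multiplying the
    non-synonymous rates by rho.  Only feasible for L <= ~14.
    """
    S = np.asarray(S, dtype=float)
    C = np.asarray(C, dtype=float)
    L = len(S)
    q_exit = 1.0 / mean_len
    p_hot = q_enter / (q_enter + q_exit) if (q_enter + q_exit) > 0 else 0.0
    T = np.array([[1 - q_enter, q_enter], [q_exit, 1 - q_exit]])
    with np.errstate(divide="ignore"):
        logT = np.log(T)
        log_init = np.log(np.array([1 - p_hot, p_hot]))

    ap = a + C.sum()
    bp = b + S.sum()
    x, w = roots_genlaguerre(n_nodes, ap - 1.0)
    lam_nodes = x / bp

    # integral of f(lam) d lam  ~=  sum_k w_k e^{x_k} x_k^{-(ap-1)} f(x_k/bp) / bp
    log_node_factor = np.log(w) + x - (ap - 1.0) * np.log(x) - np.log(bp)

    vals = np.empty(n_nodes)
    for k, lam in enumerate(lam_nodes):
        path_logs = []
        for states in itertools.product((0, 1), repeat=L):
            lp = log_init[states[0]]
            for p in range(1, L):
                lp += logT[states[p - 1], states[p]]
            for p in range(L):
                mult = rho if states[p] else 1.0
                lp += C[p] * np.log(lam * mult) if C[p] else 0.0
                lp -= lam * mult * S[p]
            path_logs.append(lp)
        logF = logsumexp(path_logs)
        # Gamma(a, b) prior density at lam (log)
        log_prior = a * np.log(b) + (a - 1.0) * np.log(lam) - b * lam - gammaln(a)
        vals[k] = logF + log_prior
    return D_total + logsumexp(log_node_factor + vals)
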