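"""Background mutation model (BMM).

The background rate of mutation type ``t`` at position ``i`` follows a
log-linear model in position-level genomic features (expression,
replication timing, chromatin contact, ...):

    log mu_it = beta0_t + sum_j x_ij beta_j

with a gene-specific multiplier ``lam_g ~ Gamma(alpha, alpha)`` capturing
residual rate variation between genes.  The marginal likelihood of a gene's
synonymous counts integrates ``lam_g`` out in closed form (Poisson–Gamma),
and the model is fit by maximum marginal likelihood on synonymous data from
all genes jointly.  Conditional on the synonymous data, ``lam_g`` has a
Gamma(alpha + y+, alpha + mu+) posterior, whose mean is the gene-effect
adjustment used downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import minimize
from scipy.special import digamma, gammaln, xlogy

from .mutation_data import N_MUTATION_TYPES, SiteTable

logger = logging.getLogger(__name__)

BETA0_FLOOR = -30.0  # log-rate clamp for mutation types never observed


@dataclass
class ConvergenceReport:
    converged: bool
    n_iter: int
    grad_norm: float
    loglik: float
    loglik_trace: list = field(default_factory=list)
    warnings_: list = field(default_factory=list)


@dataclass
class BMMParams:
    """Fitted background model: per-type intercepts, feature coefficients,
    Gamma dispersion, and the feature standardisation baked into the fit."""

    beta0: np.ndarray               # (9,) per-type log baseline rates
    beta_bg: np.ndarray             # one coefficient per background feature
    alpha: float                    # Gamma(alpha, alpha) gene-effect shape
    feature_names: list
    feature_mean: np.ndarray        # z-scoring constants (continuous features)
    feature_sd: np.ndarray
    se: np.ndarray | None = None    # SEs for (beta0, beta_bg, log alpha)
    report: ConvergenceReport | None = None

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        self.beta0 = np.asarray(self.beta0, dtype=float)
        self.beta_bg = np.asarray(self.beta_bg, dtype=float)
        if len(self.beta_bg) != len(self.feature_names):
            raise ValueError("one coefficient per background feature required")

    # -- persistence (plain key-value text, round-trips exactly) ----------
    def to_file(self, path):
        doc = {
            "model": "bmm",
            "feature_names": list(self.feature_names),
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
            "beta0": self.beta0.tolist(),
            "beta_bg": self.beta_bg.tolist(),
            "alpha": float(self.alpha),
            "se": None if self.se is None else self.se.tolist(),
        }
        if self.report is not None:
            doc["convergence"] = {
                "converged": bool(self.report.converged),
                "n_iter": int(self.report.n_iter),
                "grad_norm": float(self.report.grad_norm),
                "loglik": float(self.report.loglik),
            }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_file(cls, path) -> "BMMParams":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if doc.get("model") != "bmm":
            raise ValueError(f"{path} is not a background-model file")
        return cls(
            beta0=np.array(doc["beta0"]),
            beta_bg=np.array(doc["beta_bg"]),
            alpha=doc["alpha"],
            feature_names=doc["feature_names"],
            feature_mean=np.array(doc["feature_mean"]),
            feature_sd=np.array(doc["feature_sd"]),
            se=None if doc.get("se") is None else np.array(doc["se"]),
        )


@dataclass
class GenePosterior:
    """Gamma posterior of a gene effect given its synonymous data:
    shape a = alpha + y+, rate b = alpha + mu+."""

    a: float
    b: float

    @property
    def mean(self) -> float:
        return self.a / self.b


def _standardize(X, mean, sd):
    return (X - mean) / sd


def background_rate(sites: SiteTable, params: BMMParams) -> np.ndarray:
    """Vectorised background rate mu_it = exp(beta0_t + x.beta) per row."""
    X = sites.bg_matrix()
    if X.shape[1] != len(params.feature_names):
        raise ValueError(
            f"site table declares {X.shape[1]} background features, "
            f"model has {len(params.feature_names)}"
        )
    if np.isnan(X).any():
        bad = np.argwhere(np.isnan(X))[0]
        raise ValueError(
            f"missing background feature value at row {bad[0]}, "
            f"feature {params.feature_names[bad[1]]!r}"
        )
    Xz = _standardize(X, params.feature_mean, params.feature_sd)
    t = sites.df["mutation_type"].to_numpy(dtype=int)
    eta = params.beta0[t - 1]
    if Xz.shape[1]:
        eta = eta + Xz @ params.beta_bg
    return np.exp(eta)


def syn_marginal_loglik(gene_counts, gene_rates, alpha: float) -> float:
    """Closed-form log P(Y^Sg | beta, alpha) for one gene's synonymous sites."""
    from .marglik import poisson_gamma_loglik

    return poisson_gamma_loglik(gene_counts, gene_rates, alpha, alpha)


def gene_effect_posterior(gene_syn_counts, gene_syn_rates, alpha_hat: float) -> GenePosterior:
    """Posterior Gamma(alpha + y+, alpha + mu+) of a gene's effect lam_g."""
    if alpha_hat <= 0:
        raise ValueError("alpha_hat must be positive")
    return GenePosterior(
        a=float(alpha_hat + np.sum(gene_syn_counts)),
        b=float(alpha_hat + np.sum(gene_syn_rates)),
    )


# ---------------------------------------------------------------------------
# fitting


def _bmm_negloglik_and_grad(theta, y, types0, Xz, gene_idx, n_genes):
    """Negative marginal log-likelihood over genes and its analytic gradient.

    theta = [beta0 (9), beta_bg (p), log alpha].
    """
    p = Xz.shape[1]
    beta0 = theta[:N_MUTATION_TYPES]
    beta = theta[N_MUTATION_TYPES:N_MUTATION_TYPES + p]
    alpha = np.exp(theta[-1])
    eta = beta0[types0]
    if p:
        eta = eta + Xz @ beta
    mu = np.exp(eta)
    y_plus = np.bincount(gene_idx, weights=y, minlength=n_genes)
    R = np.bincount(gene_idx, weights=mu, minlength=n_genes)
    ll = (
        float(np.sum(xlogy(y, mu) - gammaln(y + 1.0)))
        + n_genes * (alpha * np.log(alpha) - gammaln(alpha))
        + float(np.sum(gammaln(alpha + y_plus)))
        - float(np.sum((alpha + y_plus) * np.log(alpha + R)))
    )
    # gradient through the linear predictor
    w = (alpha + y_plus) / (alpha + R)
    resid = y - mu * w[gene_idx]
    g_beta0 = np.bincount(types0, weights=resid, minlength=N_MUTATION_TYPES)
    g_beta = Xz.T @ resid if p else np.zeros(0)
    d_alpha = np.sum(
        np.log(alpha) + 1.0 - digamma(alpha)
        + digamma(alpha + y_plus) - np.log(alpha + R)
        - (alpha + y_plus) / (alpha + R)
    )
    grad = np.concatenate([g_beta0, g_beta, [alpha * d_alpha]])
    return -ll, -grad


def fit_bmm(sites: SiteTable, counts, max_iter: int = 500,
            tol: float = 1e-9, compute_se: bool = True) -> BMMParams:
    """Fit the background model by marginal ML on synonymous sites.

    Optimises (beta0, beta_bg, log alpha) jointly with L-BFGS-B using the
    analytic gradient.  Intercepts of mutation types with no observed
    synonymous mutation are driven to the floor ``BETA0_FLOOR`` and flagged.
    Standard errors come from the numerically differenced Hessian of the
    analytic gradient at the optimum.
    """
    counts = np.asarray(counts)
    syn = sites.is_syn
    y = counts[syn].astype(float)
    if y.sum() < 1:
        raise ValueError("need at least one synonymous mutation to fit the BMM")
    types0 = sites.df["mutation_type"].to_numpy(dtype=int)[syn] - 1
    X = sites.bg_matrix()[syn]
    fmean = X.mean(axis=0) if X.shape[1] else np.zeros(0)
    fsd = X.std(axis=0) if X.shape[1] else np.zeros(0)
    fsd = np.where(fsd > 0, fsd, 1.0)
    Xz = _standardize(X, fmean, fsd)
    gene_codes_all, _ = sites.gene_index()
    # re-code genes restricted to synonymous rows
    gsyn = pd.Categorical(gene_codes_all[syn])
    gene_idx = np.asarray(gsyn.codes)
    n_genes = len(gsyn.categories)

    # crude per-type initial rates
    n_t = np.bincount(types0, minlength=N_MUTATION_TYPES).astype(float)
    c_t = np.bincount(types0, weights=y, minlength=N_MUTATION_TYPES)
    beta0_init = np.log((c_t + 0.5) / np.maximum(n_t, 1.0))
    theta0 = np.concatenate([beta0_init, np.zeros(Xz.shape[1]), [0.0]])

    trace: list = []
    args = (y, types0, Xz, gene_idx, n_genes)

    def cb(xk):
        trace.append(-_bmm_negloglik_and_grad(xk, *args)[0])

    # types never observed in the synonymous data have their intercept pinned
    # at the floor: the likelihood is monotone decreasing in them and leaving
    # the direction free only destabilises the line search
    unseen = c_t == 0
    theta0[:N_MUTATION_TYPES][unseen] = BETA0_FLOOR
    bounds = (
        [(BETA0_FLOOR, BETA0_FLOOR) if unseen[t] else (BETA0_FLOOR, 10.0)
         for t in range(N_MUTATION_TYPES)]
        + [(None, None)] * Xz.shape[1]
        + [(np.log(1e-6), np.log(1e9))]
    )
    res = minimize(
        _bmm_negloglik_and_grad, theta0, args=args, jac=True,
        method="L-BFGS-B", bounds=bounds, callback=cb,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
    )
    report = ConvergenceReport(
        converged=bool(res.success),
        n_iter=int(res.nit),
        grad_norm=float(np.max(np.abs(res.jac))),
        loglik=float(-res.fun),
        loglik_trace=trace,
    )
    grad_free = np.abs(res.jac).copy()
    grad_free[:N_MUTATION_TYPES][unseen] = 0.0  # pinned directions
    if not res.success and np.max(grad_free) > 1e-2 * max(1.0, abs(res.fun)):
        raise RuntimeError(f"BMM fit did not converge: {res.message}; {report}")
    theta = res.x
    if unseen.any():
        theta[:N_MUTATION_TYPES][unseen] = BETA0_FLOOR
        msg = (f"mutation types with no observed synonymous mutation: "
               f"{(np.flatnonzero(unseen) + 1).tolist()}; intercepts clamped")
        logger.warning(msg)
        report.warnings_.append(msg)

    se = None
    if compute_se:
        se = _se_from_grad(_bmm_negloglik_and_grad, theta, args)
        if se is None:
            report.warnings_.append("singular Hessian: SEs unavailable")
    params = BMMParams(
        beta0=theta[:N_MUTATION_TYPES],
        beta_bg=theta[N_MUTATION_TYPES:N_MUTATION_TYPES + Xz.shape[1]],
        alpha=float(np.exp(theta[-1])),
        feature_names=list(sites.bg_features),
        feature_mean=fmean,
        feature_sd=fsd,
        se=se,
        report=report,
    )
    return params


def _se_from_grad(fun_and_grad, theta, args, eps: float = 1e-5):
    """SEs via central finite differences of an analytic gradient."""
    n = len(theta)
    H = np.zeros((n, n))
    for j in range(n):
        step = eps * max(1.0, abs(theta[j]))
        tp = theta.copy(); tp[j] += step
        tm = theta.copy(); tm[j] -= step
        gp = fun_and_grad(tp, *args)[1]
        gm = fun_and_grad(tm, *args)[1]
        H[:, j] = (gp - gm) / (2 * step)
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    d = np.diag(cov)
    if (d <= 0).any():
        return None
    return np.sqrt(d)


# ---------------------------------------------------------------------------
# diagnostics


def validate_gene_effects(sites: SiteTable, counts, params: BMMParams) -> pd.DataFrame:
    """Observed vs expected non-synonymous counts per gene, with and without
    the gene-effect adjustment.

    The expectation without adjustment is ``sum_{NS_g} mu_it``; the adjusted
    expectation multiplies it by the posterior mean of ``lam_g`` learned from
    the gene's synonymous data.  R-squared values are computed against the
    slope-1 diagonal (1 - SS_resid_about_diagonal / SS_total) and attached as
    ``.attrs["r2_unadjusted"]`` / ``.attrs["r2_adjusted"]`` (NaN when fewer
    than two genes survive).
    """
    counts = np.asarray(counts)
    mu = background_rate(sites, params)
    gene_codes, gene_ids = sites.gene_index()
    n_genes = len(gene_ids)
    syn = sites.is_syn
    ns = ~syn

    def gsum(values, mask):
        return np.bincount(gene_codes[mask], weights=values[mask], minlength=n_genes)

    y_syn = gsum(counts.astype(float), syn)
    mu_syn = gsum(mu, syn)
    y_ns = gsum(counts.astype(float), ns)
    mu_ns = gsum(mu, ns)
    post_mean = (params.alpha + y_syn) / (params.alpha + mu_syn)

    tab = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "observed_ns": y_ns,
            "expected_ns": mu_ns,
            "expected_ns_adjusted": post_mean * mu_ns,
            "gene_effect_post_mean": post_mean,
        }
    )
    no_ns = mu_ns == 0
    if no_ns.any():
        logger.warning("%d genes with zero NS opportunity excluded from R2", no_ns.sum())
        tab = tab[~no_ns].reset_index(drop=True)

    def r2_diag(obs, exp):
        if len(obs) < 2 or np.var(obs) == 0:
            return float("nan")
        return 1.0 - np.sum((obs - exp) ** 2) / np.sum((obs - obs.mean()) ** 2)

    tab.attrs["r2_unadjusted"] = r2_diag(tab["observed_ns"].to_numpy(),
                                         tab["expected_ns"].to_numpy())
    tab.attrs["r2_adjusted"] = r2_diag(tab["observed_ns"].to_numpy(),
                                       tab["expected_ns_adjusted"].to_numpy())
    return tab
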