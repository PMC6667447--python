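"""Selection mutation model (SMM).

Under a driver hypothesis m (oncogene, tumor suppressor, or the non-driver
null), the rate of a non-synonymous mutation is the background rate times a
selection effect

    log gamma_it = beta0_f + sum_j x_ijt beta_j_f

driven by binary functional annotations of the specific allele (LoF,
conservation, SiFT, PhyloP, MutationAssessor).  The intercept captures the
average enrichment of non-synonymous mutations under hypothesis m.
Parameters are fit by maximising the conditional likelihood of the
non-synonymous counts given each training gene's synonymous data (the
background model stays frozen and the gene effect is integrated against its
synonymous posterior).  Standard errors come from the curvature of this
likelihood, and per-tumor estimates can be stabilised across tumor types by
empirical-Bayes shrinkage toward their common mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import minimize
from scipy.special import gammaln, xlogy

from .bmm import BMMParams, ConvergenceReport, GenePosterior, background_rate, _se_from_grad
from .marglik import poisson_gamma_loglik
from .mutation_data import SiteTable

logger = logging.getLogger(__name__)

HYPOTHESES = ("H0", "OG", "TSG")


@dataclass
class SMMParams:
    hypothesis: str
    beta0_f: float
    beta_f: np.ndarray
    feature_names: list
    se: np.ndarray | None = None     # aligned with (beta0_f, *beta_f)
    report: ConvergenceReport | None = None

    def __post_init__(self):
        if self.hypothesis not in HYPOTHESES:
            raise ValueError(f"hypothesis must be one of {HYPOTHESES}")
        self.beta_f = np.asarray(self.beta_f, dtype=float)
        if len(self.beta_f) != len(self.feature_names):
            raise ValueError("one coefficient per functional feature required")
        if self.se is not None and np.any(np.asarray(self.se) < 0):
            raise ValueError("standard errors must be non-negative")

    @classmethod
    def null(cls, feature_names=()) -> "SMMParams":
        """All-zero model (gamma = 1 everywhere)."""
        return cls("H0", 0.0, np.zeros(len(feature_names)), list(feature_names))

    def to_dict(self):
        return {
            "hypothesis": self.hypothesis,
            "feature_names": list(self.feature_names),
            "beta0_f": float(self.beta0_f),
            "beta_f": self.beta_f.tolist(),
            "se": None if self.se is None else np.asarray(self.se).tolist(),
        }

    @classmethod
    def from_dict(cls, doc) -> "SMMParams":
        return cls(
            hypothesis=doc["hypothesis"],
            beta0_f=doc["beta0_f"],
            beta_f=np.array(doc["beta_f"]),
            feature_names=doc["feature_names"],
            se=None if doc.get("se") is None else np.array(doc["se"]),
        )


def write_smm_file(path, models):
    """Write one or more hypothesis blocks to a selection-model file."""
    doc = {"model": "smm", "blocks": [m.to_dict() for m in models]}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_smm_file(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc.get("model") != "smm":
        raise ValueError(f"{path} is not a selection-model file")
    models = [SMMParams.from_dict(b) for b in doc["blocks"]]
    return {m.hypothesis: m for m in models}


def selection_effect(sites: SiteTable, params: SMMParams) -> np.ndarray:
    """Per-row selection effect gamma_it = exp(beta0_f + x_f . beta_f)."""
    Xf = sites.fn_matrix(params.feature_names)
    if Xf.shape[1] != len(params.feature_names):
        raise ValueError("functional feature vector length mismatch")
    return np.exp(params.beta0_f + (Xf @ params.beta_f if Xf.shape[1] else 0.0))


def ns_conditional_loglik(gene_ns_counts, gene_ns_rates, gamma,
                          posterior: GenePosterior) -> float:
    """log P(Y^NSg | beta_f, Y^Sg): Poisson–Gamma marginal of the gene's
    non-synonymous counts with effective rates mu*gamma against the gene
    effect's synonymous posterior Gamma(a, b)."""
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma <= 0):
        raise ValueError("selection effects must be positive")
    rates = np.asarray(gene_ns_rates, dtype=float) * gamma
    return poisson_gamma_loglik(gene_ns_counts, rates, posterior.a, posterior.b)


# ---------------------------------------------------------------------------
# fitting


def _smm_negloglik_and_grad(theta, y, mu, Xf, gene_idx, a_g, b_g):
    """Negative conditional log-likelihood summed over training genes.

    theta = [beta0_f, beta_f...]; a_g, b_g are the per-gene synonymous
    posteriors (arrays over the gene re-coding used in gene_idx).
    """
    n_genes = len(a_g)
    eta = theta[0] + (Xf @ theta[1:] if Xf.shape[1] else 0.0)
    r = mu * np.exp(eta)
    y_plus = np.bincount(gene_idx, weights=y, minlength=n_genes)
    R = np.bincount(gene_idx, weights=r, minlength=n_genes)
    ll = (
        float(np.sum(xlogy(y, r) - gammaln(y + 1.0)))
        + float(np.sum(a_g * np.log(b_g) - gammaln(a_g)
                       + gammaln(a_g + y_plus)
                       - (a_g + y_plus) * np.log(b_g + R)))
    )
    w = (a_g + y_plus) / (b_g + R)
    resid = y - r * w[gene_idx]
    grad = np.concatenate([[resid.sum()], Xf.T @ resid if Xf.shape[1] else []])
    return -ll, -grad


def training_gene_mask(sites: SiteTable, og_genes, tsg_genes, hypothesis: str) -> np.ndarray:
    """Row mask of the genes a hypothesis is trained on.

    OG/TSG use their curated lists; the null model is trained on every gene
    outside both lists (the vast majority of genes should be non-drivers).
    """
    gid = sites.df["gene_id"]
    og, tsg = set(og_genes), set(tsg_genes)
    if hypothesis == "OG":
        return gid.isin(og).to_numpy()
    if hypothesis == "TSG":
        return gid.isin(tsg).to_numpy()
    return (~gid.isin(og | tsg)).to_numpy()


def fit_smm(sites: SiteTable, counts, bmm: BMMParams, hypothesis: str,
            og_genes=(), tsg_genes=(), fn_features=None, gene_mask=None,
            max_iter: int = 500, tol: float = 1e-9,
            compute_se: bool = True) -> SMMParams:
    """Fit hypothesis-specific selection coefficients with the BMM frozen.

    The spatial model is ignored during this step (spatially clustered
    mutations are rare enough not to move these estimates).  ``fn_features``
    restricts the functional features used (default: all declared in the
    site table).  ``gene_mask`` overrides the training gene set directly.
    """
    counts = np.asarray(counts)
    feats = list(sites.fn_features if fn_features is None else fn_features)
    if gene_mask is None:
        gene_mask = training_gene_mask(sites, og_genes, tsg_genes, hypothesis)
    if not gene_mask.any():
        raise ValueError(f"empty training gene set for hypothesis {hypothesis}")

    mu = background_rate(sites, bmm)
    syn = sites.is_syn
    ns_rows = gene_mask & ~syn
    syn_rows = gene_mask & syn

    gene_codes, _ = sites.gene_index()
    train_cats = np.unique(gene_codes[gene_mask])
    n_genes = len(train_cats)

    def recode(mask):
        return np.searchsorted(train_cats, gene_codes[mask])

    syn_idx = recode(syn_rows)
    a_g = np.full(n_genes, bmm.alpha) + np.bincount(
        syn_idx, weights=counts[syn_rows].astype(float), minlength=n_genes)
    b_g = np.full(n_genes, bmm.alpha) + np.bincount(
        syn_idx, weights=mu[syn_rows], minlength=n_genes)

    y = counts[ns_rows].astype(float)
    Xf = sites.fn_matrix(feats)[ns_rows]
    args = (y, mu[ns_rows], Xf, recode(ns_rows), a_g, b_g)

    theta0 = np.zeros(1 + Xf.shape[1])
    trace: list = []

    def cb(xk):
        trace.append(-_smm_negloglik_and_grad(xk, *args)[0])

    res = minimize(
        _smm_negloglik_and_grad, theta0, args=args, jac=True,
        method="L-BFGS-B", callback=cb,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
    )
    report = ConvergenceReport(
        converged=bool(res.success),
        n_iter=int(res.nit),
        grad_norm=float(np.max(np.abs(res.jac))),
        loglik=float(-res.fun),
        loglik_trace=trace,
    )
    if not res.success and np.max(np.abs(res.jac)) > 1e-2 * max(1.0, abs(res.fun)):
        raise RuntimeError(f"SMM fit ({hypothesis}) did not converge: {res.message}")

    se = None
    if compute_se:
        se = _se_from_grad(_smm_negloglik_and_grad, res.x, args)
        if se is None:
            msg = f"singular Hessian in SMM fit ({hypothesis}); SEs missing"
            logger.warning(msg)
            report.warnings_.append(msg)
    return SMMParams(
        hypothesis=hypothesis,
        beta0_f=float(res.x[0]),
        beta_f=res.x[1:],
        feature_names=feats,
        se=se,
        report=report,
    )


# ---------------------------------------------------------------------------
# cross-tumor empirical-Bayes shrinkage


@dataclass
class ShrinkageResult:
    """Normal-means shrinkage of one coefficient across tumor types."""

    raw: np.ndarray
    se: np.ndarray
    prior_mean: float
    prior_var: float          # tau^2 >= 0
    shrunk: np.ndarray

    def __post_init__(self):
        if self.prior_var < 0:
            raise ValueError("prior variance must be non-negative")


def shrink_smm_models(models_by_tumor: dict) -> dict:
    """Stabilise per-tumor selection models of one hypothesis by shrinking
    every coefficient across tumor types.

    Takes ``{tumor: SMMParams}`` fitted independently per tumor (with SEs)
    and returns a parallel dict whose coefficients are the empirical-Bayes
    posterior means; reported SEs are left at their raw values.
    """
    tumors = list(models_by_tumor)
    if not tumors:
        return {}
    first = models_by_tumor[tumors[0]]
    feats = list(first.feature_names)
    hyp = first.hypothesis
    for m in models_by_tumor.values():
        if list(m.feature_names) != feats or m.hypothesis != hyp:
            raise ValueError("models must share hypothesis and feature set")
        if m.se is None:
            raise ValueError("shrinkage needs standard errors for every tumor")
    coef = np.array([[m.beta0_f, *m.beta_f] for m in models_by_tumor.values()])
    ses = np.array([np.asarray(m.se, dtype=float) for m in models_by_tumor.values()])
    shrunk = np.column_stack([
        shrink_across_tumors(coef[:, j], ses[:, j]).shrunk
        for j in range(coef.shape[1])
    ])
    return {
        t: SMMParams(hyp, float(shrunk[i, 0]), shrunk[i, 1:], feats,
                     se=models_by_tumor[t].se)
        for i, t in enumerate(tumors)
    }


def shrink_across_tumors(estimates, ses) -> ShrinkageResult:
    """Shrink per-tumor coefficient estimates toward their common mean.

    Model: raw_k ~ Normal(truth_k, se_k^2), truth_k ~ Normal(m, tau^2); the
    hyperparameters are fit by marginal maximum likelihood with tau^2 >= 0,
    and posterior means pull each tumor toward m with weight proportional to
    its sampling variance.  A single tumor is returned unshrunk with a
    warning.
    """
    raw = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if raw.shape != se.shape:
        raise ValueError("estimates and SEs must be aligned")
    if len(raw) < 2:
        logger.warning("fewer than 2 tumors: returning estimates unshrunk")
        return ShrinkageResult(raw, se, float(raw.mean()) if len(raw) else 0.0,
                               0.0, raw.copy())
    if not np.isfinite(se).all():
        raise ValueError("all standard errors must be finite")

    v = se ** 2

    def negll(params):
        m, log_tau2 = params
        tau2 = np.exp(log_tau2)
        tot = tau2 + v
        return 0.5 * np.sum(np.log(tot) + (raw - m) ** 2 / tot)

    spread = max(raw.var(ddof=0), 1e-12)
    best = None
    for log_t0 in (np.log(spread), np.log(spread) - 4, np.log(spread) + 2):
        res = minimize(negll, np.array([raw.mean(), log_t0]),
                       method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    m, tau2 = best.x[0], float(np.exp(best.x[1]))
    # degenerate prior: all mass at m
    if tau2 < 1e-12 * max(1.0, np.max(v)):
        tau2 = 0.0
        shrunk = np.full_like(raw, m)
    else:
        w = tau2 / (tau2 + v)
        shrunk = m + w * (raw - m)
    return ShrinkageResult(raw, se, float(m), tau2, shrunk)
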