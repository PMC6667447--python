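"""Gene-level evidence: Bayes factors, driver fraction, Bayesian FDR.

For each gene the marginal likelihood of its non-synonymous counts (given
its synonymous data) is computed under the null, oncogene, and tumor
suppressor models; the Bayes factor

    BF_g = [0.5 P(Y|OG) + 0.5 P(Y|TSG)] / P(Y|H0)

weighs the driver hypotheses equally.  A two-group mixture over the BFs
gives a maximum-likelihood estimate of the driver-gene fraction pi, per-gene
posterior driver probabilities, and a Bayesian FDR (running mean of local
false-discovery probabilities down the BF-ranked list) used for calling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp, xlogy

from .bmm import BMMParams, GenePosterior, background_rate
from .smm import SMMParams, ns_conditional_loglik, selection_effect
from .spatial_hmm import GeneChain, HMMParams, hmm_marginal_loglik_many
from .mutation_data import SiteTable

logger = logging.getLogger(__name__)

LOG10 = np.log(10.0)

RESULT_COLUMNS = [
    "gene_id", "n_syn", "n_nonsyn", "loglik_H0", "loglik_OG", "loglik_TSG",
    "log10_bf", "pp", "qvalue", "called", "driver_class",
]


@dataclass
class InferenceConfig:
    fdr_threshold: float = 0.1
    prior_og_weight: float = 0.5

    def __post_init__(self):
        if not 0 <= self.prior_og_weight <= 1:
            raise ValueError("prior OG weight must be in [0, 1]")


def _build_chains(sites: SiteTable, counts, mu, gamma, alpha):
    """One GeneChain per gene (ordered by gene code) under a given gamma."""
    df = sites.df
    gene_codes, gene_ids = sites.gene_index()
    syn = sites.is_syn
    counts = np.asarray(counts, dtype=float)
    n_genes = len(gene_ids)

    y_syn = np.bincount(gene_codes[syn], weights=counts[syn], minlength=n_genes)
    mu_syn = np.bincount(gene_codes[syn], weights=mu[syn], minlength=n_genes)

    pos = df["pos"].to_numpy()
    ns = ~syn
    chains = []
    order = np.argsort(gene_codes, kind="stable")
    bounds = np.searchsorted(gene_codes[order], np.arange(n_genes + 1))
    eff = mu * gamma
    for g in range(n_genes):
        rows = order[bounds[g]:bounds[g + 1]]
        gp = pos[rows]
        all_pos = np.unique(gp)
        nrows = rows[ns[rows]]
        idx = np.searchsorted(all_pos, pos[nrows])
        S = np.bincount(idx, weights=eff[nrows], minlength=len(all_pos))
        C = np.bincount(idx, weights=counts[nrows], minlength=len(all_pos))
        D = float(np.sum(xlogy(counts[nrows], eff[nrows]) - gammaln(counts[nrows] + 1.0)))
        chains.append(
            GeneChain(S=S, C=C, D_total=D,
                      posterior=GenePosterior(alpha + y_syn[g], alpha + mu_syn[g]))
        )
    return chains, gene_ids


def _nonspatial_logliks(chains) -> np.ndarray:
    from .spatial_hmm import _nonspatial_loglik

    return np.array([_nonspatial_loglik(c) for c in chains])


def _hypothesis_logliks(sites, counts, mu, bmm, smm, hmm=None):
    gamma = selection_effect(sites, smm)
    chains, gene_ids = _build_chains(sites, counts, mu, gamma, bmm.alpha)
    if hmm is not None and not hmm.no_hotspot:
        ll = hmm_marginal_loglik_many(chains, hmm)
    else:
        ll = _nonspatial_logliks(chains)
    return ll, gene_ids


def gene_bayes_factors(sites: SiteTable, counts, bmm: BMMParams,
                       smm_h0: SMMParams, smm_og: SMMParams, smm_tsg: SMMParams,
                       hmm_og: HMMParams | None = None,
                       hmm_tsg: HMMParams | None = None,
                       og_weight: float = 0.5) -> pd.DataFrame:
    """Per-gene hypothesis log-likelihoods and log10 Bayes factors.

    The null likelihood is the non-spatial conditional marginal; the driver
    likelihoods use the spatial model when a fitted HMM without the
    no-hotspot flag is supplied.  Genes with no non-synonymous opportunity
    get BF = 1 (no evidence either way) with a warning.
    """
    counts = np.asarray(counts)
    mu = background_rate(sites, bmm)
    ll_h0, gene_ids = _hypothesis_logliks(sites, counts, mu, bmm, smm_h0)
    ll_og, _ = _hypothesis_logliks(sites, counts, mu, bmm, smm_og, hmm_og)
    ll_tsg, _ = _hypothesis_logliks(sites, counts, mu, bmm, smm_tsg, hmm_tsg)

    log_bf = (
        logsumexp(
            np.stack([ll_og, ll_tsg]),
            axis=0,
            b=np.array([[og_weight], [1.0 - og_weight]]),
        )
        - ll_h0
    )
    gene_codes, _ = sites.gene_index()
    syn = sites.is_syn
    n_genes = len(gene_ids)
    n_syn = np.bincount(gene_codes[syn], weights=counts[syn].astype(float),
                        minlength=n_genes).astype(int)
    n_ns = np.bincount(gene_codes[~syn], weights=counts[~syn].astype(float),
                       minlength=n_genes).astype(int)
    ns_opportunity = np.bincount(gene_codes[~syn], minlength=n_genes)
    no_ns = ns_opportunity == 0
    if no_ns.any():
        logger.warning("%d genes with zero NS opportunity: BF set to 1", no_ns.sum())
        log_bf[no_ns] = 0.0
    driver_class = np.where(ll_og >= ll_tsg, "OG", "TSG")
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "n_syn": n_syn,
            "n_nonsyn": n_ns,
            "loglik_H0": ll_h0,
            "loglik_OG": ll_og,
            "loglik_TSG": ll_tsg,
            "log10_bf": log_bf / LOG10,
            "driver_class": driver_class,
        }
    )


def estimate_driver_fraction(log10_bfs) -> float:
    """ML estimate of the driver-gene proportion from the BF two-group
    mixture: maximise sum_g log(pi * BF_g + 1 - pi) over pi in [0, 1]."""
    log_bf = np.asarray(log10_bfs, dtype=float) * LOG10
    if len(log_bf) == 0:
        raise ValueError("need at least one gene")
    if np.all(np.abs(log_bf) < 1e-12):
        logger.warning("all Bayes factors equal 1: likelihood flat in pi, returning 0")
        return 0.0

    def negll(pi):
        if pi <= 0:
            return 0.0
        if pi >= 1:
            return -float(np.sum(log_bf))
        return -float(np.sum(np.logaddexp(np.log(pi) + log_bf, np.log1p(-pi))))

    res = minimize_scalar(negll, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-10})
    pi = float(res.x)
    # check the boundaries explicitly (bounded Brent never lands on them)
    for cand in (0.0, 1.0):
        if negll(cand) < res.fun:
            pi = cand
    return pi


def posterior_and_fdr(results: pd.DataFrame, pi: float,
                      fdr_threshold: float = 0.1) -> pd.DataFrame:
    """Posterior driver probabilities, Bayesian FDR, and the called set.

    pp_g = pi*BF_g / (pi*BF_g + 1 - pi); genes are ranked by BF (ties broken
    by gene id) and the q-value at rank k is the mean local false-discovery
    probability (1 - pp) of the top k; the called set is the largest prefix
    with q-value <= threshold.
    """
    if not 0 <= pi <= 1:
        raise ValueError("pi must lie in [0, 1]")
    df = results.sort_values(["log10_bf", "gene_id"],
                             ascending=[False, True], kind="stable").copy()
    log_bf = df["log10_bf"].to_numpy() * LOG10
    if pi == 0.0:
        pp = np.zeros(len(df))
    elif pi == 1.0:
        pp = np.ones(len(df))
    else:
        logit = np.log(pi) - np.log1p(-pi) + log_bf
        pp = 1.0 / (1.0 + np.exp(-logit))
    df["pp"] = pp
    q = np.cumsum(1.0 - pp) / np.arange(1, len(df) + 1)
    # running mean of non-increasing pp is monotone; enforce exactly against
    # floating-point wiggle
    df["qvalue"] = np.maximum.accumulate(q)
    df["called"] = df["qvalue"] <= fdr_threshold
    return df.reset_index(drop=True)


def score_genes(sites, counts, bmm, smm_h0, smm_og, smm_tsg,
                hmm_og=None, hmm_tsg=None, fdr_threshold: float = 0.1,
                og_weight: float = 0.5, fdr_exclude=()) -> pd.DataFrame:
    """Full gene classification: BFs, pi, posterior probabilities, FDR calls.

    ``fdr_exclude`` lists genes (typically the training drivers) that are
    not discovery candidates: they still get Bayes factors and posterior
    probabilities, but are left out of the driver-fraction estimate and of
    the FDR ranking.  Keeping known drivers in the ranked list would dilute
    the running-mean q-value with their near-zero local false-discovery
    probabilities and silently degrade FDR control among the genes one can
    actually discover.
    """
    res = gene_bayes_factors(sites, counts, bmm, smm_h0, smm_og, smm_tsg,
                             hmm_og, hmm_tsg, og_weight)
    excluded = res["gene_id"].isin(set(fdr_exclude))
    candidates = res[~excluded]
    pi = estimate_driver_fraction(candidates["log10_bf"])
    out = posterior_and_fdr(candidates, pi, fdr_threshold)
    if excluded.any():
        rest = posterior_and_fdr(res[excluded.to_numpy()], pi, fdr_threshold)
        rest["qvalue"] = np.nan
        rest["called"] = False
        out = pd.concat([out, rest], ignore_index=True)
    out.attrs["pi"] = pi
    return out[RESULT_COLUMNS + []]


def leave_one_gene_out(target_gene: str, sites, counts, bmm,
                       og_genes, tsg_genes, fit_fn, fdr_threshold: float = 0.1):
    """Score ``target_gene`` with models retrained without it.

    ``fit_fn(og_genes, tsg_genes)`` must retrain the selection (and spatial)
    models on the reduced lists and return
    ``(smm_h0, smm_og, smm_tsg, hmm_og, hmm_tsg)``.  Returns the target's
    result row from the rerun.
    """
    og, tsg = list(og_genes), list(tsg_genes)
    if target_gene in og:
        og.remove(target_gene)
    elif target_gene in tsg:
        tsg.remove(target_gene)
    else:
        raise ValueError(f"{target_gene!r} is not in any training list")
    models = fit_fn(og, tsg)
    res = score_genes(sites, counts, bmm, *models, fdr_threshold=fdr_threshold)
    row = res[res["gene_id"] == target_gene]
    if row.empty:
        raise ValueError(f"{target_gene!r} absent from the site table")
    return row.iloc[0]


def leave_one_gene_out_batch(sites, counts, bmm, og_genes, tsg_genes,
                             fit_fn, fdr_threshold: float = 0.1) -> pd.DataFrame:
    """Run the leave-one-gene-out protocol over every training gene."""
    rows = []
    for gene in list(og_genes) + list(tsg_genes):
        rows.append(leave_one_gene_out(gene, sites, counts, bmm,
                                       og_genes, tsg_genes, fit_fn, fdr_threshold))
    return pd.DataFrame(rows).reset_index(drop=True)
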