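"""Ground-truth simulation of somatic mutation data.

Two designs are covered.  The *single-gene power study* simulates one gene
under positive selection (uniform rate increase plus rare mutation
hotspots) and measures the power of simple tests — a dN/dS-style likelihood
ratio, a 3-bp clustering statistic, and their Fisher combination.  The
*genome-wide benchmark* simulates an exome of genes with known driver
labels: negative-binomial background mutations whose rates vary by
trinucleotide context (deliberately richer than the nine-type inference
model), a hotspot Markov chain (entry 1e-5/bp, mean length 5 bp), and
driver selection multipliers of 3x outside hotspots and 3000x inside, with
independent Normal(0, 0.2^2) noise on the log selection strength of every
site.  Feature-dependent selection and withholding features from the
analysis add further, realistic, model misspecification.

Everything is bit-reproducible given a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .mutation_data import BASES, SiteTable

logger = logging.getLogger(__name__)

BG_FEATURES = ["expr", "reptime", "hic"]
FN_FEATURES = ["lof", "cons", "sift", "phylop", "ma"]

#: marginal frequency of each binary functional feature on NS rows
FN_FREQS = {"lof": 0.05, "cons": 0.30, "sift": 0.30, "phylop": 0.30, "ma": 0.30}

#: per-type relative background rates (CpG transitions dominate, as in
#: real exomes); scaled to the target cohort rate at simulation time
TYPE_RELATIVE_RATE = {
    1: 10.0, 2: 1.2, 3: 1.0, 4: 2.0, 5: 1.0, 6: 0.8, 7: 0.6, 8: 1.5, 9: 0.5,
}

#: effect of each background feature on the log mutation rate
BG_SIM_COEFFS = {"expr": -0.3, "reptime": 0.3, "hic": 0.2}

#: functional-feature selection coefficients per driver role (log scale);
#: the inference step is given only lof/cons/ma, so sift/phylop act as
#: unmodeled selection heterogeneity
ROLE_FN_COEFFS = {
    "TSG": {"lof": 2.0, "cons": 0.5, "sift": 0.3, "phylop": 0.3, "ma": 0.5},
    "OG": {"lof": -1.5, "cons": 0.8, "sift": 0.3, "phylop": 0.3, "ma": 0.8},
}

MISSPEC_FEATURES = ["lof", "cons", "ma"]  # the subset given to the caller


@dataclass
class SimConfig:
    """Study conditions of the genome-wide benchmark simulation."""

    n_genes: int = 2000
    n_samples: int = 500
    mean_gene_len: int = 500
    n_tsg: int = 17
    n_og: int = 13
    bg_model: str = "context192"        # or "ninetype"
    nb_shape: float = 3.0               # gene-level Gamma mixing (var/mean ~ 1.5)
    hotspot_freq: float = 1e-5
    hotspot_mean_len: float = 5.0
    sel_nonhotspot: float = 3.0
    sel_hotspot: float = 3000.0
    site_noise_sd: float = 0.2
    mut_rate_per_mb_per_sample: float = 8.0
    feature_selection: bool = True      # driver selection depends on fn features
    seed: int = 0

    def __post_init__(self):
        if self.bg_model not in ("context192", "ninetype"):
            raise ValueError("bg_model must be 'context192' or 'ninetype'")
        for name in ("nb_shape", "hotspot_mean_len", "sel_nonhotspot",
                     "sel_hotspot", "mut_rate_per_mb_per_sample"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path):
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


@dataclass
class SimTruth:
    """Ground truth aligned with the emitted site table."""

    roles: pd.Series                 # gene_id -> {"neutral", "OG", "TSG"}
    hotspot: np.ndarray              # per site-table row, bool
    multiplier: np.ndarray           # per row true selection multiplier
    gene_effect: pd.Series           # gene_id -> simulated lambda_g
    bg_mean: np.ndarray | None = None  # per row true background mean rate

    def to_tsv(self, gene_path, site_df: pd.DataFrame, site_path):
        pd.DataFrame({"gene_id": self.roles.index, "role": self.roles.values,
                      "gene_effect": self.gene_effect.reindex(self.roles.index).values}
                     ).to_csv(gene_path, sep="\t", index=False)
        out = site_df[["gene_id", "chrom", "pos", "ref", "alt"]].copy()
        out["hotspot"] = self.hotspot.astype(int)
        out["multiplier"] = self.multiplier
        out.to_csv(site_path, sep="\t", index=False)


@dataclass
class SimDataset:
    sites: SiteTable
    counts: np.ndarray
    records: pd.DataFrame            # MAF-like per-sample mutation list
    truth: SimTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# fixture


def make_genome_fixture(n_genes: int, mean_gene_len: int = 500,
                        seed: int | np.random.Generator = 0) -> SiteTable:
    """Synthetic exome: genes of variable length with reference sequence,
    nine-type labels, ~3:1 NS:S opportunity, gene-level background features,
    and binary functional features on NS rows."""
    if n_genes < 1:
        raise ValueError("need at least one gene")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths = np.maximum(30, rng.normal(mean_gene_len, 0.25 * mean_gene_len,
                                        n_genes).round().astype(int))
    gene_ids = np.array([f"g{i:05d}" for i in range(n_genes)])
    base_arr = np.array(list(BASES))
    # the 3 alternate alleles for each reference base code
    alt_table = np.array([[b for b in range(4) if b != r] for r in range(4)])

    # per-position arrays over the whole exome
    gene_of_pos = np.repeat(np.arange(n_genes), lengths)
    n_pos = int(lengths.sum())
    seq_codes = rng.integers(0, 4, n_pos + 2 * n_genes)  # one flank per gene end
    # offsets so each gene reads its own stretch (with private flanks)
    gene_starts = np.concatenate([[0], np.cumsum(lengths + 2)[:-1]])
    within = np.arange(n_pos) - np.repeat(np.cumsum(lengths) - lengths, lengths)
    idx = gene_starts[gene_of_pos] + within + 1
    ref_codes = seq_codes[idx]
    c5_codes = seq_codes[idx - 1]
    c3_codes = seq_codes[idx + 1]
    # genomic coordinates: genes laid end to end with 10 kb gaps
    genome_starts = 1000 + np.concatenate([[0], np.cumsum(lengths[:-1] + 10_000)])
    pos = genome_starts[gene_of_pos] + within

    # expand to 3 alt rows per position
    rows_gene = np.repeat(gene_of_pos, 3)
    rows_pos = np.repeat(pos, 3)
    rows_ref = np.repeat(ref_codes, 3)
    rows_alt = alt_table[ref_codes].reshape(-1)
    rows_c5 = np.repeat(c5_codes, 3)
    rows_c3 = np.repeat(c3_codes, 3)
    base_cat = lambda codes: pd.Categorical.from_codes(codes, list(BASES))
    n = len(rows_pos)
    df = pd.DataFrame({
        "gene_id": pd.Categorical.from_codes(rows_gene, list(gene_ids)),
        "chrom": pd.Categorical.from_codes(np.zeros(n, dtype=np.int8), ["chr1"]),
        "pos": rows_pos,
        "ref": base_cat(rows_ref),
        "alt": base_cat(rows_alt),
        "context5": base_cat(rows_c5),
        "context3": base_cat(rows_c3),
    })
    from .mutation_data import _TYPE_TABLE

    df["mutation_type"] = _TYPE_TABLE[rows_ref, rows_alt, rows_c5, rows_c3].astype(int)
    df["impact"] = pd.Categorical.from_codes(
        (rng.random(n) >= 0.25).astype(np.int8), ["S", "NS"])

    # gene-level background covariates, constant across a gene's rows
    gene_bg = {f: rng.normal(size=n_genes) for f in BG_FEATURES}
    for f in BG_FEATURES:
        df[f"bg:{f}"] = gene_bg[f][rows_gene]

    ns_mask = (df["impact"] == "NS").to_numpy()
    for f in FN_FEATURES:
        col = np.zeros(n, dtype=int)
        col[ns_mask] = (rng.random(ns_mask.sum()) < FN_FREQS[f]).astype(int)
        df[f"fn:{f}"] = col
    return SiteTable(df, bg_features=list(BG_FEATURES), fn_features=list(FN_FEATURES))


def simulate_hotspots(gene_lengths, hotspot_freq: float, hotspot_mean_len: float,
                      seed: int | np.random.Generator = 0):
    """Hotspot indicator per position for each gene, from a two-state Markov
    chain started at stationarity (entry prob ``hotspot_freq``, exit prob
    ``1/hotspot_mean_len``).  Returns a list of boolean arrays."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = float(hotspot_freq)
    e = 1.0 / float(hotspot_mean_len)
    out = []
    for L in gene_lengths:
        ind = np.zeros(int(L), dtype=bool)
        if q > 0:
            p_hot = q / (q + e)
            state = rng.random() < p_hot
            pos = 0
            while pos < L:
                run = rng.geometric(e if state else q)
                if state:
                    ind[pos:pos + run] = True
                pos += run
                state = not state
        out.append(ind)
    return out


# ---------------------------------------------------------------------------
# counts


def _context192_multipliers(rng, sd: float = 0.5) -> np.ndarray:
    """Random per-(c5, ref, c3, alt) log-normal rate multipliers.

    Centered so each multiplier has mean 1; the variation across contexts is
    what makes the nine-type inference model misspecified."""
    m = rng.lognormal(mean=-0.5 * sd ** 2, sigma=sd, size=(4, 4, 4, 4))
    return m


def _encode_bases(values) -> np.ndarray:
    lut = np.zeros(256, dtype=np.int8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    return lut[np.frombuffer("".join(values).encode(), dtype=np.uint8)]


def background_mean_rates(sites: SiteTable, config: SimConfig,
                          rng: np.random.Generator) -> np.ndarray:
    """Per-row expected background count for the whole cohort."""
    df = sites.df
    mu = np.array([TYPE_RELATIVE_RATE[t] for t in range(1, 10)])[
        df["mutation_type"].to_numpy() - 1].astype(float)
    if config.bg_model == "context192":
        mult = _context192_multipliers(rng)
        mu = mu * mult[
            _encode_bases(df["context5"]),
            _encode_bases(df["ref"]),
            _encode_bases(df["context3"]),
            _encode_bases(df["alt"]),
        ]
    for f in BG_FEATURES:
        mu = mu * np.exp(BG_SIM_COEFFS[f] * df[f"bg:{f}"].to_numpy())
    # cohort-aggregated per-bp rate, spread over the 3 alt rows of a position
    target_row_rate = (config.mut_rate_per_mb_per_sample * 1e-6
                       * config.n_samples / 3.0)
    return mu * (target_row_rate / mu.mean())


def assign_roles(gene_ids, n_tsg: int, n_og: int,
                 rng: np.random.Generator) -> pd.Series:
    gene_ids = list(gene_ids)
    drivers = rng.choice(len(gene_ids), size=n_tsg + n_og, replace=False)
    roles = pd.Series("neutral", index=gene_ids, name="role")
    roles.iloc[drivers[:n_tsg]] = "TSG"
    roles.iloc[drivers[n_tsg:]] = "OG"
    return roles


def simulate_counts(sites: SiteTable, roles: pd.Series, config: SimConfig,
                    rng: np.random.Generator):
    """Draw the aggregate count vector, per-sample records, and truth.

    Background counts are Poisson given a gene-level Gamma effect (i.e.
    negative binomial per gene); driver genes' NS rates are multiplied by
    the hotspot-dependent selection strength with per-site log-normal noise.
    """
    if config.nb_shape <= 0:
        raise ValueError("negative-binomial overdispersion must be positive")
    df = sites.df
    mu = background_mean_rates(sites, config, rng)

    gene_codes, gene_ids = sites.gene_index()
    n_genes = len(gene_ids)
    lam_g = rng.gamma(config.nb_shape, 1.0 / config.nb_shape, size=n_genes)

    # hotspots over each gene's positions
    pos = df["pos"].to_numpy()
    lengths, first_row = [], []
    hot_rows = np.zeros(len(df), dtype=bool)
    order = np.argsort(gene_codes, kind="stable")
    bounds = np.searchsorted(gene_codes[order], np.arange(n_genes + 1))
    gene_pos_arrays = []
    for g in range(n_genes):
        rows = order[bounds[g]:bounds[g + 1]]
        upos = np.unique(pos[rows])
        gene_pos_arrays.append((rows, upos))
        lengths.append(len(upos))
    hot_tracks = simulate_hotspots(lengths, config.hotspot_freq,
                                   config.hotspot_mean_len, rng)
    for (rows, upos), track in zip(gene_pos_arrays, hot_tracks):
        idx = np.searchsorted(upos, pos[rows])
        hot_rows[rows] = track[idx]

    # selection multipliers
    mult = np.ones(len(df))
    ns = ~sites.is_syn
    role_by_row = roles.reindex(df["gene_id"]).to_numpy()
    for role in ("TSG", "OG"):
        sel_rows = ns & (role_by_row == role)
        if not sel_rows.any():
            continue
        log_sel = np.where(hot_rows[sel_rows],
                           np.log(config.sel_hotspot),
                           np.log(config.sel_nonhotspot))
        if config.feature_selection:
            coeffs = ROLE_FN_COEFFS[role]
            Xf = sites.fn_matrix(FN_FEATURES)[sel_rows]
            log_sel = log_sel + Xf @ np.array([coeffs[f] for f in FN_FEATURES])
        log_sel = log_sel + rng.normal(0.0, config.site_noise_sd, sel_rows.sum())
        mult[sel_rows] = np.exp(log_sel)

    rate = mu * lam_g[gene_codes] * mult
    counts = rng.poisson(rate)

    records = _counts_to_records(df, counts, config.n_samples, rng)
    truth = SimTruth(
        roles=roles,
        hotspot=hot_rows,
        multiplier=mult,
        gene_effect=pd.Series(lam_g, index=gene_ids),
        bg_mean=mu,
    )
    return counts, records, truth


def _counts_to_records(df, counts, n_samples: int, rng) -> pd.DataFrame:
    """Carve aggregate counts into per-sample MAF-like rows (uniform
    multinomial assignment across samples)."""
    nz = np.flatnonzero(counts)
    reps = counts[nz]
    rows = np.repeat(nz, reps)
    samples = rng.integers(0, n_samples, rows.size)
    return pd.DataFrame({
        "sample_id": np.char.add("s", samples.astype(str)),
        "chrom": df["chrom"].to_numpy()[rows],
        "pos": df["pos"].to_numpy()[rows],
        "ref": df["ref"].to_numpy()[rows],
        "alt": df["alt"].to_numpy()[rows],
    })


def simulate_dataset(config: SimConfig) -> SimDataset:
    """End-to-end genome simulation under a config (fixture, roles, counts)."""
    rng = np.random.default_rng(config.seed)
    sites = make_genome_fixture(config.n_genes, config.mean_gene_len, rng)
    gene_ids = sites.df["gene_id"].unique()
    roles = assign_roles(gene_ids, config.n_tsg, config.n_og, rng)
    counts, records, truth = simulate_counts(sites, roles, config, rng)
    return SimDataset(sites, counts, records, truth, config)


# ---------------------------------------------------------------------------
# simple per-gene tests (power-study comparators)


def dnds_test(y_ns: float, mu_ns: float, gamma_alt: float, null_draws) -> float:
    """Likelihood-ratio statistic for an excess of non-synonymous mutations,
    T = Poisson(y; mu*gamma) / Poisson(y; mu) with gamma fixed at the
    alternative, against an empirical null with the +1/(N+1) correction.
    ``null_draws`` must contain log-statistics (:func:`dnds_log_statistic`)
    of null datasets."""
    if mu_ns <= 0:
        raise ValueError("total NS background rate must be positive")
    null_draws = np.asarray(null_draws, dtype=float)
    if null_draws.size == 0:
        raise ValueError("need non-empty null draws")
    t_obs = dnds_log_statistic(y_ns, mu_ns, gamma_alt)
    return (1.0 + np.sum(null_draws >= t_obs)) / (null_draws.size + 1.0)


def dnds_statistic(y_ns, mu_ns, gamma_alt: float):
    """T = exp(-mu (gamma-1)) * gamma^y; monotone in y for gamma > 1."""
    return np.exp(dnds_log_statistic(y_ns, mu_ns, gamma_alt))


def dnds_log_statistic(y_ns, mu_ns, gamma_alt: float):
    """log T; used for comparisons so large counts cannot overflow."""
    y_ns = np.asarray(y_ns, dtype=float)
    return -mu_ns * (gamma_alt - 1.0) + y_ns * np.log(gamma_alt)


def cluster_statistic(positions, total_rate: float, window: int = 3):
    """Max number of mutations in any sliding ``window``-bp interval,
    normalised by the gene's total mutation rate."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if total_rate <= 0:
        raise ValueError("total mutation rate must be positive")
    positions = np.sort(np.asarray(positions))
    if positions.size == 0:
        return 0.0
    # two-pointer sweep: count mutations with position in [p, p+window-1]
    best = 1
    j = 0
    for i in range(positions.size):
        while positions[i] - positions[j] > window - 1:
            j += 1
        best = max(best, i - j + 1)
    return best / total_rate


def cluster_test(positions, total_rate: float, null_draws, window: int = 3) -> float:
    """Empirical p-value of the 3-bp clustering statistic."""
    null_draws = np.asarray(null_draws, dtype=float)
    if null_draws.size == 0:
        raise ValueError("need non-empty null draws")
    t_obs = cluster_statistic(positions, total_rate, window)
    return (1.0 + np.sum(null_draws >= t_obs)) / (null_draws.size + 1.0)


def fisher_combine(p1: float, p2: float) -> float:
    """Fisher's method on two p-values (chi-squared with 4 df)."""
    for p in (p1, p2):
        if not (0 < p <= 1):
            raise ValueError("p-values must lie in (0, 1]")
    X = -2.0 * (np.log(p1) + np.log(p2))
    return float(chi2.sf(X, 4))


# ---------------------------------------------------------------------------
# single-gene power study


@dataclass
class PowerStudyConfig:
    gene_len: int = 4023        # an ERBB3-sized coding sequence
    sample_grid: tuple = (200, 500, 1000)
    n_replicates: int = 500
    n_type1_replicates: int | None = None   # default: same as n_replicates
    n_null: int = 5000
    hotspot_freq: float = 1e-5
    hotspot_mean_len: float = 5.0
    sel_nonhotspot: float = 3.0
    sel_hotspot: float = 3000.0
    mut_rate_per_mb_per_sample: float = 8.0
    nb_shape: float = 3.0
    seed: int = 0


def _single_gene_draw(mu, ns_mask, hot, cfg: PowerStudyConfig, rng, selected: bool):
    """One aggregate count vector for the study gene."""
    lam = rng.gamma(cfg.nb_shape, 1.0 / cfg.nb_shape)
    rate = mu * lam
    if selected:
        sel = np.where(hot, cfg.sel_hotspot, cfg.sel_nonhotspot)
        rate = np.where(ns_mask, rate * sel, rate)
    return rng.poisson(rate)


def power_study(cfg: PowerStudyConfig) -> pd.DataFrame:
    """Power (p < 0.05) of the dN/dS, cluster, and Fisher-combined tests
    across a cohort-size grid, plus their type-I error on null replicates.

    One gene fixture is drawn once; hotspot locations are redrawn per
    selected replicate.  Null statistic distributions are simulated from
    the background model at each cohort size.
    """
    rng = np.random.default_rng(cfg.seed)
    sites = make_genome_fixture(1, cfg.gene_len, rng)
    df = sites.df
    ns_mask = ~sites.is_syn
    pos = df["pos"].to_numpy()
    gene_len = int(pos.max() - pos.min() + 1)
    pos0 = pos - pos.min()
    rows_out = []
    for n_samples in cfg.sample_grid:
        sim_cfg = SimConfig(
            n_genes=1, n_samples=n_samples,
            mut_rate_per_mb_per_sample=cfg.mut_rate_per_mb_per_sample,
            bg_model="context192", nb_shape=cfg.nb_shape,
        )
        mu = background_mean_rates(sites, sim_cfg, rng)
        mu_ns_total = mu[ns_mask].sum()
        rate_total = mu.sum()

        def stats_from_counts(y):
            y_ns = y[ns_mask].sum()
            t_d = dnds_log_statistic(y_ns, mu_ns_total, cfg.sel_nonhotspot)
            mut_pos = np.repeat(pos[ns_mask], y[ns_mask])
            t_c = cluster_statistic(mut_pos, rate_total) if mut_pos.size else 0.0
            return t_d, t_c

        null_d = np.empty(cfg.n_null)
        null_c = np.empty(cfg.n_null)
        for k in range(cfg.n_null):
            y = _single_gene_draw(mu, ns_mask, None, cfg, rng, selected=False)
            null_d[k], null_c[k] = stats_from_counts(y)

        def pvals(y):
            y_ns = y[ns_mask].sum()
            p_d = dnds_test(y_ns, mu_ns_total, cfg.sel_nonhotspot, null_d)
            mut_pos = np.repeat(pos[ns_mask], y[ns_mask])
            p_c = cluster_test(mut_pos, rate_total, null_c)
            return p_d, p_c, fisher_combine(p_d, p_c)

        hits = np.zeros(3)
        for _ in range(cfg.n_replicates):
            hot_pos = simulate_hotspots([gene_len], cfg.hotspot_freq,
                                        cfg.hotspot_mean_len, rng)[0]
            hot = hot_pos[pos0]
            y = _single_gene_draw(mu, ns_mask, hot, cfg, rng, selected=True)
            hits += np.array(pvals(y)) < 0.05
        n_t1 = cfg.n_type1_replicates or cfg.n_replicates
        t1 = np.zeros(3)
        for _ in range(n_t1):
            y = _single_gene_draw(mu, ns_mask, None, cfg, rng, selected=False)
            t1 += np.array(pvals(y)) < 0.05
        rows_out.append({
            "n_samples": n_samples,
            "power_dnds": hits[0] / cfg.n_replicates,
            "power_cluster": hits[1] / cfg.n_replicates,
            "power_combined": hits[2] / cfg.n_replicates,
            "type1_dnds": t1[0] / n_t1,
            "type1_cluster": t1[1] / n_t1,
            "type1_combined": t1[2] / n_t1,
        })
    return pd.DataFrame(rows_out)


# ---------------------------------------------------------------------------
# benchmark scoring


def run_benchmark(roles: pd.Series, caller_tables: dict, fdr_threshold: float = 0.1,
                  training_genes=(), score_col: str = "log10_bf") -> pd.DataFrame:
    """Score caller outputs against simulation truth on test-set genes.

    ``caller_tables`` maps a caller name to a results table with columns
    ``gene_id``, a score column, and optionally ``called``; genes missing
    from a table are treated as not called with the lowest score.  Training
    genes are excluded before computing TP/FP, the realised false-discovery
    proportion, and the ROC curve.
    """
    training = set(training_genes)
    test_genes = [g for g in roles.index if g not in training]
    labels = (roles.loc[test_genes] != "neutral").to_numpy()
    out = []
    for name, tab in caller_tables.items():
        tab = tab.set_index("gene_id")
        missing = [g for g in test_genes if g not in tab.index]
        if missing:
            logger.warning("caller %s missing %d genes: treated as not called",
                           name, len(missing))
        scores = tab[score_col].reindex(test_genes).fillna(-np.inf).to_numpy()
        if "called" in tab.columns:
            called = tab["called"].reindex(test_genes).fillna(False).astype(bool).to_numpy()
        else:
            called = tab["qvalue"].reindex(test_genes).to_numpy() <= fdr_threshold
        tp = int(np.sum(called & labels))
        fp = int(np.sum(called & ~labels))
        fdp = fp / max(tp + fp, 1)
        order = np.argsort(-scores, kind="stable")
        tps = np.cumsum(labels[order])
        fps = np.cumsum(~labels[order])
        tpr = tps / max(labels.sum(), 1)
        fpr = fps / max((~labels).sum(), 1)
        auroc = float(np.trapezoid(tpr, fpr))
        out.append({"caller": name, "n_test": len(test_genes), "tp": tp,
                    "fp": fp, "n_called": tp + fp, "fdp": fdp, "auroc": auroc,
                    "roc_fpr": fpr, "roc_tpr": tpr})
    return pd.DataFrame(out)
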