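"""End-to-end orchestration: sequential estimation and scoring.

The estimation order mirrors the model's conditional structure and is
enforced: the background model is fit on synonymous mutations from all
genes and then frozen; the selection models (null, oncogene, tumor
suppressor) are fit on non-synonymous mutations from their training genes;
the spatial models are fit last with everything else fixed; finally every
gene is scored by Bayes factor and called at a Bayesian FDR threshold.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bmm as bmm_mod
from . import inference, simulate, smm as smm_mod, spatial_hmm
from .mutation_data import SiteTable, aggregate_counts, load_mutations

logger = logging.getLogger(__name__)

#: fraction of each training list used when splitting simulated drivers into
#: training and test (mirrors a 124-of-324 training design)
TRAIN_FRACTION = 124 / 324


@dataclass
class RunConfig:
    """File-level configuration of a single-tumor-type analysis run."""

    sites: str
    mutations: str
    og_list: str
    tsg_list: str
    out_dir: str
    fn_features: list | None = None      # None = all declared in the site table
    use_features: bool = True
    use_hmm: bool = True
    pool_driver_models: bool = False
    shrinkage: str = "normal-eb"         # {"normal-eb", "none"} (multi-tumor runs)
    fdr_threshold: float = 0.1
    hypermutator_max: object = "auto"
    seed: int = 0

    def validate(self):
        for name in ("sites", "mutations", "og_list", "tsg_list"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        if self.shrinkage not in ("normal-eb", "none"):
            raise ValueError("shrinkage must be 'normal-eb' or 'none'")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)


def read_gene_list(path) -> list:
    return [ln.strip() for ln in Path(path).read_text().splitlines()
            if ln.strip() and not ln.startswith("#")]


@dataclass
class FittedModels:
    bmm: bmm_mod.BMMParams
    smm: dict                      # hypothesis -> SMMParams
    hmm: dict = field(default_factory=dict)  # hypothesis -> HMMParams | None


def _training_chains(sites, counts, mu, gamma, alpha, gene_mask):
    """GeneChains restricted to the rows of the training genes."""
    sub = SiteTable(sites.df[gene_mask].copy(), sites.bg_features, sites.fn_features)
    chains, _ = inference._build_chains(sub, np.asarray(counts)[gene_mask],
                                        mu[gene_mask], gamma[gene_mask], alpha)
    return chains


def fit_all_models(sites: SiteTable, counts, og_genes, tsg_genes, *,
                   fn_features=None, use_features: bool = True,
                   use_hmm: bool = True, pool_driver_models: bool = False,
                   compute_se: bool = False) -> FittedModels:
    """Sequential estimation: background, then selection, then spatial."""
    feats = list(fn_features) if fn_features is not None else list(sites.fn_features)
    if not use_features:
        feats = []
    bg = bmm_mod.fit_bmm(sites, counts, compute_se=compute_se)

    def fit(hyp, mask=None):
        return smm_mod.fit_smm(sites, counts, bg, hyp, og_genes, tsg_genes,
                               fn_features=feats, gene_mask=mask,
                               compute_se=compute_se)

    smm_h0 = fit("H0")
    if pool_driver_models:
        pooled_mask = smm_mod.training_gene_mask(sites, og_genes, tsg_genes, "OG") | \
            smm_mod.training_gene_mask(sites, og_genes, tsg_genes, "TSG")
        pooled = fit("OG", mask=pooled_mask)
        smm_og = pooled
        smm_tsg = smm_mod.SMMParams("TSG", pooled.beta0_f, pooled.beta_f.copy(),
                                    list(pooled.feature_names), se=pooled.se)
    else:
        smm_og = fit("OG")
        smm_tsg = fit("TSG")

    hmm = {"OG": None, "TSG": None}
    if use_hmm:
        mu = bmm_mod.background_rate(sites, bg)
        for hyp, sm, genes in (("OG", smm_og, og_genes), ("TSG", smm_tsg, tsg_genes)):
            mask = smm_mod.training_gene_mask(sites, og_genes, tsg_genes, hyp)
            gamma = smm_mod.selection_effect(sites, sm)
            chains = _training_chains(sites, counts, mu, gamma, bg.alpha, mask)
            hmm[hyp] = spatial_hmm.fit_hmm(chains, hyp)
    return FittedModels(bmm=bg, smm={"H0": smm_h0, "OG": smm_og, "TSG": smm_tsg},
                        hmm=hmm)


def analyze(sites: SiteTable, counts, og_genes, tsg_genes, *,
            fn_features=None, use_features: bool = True, use_hmm: bool = True,
            pool_driver_models: bool = False, fdr_threshold: float = 0.1,
            compute_se: bool = False, exclude_training_from_fdr: bool = True):
    """Fit everything and score all genes.  Returns (results, models).

    By default the training drivers are kept out of the FDR ranking (they
    are known, not discoverable); disable with
    ``exclude_training_from_fdr=False``.
    """
    models = fit_all_models(
        sites, counts, og_genes, tsg_genes, fn_features=fn_features,
        use_features=use_features, use_hmm=use_hmm,
        pool_driver_models=pool_driver_models, compute_se=compute_se)
    exclude = (list(og_genes) + list(tsg_genes)
               if exclude_training_from_fdr else ())
    results = inference.score_genes(
        sites, counts, models.bmm, models.smm["H0"], models.smm["OG"],
        models.smm["TSG"], models.hmm.get("OG"), models.hmm.get("TSG"),
        fdr_threshold=fdr_threshold, fdr_exclude=exclude)
    return results, models


def _feature_digest(names) -> str:
    return hashlib.sha256("\t".join(names).encode()).hexdigest()[:16]


def run_full_analysis(config: RunConfig) -> pd.DataFrame:
    """File-level pipeline: load, filter, fit, score, and write outputs."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sites = SiteTable.from_tsv(config.sites).validate()
    records, sample_report = load_mutations(config.mutations, config.hypermutator_max)
    counts, unmatched = aggregate_counts(records, sites)
    og = read_gene_list(config.og_list)
    tsg = read_gene_list(config.tsg_list)

    results, models = analyze(
        sites, counts, og, tsg, fn_features=config.fn_features,
        use_features=config.use_features, use_hmm=config.use_hmm,
        pool_driver_models=config.pool_driver_models,
        fdr_threshold=config.fdr_threshold)

    models.bmm.to_file(out / "bmm_model.yaml")
    smm_mod.write_smm_file(out / "smm_model.yaml", list(models.smm.values()))
    fitted_hmms = [h for h in models.hmm.values() if h is not None]
    if fitted_hmms:
        spatial_hmm.write_hmm_file(out / "hmm_model.yaml", fitted_hmms)
    results.to_csv(out / "results.tsv", sep="\t", index=False)
    sample_report.to_tsv(out / "sample_report.tsv")

    log = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in config.__dict__.items()},
        "bg_feature_digest": _feature_digest(sites.bg_features),
        "fn_feature_digest": _feature_digest(sites.fn_features),
        "n_sites": len(sites),
        "n_genes": sites.n_genes,
        "n_records_kept": len(records),
        "n_unmatched": unmatched.n_unmatched,
        "n_reference_mismatch": unmatched.n_reference_mismatch,
        "pi": float(results.attrs.get("pi", float("nan"))),
        "n_called": int(results["called"].sum()),
        "hmm": {h: (m.to_dict() if m else None) for h, m in models.hmm.items()},
    }
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=False)
    return results


def check_model_compatibility(bmm: bmm_mod.BMMParams, sites: SiteTable):
    """Refuse a background model whose feature declaration differs from the
    site table's (stage-ordering guard for file-based runs)."""
    if list(bmm.feature_names) != list(sites.bg_features):
        raise ValueError(
            "background-model features "
            f"{bmm.feature_names} do not match the site table's {sites.bg_features}")


# ---------------------------------------------------------------------------
# simulation study


def training_split(roles: pd.Series, rng, train_fraction: float = TRAIN_FRACTION):
    """Split simulated drivers into training and held-out test lists."""
    og_all = sorted(roles.index[roles == "OG"])
    tsg_all = sorted(roles.index[roles == "TSG"])
    n_og = int(round(train_fraction * len(og_all)))
    n_tsg = int(round(train_fraction * len(tsg_all)))
    og_train = sorted(rng.choice(og_all, size=n_og, replace=False)) if n_og else []
    tsg_train = sorted(rng.choice(tsg_all, size=n_tsg, replace=False)) if n_tsg else []
    return list(og_train), list(tsg_train)


@dataclass
class StudyResult:
    results: pd.DataFrame
    benchmark: pd.DataFrame
    dataset: simulate.SimDataset
    og_train: list
    tsg_train: list


def run_simulation_study(sim_config: simulate.SimConfig, *,
                         fn_features=simulate.MISSPEC_FEATURES,
                         use_hmm: bool = True,
                         fdr_threshold: float = 0.1) -> StudyResult:
    """Simulate a genome, run the full pipeline on it with the deliberately
    restricted feature set, and score calls against the simulation truth
    (training genes excluded from the benchmark)."""
    ds = simulate.simulate_dataset(sim_config)
    rng = np.random.default_rng(sim_config.seed + 1_000_003)
    og_train, tsg_train = training_split(ds.truth.roles, rng)
    results, _ = analyze(ds.sites, ds.counts, og_train, tsg_train,
                         fn_features=fn_features, use_hmm=use_hmm,
                         fdr_threshold=fdr_threshold)
    bench = simulate.run_benchmark(
        ds.truth.roles, {"drivermaps": results}, fdr_threshold,
        training_genes=og_train + tsg_train)
    return StudyResult(results, bench, ds, og_train, tsg_train)
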