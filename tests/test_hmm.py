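"""Spatial hotspot HMM: limits, oracle equivalence, decoding, model test."""

import numpy as np
import pytest

import drivermaps as dm
from drivermaps.bmm import GenePosterior
from drivermaps.smm import ns_conditional_loglik
from drivermaps.spatial_hmm import (
    GeneChain,
    HMMParams,
    build_gene_chain,
    fit_hmm,
    hmm_marginal_loglik,
    hotspot_posterior,
    spatial_model_test,
    _nonspatial_loglik,
)

from oracles import enumerate_spatial_loglik


def random_chain(rng, n_pos=None, max_pos=8):
    n = n_pos or int(rng.integers(1, max_pos + 1))
    S = rng.uniform(0.01, 0.8, n)
    C = rng.poisson(0.6, n).astype(float)
    from scipy.special import gammaln, xlogy

    D = float(np.sum(xlogy(C, S) - gammaln(C + 1.0)))
    return GeneChain(S=S, C=C, D_total=D,
                     posterior=GenePosterior(rng.uniform(0.5, 6.0),
                                             rng.uniform(0.5, 6.0)))


class TestLimitIdentities:
    def test_rho_one_equals_nonspatial(self, rng):
        for _ in range(25):
            chain = random_chain(rng)
            hmm = HMMParams(1e-4, 5.0, 1.0)
            assert hmm_marginal_loglik(chain, hmm) == pytest.approx(
                _nonspatial_loglik(chain), abs=1e-10)

    def test_no_entry_equals_nonspatial(self, rng):
        for _ in range(25):
            chain = random_chain(rng)
            hmm = HMMParams(0.0, 5.0, 50.0)
            assert hmm_marginal_loglik(chain, hmm) == pytest.approx(
                _nonspatial_loglik(chain), abs=1e-10)

    def test_nonspatial_equals_conditional_closed_form(self, rng):
        chain = random_chain(rng, n_pos=6)
        direct = ns_conditional_loglik(chain.C, chain.S, np.ones(6), chain.posterior)
        assert _nonspatial_loglik(chain) == pytest.approx(direct, rel=1e-12)


class TestForwardVsEnumeration:
    def test_matches_brute_force_up_to_twelve_positions(self, rng):
        for trial in range(30):
            chain = random_chain(rng, max_pos=12)
            q = float(rng.uniform(1e-4, 0.2))
            L = float(rng.uniform(2.0, 8.0))
            rho = float(rng.uniform(1.5, 80.0))
            got = hmm_marginal_loglik(chain, HMMParams(q, L, rho))
            want = enumerate_spatial_loglik(
                chain.S, chain.C, chain.D_total,
                chain.posterior.a, chain.posterior.b, q, L, rho)
            assert got == pytest.approx(want, rel=1e-8, abs=1e-8)

    def test_two_position_gene(self, rng):
        chain = random_chain(rng, n_pos=2)
        got = hmm_marginal_loglik(chain, HMMParams(0.05, 4.0, 20.0))
        want = enumerate_spatial_loglik(chain.S, chain.C, chain.D_total,
                                        chain.posterior.a, chain.posterior.b,
                                        0.05, 4.0, 20.0)
        assert got == pytest.approx(want, rel=1e-8)

    def test_continuity_and_monotonicity_in_rho(self, rng):
        # all mutations on one low-rate position: while the expected hotspot
        # count stays below the observed one, raising rho helps
        chain = GeneChain(S=np.full(5, 0.005), C=np.array([0, 0, 4.0, 0, 0]),
                          D_total=0.0, posterior=GenePosterior(2.0, 2.0))
        hmm = lambda r: HMMParams(1e-3, 5.0, r)
        lls = [hmm_marginal_loglik(chain, hmm(r)) for r in (1.0, 1.001, 5, 20, 100)]
        assert lls[1] == pytest.approx(lls[0], abs=1e-2)
        assert np.all(np.diff(lls[1:]) > 0)


class TestBuildGeneChain:
    def test_aggregates_alleles_onto_positions(self):
        chain = build_gene_chain(
            positions=[10, 10, 11], ns_counts=[1, 2, 0],
            ns_effective_rates=[0.1, 0.2, 0.3],
            posterior=GenePosterior(1.0, 1.0), all_positions=[9, 10, 11])
        np.testing.assert_allclose(chain.S, [0.0, 0.3, 0.3])
        np.testing.assert_allclose(chain.C, [0.0, 3.0, 0.0])

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError):
            build_gene_chain([10], [1], [0.1], GenePosterior(1, 1),
                             all_positions=[11, 10])


class TestHotspotPosterior:
    def test_rho_one_returns_stationary_fraction(self, rng):
        chain = random_chain(rng, n_pos=7)
        hmm = HMMParams(0.01, 5.0, 1.0)
        track = hotspot_posterior(chain, hmm)
        assert np.allclose(track, hmm.stationary_hotspot_fraction, atol=1e-10)

    def test_single_position_matches_hand_computation(self):
        S, C = np.array([0.2]), np.array([2.0])
        post = GenePosterior(50.0, 50.0)  # effectively lam = 1
        hmm = HMMParams(0.1, 5.0, 10.0)
        track = hotspot_posterior(GeneChain(S, C, 0.0, post), hmm)
        p_hot = hmm.stationary_hotspot_fraction
        w_hot = p_hot * np.exp(2 * np.log(10.0) - 0.2 * 10.0)
        w_bg = (1 - p_hot) * np.exp(-0.2)
        assert track[0] == pytest.approx(w_hot / (w_hot + w_bg), abs=2e-2)

    def test_recurrent_run_lights_up_inside(self):
        S = np.full(30, 0.02)
        C = np.zeros(30)
        C[12:15] = 3.0  # a dense cluster of recurrent mutations
        chain = GeneChain(S, C, 0.0, GenePosterior(5.0, 5.0))
        hmm = HMMParams(1e-3, 3.0, 200.0)
        track = hotspot_posterior(chain, hmm)
        assert track[12:15].mean() > 10 * np.delete(track, [12, 13, 14]).mean()
        assert np.all((track >= 0) & (track <= 1))

    def test_no_hotspot_flag_returns_zeros(self, rng):
        chain = random_chain(rng, n_pos=4)
        hmm = HMMParams(0.0, 5.0, 1.0, no_hotspot=True)
        assert np.all(hotspot_posterior(chain, hmm) == 0)


def _hotspot_sim(rho, seed, n_genes=150):
    return dm.SimConfig(
        n_genes=n_genes, n_samples=4000, mean_gene_len=300, n_tsg=n_genes,
        n_og=0, bg_model="ninetype", hotspot_freq=1e-3, hotspot_mean_len=5.0,
        sel_nonhotspot=1.0, sel_hotspot=rho, site_noise_sd=0.0,
        feature_selection=False, seed=seed)


def _chains_for(ds, genes=None):
    from drivermaps.bmm import fit_bmm, background_rate
    from drivermaps.workflow import _training_chains

    bmm = fit_bmm(ds.sites, ds.counts, compute_se=False)
    mu = background_rate(ds.sites, bmm)
    mask = np.ones(len(ds.sites), dtype=bool)
    if genes is not None:
        mask = ds.sites.df["gene_id"].isin(genes).to_numpy()
    return _training_chains(ds.sites, ds.counts, mu, np.ones(len(ds.sites)),
                            bmm.alpha, mask)


class TestFitHMM:
    def test_recovers_hotspot_intensity_roughly(self):
        hits = 0
        for seed in range(6):
            ds = dm.simulate_dataset(_hotspot_sim(rho=50.0, seed=100 + seed))
            fit = fit_hmm(_chains_for(ds), "TSG")
            if not fit.no_hotspot and 50.0 / 2.5 <= fit.rho <= 50.0 * 2.5:
                hits += 1
        assert hits >= 4

    def test_flat_selection_raises_no_hotspot_flag(self):
        flags = 0
        for seed in range(4):
            ds = dm.simulate_dataset(dm.SimConfig(
                n_genes=60, n_samples=1000, mean_gene_len=300, n_tsg=0,
                n_og=0, bg_model="ninetype", hotspot_freq=0.0, seed=200 + seed))
            fit = fit_hmm(_chains_for(ds), "TSG")
            flags += fit.no_hotspot
        assert flags >= 3

    def test_zero_mutation_training_gene_flags(self):
        chain = GeneChain(np.full(10, 0.01), np.zeros(10), 0.0,
                          GenePosterior(1.0, 1.0))
        fit = fit_hmm([chain], "OG")
        assert fit.no_hotspot


class TestSpatialModelTest:
    def test_identical_likelihoods(self):
        stat, p = spatial_model_test(-10.0, -10.0)
        assert stat == 0.0 and p == 1.0

    def test_negative_statistic_is_an_error(self):
        with pytest.raises(RuntimeError):
            spatial_model_test(-11.0, -10.0)

    def test_strong_hotspots_separate_from_neutral_null(self, rng):
        """Median spatial LRT under strong hotspots exceeds the neutral 95th
        percentile (power sanity at small replicate count)."""

        def lrt(ds):
            chains = _chains_for(ds)
            fit = fit_hmm(chains, "TSG")
            ll1 = (np.sum(dm.spatial_hmm.hmm_marginal_loglik_many(chains, fit))
                   if not fit.no_hotspot else
                   sum(_nonspatial_loglik(c) for c in chains))
            ll0 = sum(_nonspatial_loglik(c) for c in chains)
            return spatial_model_test(ll1, ll0)[0]

        neutral = [lrt(dm.simulate_dataset(_hotspot_sim(1.0, 300 + s, n_genes=40)))
                   for s in range(8)]
        strong = [lrt(dm.simulate_dataset(_hotspot_sim(300.0, 400 + s, n_genes=40)))
                  for s in range(8)]
        assert np.median(strong) > np.quantile(neutral, 0.95)
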