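"""Simulator: determinism, hotspot chain laws, rates, and the simple tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import drivermaps as dm
from drivermaps.simulate import (
    PowerStudyConfig,
    SimConfig,
    cluster_statistic,
    cluster_test,
    dnds_statistic,
    dnds_test,
    fisher_combine,
    make_genome_fixture,
    run_benchmark,
    simulate_dataset,
    simulate_hotspots,
)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = SimConfig(n_genes=30, n_samples=200, mean_gene_len=200, n_tsg=3,
                        n_og=2, seed=13)
        a, b = simulate_dataset(cfg), simulate_dataset(cfg)
        np.testing.assert_array_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.records, b.records)
        pd.testing.assert_frame_equal(a.sites.df, b.sites.df)
        np.testing.assert_array_equal(a.truth.hotspot, b.truth.hotspot)

    def test_different_seed_differs(self):
        a = simulate_dataset(SimConfig(n_genes=30, n_samples=200,
                                       mean_gene_len=200, seed=13))
        b = simulate_dataset(SimConfig(n_genes=30, n_samples=200,
                                       mean_gene_len=200, seed=14))
        assert not np.array_equal(a.counts, b.counts)


class TestFixture:
    def test_three_alt_rows_per_position(self):
        sites = make_genome_fixture(10, 100, seed=3)
        sizes = sites.df.groupby(["chrom", "pos"], observed=True).size()
        assert (sizes == 3).all()
        sites.validate()

    def test_mean_gene_length(self):
        sites = make_genome_fixture(1000, 300, seed=4)
        lens = sites.df.groupby("gene_id", observed=True)["pos"].nunique()
        assert abs(lens.mean() - 300) / 300 < 0.1

    def test_ns_to_s_opportunity_ratio(self):
        sites = make_genome_fixture(200, 300, seed=5)
        impact = sites.df["impact"].value_counts()
        assert impact["NS"] / impact["S"] == pytest.approx(3.0, rel=0.1)


class TestHotspots:
    def test_zero_frequency_means_no_hotspots(self):
        tracks = simulate_hotspots([1000] * 5, 0.0, 5.0, seed=1)
        assert not any(t.any() for t in tracks)

    def test_stationary_fraction_law(self):
        tracks = simulate_hotspots([10_000_000], 1e-3, 5.0, seed=2)
        frac = tracks[0].mean()
        expected = 1e-3 / (1e-3 + 0.2)
        assert frac == pytest.approx(expected, rel=0.1)

    def test_mean_run_length_law(self):
        track = simulate_hotspots([10_000_000], 1e-3, 5.0, seed=3)[0].astype(int)
        changes = np.diff(np.concatenate([[0], track, [0]]))
        starts, ends = np.flatnonzero(changes == 1), np.flatnonzero(changes == -1)
        run_lengths = ends - starts
        assert run_lengths.mean() == pytest.approx(5.0, rel=0.1)


class TestSimulateCounts:
    def test_neutral_ns_and_s_rates_match(self):
        ds = simulate_dataset(SimConfig(
            n_genes=400, n_samples=2000, mean_gene_len=400, n_tsg=0, n_og=0,
            seed=6))
        syn = ds.sites.is_syn
        rate_s = ds.counts[syn].mean()
        rate_ns = ds.counts[~syn].mean()
        assert rate_ns / rate_s == pytest.approx(1.0, abs=0.1)

    def test_flat_threefold_driver_enrichment(self):
        """Driver NS rate is ~3x the neutral NS rate under flat selection
        with hotspots and noise switched off (million-row scale)."""
        ds = simulate_dataset(SimConfig(
            n_genes=900, n_samples=2000, mean_gene_len=400, n_tsg=300,
            n_og=0, hotspot_freq=0.0, site_noise_sd=0.0,
            feature_selection=False, seed=8))
        ns = ~ds.sites.is_syn
        driver_rows = ds.sites.df["gene_id"].isin(
            ds.truth.roles.index[ds.truth.roles == "TSG"]).to_numpy()
        ratio = (ds.counts[ns & driver_rows].mean()
                 / ds.counts[ns & ~driver_rows].mean())
        assert ratio == pytest.approx(3.0, rel=0.1)

    def test_background_counts_overdispersed(self):
        ds = simulate_dataset(SimConfig(
            n_genes=500, n_samples=3000, mean_gene_len=300, n_tsg=0, n_og=0,
            seed=9))
        per_gene = pd.DataFrame({
            "g": ds.sites.df["gene_id"], "y": ds.counts,
        }).groupby("g", observed=True)["y"].sum()
        assert per_gene.var() > per_gene.mean()

    def test_records_consistent_with_counts(self):
        ds = simulate_dataset(SimConfig(n_genes=50, n_samples=100,
                                        mean_gene_len=200, seed=10))
        assert len(ds.records) == ds.counts.sum()


class TestSimpleTests:
    def test_dnds_statistic_at_zero_counts(self):
        mu = 1.7
        assert dnds_statistic(0, mu, 3.0) == pytest.approx(np.exp(-2 * mu))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(0.1, 10.0), st.integers(0, 30))
    def test_dnds_statistic_monotone_in_counts(self, mu, y):
        assert dnds_statistic(y + 1, mu, 3.0) > dnds_statistic(y, mu, 3.0)

    def test_dnds_pvalue_near_one_for_zero_counts(self, rng):
        from drivermaps.simulate import dnds_log_statistic

        null = dnds_log_statistic(rng.poisson(2.0, 2000), 2.0, 3.0)
        assert dnds_test(0, 2.0, 3.0, null) > 0.9

    def test_cluster_statistic_counts_windows(self):
        assert cluster_statistic([10, 11, 12], 1.0) == 3.0
        assert cluster_statistic([10, 50, 90], 1.0) == 1.0
        # single mutation: 1 / total rate regardless of position
        assert cluster_statistic([77], 2.0) == 0.5
        assert cluster_statistic([3], 2.0) == 0.5

    def test_cluster_counts_recurrent_hits(self):
        assert cluster_statistic([10, 10, 10], 1.0) == 3.0

    def test_fisher_identities(self):
        assert fisher_combine(1.0, 1.0) == pytest.approx(1.0)
        assert fisher_combine(0.3, 0.7) == fisher_combine(0.7, 0.3)
        with pytest.raises(ValueError):
            fisher_combine(0.0, 0.5)

    def test_fisher_with_uninformative_partner_never_helps(self):
        for p in np.linspace(0.001, 0.5, 30):
            assert fisher_combine(p, 1.0) >= p


class TestBenchmark:
    def _roles(self, rng, n=2000, n_driver=60):
        roles = pd.Series("neutral", index=[f"g{i}" for i in range(n)])
        idx = rng.choice(n, n_driver, replace=False)
        roles.iloc[idx] = "TSG"
        return roles

    def test_perfect_caller(self, rng):
        roles = self._roles(rng)
        tab = pd.DataFrame({
            "gene_id": roles.index,
            "log10_bf": (roles != "neutral").astype(float) * 10,
            "called": roles != "neutral",
        })
        out = run_benchmark(roles, {"oracle": tab}).iloc[0]
        assert out.auroc == pytest.approx(1.0)
        assert out.fdp == 0.0 and out.fp == 0

    def test_random_caller_auroc_near_half(self, rng):
        # 324 of 2000 positive: null AUROC sd ~ 0.02, so [0.45, 0.55] is wide
        roles = self._roles(rng, n=2000, n_driver=324)
        tab = pd.DataFrame({
            "gene_id": roles.index,
            "log10_bf": rng.normal(size=len(roles)),
            "called": np.zeros(len(roles), dtype=bool),
        })
        out = run_benchmark(roles, {"random": tab}).iloc[0]
        assert 0.45 <= out.auroc <= 0.55

    def test_training_exclusion_set_algebra(self, rng):
        roles = self._roles(rng, n=200, n_driver=20)
        training = list(roles.index[roles == "TSG"][:10])
        tab = pd.DataFrame({
            "gene_id": roles.index,
            "log10_bf": rng.normal(size=len(roles)),
            "called": np.ones(len(roles), dtype=bool),
        })
        out = run_benchmark(roles, {"x": tab}, training_genes=training).iloc[0]
        assert out.n_test == 190
        assert out.tp + out.fp == 190  # every test gene called, none invented

    def test_missing_genes_treated_as_not_called(self, rng):
        roles = self._roles(rng, n=100, n_driver=10)
        tab = pd.DataFrame({
            "gene_id": roles.index[:50],
            "log10_bf": np.ones(50),
            "called": np.ones(50, dtype=bool),
        })
        out = run_benchmark(roles, {"partial": tab}).iloc[0]
        assert out.tp + out.fp == (roles.index[:50].size)


class TestPowerStudySmoke:
    def test_tiny_power_study_runs_and_orders(self):
        cfg = PowerStudyConfig(gene_len=800, sample_grid=(800,),
                               n_replicates=60, n_null=300, seed=5)
        out = dm.power_study(cfg)
        assert len(out) == 1
        row = out.iloc[0]
        assert 0 <= row.power_combined <= 1
        assert row.power_dnds > row.type1_dnds
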