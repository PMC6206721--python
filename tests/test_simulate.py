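"""Synthetic-data generator: drift model, genotype sampling, LD blocks,
coordinate layouts and AIM ascertainment."""

import numpy as np
import pandas as pd
import pytest

from panelbias import simulate
from panelbias.simulate import (
    AdmixtureSpec,
    ConfigError,
    FrequencyPanel,
    SimConfig,
    SuperPop,
    ascertain_aims,
    assign_coordinates,
    inject_ld_blocks,
    simulate_dataset,
    simulate_frequencies,
    simulate_genotypes,
)


def two_pop_config(drift=0.05, seed=0, n=10, m=200, **kw):
    tree = {"SP1": SuperPop(drift=drift, pops={"A": drift, "B": drift})}
    return SimConfig(tree=tree, n_per_pop=n, m_snps=m, seed=seed, **kw)


class TestSimulateFrequencies:
    def test_zero_drift_limit_frequencies_equal_ancestral(self):
        cfg = two_pop_config(drift=1e-9, m=500)
        panel = simulate_frequencies(cfg)
        for pop in ("A", "B"):
            np.testing.assert_allclose(panel.pop_freq.loc[pop].to_numpy(),
                                       panel.ancestral_freq, atol=1e-3)

    def test_deterministic_given_seed(self):
        cfg = two_pop_config(seed=123)
        p1 = simulate_frequencies(cfg)
        p2 = simulate_frequencies(cfg)
        np.testing.assert_array_equal(p1.ancestral_freq, p2.ancestral_freq)
        pd.testing.assert_frame_equal(p1.pop_freq, p2.pop_freq)

    def test_drift_is_mean_preserving(self):
        # Beta(p(1-F)/F, (1-p)(1-F)/F) has mean p; over many sites the mean
        # deviation from the ancestral frequency is zero within Monte-Carlo
        # error.  SE of the mean deviation is bounded by sqrt(F*var(p(1-p)))/sqrt(m).
        cfg = two_pop_config(drift=0.05, m=50_000, seed=5)
        panel = simulate_frequencies(cfg)
        dev = panel.pop_freq.loc["A"].to_numpy() - panel.ancestral_freq
        se = dev.std(ddof=1) / np.sqrt(len(dev))
        assert abs(dev.mean()) < 3 * se

    def test_frequency_bounds_preserved(self):
        cfg = two_pop_config(drift=0.3, m=2000, seed=9)
        panel = simulate_frequencies(cfg)
        vals = panel.pop_freq.to_numpy()
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_invalid_drift_rejected(self):
        with pytest.raises(ConfigError):
            two_pop_config(drift=1.5)
        with pytest.raises(ConfigError):
            two_pop_config(drift=0.0)


class TestSimulateGenotypes:
    def _panel(self, freqs: dict[str, float | np.ndarray], m: int):
        rows = {k: np.full(m, v, dtype=float) if np.isscalar(v) else np.asarray(v)
                for k, v in freqs.items()}
        return FrequencyPanel(ancestral_freq=np.full(m, 0.5),
                              pop_freq=pd.DataFrame.from_dict(rows, orient="index"))

    def test_degenerate_frequencies(self):
        cfg = two_pop_config(n=8, m=4)
        panel = self._panel({"A": 0.0, "B": 1.0}, m=4)
        g = simulate_genotypes(panel, cfg)
        idx = g.pop_indices()
        assert (g.dosages[idx["A"]] == 0).all()
        assert (g.dosages[idx["B"]] == 2).all()

    def test_genotype_values_legal(self, small_sim):
        _, _, g = small_sim
        assert set(np.unique(g.dosages)) <= {0, 1, 2}

    def test_deterministic_given_seed(self):
        cfg = two_pop_config(seed=11)
        panel = simulate_frequencies(cfg)
        g1 = simulate_genotypes(panel, cfg)
        g2 = simulate_genotypes(panel, cfg)
        np.testing.assert_array_equal(g1.dosages, g2.dosages)

    def test_balanced_admixture_matches_source_mean(self):
        # C = 50/50 mix of A and B with identical frequencies: per-site mean
        # genotype of C should match A's within binomial Monte-Carlo error.
        tree = {"SP1": SuperPop(drift=1e-9, pops={"A": 1e-9, "B": 1e-9})}
        cfg = SimConfig(tree=tree, n_per_pop=200, m_snps=300, seed=3,
                        admixture_specs=[AdmixtureSpec("C", ("A", "B"), (0.5, 0.5))])
        panel = simulate_frequencies(cfg)
        g = simulate_genotypes(panel, cfg)
        idx = g.pop_indices()
        mean_a = g.dosages[idx["A"]].mean(axis=0)
        mean_c = g.dosages[idx["C"]].mean(axis=0)
        p = panel.ancestral_freq
        se = np.sqrt(2 * p * (1 - p) * 2 / cfg.n_per_pop)   # both means vary
        assert (np.abs(mean_a - mean_c) < 3.5 * se).mean() > 0.98

    def test_unknown_admixture_source_rejected(self):
        tree = {"SP1": SuperPop(drift=0.05, pops={"A": 0.05})}
        with pytest.raises(ConfigError):
            SimConfig(tree=tree, admixture_specs=[
                AdmixtureSpec("C", ("A", "NOPE"), (0.5, 0.5))])


class TestInjectLdBlocks:
    def test_noise_zero_gives_perfect_within_block_r2(self):
        from panelbias.prune import genotype_r2

        cfg = two_pop_config(n=30, m=20, seed=21)
        panel = simulate_frequencies(cfg)
        g = simulate_genotypes(panel, cfg)
        g2 = inject_ld_blocks(g, block_len=5, noise=0.0, seed=1)
        for start in range(0, 20, 5):
            for j in range(start + 1, start + 5):
                np.testing.assert_array_equal(g2.dosages[:, j],
                                              g2.dosages[:, start])
                if len(np.unique(g2.dosages[:, start])) > 1:
                    assert genotype_r2(g2.dosages[:, start],
                                       g2.dosages[:, j]) == pytest.approx(1.0)

    def test_block_len_one_is_identity(self, small_sim):
        _, _, g = small_sim
        g2 = inject_ld_blocks(g, block_len=1, noise=0.3, seed=5)
        np.testing.assert_array_equal(g.dosages, g2.dosages)

    def test_partial_noise_gives_intermediate_r2(self):
        from panelbias.prune import genotype_r2

        cfg = two_pop_config(n=50, m=2000, seed=31)
        panel = simulate_frequencies(cfg)
        g = simulate_genotypes(panel, cfg)
        g2 = inject_ld_blocks(g, block_len=2, noise=0.5, seed=2)
        within = [genotype_r2(g2.dosages[:, j], g2.dosages[:, j + 1])
                  for j in range(0, 2000, 2)]
        cross = [genotype_r2(g2.dosages[:, j], g2.dosages[:, j + 2])
                 for j in range(0, 1996, 4)]
        assert np.mean(cross) < np.mean(within) < 1.0


class TestAssignCoordinates:
    def test_uniform_spacing_constant(self):
        cfg = two_pop_config(n=2, m=100)
        panel = simulate_frequencies(cfg)
        g = simulate_genotypes(panel, cfg)
        g2 = assign_coordinates(g, "uniform", n_chrom=1, chrom_length=1_000_000)
        diffs = np.diff(g2.sites["pos"].to_numpy())
        assert len(set(diffs.tolist())) == 1

    def test_positions_strictly_increasing(self):
        cfg = two_pop_config(n=2, m=500)
        panel = simulate_frequencies(cfg)
        g = simulate_genotypes(panel, cfg)
        for layout in ("uniform", "clustered"):
            g2 = assign_coordinates(g, layout, n_chrom=3)
            for _, sub in g2.sites.groupby("chrom"):
                assert (np.diff(sub["pos"].to_numpy()) > 0).all()

    def test_clustered_packs_pairs_close(self):
        cfg = two_pop_config(n=2, m=400)
        panel = simulate_frequencies(cfg)
        g = simulate_genotypes(panel, cfg)
        gc = assign_coordinates(g, "clustered", cluster_span=10_000, gap=500_000,
                                snps_per_cluster=20)
        gu = assign_coordinates(g, "uniform", chrom_length=400 * 25_500)

        def frac_close(gm, dist=50_000):
            pos = gm.sites["pos"].to_numpy()
            n = 0
            tot = 0
            for i in range(len(pos)):
                for j in range(i + 1, len(pos)):
                    tot += 1
                    n += abs(pos[i] - pos[j]) <= dist
            return n / tot

        assert frac_close(gc) > 5 * frac_close(gu)

    def test_tiny_cluster_span_rejected(self):
        cfg = two_pop_config(n=2, m=50)
        panel = simulate_frequencies(cfg)
        g = simulate_genotypes(panel, cfg)
        with pytest.raises(ConfigError):
            assign_coordinates(g, "clustered", cluster_span=5, snps_per_cluster=20)


@pytest.fixture(scope="module")
def panel():
    cfg = simulate.studylike_config(seed=13, n_super=3, pops_per_super=2,
                                    m_snps=5000)
    return simulate_frequencies(cfg)


class TestAscertainAims:
    def test_full_aims_come_from_top_decile(self, panel):
        idx = ascertain_aims(panel, "maf_variance_top", fraction_aims=1.0,
                             n_sites=400, seed=1)
        score = simulate.maf_variance_of_panel(panel.pop_freq)
        decile_floor = np.quantile(score, 0.9)
        assert (score[idx] >= decile_floor - 1e-12).all()

    def test_no_duplicates_and_size(self, panel):
        idx = ascertain_aims(panel, "maf_variance_top", fraction_aims=0.5,
                             n_sites=1000, seed=2)
        assert len(idx) == 1000
        assert len(np.unique(idx)) == 1000

    def test_enrichment_raises_mean_variance(self, panel):
        score = simulate.maf_variance_of_panel(panel.pop_freq)
        wins = 0
        for seed in range(30):
            aim = ascertain_aims(panel, "maf_variance_top", fraction_aims=0.8,
                                 n_sites=500, seed=seed)
            rnd = ascertain_aims(panel, "maf_variance_top", fraction_aims=0.0,
                                 n_sites=500, seed=seed + 1000)
            wins += score[aim].mean() > score[rnd].mean()
        assert wins >= 29   # >= 95% of seeds

    def test_delta_pair_mode_targets_pair(self, panel):
        pair = ("SP1P1", "SP2P1")
        idx = ascertain_aims(panel, "delta_pair", fraction_aims=1.0,
                             n_sites=300, seed=3, pair=pair)
        delta = np.abs(panel.pop_freq.loc[pair[0]].to_numpy()
                       - panel.pop_freq.loc[pair[1]].to_numpy())
        assert delta[idx].mean() > 2 * delta.mean()

    def test_too_many_sites_rejected(self, panel):
        with pytest.raises(ValueError):
            ascertain_aims(panel, "maf_variance_top", 0.5, n_sites=10**6, seed=0)


def test_simulate_dataset_bit_reproducible():
    cfg = simulate.studylike_config(seed=99, n_super=2, pops_per_super=2,
                                    n_per_pop=5, m_snps=300)
    cfg.ld_block = (5, 0.2)
    p1, g1 = simulate_dataset(cfg)
    p2, g2 = simulate_dataset(cfg)
    np.testing.assert_array_equal(g1.dosages, g2.dosages)
    pd.testing.assert_frame_equal(g1.sites, g2.sites)
    pd.testing.assert_frame_equal(p1.pop_freq, p2.pop_freq)
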