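"""Allele frequencies, Hudson F_ST, f3/f4 and the block jackknife, checked
against hand computations and naive brute-force re-implementations."""

import numpy as np
import pandas as pd
import pytest

from panelbias import simulate
from panelbias.fstats import (
    AlleleFrequencyTable,
    allele_frequencies,
    block_jackknife,
    coordinate_blocks,
    f3,
    f3_scan,
    f4,
    fst_matrix,
    hudson_fst_pair,
)
from panelbias.io import MISSING
from conftest import make_matrix


def freq_table(freqs: dict, counts: dict | float, sites=None) -> AlleleFrequencyTable:
    """Build an AlleleFrequencyTable directly from frequency arrays."""
    fdf = pd.DataFrame.from_dict(
        {k: np.asarray(v, dtype=float) for k, v in freqs.items()}, orient="index")
    if np.isscalar(counts):
        cdf = pd.DataFrame(np.full(fdf.shape, float(counts)),
                           index=fdf.index, columns=fdf.columns)
    else:
        cdf = pd.DataFrame.from_dict(
            {k: np.asarray(v, dtype=float) for k, v in counts.items()},
            orient="index")
    if sites is None:
        sites = pd.DataFrame({"chrom": "1",
                              "pos": np.arange(1, fdf.shape[1] + 1)})
    return AlleleFrequencyTable(freq=fdf, count=cdf, sites=sites)


class TestAlleleFrequencies:
    def test_basic_count_and_frequency(self):
        g = make_matrix(np.array([[0], [1], [2]]))
        t = allele_frequencies(g)
        assert t.freq.loc["pop1"].iloc[0] == pytest.approx(0.5)
        assert t.count.loc["pop1"].iloc[0] == 6

    def test_missing_excluded(self):
        g = make_matrix(np.array([[0], [MISSING], [2]]))
        t = allele_frequencies(g)
        assert t.freq.loc["pop1"].iloc[0] == pytest.approx(0.5)
        assert t.count.loc["pop1"].iloc[0] == 4

    def test_all_missing_marked_undefined(self):
        g = make_matrix(np.array([[MISSING], [MISSING]]))
        t = allele_frequencies(g)
        assert t.count.loc["pop1"].iloc[0] == 0
        assert np.isnan(t.freq.loc["pop1"].iloc[0])


class TestHudsonFst:
    def test_complete_divergence_is_one(self):
        t = freq_table({"A": [0.0] * 5, "B": [1.0] * 5}, counts=20.0)
        r = hudson_fst_pair(t, "A", "B")
        assert r.estimate == pytest.approx(1.0)

    def test_identical_frequencies_large_n_is_zero(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.1, 0.9, 200)
        t = freq_table({"A": p, "B": p}, counts=1e9)
        r = hudson_fst_pair(t, "A", "B")
        assert abs(r.estimate) < 1e-6

    def test_hand_computed_single_site(self):
        # p1=0.2, p2=0.8, n=20 alleles each:
        # N = 0.36 - 2*(0.16/19) = 0.343158, D = 0.68 -> 0.504644
        t = freq_table({"A": [0.2], "B": [0.8]}, counts=20.0)
        r = hudson_fst_pair(t, "A", "B", blocks=np.zeros(1, dtype=int))
        n_exp = 0.36 - 2 * (0.16 / 19)
        assert r.estimate == pytest.approx(n_exp / 0.68)
        assert r.estimate == pytest.approx(0.5047, abs=5e-4)

    def test_matrix_symmetric_zero_diagonal(self, small_sim):
        _, _, g = small_sim
        t = allele_frequencies(g)
        m = fst_matrix(t)
        assert np.allclose(m, m.T)
        assert (np.diag(m) == 0).all()

    def test_split_population_near_zero(self):
        # two independent halves of one panmictic population: the
        # finite-sample correction makes the estimator unbiased at 0
        rng = np.random.default_rng(5)
        d = rng.binomial(2, rng.uniform(0.1, 0.9, 2000)[None, :],
                         size=(80, 2000)).astype(np.int8)
        g = make_matrix(d, populations=["A"] * 40 + ["B"] * 40)
        t = allele_frequencies(g)
        r = hudson_fst_pair(t, "A", "B")
        assert abs(r.estimate) < 3 * r.jackknife_se

    def test_duplicated_samples_overcorrect_deterministically(self):
        # literally duplicating the same samples under two labels removes the
        # between-sample noise the correction accounts for: the estimate is
        # exactly -1/(n_alleles - 1) and the jackknife SE is 0
        rng = np.random.default_rng(5)
        d = rng.binomial(2, rng.uniform(0.1, 0.9, 500)[None, :],
                         size=(40, 500)).astype(np.int8)
        g = make_matrix(np.vstack([d, d]),
                        populations=["A"] * 40 + ["B"] * 40)
        t = allele_frequencies(g)
        r = hudson_fst_pair(t, "A", "B")
        assert r.estimate == pytest.approx(-1 / 79)
        assert r.jackknife_se == pytest.approx(0.0, abs=1e-12)

    def test_structure_orders_pairs(self, small_sim):
        cfg, _, g = small_sim
        t = allele_frequencies(g)
        m = fst_matrix(t, populations=cfg.leaf_populations())
        within = m.loc["SP1P1", "SP1P2"]
        between = m.loc["SP1P1", "SP2P1"]
        assert between > within > 0


class TestBlockJackknife:
    def test_two_block_closed_form(self):
        values = np.array([1.0, 1.0, 3.0, 3.0])
        blocks = np.array([0, 0, 1, 1])
        est, se = block_jackknife(values, np.ones(4), blocks)
        assert est == pytest.approx(2.0)
        assert se == pytest.approx(1.0)

    def test_identical_blocks_zero_se(self):
        values = np.array([2.0] * 10)
        blocks = np.arange(10) // 2
        est, se = block_jackknife(values, np.ones(10), blocks)
        assert est == pytest.approx(2.0)
        assert se == pytest.approx(0.0)

    def test_single_block_rejected(self):
        with pytest.raises(ValueError):
            block_jackknife(np.ones(5), np.ones(5), np.zeros(5, dtype=int))

    def test_se_close_to_iid_analytic(self):
        # equal weights, iid values: jackknife SE should approximate sd/sqrt(m)
        rng = np.random.default_rng(11)
        ratios = []
        for _ in range(20):
            v = rng.normal(0, 1, 1000)
            blocks = np.arange(1000) // 20
            _, se = block_jackknife(v, np.ones(1000), blocks)
            ratios.append(se / (v.std(ddof=1) / np.sqrt(1000)))
        assert all(1 / 3 < r < 3 for r in ratios)

    def test_matches_brute_force_delete_one(self):
        rng = np.random.default_rng(3)
        v = rng.normal(0, 1, 60)
        w = rng.uniform(0.5, 2.0, 60)
        blocks = rng.integers(0, 6, 60)
        est, se = block_jackknife(v, w, blocks)
        # naive re-implementation
        W = w.sum()
        theta = (v * w).sum() / W
        uniq = np.unique(blocks)
        td, wj = [], []
        for b in uniq:
            keep = blocks != b
            td.append((v[keep] * w[keep]).sum() / w[keep].sum())
            wj.append(w[blocks == b].sum())
        td, wj = np.array(td), np.array(wj)
        g = len(uniq)
        h = W / wj
        tj = g * theta - ((1 - wj / W) * td).sum()
        var = np.sum((h * theta - (h - 1) * td - tj) ** 2 / (h - 1)) / g
        assert est == pytest.approx(theta, abs=1e-12)
        assert se == pytest.approx(np.sqrt(var), abs=1e-12)


class TestF3:
    def test_infinite_n_forced_arithmetic(self):
        t = freq_table({"A": [0.1, 0.1], "B": [0.9, 0.9], "C": [0.5, 0.5]},
                       counts=1e12)
        r = f3(t, "C", "A", "B", blocks=np.array([0, 1]))
        assert r.estimate == pytest.approx(-0.16, abs=1e-6)

    def test_equal_frequencies_zero(self):
        p = np.linspace(0.2, 0.8, 10)
        t = freq_table({"A": p, "B": p, "C": p}, counts=1e12)
        r = f3(t, "C", "A", "B")
        assert r.estimate == pytest.approx(0.0, abs=1e-9)

    def test_symmetry_in_sources(self, small_sim):
        _, _, g = small_sim
        t = allele_frequencies(g)
        r1 = f3(t, "SP1P1", "SP1P2", "SP2P1")
        r2 = f3(t, "SP1P1", "SP2P1", "SP1P2")
        assert r1.estimate == pytest.approx(r2.estimate, abs=1e-15)
        assert r1.jackknife_se == pytest.approx(r2.jackknife_se, abs=1e-15)

    def test_matches_brute_force_on_toy_table(self):
        # 6 sites, 3 populations, n=20 alleles everywhere, 2 blocks
        fa = [0.1, 0.3, 0.5, 0.7, 0.2, 0.6]
        fb = [0.9, 0.5, 0.4, 0.2, 0.8, 0.3]
        fc = [0.5, 0.4, 0.45, 0.5, 0.5, 0.4]
        t = freq_table({"A": fa, "B": fb, "C": fc}, counts=20.0)
        blocks = np.array([0, 0, 0, 1, 1, 1])
        r = f3(t, "C", "A", "B", blocks=blocks)
        # naive per-site formula + unweighted delete-one-block jackknife
        ts = [(c - a) * (c - b) - c * (1 - c) / 19
              for a, b, c in zip(fa, fb, fc)]
        est = np.mean(ts)
        d0 = np.mean(ts[3:])
        d1 = np.mean(ts[:3])
        tj = 2 * est - 0.5 * (d0 + d1)
        var = ((2 * est - d0 - tj) ** 2 + (2 * est - d1 - tj) ** 2) / 2
        assert r.estimate == pytest.approx(est, abs=1e-12)
        assert r.jackknife_se == pytest.approx(np.sqrt(var), abs=1e-12)

    def test_z_scores_consistent(self, small_sim):
        _, _, g = small_sim
        t = allele_frequencies(g)
        r = f3(t, "ADM1", "SP1P1", "SP2P1")
        if r.jackknife_se > 0:
            assert r.z_score == pytest.approx(r.estimate / r.jackknife_se)


class TestF4:
    def test_forced_arithmetic(self):
        t = freq_table({"A": [0.9] * 2, "B": [0.1] * 2, "C": [0.8] * 2,
                        "D": [0.2] * 2}, counts=1e12)
        r = f4(t, "A", "B", "C", "D", blocks=np.array([0, 1]))
        assert r.estimate == pytest.approx(0.48, abs=1e-9)

    def test_equal_first_pair_exactly_zero(self):
        p = np.linspace(0.1, 0.9, 8)
        q = p[::-1].copy()
        t = freq_table({"A": p, "B": p, "C": q, "D": p}, counts=20.0)
        r = f4(t, "A", "B", "C", "D")
        assert r.estimate == 0.0

    def test_antisymmetry_and_pair_swap(self, small_sim):
        _, _, g = small_sim
        t = allele_frequencies(g)
        pops = ("SP1P1", "SP1P2", "SP2P1", "SP2P2")
        r = f4(t, *pops)
        r_swap_first = f4(t, pops[1], pops[0], pops[2], pops[3])
        r_swap_pairs = f4(t, pops[2], pops[3], pops[0], pops[1])
        assert r_swap_first.estimate == pytest.approx(-r.estimate, abs=1e-15)
        assert r_swap_pairs.estimate == pytest.approx(r.estimate, abs=1e-15)

    def test_duplicate_population_rejected(self, small_sim):
        _, _, g = small_sim
        t = allele_frequencies(g)
        with pytest.raises(ValueError):
            f4(t, "SP1P1", "SP1P1", "SP2P1", "SP2P2")


class TestF3Scan:
    def test_triad_counts(self):
        p = np.linspace(0.2, 0.8, 6)
        t3 = freq_table({c: p + i * 0.01 for i, c in enumerate("ABC")}, 20.0)
        assert len(f3_scan(t3)) == 3
        t5 = freq_table({c: p + i * 0.01 for i, c in enumerate("ABCDE")}, 20.0)
        assert len(f3_scan(t5)) == 30   # 5 * C(4,2)

    def test_identical_panels_correlate_perfectly(self, small_sim):
        _, _, g = small_sim
        t = allele_frequencies(g)
        s1 = f3_scan(t)
        s2 = f3_scan(t)
        assert np.corrcoef(s1["f3"], s2["f3"])[0, 1] == pytest.approx(1.0)


def test_coordinate_blocks_contiguous(small_sim):
    _, _, g = small_sim
    blocks = coordinate_blocks(g.sites, block_mb=5)
    # labels are non-decreasing along the coordinate-sorted sites
    assert (np.diff(blocks) >= 0).all()
    assert len(np.unique(blocks)) >= 2
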