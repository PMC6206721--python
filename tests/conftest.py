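import numpy as np
import pandas as pd
import pytest

from panelbias.io import GenotypeMatrix


def make_matrix(dosages, chrom="1", pos=None, populations=None, samples=None):
    """Build a GenotypeMatrix from a plain nested list / array of dosages."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    if isinstance(chrom, str):
        chrom = [chrom] * m
    sites = pd.DataFrame({
        "chrom": chrom, "pos": np.asarray(pos, dtype=np.int64),
        "ref": "A", "alt": "G", "id": [f"s{j}" for j in range(m)],
    })
    if samples is None:
        samples = [f"ind{i}" for i in range(n)]
    if populations is None:
        populations = ["pop1"] * n
    return GenotypeMatrix(dosages=d, sites=sites, samples=samples,
                          populations=populations)


@pytest.fixture
def two_pop_matrix():
    """Ten samples, two populations, six polymorphic sites."""
    rng = np.random.default_rng(42)
    d = np.vstack([
        rng.binomial(2, 0.2, size=(5, 6)),
        rng.binomial(2, 0.8, size=(5, 6)),
    ]).astype(np.int8)
    return make_matrix(d, populations=["A"] * 5 + ["B"] * 5)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated structured dataset shared across tests."""
    from panelbias import simulate

    cfg = simulate.studylike_config(seed=7, n_super=2, pops_per_super=2,
                                    n_per_pop=20, m_snps=2000)
    panel, g = simulate.simulate_dataset(cfg)
    return cfg, panel, g
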