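"""Canned end-to-end experiments used by the examples and the test suite.

The headline experiment contrasts an AIM-ascertained site panel with a
matched random panel drawn from the same simulated genotype set, and
measures the four signatures of SNP ascertainment bias:

* inflated F_ST between populations of different super-populations,
* a larger leading PCA eigenvalue,
* a lower correlation of triad-wise f3 values with the full-set reference,
* a right-shifted across-population MAF-variance distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import diagnostics as diag
from . import fstats, pca, simulate

__all__ = ["BiasMeasures", "ascertainment_bias_experiment"]


@dataclass
class BiasMeasures:
    """Per-seed contrast between the AIM-ascertained and random panels."""

    fst_between_aim: float       # mean between-super-population F_ST, AIM panel
    fst_between_random: float
    fst_within_aim: float        # mean within-super-population F_ST
    fst_within_random: float
    eigenvalue_aim: float        # leading eigenvalue
    eigenvalue_random: float
    f3_corr_aim: float           # triad-f3 Pearson r against the full panel
    f3_corr_random: float
    maf_var_aim: float           # mean per-site across-population MAF variance
    maf_var_random: float


def _mean_fst(mat, super_of, between: bool) -> float:
    pops = list(mat.index)
    vals = []
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            diff = super_of[a] != super_of[b]
            if diff == between:
                vals.append(mat.loc[a, b])
    return float(np.mean(vals))


def ascertainment_bias_experiment(
    seed: int,
    n_super: int = 5,
    pops_per_super: int = 3,
    n_per_pop: int = 30,
    m_snps: int = 20_000,
    panel_sites: int = 5_000,
    fraction_aims: float = 0.8,
) -> BiasMeasures:
    """One seed of the ascertained-vs-random panel contrast.

    Simulates the study-like hierarchy (no admixed population: the contrast
    concerns unadmixed structure), draws an AIM-enriched panel and a
    same-sized random panel from the simulated frequencies, and computes the
    four bias measures against the full site set as reference.
    """
    cfg = simulate.studylike_config(seed=seed, n_super=n_super,
                                   pops_per_super=pops_per_super,
                                   n_per_pop=n_per_pop, m_snps=m_snps)
    cfg.admixture_specs = []
    panel, g = simulate.simulate_dataset(cfg)
    super_of = cfg.super_of()

    # Composite array-style ascertainment: half the panel discovered by
    # overall across-population MAF variance, half by |delta p| on one
    # specific between-super-population contrast.  Real chips mix globally
    # informative AIMs with markers from particular discovery contrasts; the
    # contrast-specific half is what makes the distortion non-uniform across
    # population triads.
    pops = cfg.leaf_populations()
    contrast = (pops[0], pops[pops_per_super])   # first pop of supers 1 and 2
    half = panel_sites // 2
    idx_var = simulate.ascertain_aims(panel, "maf_variance_top",
                                      fraction_aims=fraction_aims,
                                      n_sites=half, seed=seed)
    idx_pair = simulate.ascertain_aims(panel, "delta_pair",
                                       fraction_aims=fraction_aims,
                                       n_sites=panel_sites - half,
                                       seed=seed + 20_000, pair=contrast)
    aim_idx = np.unique(np.concatenate([idx_var, idx_pair]))
    rand_idx = simulate.ascertain_aims(panel, "maf_variance_top",
                                       fraction_aims=0.0,
                                       n_sites=len(aim_idx), seed=seed + 10_000)

    freqs_full = fstats.allele_frequencies(g)
    blocks_full = fstats.coordinate_blocks(freqs_full.sites)
    f3_full = fstats.f3_scan(freqs_full, blocks=blocks_full)

    out: dict[str, dict[str, float]] = {}
    for name, idx in (("aim", aim_idx), ("random", rand_idx)):
        gp = g.take_sites(idx)
        freqs = fstats.allele_frequencies(gp)
        blocks = fstats.coordinate_blocks(freqs.sites)
        fst = fstats.fst_matrix(freqs, blocks=blocks)
        f3_tab = fstats.f3_scan(freqs, blocks=blocks)
        merged = f3_tab.merge(f3_full, on=["target", "source_a", "source_b"],
                              suffixes=("_panel", "_full"))
        r = float(np.corrcoef(merged["f3_panel"], merged["f3_full"])[0, 1])
        ev = pca.run_pca(gp, n_components=2).eigenvalues[0]
        mv = float(np.nanmean(diag.maf_variance(freqs).variance))
        out[name] = {
            "between": _mean_fst(fst, super_of, between=True),
            "within": _mean_fst(fst, super_of, between=False),
            "eig": float(ev),
            "r": r,
            "mv": mv,
        }

    return BiasMeasures(
        fst_between_aim=out["aim"]["between"],
        fst_between_random=out["random"]["between"],
        fst_within_aim=out["aim"]["within"],
        fst_within_random=out["random"]["within"],
        eigenvalue_aim=out["aim"]["eig"],
        eigenvalue_random=out["random"]["eig"],
        f3_corr_aim=out["aim"]["r"],
        f3_corr_random=out["random"]["r"],
        maf_var_aim=out["aim"]["mv"],
        maf_var_random=out["random"]["mv"],
    )
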