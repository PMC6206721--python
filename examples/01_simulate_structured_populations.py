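"""Simulate a structured population hierarchy and measure its F_ST structure.

Builds a small two-level hierarchy (2 super-populations x 2 populations,
Balding-Nichols drift 0.08 between and 0.01 within super-populations) plus
one 70/30 admixed group, then prints the pairwise Hudson F_ST matrix.
Expect within-super-population values near 2 x 0.01 and between-super values
near 2 x 0.08 + 2 x 0.01 (drift accumulates along both branches of a pair's
path), with the admixed group intermediate between its sources.
"""

from panelbias import allele_frequencies, fst_matrix, studylike_config, simulate_dataset

config = studylike_config(seed=1, n_super=2, pops_per_super=2,
                          n_per_pop=30, m_snps=5_000)
panel, genotypes = simulate_dataset(config)
print(f"{genotypes.n_samples} samples x {genotypes.n_sites} SNPs, "
      f"populations: {sorted(set(genotypes.populations))}")

freqs = allele_frequencies(genotypes)
print("\nPairwise Hudson F_ST:")
print(fst_matrix(freqs).round(3))
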