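"""Detect admixture with f3 and test tree topology with f4.

f3(C; A, B) is significantly negative when C descends from a mixture of
populations related to A and B.  f4(A, B; C, D) is consistent with zero when
((A,B),(C,D)) is the true tree and no gene flow crosses it.  Both use block
jackknife standard errors, so the printed Z scores are comparable across
panels.
"""

from panelbias import allele_frequencies, f3, f4, simulate_dataset
from panelbias.simulate import AdmixtureSpec, SimConfig, SuperPop

tree = {"S1": SuperPop(drift=0.05, pops={"A": 0.05, "B": 0.05}),
        "S2": SuperPop(drift=0.05, pops={"C": 0.05, "D": 0.05})}
config = SimConfig(tree=tree, n_per_pop=40, m_snps=10_000, seed=7,
                   admixture_specs=[AdmixtureSpec("MIX", ("A", "C"),
                                                  (0.5, 0.5))])
_, g = simulate_dataset(config)
freqs = allele_frequencies(g)

r = f3(freqs, "MIX", "A", "C")
print(f"f3(MIX; A, C) = {r.estimate:+.5f}  Z = {r.z_score:+.1f}"
      "   <- negative, |Z|>3: MIX is admixed")

r = f3(freqs, "B", "A", "C")
print(f"f3(B; A, C)   = {r.estimate:+.5f}  Z = {r.z_score:+.1f}"
      "   <- positive: B forms a simple tree with A and C")

r = f4(freqs, "A", "B", "C", "D")
print(f"f4(A, B; C, D) = {r.estimate:+.6f}  Z = {r.z_score:+.1f}"
      "  <- |Z|<3: no gene flow across the tree")

r = f4(freqs, "A", "MIX", "C", "D")
print(f"f4(A, MIX; C, D) = {r.estimate:+.6f}  Z = {r.z_score:+.1f}"
      "  <- admixed test population pulls f4 off zero")
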