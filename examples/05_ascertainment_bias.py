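"""The headline contrast: AIM-ascertained panel vs matched random panel.

One simulation seed of the full experiment: simulate the study-like
hierarchy (5 super-populations x 3 populations), draw an array-style
AIM-enriched site panel and a same-sized random panel, and compare the four
bias signatures.  The ascertained panel inflates between-super-population
F_ST and the leading eigenvalue, degrades the f3 correlation with the
full-set reference, and right-shifts the MAF-variance distribution — while
within-super-population F_ST is nearly untouched.
"""

from panelbias.experiments import ascertainment_bias_experiment

m = ascertainment_bias_experiment(seed=1)

print("                              AIM panel   random panel")
print(f"between-super F_ST (mean)    {m.fst_between_aim:9.4f}   {m.fst_between_random:9.4f}")
print(f"within-super  F_ST (mean)    {m.fst_within_aim:9.4f}   {m.fst_within_random:9.4f}")
print(f"leading eigenvalue           {m.eigenvalue_aim:9.1f}   {m.eigenvalue_random:9.1f}")
print(f"f3 correlation vs reference  {m.f3_corr_aim:9.4f}   {m.f3_corr_random:9.4f}")
print(f"mean MAF variance            {m.maf_var_aim:9.4f}   {m.maf_var_random:9.4f}")
print("\nascertainment inflates divergence measures between distant "
      "populations but leaves close pairs almost unchanged")
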