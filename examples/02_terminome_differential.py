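"""Moderated-t differential abundance of N-terminal peptides.

Simulates a terminome experiment (three genotypes x four replicates) in
which 10% of termini are twice as abundant in the overexpressor, runs the
empirical-Bayes moderated t-test on the overexpressor-vs-knock-down
comparison, and applies the significance rule (p < 0.05 and |log2FC| >
0.58, i.e. a >50% change).
"""

from ntermflow.io_formats import AnalysisConfig
from ntermflow.synthetic_data import SimParams, generate_proteome, simulate_terminome
from ntermflow.terminome_stats import moderated_t_table, significance_filter

cfg = AnalysisConfig(rng_seed=1)
params = SimParams(n_proteins=600, n_termini=800, seed=1)

proteome = generate_proteome(params)
table, truth = simulate_terminome(proteome, params)
n_quant = int(truth.termini["quantifiable"].sum())
print(f"simulated {len(truth.termini)} termini, {n_quant} quantifiable "
      f"({len(truth.termini) - n_quant} acetylated without a labeled Lys)")

res = moderated_t_table(table, "ox", "mi", cfg)
res = significance_filter(res, cfg)
print(f"empirical-Bayes prior: d0={res.attrs['d0']:.3g}, s0^2={res.attrs['s0_sq']:.3g}")
print(f"significant termini: {res.attrs['n_up']} up in ox, {res.attrs['n_down']} down")

truth_up = truth.termini[truth.termini["effect"] & truth.termini["quantifiable"]]
called = res.index[res["significant"]]
recovered = len(set(called) & set(truth_up.index))
print(f"of {len(truth_up)} quantifiable termini with a planted 2-fold effect, "
      f"{recovered} were recovered")
print()
print("The moderated test shrinks per-terminus variances toward a common")
print("prior, which stabilizes inference at n=4 replicates per genotype;")
print("'up in ox' means higher abundance in the overexpressor line.")
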