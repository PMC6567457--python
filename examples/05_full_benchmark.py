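"""The full study-scale comparison: 15 synthetic trips, five methods.

Reproduces the complete evaluation design — pooled k-means, pooled
binary clustering, pooled HMM, FPT with data-driven radius and
threshold, per-trip change-point analysis — then ranks methods by
median balanced accuracy, tests for differences (Friedman + paired
Wilcoxon vs the best), and compares foraging movement parameters with
those measured at buzz fixes. Takes a minute or two.
"""

import warnings

warnings.filterwarnings("ignore")

import batseg as bs

res = bs.run_benchmark(seed=0)

print(f"FPT scale selected : {res.fpt_radius:.0f} m, threshold {res.fpt_threshold_s:.0f} s\n")
print("median balanced accuracy per method:")
print(res.median_ba().round(3).to_string())
chi2, df, p = res.friedman
print(f"\nFriedman test: chi2 = {chi2:.2f}, df = {df}, p = {p:.2g}")
print("\npaired Wilcoxon vs the best method (Bonferroni-adjusted):")
print(res.wilcoxon_vs_best.round(4).to_string(index=False))
print("\nforaging parameters vs buzz fixes:")
cols = ["method", "foraging_speed_mean", "foraging_turn_mean",
        "commuting_speed_mean", "commuting_turn_mean"]
print(res.param_table[cols].round(2).to_string(index=False))
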