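"""Simulate a grade-stratified tumor cohort and inspect its marker structure.

Generates 100 tumors (16/43/41 across grades 1-3) with ploidy-coupled S-phase
lengthening, then prints per-grade marker means and the Pearson correlation
matrix. Mitotic and PhH3 counts track each other tightly (same cycle phase);
MIB-1 decouples from both because interphase duration varies across tumors.
"""

from prolifmark.cohort_stats import correlation_matrix, ols_fit
from prolifmark.synthetic_cohort import CohortConfig, simulate_cohort

table = simulate_cohort(CohortConfig(seed=1))

print("Per-grade means:")
cols = ["mib1_per_field", "phh3_per_field", "mitoses_per_10hpf", "iod"]
print(table.groupby("grade")[cols].mean().round(1).to_string())

print("\nPearson correlations (measured counts):")
print(correlation_matrix(table).round(3).to_string())

fit = ols_fit(table["phh3_per_field"], table["mib1_per_field"])
print(f"\nregression: MIB-1 = {fit.slope:.1f} x PhH3 + {fit.intercept:.0f} "
      f"(r = {fit.pearson_r:.2f})")
print("Note r(mitoses, PhH3) > r(MIB-1, PhH3): the decoupling signature.")
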