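"""Two-cohort comparison statistics on published-style contingency tables.

Runs Fisher's exact test (conditional-MLE odds ratio, two-sided p) on the
kind of 2x2 tables a two-cohort study reports, a Wilcoxon rank-sum
example, and Benjamini-Hochberg correction over a family of p-values.
"""

from wexscape.stats import bh_fdr, fisher_exact, wilcoxon_rank_sum

# heterogeneous samples by group: 32/95 vs 11/52
or_, p = fisher_exact(32, 63, 11, 41)
print(f"heterogeneity table:   OR = {or_:.2f}, two-sided p = {p:.3f}")

# TMB-high samples by group: 2/54 vs 1/102
_, p = fisher_exact(2, 52, 1, 101)
print(f"TMB-high table:        p = {p:.3f}")

# any actionable alteration: 39/54 vs 69/102
_, p = fisher_exact(39, 15, 69, 33)
print(f"any-AGA table:         p = {p:.3f}")

stat, p = wilcoxon_rank_sum([1.1, 0.9, 2.4, 0.5], [1.4, 3.0, 2.2, 4.1])
print(f"wilcoxon rank-sum:     U = {stat}, p = {p:.3f}")

qs = bh_fdr([0.003, 0.04, 0.04, 0.2, 0.9])
print("BH q-values:          ", [round(float(q), 3) for q in qs])
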