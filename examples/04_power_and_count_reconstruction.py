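"""A priori power analyses and exact recovery of a 2x2 table from a
printed summary.

Sizes the designs from their published effect sizes, then reconstructs
the field experiment's contingency table from nothing but the printed
condition percentages, total N and confidence intervals — and
recomputes its test statistics.
"""

from cancelnudge import (
    experiment1_summary,
    fisher_exact_2x2,
    pearson_chi2,
    reconstruct_counts,
    required_n_chi2_df1,
    required_n_two_sample_t,
)

print("a priori sample sizes")
print(f"  w = .27, one-tailed, 80% power -> total N = "
      f"{required_n_chi2_df1(0.27, tails=1)}")
print(f"  d = .60, two-tailed, 80% power -> "
      f"{required_n_two_sample_t(0.60)} per condition")
print(f"  d = .48, two-tailed, 80% power -> "
      f"{required_n_two_sample_t(0.48)} per condition")

s = experiment1_summary()
rec = reconstruct_counts(
    s["pct_later_cancellation"], s["pct_later_baseline"], s["n_total"],
    printed_cis=(s["ci_cancellation"], s["ci_baseline"]))
t = rec.table
print(f"\nreconstructed counts (unique = {rec.unique}):")
print(f"  cancellation: {t.a}/{t.a + t.b} later "
      f"({100 * t.a / (t.a + t.b):.1f}%)")
print(f"  baseline:     {t.c}/{t.c + t.d} later "
      f"({100 * t.c / (t.c + t.d):.1f}%)")
chi2 = pearson_chi2(t)
print(f"  chi2(1, N={t.n}) = {chi2.statistic:.2f}, w = {chi2.w:.2f}, "
      f"Fisher exact p = {fisher_exact_2x2(t):.3f}")
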