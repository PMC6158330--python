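"""Genotype-association statistics on a simulated cohort.

Hardy-Weinberg equilibrium on the genotyped sample, then the split-plot
ANOVA of vocal compensation (within: perturbation magnitude -50/-200
cents; between: genotype) with Bonferroni post hocs and per-genotype
correlations between compensation and the baseline-variability index.
"""

import faflab as fl

# HWE on the study's genotyped counts (AA/AG/GG = 55/71/24)
chi2, p = fl.hwe_chisq(fl.GenotypeCounts(55, 71, 24))
print(f"HWE: chi2 = {chi2:.3f}, p = {p:.3f}  (df = 1)")

# a reduced cohort with the default effect structure
spec = fl.CohortSpec(n_per_genotype={"AA": 20, "AG": 25, "GG": 10},
                     trials_per_condition=40, seed=12)
ds = fl.simulate_cohort(spec)
vs = fl.vocal_summary(ds)
res = fl.replicate_study_analyses(vs, None, ds.genotype_table())

tab = res["vocal_magnitude_anova"]
print("\nvocal magnitude ANOVA:")
print(tab[["effect", "df1", "df2", "F", "p_unc", "partial_eta_sq"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))

print("\npost hoc (-200 cents), Bonferroni-adjusted:")
print(res["vocal_posthoc_largest_shift"]
      [["group_a", "group_b", "mean_diff", "p_adj"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))

print("\ncompensation vs baseline-SD correlation by genotype:")
for g, c in res["compensation_vs_variability"].items():
    print(f"  {g}: r = {c.r:+.3f} (n = {c.n}, p = {c.p:.3f})")
# Under the default effects the GG group compensates less at -200 cents
# (significant magnitude x genotype interaction, GG-vs-AA/AG post hocs)
# and its compensation decouples from baseline variability (low r).
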