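"""Censored-data marker comparison between honey types.

2'-MAP is undetectable in some honey classes, so its values are left-
censored at the 1 mg/kg limit of reporting. The evaluation imputes the
censored values (Uniform(0, LOR) in mixed groups, LOR x Beta(1, 40) in
all-censored groups), refits a one-way ANOVA with Tukey HSD pairwise
comparisons and Benjamini-Hochberg adjustment on many simulated datasets,
and reports how often each pair of honey types separates at alpha = 0.05.
"""
from manuka import (
    GeneratorConfig,
    ImputationScheme,
    generate_honey_dataset,
    run_censored_anova,
)

honey = generate_honey_dataset(GeneratorConfig(seed=2))
y1 = honey[honey["year"] == "2014/15"]

scheme = ImputationScheme(lor=1.0, n_simulations=200, seed=0)
res = run_censored_anova(y1, "supplier_label", "2'-MAP", scheme)

print("pairwise separation of honey types on 2'-MAP "
      f"({scheme.n_simulations} imputed datasets):\n")
print(res.pairwise.round(3).to_string(index=False))
print("\nwinsorised group means (log mg/kg scale):")
print(res.group_means.round(3).to_string(index=False))
print(
    "\n'proportion_significant' is the fraction of simulations in which the\n"
    "pair differed after Tukey HSD + BH adjustment; pairs involving the\n"
    "manuka classes should separate from non-manuka in nearly all simulations."
)
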