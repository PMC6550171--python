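"""Fit the prior-adjusted classification tree and turn it into rules.

Fits a gini CART with uniform class priors to one production year using
3-PA and the two DNA markers (the refined marker set), prints the tree in
its reading convention (condition met -> left branch), grades the held-out
year's predictions with the severity matrix, and extracts threshold rules
for the manuka classes from the fitted tree.
"""
from manuka import TreeConfig, extract_rules, grow_tree, report
from manuka import GeneratorConfig, generate_honey_dataset

honey = generate_honey_dataset(GeneratorConfig(seed=3))
train = honey[honey["year"] == "2014/15"]
test = honey[honey["year"] == "2015/16"]

config = TreeConfig(markers=["3-PA", "manuka_dna", "kanuka_dna"])
tree = grow_tree(train, config, metadata={"train_year": "2014/15"})
print("fitted tree (condition met -> left):\n")
print(tree.rules_text())

rep = report(test["supplier_label"].to_numpy(), tree.predict(test))
print("\nout-of-sample severity report (2015/16 test set):")
for k, v in rep.as_dict().items():
    print(f"  {k:>10}: {v:.3f}" if isinstance(v, float) else f"  {k:>10}: {v}")

rules = extract_rules(tree)
print("\nextracted manuka pathways:")
for label, pathways in (("monofloral", rules.monofloral),
                        ("multifloral", rules.multifloral)):
    for i, pw in enumerate(pathways):
        conds = ", ".join(f"{p.marker} {p}" for p in pw.predicates)
        print(f"  {label} pathway {chr(65 + i)}: {conds}")
print(
    "\nOFP/OFN are the overall monofloral-manuka false positive/negative\n"
    "rates; SFP/SFN count only the severe cells of the severity matrix."
)
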