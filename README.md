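# manuka

Statistical pipeline for marker-based identification criteria for manuka
honey.

Manuka honey — honey derived predominantly (monofloral) or partially
(multifloral) from *Leptospermum scoparium* nectar — commands a price
premium that makes it a target for mislabelling, and there is no gold
standard for what a honey type "is". Authentication therefore rests on a
panel of nectar-derived chemical markers (concentrations in mg/kg,
left-censored at a 1 mg/kg limit of reporting) and qPCR DNA markers
(quantification cycle Cq, where lower Cq means more target DNA; Cq 36 is
the detection limit and 40 the assay maximum). This package implements the
full analysis chain that turns such a marker panel into simple threshold
rules a regulator can apply, and the machinery to test how robust those
rules are:

- **synthetic data** (`manuka.synthetic`) — six honey classes (monofloral
  manuka M, multifloral manuka MB, kanuka K, non-manuka NM, Australian AU,
  non-NZ/Aus NN) with class-dependent log-normal marker concentrations,
  detection probabilities, Cq distributions, region/year shifts and
  supplier-label noise; plus nectar (with sugar content and habitat) and
  storage-stability trial generators. The real survey data are not public,
  so every stage is exercised on these generators, which expose the ground
  truth that real data cannot.
- **preprocessing** (`manuka.preprocessing`) — natural-log transform,
  nectar mg/80%-sugar standardisation, below-LOR substitution, Cq
  recoding above the LOR to the assay maximum.
- **censored-data marker evaluation** (`manuka.censored`) — imputation by
  simulation for values below the LOR (Uniform(0, LOR) in mixed groups,
  LOR·Beta(1, 40) in all-censored groups), repeated one-way ANOVA with
  Tukey HSD and Benjamini–Hochberg adjustment, winsorised-variance group
  means, a heteroscedastic (per-honey-type variance) ANOVA for the DNA
  markers, and the stability / regional / temporal / habitat linear models.
- **classification trees** (`manuka.cart`) — a from-scratch CART engine
  with gini impurity computed on *prior-adjusted* class proportions
  (`p(j|t) ∝ π_j n_j(t)/n_j`) under explicit, by default uniform, priors —
  so the severely unbalanced class sizes do not dominate the splits.
- **severity-graded evaluation** (`manuka.severity`) — misclassifications
  graded irrelevant < mild < severe by a 6×6 matrix (calling non-manuka
  honey "monofloral manuka" is severe; confusing the two overseas classes
  is irrelevant), with overall and severe false positive/negative rates
  for the monofloral class (OFP/OFN, SFP/SFN).
- **sensitivity analysis** (`manuka.sensitivity`) — stratified bootstrap
  tree refits with marker-inclusion frequencies and percentile intervals,
  refits on imputed below-LOR data, Cq-recode comparisons, systematic
  laboratory bias at ±5/10/15/20%, threshold-rounding assessment, and a
  scenario grid (training year, island, 4- vs 6-class response, marker
  subsets).
- **identification criteria** (`manuka.criteria`) — the rule engine with
  the four candidate options and the final published criteria built in
  (`src/manuka/data/criteria.yaml`), rule extraction from fitted trees,
  and the supplier-comparison summary.

The final criteria classify a honey as manuka (either kind) only if
2′-methoxyacetophenone, 2-methoxybenzoic acid and 4-hydroxyphenyllactic
acid are present at ≥ 1 mg/kg, 3-phenyllactic acid (3-PA) ≥ 20 mg/kg, and
manuka DNA < Cq 36; it is **monofloral** iff 3-PA ≥ 400 mg/kg and
**multifloral** iff 20 ≤ 3-PA < 400 mg/kg.

## Worked example

```python
from manuka import GeneratorConfig, generate_honey_dataset, summarise_vs_supplier

honey = generate_honey_dataset(GeneratorConfig(seed=1))
print(summarise_vs_supplier(honey, "final").round(1).to_string(index=False))
```

prints

```
             supplier_identification  n_samples  not_manuka_pct  multifloral_pct  monofloral_pct
                   Monofloral manuka        144            10.4             21.5            68.1
                  Multifloral manuka         60            18.3             81.7             0.0
                              Kanuka         34           100.0              0.0             0.0
                          Non-manuka        177           100.0              0.0             0.0
Australian and other countries honey        100           100.0              0.0             0.0
```

Each row is one supplier-declared honey type and where its samples land
under the final criteria: on this synthetic survey 68.1% of
supplier-monofloral manuka satisfies the 400 mg/kg 3-PA rule, every
kanuka, non-manuka and overseas sample is rejected as not manuka, and a
fifth of supplier-monofloral samples fall into the multifloral band —
the kind of supplier/criteria disagreement the severity grading exists to
dissect.

The `examples/` directory holds one short script per capability
(simulation + classification, censored marker evaluation, tree fitting and
rule extraction, sensitivity analysis, nectar/stability models); each
prints its results with a note on how to read them. A thin CLI mirrors the
pipeline stages:

```sh
manuka simulate --seed 1 --out runs/sim
manuka fit-cart --input runs/sim/honey.csv --out runs/tree
manuka classify --input runs/sim/honey.csv --option final --out runs/labels
```

Sample tables are plain CSV with censored chemical values written as the
literal `"<LOR"`; every command writes a `manifest.json` with the seed and
a configuration hash so artifacts are regenerable.

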