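# Methods

This note documents the models, numerical choices and limitations behind
the package. It is written for a reader who wants to know exactly what the
code computes and why, and what passing the test suite does and does not
demonstrate about real honey data.

## The problem setting

Honey type is a six-level factor: monofloral manuka (M), multifloral
manuka (MB), kanuka (K), non-manuka (NM), Australian (AU) and non-NZ/Aus
(NN). A sensitivity scenario also uses a four-level coarsening in which
kanuka joins non-manuka and the two overseas classes merge. The reference
label is the *supplier identification* — what the beekeeper or packer
called the honey — which is itself noisy; there is no gold standard.

Markers come in two kinds. Chemical markers are concentrations in mg/kg
(honey) or mg/L (nectar), left-censored at a limit of reporting (LOR) of
1 mg/kg and 0.01 mg/L respectively. DNA markers are qPCR quantification
cycles (Cq); lower Cq means more target DNA, Cq 36 is the detection LOR
and 40 the assay maximum.

## Synthetic data generator

Real survey data are not publicly available, so the package carries a
first-class generator whose defaults define the conditions every analysis
is exercised under.

Per class and chemical marker the model is two-part: the marker is
*detected* with probability `detect`; a detected concentration is
log-normal with location `loc` and scale `scale` on the natural-log mg/kg
scale. Non-detections and detected draws below the LOR are flagged
left-censored and carry no numeric value (`NaN` in memory, the literal
`"<LOR"` in CSV). Cq values are Gaussian per class, clipped to (0, 40].
Region and production-year effects are additive shifts on the log
concentration scale; supplier-label noise (off by default) confuses a true
class with an adjacent one (e.g. M↔MB) at a configurable rate.

Default parameters were chosen once so that class *orderings* match the
qualitative structure the analysis assumes — 2′-MAP essentially absent
outside manuka-derived and Australian honey; 3-PA highest in monofloral
manuka (median 650 mg/kg) and intermediate in multifloral (120 mg/kg);
manuka DNA Cq lowest in M (mean 27) and above the LOR in NM/AU/NN; marker
concentrations higher in the 2014/15 production year than 2015/16 — and so
that the default survey has the study's class imbalance (M and NM
dominate) at about 500 samples over two production years plus archive.
They are illustrative: no attempt is made to match unpublished numeric
distributions, and the absolute classification percentages the examples
print are properties of these defaults, not estimates of any real rate.

The nectar generator adds sugar content (truncated normal on (0, 100]),
species-level marker models and the five habitat types; the stability
generator reproduces the trial design (six honeys, triplicate aliquots at
time zero and after 68 days at 4/20/35 °C) with configurable additive
log-scale drift per marker (`DriftModel`: log-drift per day, and per °C
above the coldest storage temperature).

Because the generator is explicit, the maximum-likelihood ("Bayes
optimal") class of any marker vector is computable
(`bayes_optimal_class`), which recovery tests use as planted truth.

What the generator does *not* emulate: collector bias, batch effects,
adulteration, correlation between markers within a sample (markers are
conditionally independent given class), or any geographic structure beyond
additive region shifts. Tests passing on this generator show the
*machinery* is correct and calibrated, not that real honey satisfies the
criteria at any particular rate.

## Preprocessing conventions

- Chemical concentrations are analysed on the natural-log scale.
- Nectar concentrations are converted to a mg/80%-sugar scale. The
  conversion formula is a design choice: we interpret the scale as "mg per
  volume of nectar containing the reference 80% sugar", i.e.
  `conc × 80 / sugar_content` — linear, identity at 80% sugar, strictly
  decreasing in sugar content.
- For the habitat analysis only, censored nectar values are set to a fixed
  0.1 mg/L before sugar conversion.
- Cq recoding (values above 36 → 40) is a *scenario*, not the baseline:
  baseline analyses use Cq values as measured. Both behaviours are
  supported (`recode_cq`, `cq_recode_comparison`).
- Trees are fitted on the raw concentration scale so that thresholds are
  reported in mg/kg; CART is invariant to monotone transforms, so this is
  equivalent to fitting on logs (asserted by a test). Censored chemical
  values entering a tree fit are substituted with LOR/2 by default
  (configurable) — any value inside (0, LOR) gives the same splits unless
  a threshold falls below the LOR.

## Censored-data marker evaluation

Below-LOR values are imputed by simulation, per group:

1. mixed rule — groups with values on both sides of the LOR get
   Uniform(0, LOR) draws for each censored value;
2. all-below rule — fully censored groups get `LOR × Beta(1, 40)` draws,
   a strongly left-skewed distribution with mean LOR/41 ≈ 0.024·LOR.

Uncensored values are never modified; exact zeros from the uniform rule (a
probability-zero event) are redrawn so logs stay finite. Imputation
happens on the raw scale before the log transform.

Each of `n_simulations` (default 1000; analyses in this repository use
smaller counts noted below) imputed datasets gets a one-way ANOVA, Tukey
HSD pairwise comparisons (Tukey–Kramer for unbalanced groups, via the
studentized-range distribution) and Benjamini–Hochberg adjustment *within
the Tukey family of one simulation* — the per-comparison framing; adjusting
across markers is not done. Results aggregate to the proportion of
simulations each pair separates at α = 0.05, the mean difference and mean
SE, and winsorised group means across simulations (trim fraction 0.2 per
the usual robust-summary convention; configurable).

A note on calibration: for a *fixed* dataset the only randomness across
simulations is the imputation noise, so the per-pair significance
proportion is not a type-I error rate — with no censoring it is exactly 0
or 1. The calibration property (rejection rate ≈ 0.05 on exchangeable null
data) is therefore verified over independently generated null datasets,
one imputation pass each; the planted-separation power property (proportion
= 1 at a five-sigma group separation) is verified on the fixed-dataset
path.

The heteroscedastic ANOVA used for the manuka DNA Cq comparison fits group
means with a free per-group variance by Gaussian maximum likelihood and
reports two likelihood-ratio tests: the group-mean effect (against a
common-mean model that retains per-group variances; df = groups − 1) and
the variance structure itself (against a pooled-variance model with the
same means). The stability ANOVA averages replicates to per-sample cell
means before testing (temperature is a factor whose levels include the
time-zero baseline, coded `"t0"`); the interaction is checked step-wise on
the replicate-level data and reported, as the cell-mean layout leaves it
no residual degrees of freedom. Regional (12-level) and temporal (3-level)
variation use one-way linear models on log concentrations with omnibus
F-tests. The habitat analysis routes markers with more than 20% censoring
(configurable) through the imputation simulation instead of the
deterministic 0.1 mg/L substitution.

## Classification trees

The tree engine is written from scratch because its fitting semantics —
gini impurity on prior-adjusted class proportions under explicit priors —
is the heart of the method. With priors π_j and training class totals n_j:

    p(j, t) = π_j n_j(t) / n_j     p(t) = Σ_j p(j, t)     p(j|t) = p(j, t)/p(t)
    I(t) = 1 − Σ_j p(j|t)²
    ΔI = p(t) I(t) − p(t_L) I(t_L) − p(t_R) I(t_R)

Uniform priors are the default: with class sizes as unbalanced as this
survey's, empirical priors would let the two large classes dominate every
split. With exactly balanced classes the two coincide (tested).

The split search is exhaustive over features and candidate thresholds
(midpoints between consecutive distinct sorted values), subject to the
stopping rules: minimum 20 samples to split a node, minimum leaf size 7,
maximum depth 30, and a relative-improvement threshold — a split is
accepted only if ΔI ≥ 0.01 × the root impurity mass. These are the usual
recursive-partitioning defaults; all are configurable. Ties in ΔI are
broken by feature order, then by the smaller threshold; the candidate
scoring keeps cumulative class counts integral so per-candidate arithmetic
is exact and tie-breaking is deterministic and reproducible against an
independent brute-force search. Routing follows the reading convention of
the tree figures: an internal node tests `value ≥ threshold`, and a sample
meeting the condition takes the left branch. There are no surrogate
splits; a missing marker at prediction time is an error.

Cost-complexity pruning exists nowhere in the model-selection path:
refinement is by explicit marker-set and class-set restriction, which
gives direct control over *which* misclassifications are traded off —
pruning would not penalise severe cells more heavily.

## Severity grading

The 6×6 severity matrix defaults to: diagonal correct; mild = {M→MB,
K→MB, NM→MB, MB→M, MB→K}; severe = {NM→M, AU→M, AU→MB, NN→M, NN→MB,
M→NM, M→AU, M→NN}; every remaining off-diagonal cell irrelevant. The
mild and severe cells encode the stated constraints (honey without a
manuka claim predicted as a manuka class is severe; types plausibly
confusable with multifloral manuka are mild); cells not fixed by those
constraints default to the mildest interpretation consistent with
manuka-involving errors being the priority. The matrix is data, not code
— fully overridable from CSV/YAML. OFP/OFN are the monofloral-manuka
false positive/negative rates over all samples; SFP/SFN count only severe
cells, so SFP ≤ OFP and SFN ≤ OFN always.

## Sensitivity machinery

Bootstrap refits resample with replacement *within each class* (the two
overseas classes are their own strata), preserving per-class counts in
every replicate; 95% intervals are percentile intervals of the bootstrap
distribution (the interval method is a design choice). The default
replicate count in examples and tests is 100–200; the full analysis count
of 1000 is a parameter away. Bias injection multiplies all values of one
marker kind by (1 + level) with levels 0, ±5, 10, 15, 20% — the 15% level
is included in the default grid alongside 5/10/20 because both grids
appear in the source material for this design; the grid is config-driven.
Threshold rounding is assessed by classifying every dataset under the
exact and rounded rule sets (`option1_exact` stores the unrounded 3-PA
thresholds 435 and 18.5 mg/kg) and reporting the fraction of samples whose
label changes; only samples inside a rounding window can move.

## Criteria rule sets

The four candidate options and the final criteria live in a versioned
YAML data file. Two transcription caveats are deliberately preserved
there rather than "fixed" in code: the kanuka DNA boundary is `>25` in
option 1 but `≥25` in option 3 (so Cq exactly 25 behaves differently
between them), and the option 2/4 multifloral band has no lower 3-PA
bound while the final criteria impose ≥ 20 mg/kg. Within an option,
monofloral pathways are evaluated before multifloral ones; for the
published rule sets the regions are disjoint at every grid point tested,
but evaluation order is fixed so any overlapping custom rule set still
classifies deterministically. Censored chemical values evaluate as a
value below the LOR (LOR/2), so they fail every ≥ 1 mg/kg presence gate —
the criteria's 1 mg/kg floor *is* the LOR — and satisfy upper bounds.

Rule extraction maps each tree leaf predicting a target class to one
pathway by intersecting the conditions along its root-to-leaf path into a
single interval per marker; applied back to the training data the
extracted rules reproduce the tree's predictions exactly (tested).

## Verification strategy and problem sizes

The acceptance script and the deeper tests check the implementation
against independent oracles, at sizes chosen to keep the whole suite under
a minute apiece: 100 random small problems (n ≤ 50, ≤ 3 markers, 2–6
classes) against an exhaustive brute-force tree search; 50–100 seeds of a
six-class planted-boundary dataset (500/class) for first-split recovery;
10⁵ draws against the Beta(1, 40) closed form and a Kolmogorov–Smirnov
uniformity check for the imputation rules; 1000 fresh null datasets for
ANOVA calibration; a 5600-point truth-table grid crossing every published
threshold for the rule engine; and 200 stratified bootstrap replicates for
first-split stability.

## Known limitations

- Maximum-likelihood censored (Tobit) models are out of scope by design;
  the evaluation approach is imputation by simulation.
- The tree engine supports classification only (no regression trees, no
  forests), and internal cross-validation is not wired into model
  selection.
- The generator's marker independence given class understates real
  between-marker correlation, which would make bootstrap intervals on real
  data wider than on synthetic data.
- Percentage nectar contribution is explicitly not estimable from these
  criteria; the package makes no attempt at it.
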