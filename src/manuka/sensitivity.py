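"""Bootstrap and scenario robustness machinery for the classification trees
and criteria.

Covers: stratified bootstrap refits of the tree (marker inclusion and
first-split frequencies, bootstrap distributions of every severity-report
statistic with percentile 95% intervals); refits on below-LOR-imputed
chemical data compared against the original fit; systematic laboratory
bias injection at +/-5/10/15/20%; threshold-rounding reclassification
assessment; and the scenario grid (training year, island, 4- vs 6-class
response, marker subsets).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cart import FittedTree, TreeConfig, grow_tree
from .censored import ImputationScheme, impute_below_lor
from .criteria import CriteriaOption, Pathway, Predicate, classify_table
from .markers import (
    CHEMICAL_MARKERS,
    DNA_MARKERS,
    collapse_to_four,
    marker_kind,
    MarkerKind,
)
from .samples import censor_col
from .severity import ClassificationReport, SeverityMatrix, report

#: Bias levels assessed, as signed fractions.
BIAS_LEVELS = (0.0, 0.05, 0.10, 0.15, 0.20, -0.05, -0.10, -0.15, -0.20)


def stratified_resample(
    table: pd.DataFrame,
    rng: np.random.Generator,
    label_col: str = "supplier_label",
) -> pd.DataFrame:
    """Resample with replacement within each class.

    Every class keeps its sample count in the replicate; the overseas
    classes are strata of their own, so they are resampled separately from
    the New Zealand honey types.
    """
    parts = []
    for cls in sorted(table[label_col].unique()):
        sub = table[table[label_col] == cls]
        idx = rng.integers(0, len(sub), size=len(sub))
        parts.append(sub.iloc[idx])
    return pd.concat(parts, ignore_index=True)


def _percentile_ci(values: np.ndarray) -> tuple[float, float]:
    return (
        float(np.percentile(values, 2.5)),
        float(np.percentile(values, 97.5)),
    )


@dataclass
class BootstrapResult:
    """Aggregate of bootstrap tree refits."""

    n_replicates: int
    seed: int
    inclusion_frequency: dict[str, float]   # marker used anywhere in the tree
    first_split_frequency: dict[str, float]
    statistics: pd.DataFrame  # statistic, mean, lo95, hi95
    replicate_stats: pd.DataFrame = field(repr=False, default=None)


def bootstrap_cart(
    train: pd.DataFrame,
    config: TreeConfig,
    n_replicates: int = 200,
    seed: int = 0,
    test: pd.DataFrame | None = None,
    label_col: str = "supplier_label",
    matrix: SeverityMatrix | None = None,
) -> BootstrapResult:
    """Refit the tree on stratified bootstrap replicates of the training set.

    Tracks how often each marker is included in a fitted tree (as first
    split or otherwise) and the bootstrap distribution of every
    severity-report statistic, evaluated on ``test`` if given (out of
    sample) or on the original training table otherwise.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    counts = train[label_col].value_counts()
    if (counts < 1).any() or train.empty:
        raise ValueError("every honey type must be non-empty in training data")
    rng = np.random.default_rng(seed)
    markers = config.markers or list(CHEMICAL_MARKERS + DNA_MARKERS)
    eval_table = test if test is not None else train
    incl = {m: 0 for m in markers}
    first = {m: 0 for m in markers}
    stat_rows = []
    for b in range(n_replicates):
        boot = stratified_resample(train, rng, label_col)
        tree = grow_tree(boot, config, label_col=label_col)
        used = tree.markers_used()
        for m in used:
            incl[m] += 1
        fs = tree.first_split()
        if fs is not None:
            first[fs[0]] += 1
        rep = report(
            eval_table[label_col].to_numpy(),
            tree.predict(eval_table),
            matrix=matrix,
        )
        stat_rows.append({"replicate": b, **rep.as_dict()})
    reps = pd.DataFrame(stat_rows)
    agg = []
    for stat in ClassificationReport.STAT_NAMES:
        vals = reps[stat].to_numpy(dtype=float)
        lo, hi = _percentile_ci(vals)
        agg.append(
            {"statistic": stat, "mean": float(vals.mean()), "lo95": lo, "hi95": hi}
        )
    return BootstrapResult(
        n_replicates=n_replicates,
        seed=seed,
        inclusion_frequency={m: incl[m] / n_replicates for m in markers},
        first_split_frequency={m: first[m] / n_replicates for m in markers},
        statistics=pd.DataFrame(agg),
        replicate_stats=reps,
    )


# LOR-imputation CART comparison -------------------------------------------

@dataclass
class LorSimResult:
    original_report: ClassificationReport
    simulated: pd.DataFrame           # per-simulation report statistics
    paired_differences: pd.DataFrame  # statistic, mean_diff, lo95, hi95
    n_simulations: int


def _impute_chemicals(
    table: pd.DataFrame,
    scheme: ImputationScheme,
    rng: np.random.Generator,
    label_col: str,
    markers: list[str],
) -> pd.DataFrame:
    """Impute censored chemical values per class group; DNA left unchanged."""
    out = table.copy()
    for m in markers:
        if marker_kind(m) is not MarkerKind.CHEMICAL:
            continue
        flag = censor_col(m)
        if flag not in out.columns:
            continue
        for cls in sorted(out[label_col].unique()):
            sel = out[label_col] == cls
            vals = impute_below_lor(
                out.loc[sel, m].to_numpy(),
                out.loc[sel, flag].to_numpy(),
                scheme,
                rng,
            )
            out.loc[sel, m] = vals
        out[flag] = False
    return out


def lor_sim_cart(
    train: pd.DataFrame,
    config: TreeConfig,
    scheme: ImputationScheme,
    n_simulations: int = 200,
    test: pd.DataFrame | None = None,
    label_col: str = "supplier_label",
    matrix: SeverityMatrix | None = None,
) -> LorSimResult:
    """Compare trees fitted on below-LOR-imputed chemical data to the
    original-data tree.

    Per simulation the censored chemical values are imputed (uniform /
    beta rules per class group), the original DNA data are kept, the tree
    is refitted and evaluated; the paired difference of every report
    statistic against the original fit is summarised with a percentile
    95% interval.
    """
    markers = config.markers or list(CHEMICAL_MARKERS + DNA_MARKERS)
    flags = [censor_col(m) for m in markers if censor_col(m) in train.columns]
    n_censored = int(train[flags].to_numpy(dtype=bool).sum()) if flags else 0
    if n_censored == 0:
        warnings.warn(
            "training data has no censored values; "
            "simulated-data fits are identical to the original fit",
            stacklevel=2,
        )
    rng = np.random.default_rng(scheme.seed)
    eval_table = test if test is not None else train
    base_tree = grow_tree(train, config, label_col=label_col)
    base_rep = report(
        eval_table[label_col].to_numpy(), base_tree.predict(eval_table), matrix=matrix
    )
    rows = []
    for s in range(n_simulations):
        sim = _impute_chemicals(train, scheme, rng, label_col, markers)
        tree = grow_tree(sim, config, label_col=label_col)
        rep = report(
            eval_table[label_col].to_numpy(), tree.predict(eval_table), matrix=matrix
        )
        rows.append({"simulation": s, **rep.as_dict()})
    sims = pd.DataFrame(rows)
    diffs = []
    base = base_rep.as_dict()
    for stat in ClassificationReport.STAT_NAMES:
        d = sims[stat].to_numpy(dtype=float) - base[stat]
        lo, hi = _percentile_ci(d)
        diffs.append(
            {"statistic": stat, "mean_diff": float(d.mean()), "lo95": lo, "hi95": hi}
        )
    return LorSimResult(
        original_report=base_rep,
        simulated=sims,
        paired_differences=pd.DataFrame(diffs),
        n_simulations=n_simulations,
    )


def cq_recode_comparison(
    train: pd.DataFrame,
    config: TreeConfig,
    test: pd.DataFrame | None = None,
    label_col: str = "supplier_label",
    matrix: SeverityMatrix | None = None,
) -> pd.DataFrame:
    """Compare trees fitted on raw vs LOR-recoded DNA Cq values.

    The baseline analysis uses Cq values as measured; the recode scenario
    sets every Cq above the LOR (36) to the assay maximum (40) before
    fitting. Returns the severity-report statistics of both fits side by
    side, evaluated on ``test`` if given.
    """
    from .preprocessing import recode_cq

    eval_table = test if test is not None else train
    rows = []
    for name, transform in (("raw", False), ("recoded", True)):
        tr, ev = train, eval_table
        if transform:
            tr = train.copy()
            ev = eval_table.copy()
            for m in DNA_MARKERS:
                if m in tr.columns:
                    tr[m] = recode_cq(tr[m].to_numpy())
                    ev[m] = recode_cq(ev[m].to_numpy())
        tree = grow_tree(tr, config, label_col=label_col)
        rep = report(ev[label_col].to_numpy(), tree.predict(ev), matrix=matrix)
        rows.append({"dna_treatment": name, **rep.as_dict()})
    return pd.DataFrame(rows)


# Systematic bias -----------------------------------------------------------

def inject_bias(
    table: pd.DataFrame,
    kind: MarkerKind | str,
    level: float,
    allow_any_level: bool = False,
) -> pd.DataFrame:
    """Multiply every marker value of one kind by ``1 + level``.

    Emulates systematic laboratory bias: chemical concentrations and DNA
    Cq values are biased in separate runs. Levels outside the assessed
    grid (0, +/-5, 10, 15, 20%) are rejected unless ``allow_any_level``.
    """
    kind = MarkerKind(kind)
    if not allow_any_level and not any(
        abs(level - l) < 1e-12 for l in BIAS_LEVELS
    ):
        raise ValueError(
            f"bias level {level} not in the assessed grid {sorted(set(BIAS_LEVELS))}"
        )
    out = table.copy()
    names = CHEMICAL_MARKERS if kind is MarkerKind.CHEMICAL else DNA_MARKERS
    for m in names:
        if m in out.columns:
            out[m] = out[m].astype(float) * (1.0 + level)
    return out


def bias_assessment(
    table: pd.DataFrame,
    option: CriteriaOption | str,
    levels=BIAS_LEVELS,
) -> pd.DataFrame:
    """Fraction of samples whose criteria label changes under each bias.

    One row per (marker kind, level) pair, comparing classification of the
    biased table against the unbiased one.
    """
    baseline = classify_table(table, option)
    rows = []
    for kind in (MarkerKind.CHEMICAL, MarkerKind.DNA):
        for level in levels:
            biased = inject_bias(table, kind, level)
            labels = classify_table(biased, option)
            rows.append(
                {
                    "marker_kind": kind.value,
                    "level": level,
                    "fraction_reclassified": float(np.mean(labels != baseline)),
                }
            )
    return pd.DataFrame(rows)


# Threshold rounding --------------------------------------------------------

def round_option(
    option: CriteriaOption, rounding_map: dict[float, float]
) -> CriteriaOption:
    """Apply a threshold rounding map to every predicate bound.

    Every distinct bound value appearing in the option must be a key of
    the map (mapping a value to itself leaves it unrounded).
    """

    def round_bound(v):
        if v is None:
            return None
        if v not in rounding_map:
            raise ValueError(f"rounding map does not cover threshold {v}")
        return rounding_map[v]

    def conv(pathways):
        return [
            Pathway(
                tuple(
                    Predicate(
                        p.marker,
                        round_bound(p.lower),
                        p.lower_inclusive,
                        round_bound(p.upper),
                        p.upper_inclusive,
                    )
                    for p in pw.predicates
                )
            )
            for pw in pathways
        ]

    return CriteriaOption(
        name=option.name + "_rounded",
        monofloral=conv(option.monofloral),
        multifloral=conv(option.multifloral),
    )


def identity_rounding_map(option: CriteriaOption) -> dict[float, float]:
    out = {}
    for pw in option.monofloral + option.multifloral:
        for p in pw.predicates:
            for v in (p.lower, p.upper):
                if v is not None:
                    out[v] = v
    return out


def rounding_assessment(
    option: CriteriaOption | str,
    rounding_map: dict[float, float],
    datasets: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Fraction of samples reclassified when thresholds are rounded.

    Classifies every dataset under the exact and the rounded rule sets and
    reports the fraction whose label changes.
    """
    if isinstance(option, str):
        from .criteria import load_option

        option = load_option(option)
    rounded = round_option(option, rounding_map)
    rows = []
    for name, df in datasets.items():
        exact_labels = classify_table(df, option)
        rounded_labels = classify_table(df, rounded)
        rows.append(
            {
                "dataset": name,
                "n": len(df),
                "fraction_reclassified": float(
                    np.mean(exact_labels != rounded_labels)
                ),
            }
        )
    return pd.DataFrame(rows)


# Scenario grid -------------------------------------------------------------

@dataclass
class Scenario:
    """One cell of the sensitivity scenario grid."""

    name: str
    train_year: str = "2014/15"
    islands: tuple[str, ...] | None = None  # None = both
    n_classes: int = 6
    markers: tuple[str, ...] = (
        "2'-MAP", "2-MBA", "3-PA", "4-HPA", "manuka_dna", "kanuka_dna",
    )
    test_years: tuple[str, ...] = ("2015/16", "archive")

    def __post_init__(self) -> None:
        if self.n_classes not in (4, 6):
            raise ValueError("response must have 4 or 6 classes")


def _scenario_tables(
    data: pd.DataFrame, scenario: Scenario, label_col: str
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    df = data.copy()
    if scenario.n_classes == 4:
        df[label_col] = df[label_col].map(collapse_to_four)
    train = df[df["year"] == scenario.train_year]
    if scenario.islands is not None:
        # island restriction applies to NZ samples; overseas classes are
        # always retained so every honey type can be classified
        nz = train["country"] == "NZ"
        train = train[~nz | train["island"].isin(scenario.islands)]
    tests = {
        y: df[df["year"] == y] for y in scenario.test_years if (df["year"] == y).any()
    }
    return train, tests


def run_scenarios(
    scenarios: list[Scenario],
    data: pd.DataFrame,
    config: TreeConfig | None = None,
    n_replicates: int = 200,
    seed: int = 0,
    label_col: str = "supplier_label",
    matrix: SeverityMatrix | None = None,
) -> pd.DataFrame:
    """Run the scenario grid: per scenario, bootstrap tree refits on the
    specified training subset and evaluation on the held-out year(s).

    Returns a tidy table (scenario, test_set, statistic, mean, lo95,
    hi95), with one ``within_sample`` test set per scenario plus one per
    held-out year. Scenarios with an empty training stratum are skipped
    with a warning.
    """
    rows = []
    for i, sc in enumerate(scenarios):
        base = config or TreeConfig()
        cfg = replace(base, markers=list(sc.markers))
        train, tests = _scenario_tables(data, sc, label_col)
        if train.empty or train[label_col].nunique() < 2:
            warnings.warn(f"scenario {sc.name!r}: empty training stratum, skipped",
                          stacklevel=2)
            continue
        eval_sets = {"within_sample": None, **tests}
        for test_name, test_df in eval_sets.items():
            res = bootstrap_cart(
                train,
                cfg,
                n_replicates=n_replicates,
                seed=seed + i,
                test=test_df,
                label_col=label_col,
                matrix=matrix,
            )
            for _, r in res.statistics.iterrows():
                rows.append(
                    {
                        "scenario": sc.name,
                        "train_year": sc.train_year,
                        "n_classes": sc.n_classes,
                        "test_set": test_name,
                        "statistic": r["statistic"],
                        "mean": r["mean"],
                        "lo95": r["lo95"],
                        "hi95": r["hi95"],
                    }
                )
    return pd.DataFrame(rows)
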