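"""Marker evaluation under left-censoring, and the linear-model analyses.

Concentrations below the limit of reporting (LOR) are left-censored. Rather
than substituting a fixed value, marker comparisons use imputation by
simulation with two rules applied per group:

1. *mixed rule* — if a group has values both below and above the LOR, each
   censored value is replaced by a Uniform(0, LOR) draw;
2. *all-below rule* — if every value in the group is censored, each is
   replaced by ``LOR * Beta(1, 40)``, giving a consistently left-skewed
   distribution near zero (mean LOR/41).

Many simulated datasets (1000 by default) are analysed with a one-way
ANOVA, Tukey HSD pairwise comparisons and Benjamini-Hochberg adjustment,
and the results are aggregated: the proportion of simulations in which a
pair of groups differed at alpha = 0.05, the mean difference and its mean
standard error, and winsorised-variance group means.

The module also houses the heteroscedastic (per-group variance) ANOVA used
for the manuka DNA Cq comparisons, the storage-stability ANOVA, the
regional/temporal linear models, and the nectar habitat analysis.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .markers import HONEY_LOR
from .preprocessing import standardise_nectar_table
from .samples import censor_col

ALPHA = 0.05


@dataclass
class ImputationScheme:
    """Below-LOR imputation rules.

    ``beta_shapes`` defaults to (1, 40): scaled by the LOR this keeps
    imputed all-censored groups strongly left-skewed with mean LOR/41.
    """

    lor: float = HONEY_LOR
    n_simulations: int = 1000
    beta_shapes: tuple[float, float] = (1.0, 40.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lor <= 0:
            raise ValueError("LOR must be positive")
        if self.n_simulations < 1:
            raise ValueError("need at least one simulation")


def impute_below_lor(
    values,
    censored,
    scheme: ImputationScheme,
    rng: np.random.Generator,
) -> np.ndarray:
    """Impute censored values within one group.

    If the group mixes censored and uncensored values, censored entries get
    Uniform(0, LOR) draws; if every entry is censored, each gets a
    ``LOR * Beta(1, 40)`` draw. Uncensored values are never altered. Exact
    zeros from the uniform rule (a probability-zero event) are redrawn so
    the subsequent log transform stays finite.
    """
    vals = np.asarray(values, dtype=float)
    mask = np.asarray(censored, dtype=bool)
    if vals.size == 0:
        raise ValueError("group is empty")
    out = vals.copy()
    n_c = int(mask.sum())
    if n_c == 0:
        return out
    if mask.all():
        a, b = scheme.beta_shapes
        draws = scheme.lor * rng.beta(a, b, size=n_c)
    else:
        draws = rng.uniform(0.0, scheme.lor, size=n_c)
    while np.any(draws == 0.0):  # keep log-transformable
        zero = draws == 0.0
        draws[zero] = rng.uniform(0.0, scheme.lor, size=int(zero.sum()))
    out[mask] = draws
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def tukey_hsd(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons from a one-way layout.

    Uses the studentized-range distribution with the Tukey-Kramer
    correction for unbalanced group sizes. Returns one row per unordered
    pair with the mean difference, its standard error, the q statistic and
    the unadjusted Tukey p-value.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("Tukey HSD needs at least two groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    n = {g: a.size for g, a in arrays.items()}
    means = {g: a.mean() for g, a in arrays.items()}
    N = sum(n.values())
    k = len(names)
    df_err = N - k
    if df_err <= 0:
        raise ValueError("no residual degrees of freedom")
    sse = sum(((a - means[g]) ** 2).sum() for g, a in arrays.items())
    mse = sse / df_err
    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        diff = means[g2] - means[g1]
        se = np.sqrt(mse / 2.0 * (1.0 / n[g1] + 1.0 / n[g2]))
        if se == 0.0:
            q = 0.0 if diff == 0 else np.inf
        else:
            q = abs(diff) / se
        p = float(stats.studentized_range.sf(q, k, df_err))
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "difference": diff,
                "se": se * np.sqrt(2.0),  # SE of the difference itself
                "q": q,
                "p": min(p, 1.0),
            }
        )
    return pd.DataFrame(rows)


def winsorised_mean_variance(values, trim_fraction: float = 0.2):
    """Winsorised mean and variance.

    The lowest and highest ``floor(trim * n)`` order statistics are
    replaced by the adjacent retained values before computing the mean and
    the (ddof=1) variance.
    """
    if not 0.0 <= trim_fraction < 0.5:
        raise ValueError("trim fraction must be in [0, 0.5)")
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two values")
    w = np.asarray(
        stats.mstats.winsorize(arr, limits=(trim_fraction, trim_fraction))
    )
    return float(w.mean()), float(w.var(ddof=1))


@dataclass
class CensoredAnovaResult:
    """Aggregate of the repeated imputed-data ANOVA."""

    marker: str
    group_factor: str
    n_simulations: int
    pairwise: pd.DataFrame  # group1, group2, proportion_significant, mean_difference, mean_se
    group_means: pd.DataFrame  # group, winsorised_mean, winsorised_variance, n, n_censored
    warnings: list[str] = field(default_factory=list)


def run_censored_anova(
    table: pd.DataFrame,
    group_factor: str,
    marker: str,
    scheme: ImputationScheme,
    log_scale: bool = True,
    trim_fraction: float = 0.2,
) -> CensoredAnovaResult:
    """Repeated-imputation one-way ANOVA with Tukey HSD and BH adjustment.

    Per simulation: impute below-LOR values per group on the raw scale,
    optionally log-transform, fit the one-way ANOVA, compute Tukey HSD
    pairwise p-values and BH-adjust them within the family. Aggregates the
    per-pair significance proportion at alpha = 0.05 and mean
    difference/SE, plus winsorised-variance group means across simulations.
    """
    rng = np.random.default_rng(scheme.seed)
    groups = sorted(table[group_factor].dropna().unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    raw: dict[str, np.ndarray] = {}
    cens: dict[str, np.ndarray] = {}
    warn: list[str] = []
    flag = censor_col(marker)
    for g in groups:
        sub = table[table[group_factor] == g]
        raw[g] = sub[marker].to_numpy(dtype=float)
        cens[g] = (
            sub[flag].to_numpy(dtype=bool)
            if flag in sub.columns
            else np.zeros(len(sub), dtype=bool)
        )
        if raw[g].size < 2:
            warn.append(f"group {g!r} has n={raw[g].size} (degenerate)")

    pairs = list(itertools.combinations(groups, 2))
    sig = {p: 0 for p in pairs}
    diffs = {p: [] for p in pairs}
    ses = {p: [] for p in pairs}
    sim_means = {g: [] for g in groups}
    for _ in range(scheme.n_simulations):
        filled = {
            g: impute_below_lor(raw[g], cens[g], scheme, rng) for g in groups
        }
        if log_scale:
            filled = {g: np.log(v) for g, v in filled.items()}
        tk = tukey_hsd(filled)
        tk["p_adj"] = bh_adjust(tk["p"].to_numpy())
        for _, row in tk.iterrows():
            key = (row["group1"], row["group2"])
            if row["p_adj"] < ALPHA:
                sig[key] += 1
            diffs[key].append(row["difference"])
            ses[key].append(row["se"])
        for g in groups:
            sim_means[g].append(filled[g].mean())

    pw = pd.DataFrame(
        {
            "group1": [p[0] for p in pairs],
            "group2": [p[1] for p in pairs],
            "proportion_significant": [
                sig[p] / scheme.n_simulations for p in pairs
            ],
            "mean_difference": [float(np.mean(diffs[p])) for p in pairs],
            "mean_se": [float(np.mean(ses[p])) for p in pairs],
        }
    )
    gm_rows = []
    for g in groups:
        arr = np.asarray(sim_means[g])
        if arr.size >= 2 and scheme.n_simulations >= 2:
            wm, wv = winsorised_mean_variance(arr, trim_fraction)
        else:
            wm, wv = float(arr.mean()), float("nan")
        gm_rows.append(
            {
                "group": g,
                "winsorised_mean": wm,
                "winsorised_variance": wv,
                "n": int(raw[g].size),
                "n_censored": int(cens[g].sum()),
            }
        )
    return CensoredAnovaResult(
        marker=marker,
        group_factor=group_factor,
        n_simulations=scheme.n_simulations,
        pairwise=pw,
        group_means=pd.DataFrame(gm_rows),
        warnings=warn,
    )


# Heteroscedastic one-way ANOVA (per-group variances) -----------------------

@dataclass
class HeteroscedasticAnovaResult:
    group_means: dict[str, float]
    group_variances: dict[str, float]
    group_sizes: dict[str, int]
    lr_mean: float       # group-effect LR test (per-group variances kept)
    df_mean: int
    p_mean: float
    lr_variance: float   # variance-structure LR test (group means kept)
    df_variance: int
    p_variance: float


def _gaussian_llf(resid_sq_by_group: dict[str, np.ndarray], variances) -> float:
    llf = 0.0
    for g, r2 in resid_sq_by_group.items():
        v = variances[g] if isinstance(variances, dict) else variances
        llf += -0.5 * (r2.size * np.log(2 * np.pi * v) + r2.sum() / v)
    return float(llf)


def heteroscedastic_anova(
    table: pd.DataFrame, group_factor: str, value_col: str
) -> HeteroscedasticAnovaResult:
    """One-way Gaussian ANOVA with a separate residual variance per group.

    Maximum-likelihood fit of group means with a per-group variance
    structure (the model used for the manuka DNA Cq comparison, where
    variance depends on honey type). Reports two likelihood-ratio tests:
    the group-mean effect (against a common-mean model that keeps the
    per-group variances) and the variance structure itself (against a
    pooled-variance model with the same means).
    """
    groups = sorted(table[group_factor].dropna().unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    data = {
        g: table.loc[table[group_factor] == g, value_col].to_numpy(dtype=float)
        for g in groups
    }
    for g, a in data.items():
        if a.size < 2:
            raise ValueError(f"group {g!r} has n < 2; variance undefined")

    means = {g: float(a.mean()) for g, a in data.items()}
    variances = {g: float(a.var(ddof=0)) for g, a in data.items()}
    r2_full = {g: (a - means[g]) ** 2 for g, a in data.items()}
    llf_full = _gaussian_llf(r2_full, variances)

    # Null for the mean effect: common mean, free per-group variances (IRLS).
    y_all = np.concatenate(list(data.values()))
    mu = float(y_all.mean())
    v_null = dict(variances)
    for _ in range(200):
        w = np.array([data[g].size / max(v_null[g], 1e-12) for g in groups])
        s = np.array([data[g].sum() / max(v_null[g], 1e-12) for g in groups])
        mu_new = float(s.sum() / w.sum())
        v_new = {g: float(((data[g] - mu_new) ** 2).mean()) for g in groups}
        if abs(mu_new - mu) < 1e-12:
            mu, v_null = mu_new, v_new
            break
        mu, v_null = mu_new, v_new
    r2_null = {g: (a - mu) ** 2 for g, a in data.items()}
    llf_null = _gaussian_llf(r2_null, v_null)
    lr_mean = max(2.0 * (llf_full - llf_null), 0.0)
    df_mean = len(groups) - 1
    p_mean = float(stats.chi2.sf(lr_mean, df_mean))

    # Variance-structure test: same group means, pooled variance.
    pooled = float(np.concatenate(list(r2_full.values())).mean())
    llf_hom = _gaussian_llf(r2_full, pooled)
    lr_var = max(2.0 * (llf_full - llf_hom), 0.0)
    df_var = len(groups) - 1
    p_var = float(stats.chi2.sf(lr_var, df_var))

    return HeteroscedasticAnovaResult(
        group_means=means,
        group_variances=variances,
        group_sizes={g: int(a.size) for g, a in data.items()},
        lr_mean=lr_mean,
        df_mean=df_mean,
        p_mean=p_mean,
        lr_variance=lr_var,
        df_variance=df_var,
        p_variance=p_var,
    )


# Stability, regional/temporal and habitat analyses -------------------------

def stability_analysis(
    stability: pd.DataFrame, markers: list[str]
) -> dict[str, dict]:
    """Storage-stability ANOVA per marker.

    Replicates are first averaged to one mean per sample x condition cell
    (significance testing uses per-sample means). Two additive models are
    fitted per marker: concentration ~ sample + temperature (temperature a
    factor including the time-zero level) and concentration ~ sample +
    date. A step-wise check fits the interaction on the replicate-level
    data and reports whether it is significant at alpha = 0.05.
    """
    required = {"sample", "temperature", "day", "replicate"}
    if not required <= set(stability.columns):
        raise ValueError(f"stability table must have columns {sorted(required)}")
    if stability["sample"].nunique() < 2:
        raise ValueError("stability ANOVA needs at least two distinct samples")
    cells = stability.groupby(["sample", "temperature"], as_index=False)
    n_cells = cells.size()
    expected = stability["sample"].nunique() * stability["temperature"].nunique()
    if len(n_cells) != expected:
        raise ValueError("missing cells in the sample x temperature layout")

    out: dict[str, dict] = {}
    for m in markers:
        means = stability.groupby(
            ["sample", "temperature"], as_index=False
        ).agg(value=(m, "mean"), day=("day", "first"))
        means["date"] = np.where(means["day"] > 0, "final", "t0")

        fit_t = smf.ols("value ~ C(sample) + C(temperature)", means).fit()
        an_t = sm.stats.anova_lm(fit_t, typ=2)
        fit_d = smf.ols("value ~ C(sample) + C(date)", means).fit()
        an_d = sm.stats.anova_lm(fit_d, typ=2)

        reps = stability[["sample", "temperature", "day", m]].rename(
            columns={m: "value"}
        )
        inter = smf.ols("value ~ C(sample) * C(temperature)", reps).fit()
        add = smf.ols("value ~ C(sample) + C(temperature)", reps).fit()
        cmp_ = sm.stats.anova_lm(add, inter)
        p_int = float(cmp_["Pr(>F)"].iloc[-1])

        out[m] = {
            "temperature_F": float(an_t.loc["C(temperature)", "F"]),
            "temperature_p": float(an_t.loc["C(temperature)", "PR(>F)"]),
            "date_F": float(an_d.loc["C(date)", "F"]),
            "date_p": float(an_d.loc["C(date)", "PR(>F)"]),
            "interaction_p": p_int,
            "interaction_retained": p_int < ALPHA,
        }
    return out


@dataclass
class LinearModelResult:
    marker: str
    factor: str
    f_statistic: float
    p_value: float
    df_num: int
    df_den: int
    group_means: dict[str, float]
    n: int


def regional_temporal_model(
    table: pd.DataFrame, marker: str, factor: str
) -> LinearModelResult:
    """One-way linear model on log concentrations for a region/year factor.

    Censored rows carry no reportable concentration and are dropped; empty
    factor levels are dropped with a warning. Reports the omnibus F test
    and per-level means on the log scale.
    """
    flag = censor_col(marker)
    df = table[[factor, marker]].copy()
    if flag in table.columns:
        df = df[~table[flag].astype(bool)]
    df = df.dropna()
    levels = sorted(df[factor].unique())
    all_levels = sorted(table[factor].dropna().unique())
    dropped = sorted(set(all_levels) - set(levels))
    if dropped:
        warnings.warn(
            f"dropping empty levels for {marker}: {dropped}", stacklevel=2
        )
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has fewer than two non-empty levels")
    df["logv"] = np.log(df[marker].astype(float))
    fit = smf.ols(f"logv ~ C(Q('{factor}'))", df).fit()
    an = sm.stats.anova_lm(fit, typ=2)
    term = an.index[0]
    means = df.groupby(factor)["logv"].mean().to_dict()
    return LinearModelResult(
        marker=marker,
        factor=factor,
        f_statistic=float(an.loc[term, "F"]),
        p_value=float(an.loc[term, "PR(>F)"]),
        df_num=int(an.loc[term, "df"]),
        df_den=int(an.loc["Residual", "df"]),
        group_means={str(k): float(v) for k, v in means.items()},
        n=len(df),
    )


def habitat_analysis(
    nectar: pd.DataFrame,
    markers: list[str],
    scheme: ImputationScheme | None = None,
    heavy_censoring_threshold: float = 0.2,
) -> dict[str, dict]:
    """Habitat-effect tests for nectar markers on the sugar-equivalent scale.

    Lightly censored markers get the deterministic route: censored cells
    set to 0.1 mg/L, sugar-scale conversion, then a one-way linear model
    with the 5-level habitat factor. Markers whose censoring fraction
    exceeds ``heavy_censoring_threshold`` are routed through the
    imputation-simulation approach instead, reporting the proportion of
    simulations with a significant omnibus F.
    """
    out: dict[str, dict] = {}
    for m in markers:
        flag = censor_col(m)
        cens_frac = float(nectar[flag].astype(bool).mean())
        if cens_frac <= heavy_censoring_threshold:
            std = standardise_nectar_table(nectar, [m])
            fit = smf.ols(f"Q('{m}') ~ C(habitat)", std).fit()
            an = sm.stats.anova_lm(fit, typ=2)
            out[m] = {
                "method": "linear_model",
                "censored_fraction": cens_frac,
                "F": float(an.loc["C(habitat)", "F"]),
                "p": float(an.loc["C(habitat)", "PR(>F)"]),
            }
        else:
            sch = scheme or ImputationScheme(lor=0.01, n_simulations=200)
            rng = np.random.default_rng(sch.seed)
            habitats = sorted(nectar["habitat"].unique())
            n_sig = 0
            fs = []
            for _ in range(sch.n_simulations):
                groups = []
                for h in habitats:
                    sub = nectar[nectar["habitat"] == h]
                    vals = impute_below_lor(
                        sub[m].to_numpy(), sub[flag].to_numpy(), sch, rng
                    )
                    vals = vals * 80.0 / sub["sugar_content"].to_numpy()
                    groups.append(np.log(vals))
                f, p = stats.f_oneway(*groups)
                fs.append(f)
                if p < ALPHA:
                    n_sig += 1
            out[m] = {
                "method": "simulation",
                "censored_fraction": cens_frac,
                "mean_F": float(np.mean(fs)),
                "proportion_significant": n_sig / sch.n_simulations,
            }
    return out
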