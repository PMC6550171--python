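"""Standardisation applied to raw tables before any model fitting.

Three conventions are fixed here:

* nectar concentrations are rescaled to a mg/80%-sugar scale so samples of
  different sugar content are comparable;
* chemical concentrations are analysed on the natural-log scale;
* for the Cq-recode sensitivity scenario, DNA quantification cycles above
  the Cq 36 limit of reporting are recoded to the assay maximum of 40 (the
  baseline analyses use Cq values as measured, with no truncation).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markers import CQ_LOR, CQ_MAX, NECTAR_LOR
from .samples import censor_col


@dataclass(frozen=True)
class StandardisationRules:
    """The fixed constants of the standardisation step."""

    nectar_reference_sugar: float = 80.0   # % mass
    below_lor_substitute_nectar: float = 0.1  # mg/L, habitat analysis only
    cq_recode_threshold: float = CQ_LOR
    cq_recode_value: float = CQ_MAX

    def __post_init__(self) -> None:
        if not 0.0 < self.nectar_reference_sugar <= 100.0:
            raise ValueError("reference sugar must be in (0, 100]")
        if self.cq_recode_value < self.cq_recode_threshold:
            raise ValueError("Cq recode value must be >= the recode threshold")


DEFAULT_RULES = StandardisationRules()


def sugar_standardise(conc, sugar_content):
    """Convert a nectar concentration (mg/L) to the mg/80%-sugar scale.

    The scale expresses the marker mass per volume of nectar containing the
    reference 80% sugar, i.e. ``conc * 80 / sugar_content``; at the
    reference sugar content the conversion is the identity, and the result
    is strictly decreasing in sugar content.
    """
    sugar = np.asarray(sugar_content, dtype=float)
    if np.any(sugar <= 0):
        raise ValueError("sugar content must be positive")
    out = np.asarray(conc, dtype=float) * 80.0 / sugar
    return out if out.ndim else float(out)


def log_transform(conc):
    """Natural-log transform of positive concentrations."""
    arr = np.asarray(conc, dtype=float)
    if np.any(arr[~np.isnan(arr)] <= 0):
        raise ValueError("log transform requires strictly positive values")
    out = np.log(arr)
    return out if out.ndim else float(out)


def recode_cq(cq, rules: StandardisationRules = DEFAULT_RULES):
    """Recode Cq values above the LOR to the assay maximum.

    Values at or below the threshold pass through unchanged; values above
    it become the assay maximum (40 by default). Idempotent.
    """
    arr = np.asarray(cq, dtype=float)
    if np.any(arr <= 0) or np.any(arr > rules.cq_recode_value):
        raise ValueError(
            f"Cq values must lie in (0, {rules.cq_recode_value}]"
        )
    out = np.where(arr > rules.cq_recode_threshold, rules.cq_recode_value, arr)
    return out if out.ndim else float(out)


def substitute_below_lor_nectar(
    values,
    censored,
    rules: StandardisationRules = DEFAULT_RULES,
):
    """Replace censored nectar values by the fixed 0.1 mg/L substitute.

    Used only by the habitat analysis, where a deterministic stand-in below
    the 0.01 mg/L LOR region keeps the subsequent sugar-scale conversion
    well defined. Uncensored values are untouched.
    """
    vals = np.asarray(values, dtype=float)
    mask = np.asarray(censored, dtype=bool)
    out = np.where(mask, rules.below_lor_substitute_nectar, vals)
    return out if out.ndim else float(out)


def standardise_nectar_table(
    df: pd.DataFrame,
    markers: list[str],
    rules: StandardisationRules = DEFAULT_RULES,
) -> pd.DataFrame:
    """Habitat-analysis preprocessing of a nectar table.

    For each marker: censored cells -> 0.1 mg/L, then conversion to the
    mg/80%-sugar scale. Returns a copy with marker columns replaced by
    their sugar-scale equivalents (censor flags retained).
    """
    out = df.copy()
    for m in markers:
        vals = substitute_below_lor_nectar(
            out[m].to_numpy(), out[censor_col(m)].to_numpy(), rules
        )
        out[m] = sugar_standardise(vals, out["sugar_content"].to_numpy())
    return out
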