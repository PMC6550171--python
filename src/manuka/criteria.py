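"""Rule-based identification criteria for manuka honey.

A criteria option classifies a sample into one of three labels —
``monofloral``, ``multifloral`` or ``not_manuka`` — by evaluating one or
more *pathways* per target class, each a conjunction of per-marker
interval predicates. The published final criteria require, for any manuka
claim, presence of 2'-MAP, 2-MBA and 4-HPA at >= 1 mg/kg (the LOR),
3-PA >= 20 mg/kg and manuka DNA below Cq 36; 3-PA then separates
monofloral (>= 400 mg/kg) from multifloral (>= 20 but < 400 mg/kg).

Chemical values reported below the LOR ("<LOR") evaluate as a value below
1 mg/kg, so they fail every presence gate but satisfy upper-bound
predicates. Monofloral pathways are evaluated before multifloral ones.

Rule sets can also be extracted from a fitted classification tree: each
leaf predicting a target class becomes one pathway formed by intersecting
the interval conditions along its root-to-leaf path, with optional
threshold rounding.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cart import FittedTree
from .markers import HONEY_LOR
from .samples import censor_col

MONOFLORAL = "monofloral"
MULTIFLORAL = "multifloral"
NOT_MANUKA = "not_manuka"
CRITERIA_LABELS = (NOT_MANUKA, MULTIFLORAL, MONOFLORAL)


@dataclass(frozen=True)
class Predicate:
    """An interval constraint on one marker.

    Bounds are in marker units (mg/kg for chemicals, Cq for DNA); a missing
    bound means unconstrained on that side.
    """

    marker: str
    lower: float | None = None
    lower_inclusive: bool = True
    upper: float | None = None
    upper_inclusive: bool = False

    def __post_init__(self) -> None:
        if self.lower is not None and self.upper is not None:
            if not self.lower < self.upper:
                raise ValueError(
                    f"empty interval for {self.marker}: "
                    f"[{self.lower}, {self.upper}]"
                )

    def matches(self, value: float) -> bool:
        if self.lower is not None:
            if value < self.lower or (value == self.lower and not self.lower_inclusive):
                return False
        if self.upper is not None:
            if value > self.upper or (value == self.upper and not self.upper_inclusive):
                return False
        return True

    def __str__(self) -> str:
        parts = []
        if self.lower is not None:
            parts.append((">=" if self.lower_inclusive else ">") + f"{self.lower:g}")
        if self.upper is not None:
            parts.append(("<=" if self.upper_inclusive else "<") + f"{self.upper:g}")
        return " and ".join(parts) if parts else "NA"

    @classmethod
    def parse(cls, marker: str, text: str) -> "Predicate":
        """Parse a predicate string such as ``">=50 and <400"``."""
        lower = upper = None
        lower_inc = True
        upper_inc = False
        for token in re.split(r"\s+and\s+", text.strip()):
            m = re.fullmatch(r"(>=|<=|>|<)\s*([0-9.]+)", token.strip())
            if m is None:
                raise ValueError(f"cannot parse predicate token {token!r}")
            op, num = m.group(1), float(m.group(2))
            if op in (">=", ">"):
                lower, lower_inc = num, op == ">="
            else:
                upper, upper_inc = num, op == "<="
        return cls(marker, lower, lower_inc, upper, upper_inc)


@dataclass(frozen=True)
class Pathway:
    """A conjunction of predicates; all must hold for the pathway to fire."""

    predicates: tuple[Predicate, ...]

    def markers(self) -> list[str]:
        return [p.marker for p in self.predicates]

    def matches(self, values: dict[str, float]) -> bool:
        for p in self.predicates:
            if p.marker not in values:
                raise ValueError(f"sample is missing marker {p.marker!r}")
            if not p.matches(values[p.marker]):
                return False
        return True


@dataclass
class CriteriaOption:
    """A named rule set: pathways for monofloral and multifloral manuka."""

    name: str
    monofloral: list[Pathway] = field(default_factory=list)
    multifloral: list[Pathway] = field(default_factory=list)

    def markers(self) -> list[str]:
        out: list[str] = []
        for pw in self.monofloral + self.multifloral:
            for m in pw.markers():
                if m not in out:
                    out.append(m)
        return out

    @classmethod
    def from_dict(cls, name: str, spec: dict) -> "CriteriaOption":
        def build(pathways):
            return [
                Pathway(tuple(Predicate.parse(m, s) for m, s in pw.items()))
                for pw in pathways
            ]

        return cls(
            name=name,
            monofloral=build(spec.get("monofloral", [])),
            multifloral=build(spec.get("multifloral", [])),
        )


def _builtin_options() -> dict[str, CriteriaOption]:
    text = resources.files("manuka.data").joinpath("criteria.yaml").read_text()
    data = yaml.safe_load(text)
    return {name: CriteriaOption.from_dict(name, spec) for name, spec in data.items()}


_OPTIONS_CACHE: dict[str, CriteriaOption] | None = None


def load_option(name: str) -> CriteriaOption:
    """Load a built-in rule set: option1..option4, final, or option1_exact."""
    global _OPTIONS_CACHE
    if _OPTIONS_CACHE is None:
        _OPTIONS_CACHE = _builtin_options()
    try:
        return _OPTIONS_CACHE[name]
    except KeyError:
        raise ValueError(
            f"unknown criteria option {name!r}; "
            f"available: {sorted(_OPTIONS_CACHE)}"
        ) from None


def load_options_from_yaml(path: str | Path) -> dict[str, CriteriaOption]:
    data = yaml.safe_load(Path(path).read_text())
    return {name: CriteriaOption.from_dict(name, spec) for name, spec in data.items()}


def _effective_values(sample, markers: list[str], lor: float) -> dict[str, float]:
    """Marker values for predicate evaluation; censored chemicals -> LOR/2."""
    values: dict[str, float] = {}
    for m in markers:
        try:
            v = sample[m]
        except (KeyError, IndexError):
            raise ValueError(f"sample is missing marker {m!r}") from None
        flag = censor_col(m)
        censored = False
        try:
            censored = bool(sample[flag])
        except (KeyError, IndexError):
            pass
        if censored or (isinstance(v, float) and np.isnan(v)):
            v = lor / 2.0
        values[m] = float(v)
    return values


def apply_criteria(
    sample,
    option: CriteriaOption | str,
    lor: float = HONEY_LOR,
) -> str:
    """Classify one sample under a rule set.

    ``sample`` is any mapping from marker name to value (a dict, a pandas
    row, ...), optionally carrying ``<marker>_cens`` censor flags. Returns
    ``monofloral``, ``multifloral`` or ``not_manuka``.
    """
    if isinstance(option, str):
        option = load_option(option)
    values = _effective_values(sample, option.markers(), lor)
    if any(pw.matches(values) for pw in option.monofloral):
        return MONOFLORAL
    if any(pw.matches(values) for pw in option.multifloral):
        return MULTIFLORAL
    return NOT_MANUKA


def classify_table(
    table: pd.DataFrame,
    option: CriteriaOption | str,
    lor: float = HONEY_LOR,
) -> np.ndarray:
    """Vector of criteria labels for every row of a sample table."""
    if isinstance(option, str):
        option = load_option(option)
    return np.array(
        [apply_criteria(row, option, lor) for _, row in table.iterrows()],
        dtype=object,
    )


# Rule extraction from trees ------------------------------------------------

def extract_rules(
    tree: FittedTree,
    class_map: dict[str, str] | None = None,
    rounding_map: dict[float, float] | None = None,
) -> CriteriaOption:
    """Turn a fitted tree into a criteria option.

    Each leaf predicting a mapped target class becomes one pathway: the
    conjunction of the conditions along its root-to-leaf path, merged into
    a single interval per marker (left edges contribute inclusive lower
    bounds, right edges exclusive upper bounds). ``rounding_map`` replaces
    exact thresholds by rounded ones after merging.
    """
    class_map = class_map or {"M": MONOFLORAL, "MB": MULTIFLORAL}
    rounding_map = rounding_map or {}
    pathways: dict[str, list[Pathway]] = {MONOFLORAL: [], MULTIFLORAL: []}

    def walk(node, bounds: dict[str, tuple[float | None, float | None]]):
        if node.is_leaf:
            target = class_map.get(node.predicted_class)
            if target is not None:
                preds = []
                for m, (lo, hi) in bounds.items():
                    lo = rounding_map.get(lo, lo)
                    hi = rounding_map.get(hi, hi)
                    preds.append(
                        Predicate(m, lower=lo, lower_inclusive=True,
                                  upper=hi, upper_inclusive=False)
                    )
                pathways[target].append(Pathway(tuple(preds)))
            return
        m, t = node.split_marker, node.split_threshold
        lo, hi = bounds.get(m, (None, None))
        left_bounds = dict(bounds)
        left_bounds[m] = (t if lo is None else max(lo, t), hi)
        right_bounds = dict(bounds)
        right_bounds[m] = (lo, t if hi is None else min(hi, t))
        walk(node.left, left_bounds)
        walk(node.right, right_bounds)

    walk(tree.root, {})
    for target, cls in ((MONOFLORAL, "M"), (MULTIFLORAL, "MB")):
        if cls in class_map and not pathways[target]:
            warnings.warn(
                f"tree has no leaf predicting {cls!r}; "
                f"{target} pathway set is empty",
                stacklevel=2,
            )
    return CriteriaOption(
        name="extracted",
        monofloral=pathways[MONOFLORAL],
        multifloral=pathways[MULTIFLORAL],
    )


# Supplier-comparison summary ----------------------------------------------

#: Display rows of the supplier-comparison table; AU and NN are reported
#: together as honey from Australia and other countries.
_SUMMARY_ROWS = (
    ("Monofloral manuka", ("M",)),
    ("Multifloral manuka", ("MB",)),
    ("Kanuka", ("K",)),
    ("Non-manuka", ("NM",)),
    ("Australian and other countries honey", ("AU", "NN")),
)


def summarise_vs_supplier(
    table: pd.DataFrame,
    option: CriteriaOption | str,
    label_col: str = "supplier_label",
    lor: float = HONEY_LOR,
) -> pd.DataFrame:
    """Cross-tabulate criteria labels against supplier identifications.

    One row per supplier group with the sample count and the row
    percentages classified not manuka / multifloral / monofloral.
    """
    if len(table) == 0:
        raise ValueError("empty sample table")
    labels = classify_table(table, option, lor)
    sup = table[label_col].astype(str).to_numpy()
    rows = []
    for display, classes in _SUMMARY_ROWS:
        mask = np.isin(sup, classes)
        n = int(mask.sum())
        if n == 0:
            continue
        sub = labels[mask]
        rows.append(
            {
                "supplier_identification": display,
                "n_samples": n,
                "not_manuka_pct": 100.0 * float(np.mean(sub == NOT_MANUKA)),
                "multifloral_pct": 100.0 * float(np.mean(sub == MULTIFLORAL)),
                "monofloral_pct": 100.0 * float(np.mean(sub == MONOFLORAL)),
            }
        )
    return pd.DataFrame(rows)
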