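"""Severity-graded assessment of honey-type predictions.

Because there is no gold standard for honey type and supplier labels are
themselves noisy, a flat error rate is misleading. Misclassifications are
instead graded on an ordered scale — irrelevant < mild < severe — by a
6x6 severity matrix over (supplier label, predicted label) pairs. For
example, calling a non-manuka honey "monofloral manuka" is severe, while
confusing the two overseas classes is irrelevant for authentication.

The default matrix encodes:

* mild — types plausibly confusable with multifloral manuka (monofloral
  manuka, kanuka or non-manuka predicted as multifloral) and the reverse
  moves out of multifloral into its neighbours;
* severe — any honey without a manuka claim predicted as monofloral or
  multifloral manuka (non-manuka, Australian or non-NZ/Aus predicted M or
  MB) and supplier monofloral manuka predicted right out of the manuka
  group (as NM, AU or NN);
* irrelevant — every remaining off-diagonal cell.

The summary report also carries the monofloral-manuka false positive and
false negative rates, overall (OFP/OFN) and restricted to severe cells
(SFP/SFN).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

CLASSES = ("M", "MB", "K", "NM", "AU", "NN")

CORRECT = "correct"
IRRELEVANT = "irrelevant"
MILD = "mild"
SEVERE = "severe"
CATEGORIES = (CORRECT, IRRELEVANT, MILD, SEVERE)

_DEFAULT_MILD = {("M", "MB"), ("K", "MB"), ("NM", "MB"), ("MB", "M"), ("MB", "K")}
_DEFAULT_SEVERE = {
    ("NM", "M"),
    ("AU", "M"),
    ("AU", "MB"),
    ("NN", "M"),
    ("NN", "MB"),
    ("M", "NM"),
    ("M", "NN"),
    ("M", "AU"),
}


@dataclass(frozen=True)
class SeverityMatrix:
    """6x6 map from (supplier label, predicted label) to a severity category."""

    cells: dict[tuple[str, str], str]

    def __post_init__(self) -> None:
        for s in CLASSES:
            for p in CLASSES:
                cat = self.cells.get((s, p))
                if cat is None:
                    raise ValueError(f"severity matrix missing cell ({s}, {p})")
                if s == p and cat != CORRECT:
                    raise ValueError("diagonal cells must be 'correct'")
                if cat not in CATEGORIES:
                    raise ValueError(f"unknown severity category {cat!r}")

    @classmethod
    def default(cls) -> "SeverityMatrix":
        cells = {}
        for s in CLASSES:
            for p in CLASSES:
                if s == p:
                    cells[(s, p)] = CORRECT
                elif (s, p) in _DEFAULT_SEVERE:
                    cells[(s, p)] = SEVERE
                elif (s, p) in _DEFAULT_MILD:
                    cells[(s, p)] = MILD
                else:
                    cells[(s, p)] = IRRELEVANT
        return cls(cells)

    def grade(self, supplier_label: str, predicted_label: str) -> str:
        try:
            return self.cells[(str(supplier_label), str(predicted_label))]
        except KeyError:
            raise ValueError(
                f"unknown label pair ({supplier_label!r}, {predicted_label!r})"
            ) from None

    # I/O --------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.cells[(s, p)] for p in CLASSES] for s in CLASSES],
            index=list(CLASSES),
            columns=list(CLASSES),
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="supplier")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SeverityMatrix":
        df = pd.read_csv(path, index_col=0)
        cells = {
            (str(s), str(p)): str(df.loc[s, p]) for s in df.index for p in df.columns
        }
        return cls(cells)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SeverityMatrix":
        data = yaml.safe_load(Path(path).read_text())
        cells = {
            (str(s), str(p)): str(cat)
            for s, row in data.items()
            for p, cat in row.items()
        }
        return cls(cells)


def grade(supplier_label: str, predicted_label: str,
          matrix: SeverityMatrix | None = None) -> str:
    """Severity category of a single (supplier, predicted) label pair."""
    matrix = matrix or SeverityMatrix.default()
    return matrix.grade(supplier_label, predicted_label)


@dataclass
class ClassificationReport:
    """Severity-graded summary of a prediction set.

    Rates are fractions in [0, 1]; ``correct + irrelevant + mild + severe``
    is exactly 1. OFP is the fraction of non-monofloral-supplier samples
    predicted monofloral manuka; OFN the fraction of supplier-monofloral
    samples predicted otherwise; SFP/SFN restrict those to severe cells.
    """

    n: int
    correct: float
    irrelevant: float
    mild: float
    severe: float
    ofp: float
    ofn: float
    sfp: float
    sfn: float

    def as_dict(self) -> dict[str, float]:
        return {
            "n": self.n,
            "correct": self.correct,
            "irrelevant": self.irrelevant,
            "mild": self.mild,
            "severe": self.severe,
            "OFP": self.ofp,
            "OFN": self.ofn,
            "SFP": self.sfp,
            "SFN": self.sfn,
        }

    STAT_NAMES = ("correct", "irrelevant", "mild", "severe", "OFP", "OFN", "SFP", "SFN")


def report(
    supplier_labels,
    predictions,
    matrix: SeverityMatrix | None = None,
    positive_class: str = "M",
) -> ClassificationReport:
    """Severity-graded classification report against supplier labels."""
    matrix = matrix or SeverityMatrix.default()
    sup = np.asarray(supplier_labels, dtype=object)
    pred = np.asarray(predictions, dtype=object)
    if sup.size != pred.size:
        raise ValueError("label vectors must have equal length")
    if sup.size == 0:
        raise ValueError("empty input")
    grades = np.array([matrix.grade(s, p) for s, p in zip(sup, pred)], dtype=object)
    n = sup.size
    frac = {c: float(np.mean(grades == c)) for c in CATEGORIES}

    is_sup_pos = sup == positive_class
    is_pred_pos = pred == positive_class
    n_pos = int(is_sup_pos.sum())
    n_neg = n - n_pos
    fp = is_pred_pos & ~is_sup_pos
    fn = ~is_pred_pos & is_sup_pos
    ofp = float(fp.sum() / n_neg) if n_neg else 0.0
    ofn = float(fn.sum() / n_pos) if n_pos else 0.0
    sfp = float((fp & (grades == SEVERE)).sum() / n_neg) if n_neg else 0.0
    sfn = float((fn & (grades == SEVERE)).sum() / n_pos) if n_pos else 0.0
    return ClassificationReport(
        n=n,
        correct=frac[CORRECT],
        irrelevant=frac[IRRELEVANT],
        mild=frac[MILD],
        severe=frac[SEVERE],
        ofp=ofp,
        ofn=ofn,
        sfp=sfp,
        sfn=sfn,
    )
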