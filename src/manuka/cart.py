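"""Binary classification trees with gini impurity under explicit class priors.

This is a from-scratch CART engine matching the fitting semantics used to
derive the honey identification criteria: the impurity function is the
gini index computed on *prior-adjusted* class proportions, and class
priors are explicit (uniform by default) rather than estimated from the
data — with strongly unbalanced honey-type sample sizes, empirical priors
would let the large classes dominate every split.

Prior-adjusted node quantities, for priors ``pi_j`` and training class
totals ``n_j``:

    p(j, t) = pi_j * n_j(t) / n_j          (joint mass of class j at node t)
    p(t)    = sum_j p(j, t)                (node mass; 1 at the root)
    p(j|t)  = p(j, t) / p(t)               (class proportions at the node)
    I(t)    = 1 - sum_j p(j|t)^2           (gini impurity)

A split of t into (L, R) is scored by the impurity decrease

    dI = p(t) I(t) - p(L) I(L) - p(R) I(R)

maximised by exhaustive search over features and candidate thresholds
(midpoints between consecutive distinct sorted values). Splitting stops at
the usual recursive-partitioning defaults (minimum 20 samples to split,
minimum leaf size 7, maximum depth 30) and when the best decrease falls
below ``complexity_threshold`` times the root impurity mass (the relative
improvement criterion at root scale).

Routing convention: an internal node tests ``value >= threshold``; if the
condition is met the sample takes the left branch, otherwise the right.
Ties in dI are broken deterministically by feature order, then by the
smaller threshold.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .markers import HONEY_LOR, marker_kind, MarkerKind
from .samples import censor_col


@dataclass
class TreeConfig:
    """Fitting parameters of the classification tree."""

    priors: dict[str, float] | None = None  # None -> uniform over observed classes
    min_samples_to_split: int = 20
    min_leaf_size: int = 7
    complexity_threshold: float = 0.01
    max_depth: int = 30
    markers: list[str] | None = None
    #: Value substituted for a censored chemical concentration when building
    #: the design matrix ("<LOR" cells); half the honey LOR by default.
    censored_fill: float = HONEY_LOR / 2.0

    def __post_init__(self) -> None:
        if self.min_leaf_size > self.min_samples_to_split:
            raise ValueError("min_leaf_size must be <= min_samples_to_split")
        if self.complexity_threshold < 0:
            raise ValueError("complexity_threshold must be >= 0")
        if self.priors is not None:
            vals = np.array(list(self.priors.values()), dtype=float)
            if np.any(vals <= 0) or abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError("priors must be positive and sum to 1")


@dataclass
class TreeNode:
    counts: dict[str, int]
    proportions: dict[str, float]
    mass: float
    predicted_class: str
    depth: int
    split_marker: str | None = None
    split_threshold: float | None = None
    left: "TreeNode | None" = None   # condition value >= threshold met
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split_marker is None

    def to_dict(self) -> dict:
        d = {
            "counts": self.counts,
            "proportions": self.proportions,
            "mass": self.mass,
            "predicted_class": self.predicted_class,
            "depth": self.depth,
        }
        if not self.is_leaf:
            d["split_marker"] = self.split_marker
            d["split_threshold"] = self.split_threshold
            d["left"] = self.left.to_dict()
            d["right"] = self.right.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        node = cls(
            counts={k: int(v) for k, v in d["counts"].items()},
            proportions=d["proportions"],
            mass=d["mass"],
            predicted_class=d["predicted_class"],
            depth=d["depth"],
        )
        if "split_marker" in d:
            node.split_marker = d["split_marker"]
            node.split_threshold = d["split_threshold"]
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


def node_probabilities(counts, class_totals, priors):
    """Prior-adjusted class proportions and mass of a node.

    ``p(j|t) = pi_j n_j(t)/n_j`` normalised to sum 1, and the node mass
    ``p(t) = sum_j pi_j n_j(t)/n_j``. Every class must have a positive
    training total.
    """
    counts = np.asarray(counts, dtype=float)
    totals = np.asarray(class_totals, dtype=float)
    pi = np.asarray(priors, dtype=float)
    if np.any(totals <= 0):
        raise ValueError("every class needs a positive training total")
    joint = pi * counts / totals
    mass = joint.sum()
    if mass <= 0:
        raise ValueError("empty node")
    return joint / mass, float(mass)


def gini_impurity(proportions) -> float:
    """Gini index ``1 - sum_j p(j|t)^2`` of a probability vector."""
    p = np.asarray(proportions, dtype=float)
    return float(1.0 - np.sum(p * p))


def _node_from_counts(counts: np.ndarray, classes, weights, depth) -> TreeNode:
    joint = weights * counts
    mass = joint.sum()
    props = joint / mass
    pred = classes[int(np.argmax(props))]
    return TreeNode(
        counts={c: int(n) for c, n in zip(classes, counts)},
        proportions={c: float(p) for c, p in zip(classes, props)},
        mass=float(mass),
        predicted_class=pred,
        depth=depth,
    )


def _best_split_arrays(X, y_idx, n_classes, weights, config):
    """Exhaustive split search at one node.

    Returns (feature index, threshold, dI) maximising the prior-adjusted
    impurity decrease, or None if no admissible split exists. ``weights``
    is ``pi_j / n_j``. Tie-break: lower feature index, then lower
    threshold.
    """
    n = y_idx.size
    counts = np.bincount(y_idx, minlength=n_classes).astype(float)
    a_parent = weights * counts
    mass_parent = a_parent.sum()
    parent_impurity_mass = mass_parent - (a_parent**2).sum() / mass_parent
    if parent_impurity_mass <= 0:
        return None
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), y_idx] = 1.0

    best = None  # (dI, feature, threshold)
    for f in range(X.shape[1]):
        x = X[:, f]
        # descending sort: the left child (value >= threshold) is a prefix
        order = np.argsort(-x, kind="stable")
        xs = x[order]
        if xs[0] == xs[-1]:
            continue  # constant feature
        # cumulative counts kept integral so per-candidate arithmetic is
        # exact and ties resolve deterministically by feature order
        cum = np.cumsum(onehot[order], axis=0)
        i = np.arange(1, n)
        valid = xs[:-1] != xs[1:]
        valid &= (i >= config.min_leaf_size) & (n - i >= config.min_leaf_size)
        if not valid.any():
            continue
        aL = cum[:-1] * weights         # boundary i: left = first i samples
        mL = aL.sum(axis=1)
        aR = (counts[None, :] - cum[:-1]) * weights
        mR = aR.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            gL = mL - (aL**2).sum(axis=1) / mL
            gR = mR - (aR**2).sum(axis=1) / mR
        delta = parent_impurity_mass - gL - gR
        delta[~valid] = -np.inf
        dmax = delta.max()
        if dmax <= 0:
            continue
        idx = np.flatnonzero(delta == dmax)
        thr = (xs[idx] + xs[idx + 1]) / 2.0
        t = float(thr.min())  # lowest threshold among exact ties
        if best is None or dmax > best[0]:
            best = (float(dmax), f, t)
    return best


def design_matrix(
    table: pd.DataFrame, markers: list[str], censored_fill: float
) -> np.ndarray:
    """Numeric feature matrix; censored chemical cells get ``censored_fill``."""
    cols = []
    for m in markers:
        v = table[m].to_numpy(dtype=float).copy()
        flag = censor_col(m)
        if marker_kind(m) is MarkerKind.CHEMICAL and flag in table.columns:
            v[table[flag].to_numpy(dtype=bool)] = censored_fill
        if np.any(np.isnan(v)):
            raise ValueError(f"marker {m!r} has unflagged missing values")
        cols.append(v)
    return np.column_stack(cols)


@dataclass
class FittedTree:
    """A fitted classification tree plus everything needed to apply it."""

    root: TreeNode
    config: TreeConfig
    classes: list[str]
    class_totals: dict[str, int]
    markers: list[str]
    metadata: dict = field(default_factory=dict)

    # prediction ------------------------------------------------------
    def predict_row(self, row) -> tuple[str, dict[str, float]]:
        node = self.root
        while not node.is_leaf:
            m = node.split_marker
            try:
                v = row[m]
            except (KeyError, IndexError):
                raise ValueError(f"sample is missing marker {m!r}") from None
            if v is None or (isinstance(v, float) and np.isnan(v)):
                raise ValueError(f"sample is missing marker {m!r}")
            node = node.left if v >= node.split_threshold else node.right
        return node.predicted_class, node.proportions

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = design_matrix(table, self.markers, self.config.censored_fill)
        out = np.empty(len(table), dtype=object)
        for i in range(len(table)):
            row = dict(zip(self.markers, X[i]))
            out[i], _ = self.predict_row(row)
        return out

    # introspection ---------------------------------------------------
    def depth(self) -> int:
        def d(node):
            if node.is_leaf:
                return node.depth
            return max(d(node.left), d(node.right))
        return d(self.root)

    def markers_used(self) -> set[str]:
        used = set()

        def walk(node):
            if not node.is_leaf:
                used.add(node.split_marker)
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return used

    def first_split(self) -> tuple[str, float] | None:
        if self.root.is_leaf:
            return None
        return self.root.split_marker, self.root.split_threshold

    def leaves(self) -> list[TreeNode]:
        out = []

        def walk(node):
            if node.is_leaf:
                out.append(node)
            else:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    # serialisation ---------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "classes": self.classes,
            "class_totals": self.class_totals,
            "markers": self.markers,
            "metadata": self.metadata,
            "root": self.root.to_dict(),
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FittedTree":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        return cls(
            root=TreeNode.from_dict(doc["root"]),
            config=TreeConfig(markers=doc["markers"]),
            classes=doc["classes"],
            class_totals={k: int(v) for k, v in doc["class_totals"].items()},
            markers=doc["markers"],
            metadata=doc.get("metadata", {}),
        )

    def rules_text(self) -> str:
        """Readable rule paths; the met condition takes the left branch."""
        lines: list[str] = []

        def walk(node, indent):
            pad = "  " * indent
            if node.is_leaf:
                props = ", ".join(
                    f"{c}={p:.2f}" for c, p in node.proportions.items() if p > 0
                )
                lines.append(f"{pad}predict {node.predicted_class} ({props})")
            else:
                lines.append(
                    f"{pad}if {node.split_marker} >= {node.split_threshold:g}:"
                )
                walk(node.left, indent + 1)
                lines.append(f"{pad}else:")
                walk(node.right, indent + 1)

        walk(self.root, 0)
        return "\n".join(lines)


def best_split(
    table: pd.DataFrame,
    label_col: str,
    config: TreeConfig,
) -> tuple[str, float, float] | None:
    """Best (marker, threshold, impurity decrease) for the samples given.

    Thin wrapper over the node-level search used by :func:`grow_tree`;
    returns None when no admissible split clears the complexity threshold.
    """
    markers = config.markers
    if markers is None:
        raise ValueError("config.markers must list the candidate markers")
    y = table[label_col].to_numpy()
    classes = sorted(np.unique(y).tolist())
    X = design_matrix(table, markers, config.censored_fill)
    y_idx = np.searchsorted(classes, y)
    totals = np.bincount(y_idx, minlength=len(classes)).astype(float)
    pi = _resolve_priors(config, classes)
    weights = pi / totals
    res = _best_split_arrays(X, y_idx, len(classes), weights, config)
    if res is None:
        return None
    root_impurity_mass = _impurity_mass(weights * totals)
    if res[0] < config.complexity_threshold * root_impurity_mass:
        return None
    return markers[res[1]], res[2], res[0]


def _impurity_mass(joint: np.ndarray) -> float:
    mass = joint.sum()
    return float(mass - (joint**2).sum() / mass)


def _resolve_priors(config: TreeConfig, classes: list[str]) -> np.ndarray:
    if config.priors is None:
        return np.full(len(classes), 1.0 / len(classes))
    missing = [c for c in classes if c not in config.priors]
    if missing:
        raise ValueError(f"priors missing for classes {missing}")
    pi = np.array([config.priors[c] for c in classes], dtype=float)
    return pi / pi.sum()


def grow_tree(
    table: pd.DataFrame,
    config: TreeConfig,
    label_col: str = "supplier_label",
    metadata: dict | None = None,
) -> FittedTree:
    """Fit a classification tree by greedy recursive partitioning.

    Deterministic given the data and configuration. Single-class data
    yields a root leaf; ``max_depth=0`` yields a root leaf predicting the
    argmax prior-adjusted class proportion.
    """
    if len(table) == 0:
        raise ValueError("cannot fit a tree on empty data")
    markers = config.markers
    if markers is None:
        raise ValueError("config.markers must list the candidate markers")
    y = table[label_col].to_numpy()
    classes = sorted(np.unique(y).tolist())
    X = design_matrix(table, markers, config.censored_fill)
    y_idx = np.searchsorted(classes, y)
    totals = np.bincount(y_idx, minlength=len(classes)).astype(float)
    pi = _resolve_priors(config, classes)
    weights = pi / totals
    root_impurity_mass = _impurity_mass(weights * totals)
    min_gain = config.complexity_threshold * max(root_impurity_mass, 1e-300)

    def build(Xn, yn, depth) -> TreeNode:
        counts = np.bincount(yn, minlength=len(classes)).astype(float)
        node = _node_from_counts(counts, classes, weights, depth)
        if (
            depth >= config.max_depth
            or yn.size < config.min_samples_to_split
            or np.count_nonzero(counts) < 2
        ):
            return node
        res = _best_split_arrays(Xn, yn, len(classes), weights, config)
        if res is None or res[0] < min_gain:
            return node
        gain, f, thr = res
        go_left = Xn[:, f] >= thr
        node.split_marker = markers[f]
        node.split_threshold = thr
        node.left = build(Xn[go_left], yn[go_left], depth + 1)
        node.right = build(Xn[~go_left], yn[~go_left], depth + 1)
        return node

    root = build(X, y_idx, 0)
    return FittedTree(
        root=root,
        config=config,
        classes=classes,
        class_totals={c: int(t) for c, t in zip(classes, totals)},
        markers=markers,
        metadata=metadata or {},
    )
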