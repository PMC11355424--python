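"""Human-readable classification rules and essential-gene intersections.

A fitted decision tree is equivalent to its set of root-to-leaf paths;
each path becomes one :class:`Rule` — a conjunction of gene/threshold
predicates implying the leaf's majority class, with the leaf's training
support and purity attached. Redundant conditions on the same gene along
a path are merged into the tightest interval, which is what makes the
rules readable without changing what they predict: rule-based prediction
reproduces the tree exactly, and the rules are mutually exclusive and
jointly exhaustive by construction.

The intersection table is the data behind an upset plot: for the
essential-gene sets of the six ranking methods it counts, for every
non-empty method subset S, the genes belonging to exactly the methods
in S.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .dataset import ValidationError
from .ifs import FittedClassifier


@dataclass
class Rule:
    """Conjunction of (gene, relation, threshold) predicates → class."""

    predicates: list          # (gene_id, "<=" or ">", threshold)
    consequent: str
    support: int
    confidence: float

    def __post_init__(self):
        for g, op, thr in self.predicates:
            if op not in ("<=", ">"):
                raise ValidationError(f"bad relation {op!r}")
            if not np.isfinite(thr):
                raise ValidationError("thresholds must be finite")
        if not (0 < self.confidence <= 1):
            raise ValidationError("confidence must be in (0, 1]")

    def matches(self, row: np.ndarray, gene_index: dict) -> bool:
        for g, op, thr in self.predicates:
            v = row[gene_index[g]]
            if op == "<=" and not v <= thr:
                return False
            if op == ">" and not v > thr:
                return False
        return True

    def to_text(self) -> str:
        if self.predicates:
            cond = " AND ".join(
                f"{g} {op} {thr:.4g}" for g, op, thr in self.predicates
            )
        else:
            cond = "TRUE"
        return (f"IF {cond} THEN {self.consequent}  "
                f"[support={self.support}, confidence={self.confidence:.2f}]")


@dataclass
class RuleSet:
    """All root-to-leaf rules of one best decision-tree classifier."""

    method: str
    class_names: list
    rules: list

    def per_class_counts(self) -> dict:
        counts = {c: 0 for c in self.class_names}
        for r in self.rules:
            counts[r.consequent] += 1
        return counts

    def predict(self, X: np.ndarray, genes) -> list:
        """Rule-based prediction; exactly one rule fires per row."""
        gene_index = {g: j for j, g in enumerate(genes)}
        X = np.asarray(X, dtype=np.float64)
        out = []
        for row in X:
            hits = [r for r in self.rules if r.matches(row, gene_index)]
            if len(hits) != 1:
                raise ValidationError(
                    f"rules are not a partition: {len(hits)} rules fired"
                )
            out.append(hits[0].consequent)
        return out

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "class_names": self.class_names,
            "per_class_counts": self.per_class_counts(),
            "rules": [
                {
                    "predicates": [
                        {"gene": g, "relation": op, "threshold": thr}
                        for g, op, thr in r.predicates
                    ],
                    "class": r.consequent,
                    "support": r.support,
                    "confidence": r.confidence,
                }
                for r in self.rules
            ],
        }

    def to_text(self) -> str:
        return "".join(r.to_text() + "\n" for r in self.rules)


def extract_rules(handle: FittedClassifier) -> RuleSet:
    """One rule per leaf of a fitted decision tree.

    Path conditions on the same gene are merged to the tightest lower/upper
    bound; the consequent is the leaf's majority class (ties broken toward
    the earlier class, matching the tree's own argmax).
    """
    if handle.kind != "dt" or not isinstance(handle.model, DecisionTreeClassifier):
        raise ValidationError("rule extraction requires a fitted decision tree")
    tree = handle.model.tree_
    model_classes = list(handle.model.classes_)
    rules = []

    def walk(node: int, lower: dict, upper: dict):
        left, right = tree.children_left[node], tree.children_right[node]
        if left == -1:
            majority = int(np.argmax(tree.value[node][0]))
            predicates = []
            for g in sorted(set(lower) | set(upper)):
                if g in lower:
                    predicates.append((g, ">", lower[g]))
                if g in upper:
                    predicates.append((g, "<=", upper[g]))
            rules.append(Rule(
                predicates=predicates,
                consequent=str(model_classes[majority]),
                support=int(round(tree.weighted_n_node_samples[node])),
                confidence=float(tree.value[node][0][majority] / tree.value[node][0].sum()),
            ))
            return
        gene = handle.genes[int(tree.feature[node])]
        thr = float(tree.threshold[node])
        u2 = dict(upper)
        u2[gene] = min(upper.get(gene, np.inf), thr)     # tightest upper bound
        walk(left, lower, u2)
        l2 = dict(lower)
        l2[gene] = max(lower.get(gene, -np.inf), thr)    # tightest lower bound
        walk(right, l2, upper)

    walk(0, {}, {})
    return RuleSet(method="", class_names=list(handle.class_names), rules=rules)


def rules_per_class(ruleset: RuleSet) -> dict:
    return ruleset.per_class_counts()


@dataclass
class IntersectionTable:
    """Exclusive-region counts over all non-empty subsets of the method sets."""

    methods: list
    region_counts: dict       # tuple(sorted subset) -> count
    set_sizes: dict
    gene_membership: dict     # gene -> tuple of methods containing it

    def union_size(self) -> int:
        return len(self.gene_membership)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in range(1, len(self.methods) + 1):
            for subset in combinations(self.methods, r):
                rows.append({
                    "subset": "+".join(subset),
                    "n_methods": r,
                    "count": self.region_counts.get(subset, 0),
                })
        return pd.DataFrame(rows)


def essential_sets(selection_reports: dict) -> dict:
    """Per ranking method, the suboptimal random-forest gene set
    (the method's essential genes)."""
    sets = {}
    for method, report in selection_reports.items():
        if "rf" not in report.per_classifier:
            raise ValidationError(f"report for {method!r} has no RF selection")
        sets[method] = set(report.genes["rf"]["suboptimal"])
    return sets


def intersect(gene_sets: dict) -> IntersectionTable:
    """Exact exclusive-region counts plus each gene's membership signature."""
    if not 1 <= len(gene_sets) <= 6:
        raise ValidationError("expected 1-6 named gene sets")
    methods = list(gene_sets)
    membership: dict = {}
    for gene in sorted(set().union(*gene_sets.values())):
        sig = tuple(m for m in methods if gene in gene_sets[m])
        membership[gene] = sig
    region_counts: dict = {}
    for sig in membership.values():
        region_counts[sig] = region_counts.get(sig, 0) + 1
    return IntersectionTable(
        methods=methods,
        region_counts=region_counts,
        set_sizes={m: len(s) for m, s in gene_sets.items()},
        gene_membership=membership,
    )
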