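"""Monte Carlo Feature Selection relative importance, from first principles.

MCFS grows a large population of decision trees, each on a random
projection of m genes and a random stratified train/test split, and
accumulates per-gene relative importance

    RI_g = Σ_τ (wAcc_τ)^u · Σ_{nodes n_g(τ) split on g} IG(n_g) · (cov(n_g))^v

where wAcc_τ is the tree's weighted accuracy on its held-out split (the
unweighted mean of per-class recalls), IG is the information gain of the
node's split in bits, and cov(n_g) is the fraction of the tree's training
samples reaching the node. A gene never drawn into any projection has
RI exactly 0.

Defaults: u = v = 1, train fraction 0.66, s·t sized so the population
holds at least 2000 trees, and m = 3⌈√p⌉ genes per projection. The
projection size is deliberately larger than the √p rule of thumb: when
informative genes are a fraction of a percent of all genes (the regime
this pipeline targets), √p-sized projections rarely contain a marker
together with enough signal to win splits, and importance estimates stay
noisy; tripling m exposes each gene to ~3× more trees at unchanged cost
per tree population. Projections are drawn over the lexicographically
sorted gene list, so the importance map does not depend on the column
order of the input.
"""

from __future__ import annotations

import math

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .dataset import ExpressionDataset, FeatureList, ValidationError, ordered_feature_list


def _stratified_split(y_codes: np.ndarray, frac: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random split; every class keeps >= 1 training sample and,
    when it has >= 2 members, >= 1 test sample."""
    train, test = [], []
    for c in np.unique(y_codes):
        idx = np.flatnonzero(y_codes == c)
        idx = rng.permutation(idx)
        n_train = int(round(frac * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1) if len(idx) > 1 else 1
        train.append(idx[:n_train])
        test.append(idx[n_train:])
    return np.concatenate(train), np.concatenate(test)


def _weighted_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Unweighted mean of per-class recalls over classes present in y_true."""
    recalls = []
    for c in np.unique(y_true):
        mask = y_true == c
        recalls.append(np.mean(y_pred[mask] == c))
    return float(np.mean(recalls))


def _tree_gene_contributions(tree: DecisionTreeClassifier, n_train: int, v: float) -> dict:
    """Per-local-feature Σ IG(node) · coverage(node)^v over the tree's splits."""
    t = tree.tree_
    contrib: dict = {}
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:  # leaf
            continue
        n_node = t.weighted_n_node_samples[node]
        ig = t.impurity[node] - (
            t.weighted_n_node_samples[left] / n_node * t.impurity[left]
            + t.weighted_n_node_samples[right] / n_node * t.impurity[right]
        )
        coverage = n_node / n_train
        feat = int(t.feature[node])
        contrib[feat] = contrib.get(feat, 0.0) + max(ig, 0.0) * coverage**v
    return contrib


def mcfs_importance(
    dataset: ExpressionDataset,
    s: int | None = None,
    t: int = 5,
    m: int | None = None,
    u: float = 1.0,
    v: float = 1.0,
    split_fraction: float = 0.66,
    min_total_trees: int = 2000,
    seed: int = 0,
) -> FeatureList:
    """Accumulate MCFS relative importance over s projections × t splits.

    Parameters
    ----------
    s : int, optional
        Number of random gene projections; defaults to
        ``ceil(min_total_trees / t)``.
    t : int
        Train/test splits (one tree each) per projection.
    m : int, optional
        Genes per projection; defaults to ``min(3 ceil(sqrt(n_genes)), n_genes)``.
    u, v : float
        Exponents on the tree's weighted accuracy and the node coverage.
    """
    dataset.require_labels(min_classes=2)
    p = dataset.n_genes
    if m is None:
        m = min(3 * math.ceil(math.sqrt(p)), p)
    if m > p:
        raise ValidationError(f"projection size m={m} exceeds {p} genes")
    if not (t >= 1 and (s is None or s >= 1)):
        raise ValidationError("s and t must be >= 1")
    if not (u > 0 and v > 0):
        raise ValidationError("u and v must be > 0")
    if not (0 < split_fraction < 1):
        raise ValidationError("split_fraction must be in (0, 1)")
    if s is None:
        s = math.ceil(min_total_trees / t)

    # column-order independence: draw projections over sorted gene ids
    sorted_order = sorted(range(p), key=lambda j: dataset.gene_ids[j])
    y = dataset.y_codes()
    X = dataset.matrix

    ri = np.zeros(p)
    children = np.random.SeedSequence(seed).spawn(s)
    for proj, child in enumerate(children):
        rng = np.random.default_rng(child)
        proj_cols = np.array(sorted_order)[rng.choice(p, size=m, replace=False)]
        Xp = X[:, proj_cols]
        for split in range(t):
            tr, te = _stratified_split(y, split_fraction, rng)
            tree = DecisionTreeClassifier(criterion="entropy", random_state=0)
            tree.fit(Xp[tr], y[tr])
            if len(te) == 0:
                continue
            wacc = _weighted_accuracy(y[te], tree.predict(Xp[te]))
            if wacc == 0.0:
                continue
            for feat, c in _tree_gene_contributions(tree, len(tr), v).items():
                ri[proj_cols[feat]] += wacc**u * c

    return ordered_feature_list(
        "mcfs", dataset.gene_ids, ri,
        backing=f"from-scratch MCFS (s={s}, t={t}, m={m}, u={u}, v={v})",
    )
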