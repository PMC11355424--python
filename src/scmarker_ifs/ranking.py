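"""The six feature-importance rankings behind one dispatch interface.

Methods
-------
``catboost_pvc``
    Prediction-values-change importance: a gradient-boosted tree model is
    fit, then each feature's column is shuffled and the mean absolute
    change of the predicted class probabilities is its importance
    (0 exactly for features the model never uses). Backed by sklearn's
    HistGradientBoostingClassifier.
``lasso``
    L1-penalized multinomial logistic regression on standardized features;
    penalty chosen by stratified 5-fold CV over a log grid; importance of a
    gene is the max over classes of |coefficient|.
``lightgbm_gain`` / ``xgboost_gain``
    The libraries' "gain" importances (total / average training-loss
    reduction from the feature's splits).
``mcfs``
    Monte Carlo Feature Selection relative importance (see
    :mod:`scmarker_ifs.mcfs`).
``rf_mdi``
    Random-forest Mean Decrease Impurity (100 trees, √p features/split).

Every method returns a :class:`FeatureList` covering all genes: unused
genes score 0 and sort after scored genes; ties break by ascending
gene_id, so a ranking is bitwise reproducible given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import ExpressionDataset, FeatureList, ValidationError, ordered_feature_list
from .mcfs import mcfs_importance

METHODS = ("catboost_pvc", "lasso", "lightgbm_gain", "mcfs", "rf_mdi", "xgboost_gain")


@dataclass
class RankingParams:
    """Knobs for one ranking run; only the method's own fields are read."""

    method: str
    seed: int = 0
    n_estimators: int = 100          # tree-ensemble methods
    # mcfs
    mcfs_s: int | None = None
    mcfs_t: int = 5
    mcfs_m: int | None = None
    mcfs_u: float = 1.0
    mcfs_v: float = 1.0
    mcfs_split_fraction: float = 0.66
    mcfs_min_total_trees: int = 2000
    # lasso
    lasso_n_penalties: int = 20
    lasso_c_bounds: tuple = (1e-2, 1e2)   # 4 decades
    lasso_cv_folds: int = 5
    lasso_tol: float = 1e-3
    lasso_max_iter: int = 2000
    # xgboost: many shallow rounds suit n << p expression matrices
    xgb_n_estimators: int = 500
    xgb_max_depth: int = 2
    # gradient-boosted backing for catboost_pvc
    gbm_max_iter: int = 300
    gbm_min_samples_leaf: int = 10
    gbm_max_depth: int | None = 3
    gbm_max_features: float = 0.05

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValidationError(
                f"unknown ranking method {self.method!r}; choose from {METHODS}"
            )


def rank_features(dataset: ExpressionDataset, params: RankingParams) -> FeatureList:
    """Dispatch to the requested ranking; returns a full-coverage FeatureList."""
    dataset.require_labels(min_classes=2)
    counts = dataset.class_counts()
    small = [c for c, n in counts.items() if n < 2]
    if small:
        raise ValidationError(f"classes with < 2 cells cannot be ranked: {small}")
    if params.method == "mcfs":
        return mcfs_importance(
            dataset,
            s=params.mcfs_s,
            t=params.mcfs_t,
            m=params.mcfs_m,
            u=params.mcfs_u,
            v=params.mcfs_v,
            split_fraction=params.mcfs_split_fraction,
            min_total_trees=params.mcfs_min_total_trees,
            seed=params.seed,
        )
    if params.method == "lasso":
        return lasso_importance(dataset, params)
    if params.method == "rf_mdi":
        return _rf_mdi(dataset, params)
    if params.method == "lightgbm_gain":
        return _lightgbm_gain(dataset, params)
    if params.method == "xgboost_gain":
        return _xgboost_gain(dataset, params)
    if params.method == "catboost_pvc":
        return _pvc_importance(dataset, params)
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# LASSO
# ---------------------------------------------------------------------------

def lasso_importance(dataset: ExpressionDataset, params: RankingParams | None = None) -> FeatureList:
    """Max-|coefficient| aggregation of an L1 multinomial logistic fit.

    Features are standardized per gene (zero-variance genes are excluded
    from the fit and score 0). The inverse penalty C is selected by
    stratified k-fold cross-validation over a logarithmic grid, then the
    model is refit on all data at the chosen C.
    """
    from sklearn.linear_model import LogisticRegressionCV
    from sklearn.model_selection import StratifiedKFold

    params = params or RankingParams(method="lasso")
    dataset.require_labels(min_classes=2)
    X = dataset.matrix
    std = X.std(axis=0)
    keep = np.flatnonzero(std > 0)
    if keep.size == 0:
        raise ValidationError("all genes have zero variance; nothing to fit")
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / std[keep]
    y = dataset.y_codes()

    lo, hi = params.lasso_c_bounds
    Cs = np.logspace(np.log10(lo), np.log10(hi), params.lasso_n_penalties)
    folds = min(params.lasso_cv_folds, min(np.bincount(y)))
    model = LogisticRegressionCV(
        Cs=Cs,
        cv=StratifiedKFold(folds, shuffle=True, random_state=params.seed),
        l1_ratios=(1.0,),                 # pure L1
        solver="saga",
        scoring="accuracy",
        tol=params.lasso_tol,
        max_iter=params.lasso_max_iter,
        random_state=params.seed,
        use_legacy_attributes=False,
    )
    model.fit(Xs, y)
    coef = np.abs(model.coef_)          # (L, n_kept) — binary fits give (1, n_kept)
    importance = np.zeros(dataset.n_genes)
    importance[keep] = coef.max(axis=0)
    chosen_c = float(np.atleast_1d(model.C_)[0])
    return ordered_feature_list(
        "lasso", dataset.gene_ids, importance,
        backing=f"sklearn LogisticRegressionCV l1/saga (C={chosen_c:.4g})",
    )


# ---------------------------------------------------------------------------
# tree-ensemble importances
# ---------------------------------------------------------------------------

def _rf_mdi(dataset: ExpressionDataset, params: RankingParams) -> FeatureList:
    from sklearn.ensemble import RandomForestClassifier

    rf = RandomForestClassifier(
        n_estimators=params.n_estimators,
        max_features="sqrt",
        random_state=params.seed,
        n_jobs=1,
    )
    rf.fit(dataset.matrix, dataset.y_codes())
    return ordered_feature_list(
        "rf_mdi", dataset.gene_ids, rf.feature_importances_,
        backing=f"sklearn RandomForestClassifier MDI ({params.n_estimators} trees)",
    )


def _lightgbm_gain(dataset: ExpressionDataset, params: RankingParams) -> FeatureList:
    import lightgbm as lgb

    model = lgb.LGBMClassifier(
        n_estimators=params.n_estimators,
        random_state=params.seed,
        n_jobs=1,
        verbose=-1,
    )
    model.fit(dataset.matrix, dataset.y_codes())
    gain = model.booster_.feature_importance(importance_type="gain")
    return ordered_feature_list(
        "lightgbm_gain", dataset.gene_ids, gain,
        backing=f"lightgbm {lgb.__version__} gain",
    )


def _xgboost_gain(dataset: ExpressionDataset, params: RankingParams) -> FeatureList:
    import xgboost as xgb

    model = xgb.XGBClassifier(
        n_estimators=params.xgb_n_estimators,
        max_depth=params.xgb_max_depth,
        random_state=params.seed,
        n_jobs=1,
        tree_method="hist",
        verbosity=0,
    )
    model.fit(dataset.matrix, dataset.y_codes())
    raw = model.get_booster().get_score(importance_type="gain")
    importance = np.zeros(dataset.n_genes)
    for name, v in raw.items():          # features never split on are absent
        importance[int(name[1:])] = v
    return ordered_feature_list(
        "xgboost_gain", dataset.gene_ids, importance,
        backing=f"xgboost {xgb.__version__} gain",
    )


def _eval_hgb_tree(nodes, X: np.ndarray) -> np.ndarray:
    """Vectorized leaf-value lookup for one HistGradientBoosting predictor."""
    out = np.zeros(X.shape[0])
    stack = [(0, np.arange(X.shape[0]))]
    while stack:
        ni, idx = stack.pop()
        node = nodes[ni]
        if node["is_leaf"]:
            out[idx] = node["value"]
            continue
        go_left = X[idx, int(node["feature_idx"])] <= node["num_threshold"]
        stack.append((int(node["left"]), idx[go_left]))
        stack.append((int(node["right"]), idx[~go_left]))
    return out


def _raw_to_proba(raw: np.ndarray) -> np.ndarray:
    from scipy.special import expit, softmax

    if raw.shape[1] == 1:
        p1 = expit(raw[:, 0])
        return np.column_stack([1 - p1, p1])
    return softmax(raw, axis=1)


def _pvc_importance(dataset: ExpressionDataset, params: RankingParams) -> FeatureList:
    """Prediction-values-change importance on a boosted-tree model.

    For each gene, its column is shuffled once (seeded) and the importance
    is the mean absolute change in predicted class probabilities over all
    cells and classes. Only trees that split on the gene are re-evaluated
    (all other trees are provably unchanged), so genes the model ignores
    score exactly 0 and the scan stays cheap even at thousands of genes.
    """
    from sklearn.ensemble import HistGradientBoostingClassifier

    model = HistGradientBoostingClassifier(
        max_iter=params.gbm_max_iter,
        min_samples_leaf=params.gbm_min_samples_leaf,
        max_depth=params.gbm_max_depth,
        max_features=params.gbm_max_features,
        random_state=params.seed,
        early_stopping=False,
    )
    X = dataset.matrix
    model.fit(X, dataset.y_codes())

    # flatten predictors to (class_column, nodes, features_used, baseline_output)
    trees = []
    by_feature: dict = {}
    for iteration in model._predictors:
        for k, pred in enumerate(iteration):
            nodes = pred.nodes
            feats = {
                int(f)
                for f, leaf in zip(nodes["feature_idx"], nodes["is_leaf"])
                if not leaf
            }
            if not feats:
                continue
            ti = len(trees)
            trees.append((k, nodes, _eval_hgb_tree(nodes, X)))
            for f in feats:
                by_feature.setdefault(f, []).append(ti)

    raw0 = np.tile(np.asarray(model._baseline_prediction).ravel(), (X.shape[0], 1)).astype(float)
    for k, _, out in trees:
        raw0[:, k] += out
    proba0 = _raw_to_proba(raw0)

    rng = np.random.default_rng(params.seed)
    importance = np.zeros(dataset.n_genes)
    work = X.copy()
    for j in range(dataset.n_genes):
        col = work[:, j]
        affected = by_feature.get(j)
        perm = rng.permutation(len(col))  # one draw per gene, in gene order
        if not affected or np.all(col == col[0]):
            continue
        shuffled = col[perm]
        work[:, j] = shuffled
        raw = raw0.copy()
        for ti in affected:
            k, nodes, out = trees[ti]
            raw[:, k] += _eval_hgb_tree(nodes, work) - out
        work[:, j] = col
        importance[j] = np.mean(np.abs(_raw_to_proba(raw) - proba0))
    return ordered_feature_list(
        "catboost_pvc", dataset.gene_ids, importance,
        backing="sklearn HistGradientBoosting + from-scratch prediction-values-change",
    )
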