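"""Incremental feature selection with SMOTE-balanced stratified cross-validation.

For each prefix length k on a grid (default every 5 features up to 1000),
the expression matrix is restricted to the top-k genes of one feature
list; a stratified k-fold split — fixed once per scan, identical across
prefix lengths and classifiers — is evaluated by balancing each training
fold with SMOTE, fitting a decision tree and/or random forest, predicting
the untouched test fold, pooling the out-of-fold predictions, and scoring
ACC / MCC / macro F1 / weighted F1. The curve of weighted F1 against k
identifies the *optimal* prefix (maximal weighted F1, smallest k on ties)
and the *suboptimal* prefix (smallest k within ``delta`` of the optimum);
the suboptimal gene set is the method's "essential genes".

By default SMOTE runs inside each training fold only, so no synthetic
point ever reaches a test fold. ``smote_mode="prefold"`` instead balances
the whole dataset once before splitting — closer to a common shortcut in
the literature, but it leaks interpolated copies of test cells into
training and inflates scores; both modes are recorded in the curve's
provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .dataset import ExpressionDataset, FeatureList, ValidationError
from .metrics import MetricSet, evaluate
from .smote import SmoteParams, smote_balance
from .util import derive_seed

log = logging.getLogger(__name__)

CLASSIFIERS = ("dt", "rf")


@dataclass
class IFSGrid:
    """Prefix lengths to evaluate: step, 2·step, …, max_k.

    ``coarse_after``/``coarse_step`` optionally thin the grid beyond a
    point where the curve has flattened: fine steps up to ``coarse_after``,
    then ``coarse_step`` up to ``max_k``.
    """

    step: int = 5
    max_k: int = 1000
    coarse_after: int | None = None
    coarse_step: int | None = None

    def __post_init__(self):
        if self.step < 1 or self.max_k < self.step:
            raise ValidationError("need 1 <= step <= max_k")
        if (self.coarse_after is None) != (self.coarse_step is None):
            raise ValidationError("coarse_after and coarse_step go together")

    def ks(self, n_available: int) -> list:
        top = min(self.max_k, n_available)
        if top < self.max_k:
            log.warning("grid max_k lowered from %d to %d available genes",
                        self.max_k, top)
        if self.coarse_after is None or self.coarse_after >= top:
            return list(range(self.step, top + 1, self.step))
        fine = list(range(self.step, self.coarse_after + 1, self.step))
        coarse = list(range(fine[-1] + self.coarse_step, top + 1, self.coarse_step))
        return fine + coarse


@dataclass
class CVSpec:
    """Stratified k-fold specification (default 10 folds)."""

    folds: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.folds < 2:
            raise ValidationError("folds must be >= 2")


@dataclass
class ClassifierParams:
    """CART / random-forest hyperparameters (Gini, unlimited depth,
    100 trees with sqrt(p) features per split for the forest)."""

    rf_n_estimators: int = 100
    dt_kwargs: dict = field(default_factory=dict)
    rf_kwargs: dict = field(default_factory=dict)

    def build(self, kind: str, seed: int):
        if kind == "dt":
            return DecisionTreeClassifier(
                criterion="gini", random_state=seed, **self.dt_kwargs
            )
        if kind == "rf":
            return RandomForestClassifier(
                n_estimators=self.rf_n_estimators,
                criterion="gini",
                max_features="sqrt",
                random_state=seed,
                n_jobs=1,
                **self.rf_kwargs,
            )
        raise ValidationError(f"unknown classifier {kind!r}; choose from {CLASSIFIERS}")


@dataclass
class IFSRecord:
    k: int
    classifier: str
    metrics: MetricSet


@dataclass
class IFSCurve:
    """All (k, classifier) evaluation records for one feature list."""

    method: str
    records: list
    provenance: dict = field(default_factory=dict)

    def classifiers(self) -> list:
        return list(dict.fromkeys(r.classifier for r in self.records))

    def for_classifier(self, classifier: str) -> list:
        recs = [r for r in self.records if r.classifier == classifier]
        if not recs:
            raise ValidationError(f"classifier {classifier!r} absent from curve")
        return sorted(recs, key=lambda r: r.k)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"method": self.method, "classifier": r.classifier, "k": r.k,
             **r.metrics.to_dict()}
            for r in sorted(self.records, key=lambda r: (r.classifier, r.k))
        ]
        return pd.DataFrame(rows)


@dataclass
class SelectionReport:
    """Optimal / suboptimal prefix per classifier plus the gene lists."""

    method: str
    delta: float
    per_classifier: dict   # classifier -> dict with optimal_k/metrics, suboptimal_k/metrics
    genes: dict            # classifier -> {"optimal": [...], "suboptimal": [...]}

    def __post_init__(self):
        for clf, sel in self.per_classifier.items():
            if sel["suboptimal_k"] > sel["optimal_k"]:
                raise ValidationError(
                    f"{clf}: suboptimal k {sel['suboptimal_k']} exceeds optimal "
                    f"k {sel['optimal_k']}"
                )

    def to_dict(self) -> dict:
        out = {"method": self.method, "delta": self.delta, "classifiers": {}}
        for clf, sel in self.per_classifier.items():
            out["classifiers"][clf] = {
                "optimal_k": sel["optimal_k"],
                "optimal_metrics": sel["optimal_metrics"].to_dict(),
                "suboptimal_k": sel["suboptimal_k"],
                "suboptimal_metrics": sel["suboptimal_metrics"].to_dict(),
                "optimal_genes": self.genes[clf]["optimal"],
                "suboptimal_genes": self.genes[clf]["suboptimal"],
            }
        return out


def _stratified_folds(labels, cv: CVSpec) -> list:
    """Fold index pairs; a function of (labels, cv.seed) only."""
    y = np.asarray(labels)
    min_count = min(np.unique(y, return_counts=True)[1])
    folds = cv.folds
    if min_count < folds:
        folds = max(2, int(min_count))
        log.warning("smallest class has %d members; folds reduced %d -> %d",
                    min_count, cv.folds, folds)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cv.seed)
    return list(skf.split(np.zeros(len(y)), y))


def ifs_scan(
    dataset: ExpressionDataset,
    feature_list: FeatureList,
    grid: IFSGrid | None = None,
    cv: CVSpec | None = None,
    smote: SmoteParams | None = None,
    classifiers=CLASSIFIERS,
    classifier_params: ClassifierParams | None = None,
    smote_mode: str = "infold",
    fold_aggregation: str = "pooled",
    seed: int = 0,
) -> IFSCurve:
    """Evaluate every grid prefix of ``feature_list`` under each classifier.

    Deterministic given (``cv.seed``, ``smote.seed``, ``seed``); the fold
    assignment is shared by all k and classifiers within the scan.
    """
    dataset.require_labels(min_classes=2)
    grid = grid or IFSGrid()
    cv = cv or CVSpec()
    smote = smote or SmoteParams()
    classifier_params = classifier_params or ClassifierParams()
    if smote_mode not in ("infold", "prefold"):
        raise ValidationError("smote_mode must be 'infold' or 'prefold'")
    if fold_aggregation not in ("pooled", "mean"):
        raise ValidationError("fold_aggregation must be 'pooled' or 'mean'")
    for clf in classifiers:
        if clf not in CLASSIFIERS:
            raise ValidationError(f"unknown classifier {clf!r}")

    usable = [g for g in feature_list.gene_ids if g in set(dataset.gene_ids)]
    ks = grid.ks(len(usable))
    X_full = dataset.gene_matrix(usable[: max(ks)])
    labels = np.asarray(dataset.labels)
    folds = _stratified_folds(dataset.labels, cv)

    records = []
    for k in ks:
        X_k = X_full[:, :k]
        if smote_mode == "prefold":
            bal = smote_balance(X_k, dataset.labels,
                                SmoteParams(smote.k_neighbors, derive_seed(smote.seed, k)))
            Xk_all, yk_all = bal.X, np.asarray(bal.y)
            k_folds = _stratified_folds(list(yk_all), cv)
        per_clf_true = {c: [] for c in classifiers}
        per_clf_pred = {c: [] for c in classifiers}
        per_clf_fold_metrics = {c: [] for c in classifiers}
        use_folds = k_folds if smote_mode == "prefold" else folds
        for fold_i, (tr, te) in enumerate(use_folds):
            if smote_mode == "infold":
                bal = smote_balance(
                    X_k[tr], list(labels[tr]),
                    SmoteParams(smote.k_neighbors,
                                derive_seed(smote.seed, k, fold_i)),
                )
                X_train, y_train = bal.X, bal.y
                X_test, y_test = X_k[te], list(labels[te])
            else:
                X_train, y_train = Xk_all[tr], list(yk_all[tr])
                X_test, y_test = Xk_all[te], list(yk_all[te])
            for clf in classifiers:
                model = classifier_params.build(clf, derive_seed(seed, clf, k, fold_i))
                model.fit(X_train, y_train)
                pred = list(model.predict(X_test))
                per_clf_true[clf].extend(y_test)
                per_clf_pred[clf].extend(pred)
                if fold_aggregation == "mean":
                    per_clf_fold_metrics[clf].append(
                        evaluate(y_test, pred, classes=dataset.class_names)
                    )
        for clf in classifiers:
            if fold_aggregation == "pooled":
                ms = evaluate(per_clf_true[clf], per_clf_pred[clf],
                              classes=dataset.class_names)
            else:
                parts = per_clf_fold_metrics[clf]
                ms = MetricSet(**{
                    f: float(np.mean([getattr(p, f) for p in parts]))
                    for f in ("acc", "mcc", "macro_f1", "weighted_f1")
                })
            records.append(IFSRecord(k=k, classifier=clf, metrics=ms))

    return IFSCurve(
        method=feature_list.method,
        records=records,
        provenance={
            "cv_seed": cv.seed, "scan_seed": seed, "smote_seed": smote.seed,
            "smote_mode": smote_mode, "folds": len(folds),
            "fold_aggregation": fold_aggregation,
            "step": grid.step, "max_k": max(ks),
        },
    )


def select_optimal(curve: IFSCurve, classifier: str) -> tuple[int, MetricSet]:
    """The prefix with maximal weighted F1; ties go to the smallest k."""
    recs = curve.for_classifier(classifier)
    for r in recs:
        if any(np.isnan(v) for v in r.metrics.to_dict().values()):
            raise ValidationError(f"corrupt curve: NaN metrics at k={r.k}")
    best = max(recs, key=lambda r: (r.metrics.weighted_f1, -r.k))
    return best.k, best.metrics


def select_suboptimal(curve: IFSCurve, classifier: str, delta: float = 0.01
                      ) -> tuple[int, MetricSet]:
    """The smallest prefix whose weighted F1 is within ``delta`` of the optimum."""
    if delta < 0:
        raise ValidationError("delta must be >= 0")
    _, opt = select_optimal(curve, classifier)
    for r in curve.for_classifier(classifier):
        if r.metrics.weighted_f1 >= opt.weighted_f1 - delta:
            return r.k, r.metrics
    raise AssertionError("unreachable: the optimum always qualifies")


def build_selection_report(curve: IFSCurve, feature_list: FeatureList,
                           delta: float = 0.01) -> SelectionReport:
    per_clf, genes = {}, {}
    for clf in curve.classifiers():
        ok, om = select_optimal(curve, clf)
        sk, sm = select_suboptimal(curve, clf, delta)
        per_clf[clf] = {"optimal_k": ok, "optimal_metrics": om,
                        "suboptimal_k": sk, "suboptimal_metrics": sm}
        genes[clf] = {"optimal": feature_list.top(ok),
                      "suboptimal": feature_list.top(sk)}
    return SelectionReport(method=curve.method, delta=delta,
                           per_classifier=per_clf, genes=genes)


@dataclass
class FittedClassifier:
    """A classifier refit on the full (SMOTE-balanced) dataset, restricted
    to an ordered gene subset; exposes predictions in gene-id space."""

    kind: str
    genes: list
    model: object
    class_names: list

    def predict(self, X: np.ndarray) -> list:
        """Predict labels for rows already in ``self.genes`` column order."""
        return list(self.model.predict(np.asarray(X, dtype=np.float64)))

    def predict_dataset(self, dataset: ExpressionDataset) -> list:
        return self.predict(dataset.gene_matrix(self.genes))


def train_final(
    dataset: ExpressionDataset,
    genes,
    classifier: str,
    smote: SmoteParams | None = None,
    classifier_params: ClassifierParams | None = None,
    seed: int = 0,
) -> FittedClassifier:
    """Fit one classifier on the full dataset after SMOTE balancing."""
    dataset.require_labels(min_classes=2)
    smote = smote or SmoteParams()
    classifier_params = classifier_params or ClassifierParams()
    genes = list(genes)
    X = dataset.gene_matrix(genes)
    bal = smote_balance(X, dataset.labels, smote)
    model = classifier_params.build(classifier, seed)
    model.fit(bal.X, bal.y)
    return FittedClassifier(kind=classifier, genes=genes, model=model,
                            class_names=list(dataset.class_names))
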