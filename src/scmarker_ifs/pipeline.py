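"""End-to-end orchestration: rank → IFS → select → rules → intersect.

The analysis surface is modelled on the model/results idiom: a
:class:`MarkerDiscovery` object is built from a labeled
:class:`ExpressionDataset` (plus the knobs of every stage), its
:meth:`~MarkerDiscovery.fit` executes all stages and returns a
:class:`MarkerDiscoveryResults` holding the six feature lists, IFS
curves, selection reports, rule sets and the essential-gene intersection
table, with a ``summary()`` table of the headline numbers.

:func:`run` wraps that surface for batch use: it reads a
:class:`RunConfig` (YAML/JSON-friendly), optionally generates the input
synthetically, writes every artifact in its stable text format and
returns a manifest. All stage seeds derive from one master seed by
hashing (master, stage, method), so adding a method never perturbs the
seeds of the others and a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as _io
from .dataset import ExpressionDataset, ValidationError
from .ifs import (
    CLASSIFIERS,
    ClassifierParams,
    CVSpec,
    IFSGrid,
    SelectionReport,
    build_selection_report,
    ifs_scan,
    train_final,
)
from .ranking import METHODS, RankingParams, rank_features
from .rules import essential_sets, extract_rules, intersect
from .simulate import SyntheticSpec, composition_preset, generate
from .smote import SmoteParams
from .util import derive_seed

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage, carries the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """One reproducible run: input source, stage parameters, output dir."""

    out_dir: str
    seed: int = 0
    # input: either file paths ...
    expression_path: str | None = None
    labels_path: str | None = None
    # ... or a synthetic specification
    synthetic: SyntheticSpec | None = None
    methods: tuple = METHODS
    classifiers: tuple = CLASSIFIERS
    grid: IFSGrid = field(default_factory=IFSGrid)
    cv_folds: int = 10
    smote_k_neighbors: int = 5
    smote_mode: str = "infold"
    delta: float = 0.01
    ranking_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if isinstance(self.synthetic, dict):
            syn = dict(self.synthetic)
            comp = syn.pop("composition")
            if isinstance(comp, str):
                comp = composition_preset(comp)
            elif isinstance(comp, dict):
                from .simulate import CompositionSpec

                comp = CompositionSpec(comp)
            self.synthetic = SyntheticSpec(composition=comp, **syn)
        if isinstance(self.grid, dict):
            self.grid = IFSGrid(**self.grid)
        self.methods = tuple(self.methods)
        self.classifiers = tuple(self.classifiers)

    @classmethod
    def from_dict(cls, obj: dict) -> "RunConfig":
        return cls(**obj)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


class MarkerDiscovery:
    """The marker-discovery analysis bound to one labeled dataset.

    Parameters mirror the pipeline stages; ``fit()`` runs them all.
    """

    def __init__(
        self,
        dataset: ExpressionDataset,
        methods=METHODS,
        classifiers=CLASSIFIERS,
        grid: IFSGrid | None = None,
        cv: CVSpec | None = None,
        smote: SmoteParams | None = None,
        classifier_params: ClassifierParams | None = None,
        smote_mode: str = "infold",
        delta: float = 0.01,
        seed: int = 0,
        ranking_overrides: dict | None = None,
    ):
        dataset.require_labels(min_classes=2)
        self.dataset = dataset
        self.methods = tuple(methods)
        self.classifiers = tuple(classifiers)
        self.grid = grid or IFSGrid()
        self.cv = cv or CVSpec(seed=derive_seed(seed, "cv"))
        self.smote = smote or SmoteParams(seed=derive_seed(seed, "smote"))
        self.classifier_params = classifier_params or ClassifierParams()
        self.smote_mode = smote_mode
        self.delta = delta
        self.seed = seed
        self.ranking_overrides = dict(ranking_overrides or {})

    def fit(self) -> "MarkerDiscoveryResults":
        feature_lists, curves, reports, rulesets, timings = {}, {}, {}, {}, {}
        for method in self.methods:
            t0 = time.time()
            params = RankingParams(
                method=method,
                seed=derive_seed(self.seed, "rank", method),
                **self.ranking_overrides.get(method, {}),
            )
            try:
                flist = rank_features(self.dataset, params)
            except Exception as e:
                raise StageError(f"rank:{method}", e) from e
            feature_lists[method] = flist
            timings[f"rank:{method}"] = time.time() - t0

            t0 = time.time()
            curve = ifs_scan(
                self.dataset,
                flist,
                grid=self.grid,
                cv=self.cv,
                smote=self.smote,
                classifiers=self.classifiers,
                classifier_params=self.classifier_params,
                smote_mode=self.smote_mode,
                seed=derive_seed(self.seed, "ifs", method),
            )
            curves[method] = curve
            reports[method] = build_selection_report(curve, flist, delta=self.delta)
            timings[f"ifs:{method}"] = time.time() - t0

            if "dt" in self.classifiers:
                best_dt = train_final(
                    self.dataset,
                    reports[method].genes["dt"]["optimal"],
                    "dt",
                    smote=self.smote,
                    classifier_params=self.classifier_params,
                    seed=derive_seed(self.seed, "final", method, "dt"),
                )
                rs = extract_rules(best_dt)
                rs.method = method
                rulesets[method] = rs

        intersection = None
        if "rf" in self.classifiers:
            intersection = intersect(essential_sets(reports))
        return MarkerDiscoveryResults(
            model=self,
            feature_lists=feature_lists,
            curves=curves,
            reports=reports,
            rulesets=rulesets,
            intersection=intersection,
            timings=timings,
        )


@dataclass
class MarkerDiscoveryResults:
    """Everything one fit produced, with a summary table."""

    model: MarkerDiscovery
    feature_lists: dict
    curves: dict
    reports: dict
    rulesets: dict
    intersection: object
    timings: dict

    def summary(self) -> pd.DataFrame:
        rows = []
        for method in self.model.methods:
            rep: SelectionReport = self.reports[method]
            row = {"method": method}
            for clf in self.model.classifiers:
                sel = rep.per_classifier[clf]
                row[f"{clf}_optimal_k"] = sel["optimal_k"]
                row[f"{clf}_optimal_wf1"] = sel["optimal_metrics"].weighted_f1
                row[f"{clf}_suboptimal_k"] = sel["suboptimal_k"]
                row[f"{clf}_suboptimal_wf1"] = sel["suboptimal_metrics"].weighted_f1
            if method in self.rulesets:
                row["n_rules"] = len(self.rulesets[method].rules)
            rows.append(row)
        return pd.DataFrame(rows)

    def marker_recovery(self, truth, top: int) -> dict:
        """Fraction of planted markers each method puts in its top ranks."""
        planted = truth.all_markers()
        return {
            m: len(planted & set(fl.top(top))) / len(planted)
            for m, fl in self.feature_lists.items()
        }


def run(config: RunConfig) -> dict:
    """Execute a full configured run, writing every artifact; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "artifacts": {}, "versions": {}}
    import sklearn

    import scmarker_ifs

    manifest["versions"] = {
        "scmarker_ifs": getattr(scmarker_ifs, "__version__", "dev"),
        "sklearn": sklearn.__version__,
    }

    truth = None
    t0 = time.time()
    if config.synthetic is not None:
        dataset, truth = generate(config.synthetic)
        _io.write_dense(dataset, out / "expression.tsv")
        _io.write_labels(dataset, out / "labels.tsv")
        _io.write_marker_truth(truth, out / "marker_truth.json")
        manifest["artifacts"]["expression"] = str(out / "expression.tsv")
        manifest["artifacts"]["labels"] = str(out / "labels.tsv")
        manifest["artifacts"]["marker_truth"] = str(out / "marker_truth.json")
    elif config.expression_path and config.labels_path:
        dataset = _io.read_expression(config.expression_path)
        dataset = _io.attach_labels(dataset, config.labels_path)
    else:
        raise ValidationError("config needs either synthetic or expression+labels paths")
    manifest["stages"]["input"] = {"seconds": round(time.time() - t0, 3),
                                   "n_cells": dataset.n_cells,
                                   "n_genes": dataset.n_genes}

    model = MarkerDiscovery(
        dataset,
        methods=config.methods,
        classifiers=config.classifiers,
        grid=config.grid,
        cv=CVSpec(folds=config.cv_folds, seed=derive_seed(config.seed, "cv")),
        smote=SmoteParams(k_neighbors=config.smote_k_neighbors,
                          seed=derive_seed(config.seed, "smote")),
        smote_mode=config.smote_mode,
        delta=config.delta,
        seed=config.seed,
        ranking_overrides=config.ranking_overrides,
    )
    try:
        results = model.fit()
    except StageError as e:
        manifest["failed_stage"] = e.stage
        with open(out / "manifest.partial.json", "w", encoding="utf-8",
                  newline="\n") as fh:
            json.dump(manifest, fh, indent=2)
            fh.write("\n")
        raise

    for method in config.methods:
        _io.write_feature_list(results.feature_lists[method], out / f"ranks.{method}.tsv")
        _io.write_ifs_curve(results.curves[method], out / f"ifs.{method}.csv")
        _io.write_selection_report(results.reports[method], out / f"selection.{method}.json")
        manifest["artifacts"][f"ranks.{method}"] = str(out / f"ranks.{method}.tsv")
        manifest["artifacts"][f"ifs.{method}"] = str(out / f"ifs.{method}.csv")
        manifest["artifacts"][f"selection.{method}"] = str(out / f"selection.{method}.json")
        if method in results.rulesets:
            _io.write_ruleset(results.rulesets[method],
                              out / f"rules.{method}.json",
                              out / f"rules.{method}.txt")
            manifest["artifacts"][f"rules.{method}"] = str(out / f"rules.{method}.json")
    if results.intersection is not None:
        _io.write_intersection(results.intersection, out / "intersection.tsv")
        manifest["artifacts"]["intersection"] = str(out / "intersection.tsv")

    results.summary().to_csv(out / "summary.csv", index=False, lineterminator="\n")
    manifest["artifacts"]["summary"] = str(out / "summary.csv")
    manifest["stages"]["timings"] = {k: round(v, 3) for k, v in results.timings.items()}
    manifest["stage_seeds"] = {
        f"rank:{m}": derive_seed(config.seed, "rank", m) for m in config.methods
    } | {f"ifs:{m}": derive_seed(config.seed, "ifs", m) for m in config.methods}
    with open(out / "manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return manifest
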