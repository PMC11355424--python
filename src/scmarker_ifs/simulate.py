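"""Synthetic labeled single-cell expression data with planted marker genes.

The generator emulates the statistical structure the downstream analysis
assumes: a handful of imbalanced disease classes, a small disjoint set of
class-specific marker genes hidden among thousands of uninformative genes,
and count-like expression with dropout. Per-gene baseline means are drawn
once from a lognormal (median ``base_mean``, log-sd ``mean_sdlog``); a cell
of class *c* then draws gene *g* from a negative binomial whose mean is the
baseline, multiplied by ``fold_change`` when *g* is one of *c*'s markers,
and each observed value is independently zeroed with ``dropout_rate``.

Composition presets reproduce the six-condition cell counts of the cardiac
single-nucleus study the pipeline targets (cardiac fibroblasts ``CF``,
cardiomyocytes ``CM``, endothelial cells ``Endo``) plus a small ``desk``
preset for fast end-to-end runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dataset import ExpressionDataset, ValidationError

log = logging.getLogger(__name__)

_CLASSES = ("DCM", "control", "HCM", "HF_HLHS", "Neo_HLHS", "TOF")

_COMPOSITIONS = {
    "CF": (6318, 6077, 1941, 3515, 1158, 2025),
    "CM": (5189, 28506, 10433, 14745, 4207, 10216),
    "Endo": (10420, 8596, 6083, 7755, 1112, 1707),
    "desk": (120, 115, 40, 70, 25, 45),
}


@dataclass
class CompositionSpec:
    """Ordered class-name → cell-count map (≥ 2 classes, all counts ≥ 1)."""

    class_counts: dict

    def __post_init__(self):
        self.class_counts = dict(self.class_counts)
        if len(self.class_counts) < 2:
            raise ValidationError("composition needs >= 2 classes")
        for k, v in self.class_counts.items():
            if int(v) != v or v < 1:
                raise ValidationError(f"class {k!r} count must be a positive integer")
            self.class_counts[k] = int(v)

    @property
    def classes(self) -> list:
        return list(self.class_counts)

    @property
    def total(self) -> int:
        return sum(self.class_counts.values())


def composition_preset(name: str) -> CompositionSpec:
    """Six-condition composition presets: ``CF``, ``CM``, ``Endo``, ``desk``."""
    if name not in _COMPOSITIONS:
        raise ValidationError(
            f"unknown composition preset {name!r}; choose from {sorted(_COMPOSITIONS)}"
        )
    return CompositionSpec(dict(zip(_CLASSES, _COMPOSITIONS[name])))


@dataclass
class SyntheticSpec:
    """Full parameterization of one synthetic dataset.

    fold_change multiplies a marker gene's mean within its own class; values
    in (0, 1) model down-regulated markers and require
    ``allow_downregulated=True``. ``dispersion`` is the negative-binomial
    size parameter (smaller = more overdispersed).
    """

    composition: CompositionSpec
    n_genes: int = 2000
    markers_per_class: int = 10
    fold_change: float = 4.0
    base_mean: float = 8.0
    mean_sdlog: float = 0.5
    dispersion: float = 2.0
    dropout_rate: float = 0.5
    seed: int = 0
    allow_downregulated: bool = False

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValidationError("n_genes must be positive")
        if self.markers_per_class < 0:
            raise ValidationError("markers_per_class must be non-negative")
        n_classes = len(self.composition.classes)
        if self.markers_per_class * n_classes > self.n_genes:
            raise ValidationError("more planted markers than genes")
        if self.fold_change <= 0:
            raise ValidationError("fold_change must be > 0")
        if self.fold_change <= 1 and not self.allow_downregulated:
            raise ValidationError(
                "fold_change <= 1 models down-regulation; set allow_downregulated=True"
            )
        if not (self.base_mean > 0 and self.dispersion > 0):
            raise ValidationError("base_mean and dispersion must be > 0")
        if not (0 <= self.dropout_rate < 1):
            raise ValidationError("dropout_rate must be in [0, 1)")


@dataclass
class MarkerTruth:
    """The planted class → marker-gene map (disjoint lists); recovery ground truth."""

    markers: dict

    def __post_init__(self):
        seen: set = set()
        for k, genes in self.markers.items():
            genes = list(genes)
            if seen & set(genes):
                raise ValidationError("marker lists must be disjoint across classes")
            seen |= set(genes)
            self.markers[k] = genes

    def all_markers(self) -> set:
        return {g for genes in self.markers.values() for g in genes}


def desk_spec(seed: int = 1, **overrides) -> SyntheticSpec:
    """The small six-class benchmark configuration (415 cells, 2000 genes,
    10 markers per class, fold change 4, dropout 0.5, dispersion 2)."""
    kwargs = dict(
        composition=composition_preset("desk"),
        n_genes=2000,
        markers_per_class=10,
        fold_change=4.0,
        dispersion=2.0,
        dropout_rate=0.5,
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticSpec(**kwargs)


def generate(spec: SyntheticSpec) -> tuple[ExpressionDataset, MarkerTruth]:
    """Draw one dataset from ``spec``. Deterministic given ``spec.seed``.

    Cell ids encode the class for debuggability; gene ids are anonymous
    (``g0001`` …) with marker identity recorded only in the returned
    :class:`MarkerTruth`.
    """
    rng = np.random.default_rng(spec.seed)
    classes = spec.composition.classes
    n_genes = spec.n_genes
    width = max(4, len(str(n_genes)))
    gene_ids = [f"g{j + 1:0{width}d}" for j in range(n_genes)]

    # per-gene baseline mean, lognormal with median base_mean
    mu = spec.base_mean * np.exp(rng.normal(0.0, spec.mean_sdlog, size=n_genes))

    marker_idx = rng.choice(n_genes, size=spec.markers_per_class * len(classes),
                            replace=False)
    truth = MarkerTruth(markers={
        c: [gene_ids[j] for j in
            marker_idx[i * spec.markers_per_class:(i + 1) * spec.markers_per_class]]
        for i, c in enumerate(classes)
    })

    blocks, cell_ids, labels = [], [], []
    for i, c in enumerate(classes):
        n_c = spec.composition.class_counts[c]
        mean_c = mu.copy()
        cols = marker_idx[i * spec.markers_per_class:(i + 1) * spec.markers_per_class]
        mean_c[cols] *= spec.fold_change
        # NB with mean m and size r: p = r / (r + m)
        p = spec.dispersion / (spec.dispersion + mean_c)
        counts = rng.negative_binomial(spec.dispersion, p, size=(n_c, n_genes))
        if spec.dropout_rate > 0:
            counts = np.where(rng.random((n_c, n_genes)) < spec.dropout_rate, 0, counts)
        blocks.append(counts.astype(np.float64))
        cell_ids.extend(f"{c}_c{j + 1:05d}" for j in range(n_c))
        labels.extend([c] * n_c)

    dataset = ExpressionDataset(
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        matrix=np.vstack(blocks),
        labels=labels,
        class_names=classes,
    )
    return dataset, truth


def shuffle_labels(dataset: ExpressionDataset, seed: int) -> ExpressionDataset:
    """Permute labels uniformly at random; the matrix is untouched.

    The negative-control input: any class signal surviving the shuffle is
    an artifact of the analysis, not of the data.
    """
    dataset.require_labels()
    rng = np.random.default_rng(seed)
    perm = rng.permutation(dataset.n_cells)
    return dataset.with_labels(
        [dataset.labels[i] for i in perm], class_names=dataset.class_names
    )
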