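"""Core in-memory containers: labeled expression matrices and ranked feature lists.

The pipeline's universal input is an :class:`ExpressionDataset` — a dense
cells × genes matrix of non-negative expression values (raw or normalized
counts; the pipeline is value-scale agnostic) with per-cell class labels.
A :class:`FeatureList` is one ranking method's ordered gene list with
non-increasing importance scores.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from collections import Counter

import numpy as np


class ValidationError(ValueError):
    """An object violates one of its structural invariants."""


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = sorted(k for k, c in Counter(ids).items() if c > 1)
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class ExpressionDataset:
    """Dense cells × genes expression matrix with optional per-cell labels.

    Parameters
    ----------
    cell_ids : list of str
        Unique cell identifiers, one per matrix row.
    gene_ids : list of str
        Unique gene identifiers, one per matrix column.
    matrix : ndarray, shape (n_cells, n_genes)
        Non-negative expression values, stored as float64.
    labels : list of str, optional
        Per-cell class name aligned to ``cell_ids``. ``None`` for an
        unlabeled dataset.
    class_names : list of str, optional
        Ordered distinct labels. Derived from ``labels`` (first-appearance
        order) when omitted.
    """

    cell_ids: list
    gene_ids: list
    matrix: np.ndarray
    labels: list | None = None
    class_names: list | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.cell_ids = list(self.cell_ids)
        self.gene_ids = list(self.gene_ids)
        if self.matrix.ndim != 2:
            raise ValidationError("matrix must be 2-dimensional (cells x genes)")
        if self.matrix.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValidationError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        _check_unique(self.cell_ids, "cell ids")
        _check_unique(self.gene_ids, "gene ids")
        if np.any(self.matrix < 0):
            raise ValidationError("expression values must be non-negative")
        if self.labels is not None:
            self.labels = list(self.labels)
            if len(self.labels) != len(self.cell_ids):
                raise ValidationError("labels length does not match cell count")
            if self.class_names is None:
                self.class_names = list(dict.fromkeys(self.labels))
            else:
                self.class_names = list(self.class_names)
                missing = set(self.labels) - set(self.class_names)
                if missing:
                    raise ValidationError(f"labels not in class_names: {sorted(missing)}")

    # -- basic views ----------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def is_labeled(self) -> bool:
        return self.labels is not None

    def class_counts(self) -> dict:
        """Per-class cell counts in ``class_names`` order."""
        self.require_labels()
        c = Counter(self.labels)
        return {k: c.get(k, 0) for k in self.class_names}

    def require_labels(self, min_classes: int = 1) -> None:
        if self.labels is None:
            raise ValidationError("operation requires a labeled dataset")
        if len(self.class_names) < min_classes:
            raise ValidationError(
                f"operation requires >= {min_classes} classes, found {len(self.class_names)}"
            )

    def y_codes(self) -> np.ndarray:
        """Labels as integer codes in ``class_names`` order."""
        self.require_labels()
        lut = {c: i for i, c in enumerate(self.class_names)}
        return np.array([lut[l] for l in self.labels], dtype=np.int64)

    # -- derived datasets -----------------------------------------------

    def with_labels(self, labels, class_names=None) -> "ExpressionDataset":
        return replace(self, labels=list(labels), class_names=class_names)

    def subset_genes(self, genes) -> "ExpressionDataset":
        """Restrict to ``genes`` (kept in the given order)."""
        genes = list(genes)
        lut = {g: j for j, g in enumerate(self.gene_ids)}
        try:
            cols = [lut[g] for g in genes]
        except KeyError as e:
            raise ValidationError(f"gene not in dataset: {e.args[0]}") from None
        return replace(self, gene_ids=genes, matrix=self.matrix[:, cols])

    def gene_matrix(self, genes) -> np.ndarray:
        """Column-sliced matrix for an ordered gene subset."""
        lut = {g: j for j, g in enumerate(self.gene_ids)}
        cols = [lut[g] for g in genes]
        return self.matrix[:, cols]

    def equals(self, other: "ExpressionDataset") -> bool:
        return (
            self.cell_ids == other.cell_ids
            and self.gene_ids == other.gene_ids
            and np.array_equal(self.matrix, other.matrix)
            and self.labels == other.labels
        )


@dataclass
class FeatureList:
    """One ranking method's ordered gene list (rank 1 first) with scores.

    Scores are non-negative and non-increasing; every gene appears once.
    ``backing`` records which library/model produced the importances.
    """

    method: str
    gene_ids: list
    scores: np.ndarray
    backing: str = ""

    def __post_init__(self):
        self.gene_ids = list(self.gene_ids)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if len(self.gene_ids) != len(self.scores):
            raise ValidationError("gene_ids and scores must have equal length")
        _check_unique(self.gene_ids, "gene ids")
        if np.any(np.diff(self.scores) > 0):
            raise ValidationError("scores must be non-increasing")
        if len(self.scores) and self.scores[-1] < 0:
            raise ValidationError("scores must be non-negative")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def top(self, k: int) -> list:
        """The first ``k`` genes of the ranking."""
        if k < 1:
            raise ValidationError("k must be >= 1")
        return self.gene_ids[: min(k, len(self.gene_ids))]

    def score_map(self) -> dict:
        return dict(zip(self.gene_ids, self.scores.tolist()))

    def equals(self, other: "FeatureList") -> bool:
        return (
            self.method == other.method
            and self.gene_ids == other.gene_ids
            and np.allclose(self.scores, other.scores, rtol=1e-12, atol=0)
        )


def ordered_feature_list(method: str, gene_ids, scores, backing: str = "") -> FeatureList:
    """Build a FeatureList from an unordered gene → score mapping.

    Ordering is descending score with ascending gene_id as the global
    tie-break, so identical inputs always produce bitwise-identical lists
    and zero-scored genes sort after all scored genes.
    """
    gene_ids = list(gene_ids)
    scores = np.asarray(scores, dtype=np.float64)
    if np.any(scores < 0):
        raise ValidationError("importance scores must be non-negative")
    order = sorted(range(len(gene_ids)), key=lambda j: (-scores[j], gene_ids[j]))
    return FeatureList(
        method=method,
        gene_ids=[gene_ids[j] for j in order],
        scores=scores[order],
        backing=backing,
    )
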