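"""Readers and writers for every pipeline artifact.

Expression input comes as either a dense delimited table (cells in rows,
genes in columns, delimiter sniffed from the header) or a 10x-style
MatrixMarket triplet directory (``matrix.mtx`` stored genes × cells with
1-based indices, plus ``features.tsv`` and ``barcodes.tsv``). All outputs
are UTF-8 text with LF line endings: feature lists as rank/gene/score TSV,
IFS curves as CSV, selection reports and rule sets as JSON (rules also as
a human-readable text rendering), intersection tables as TSV.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .dataset import ExpressionDataset, FeatureList, FormatError, ValidationError

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"   # shortest-exact is not guaranteed by printf; 17 digits round-trips binary64


# ---------------------------------------------------------------------------
# expression input
# ---------------------------------------------------------------------------

def read_expression(path, format: str | None = None) -> ExpressionDataset:
    """Read an expression matrix into a cells × genes dataset (labels empty).

    Parameters
    ----------
    path : path-like
        A delimited table file (``format="dense"``) or a directory holding
        ``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``
        (``format="mtx_triplet"``).
    format : {"dense", "mtx_triplet"}, optional
        Auto-detected from whether ``path`` is a directory when omitted.
    """
    path = Path(path)
    if format is None:
        format = "mtx_triplet" if path.is_dir() else "dense"
    if format == "dense":
        return _read_dense(path)
    if format == "mtx_triplet":
        return _read_mtx_triplet(path)
    raise FormatError(f"unknown expression format: {format!r}")


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _read_dense(path: Path) -> ExpressionDataset:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = _sniff_delimiter(header)
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    matrix = df.to_numpy(dtype=np.float64)
    return ExpressionDataset(
        cell_ids=[str(c) for c in df.index],
        gene_ids=[str(g) for g in df.columns],
        matrix=matrix,
    )


def _read_id_column(path: Path) -> list:
    with open(path, encoding="utf-8") as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def _read_mtx_triplet(path: Path) -> ExpressionDataset:
    mtx_path = path / "matrix.mtx"
    try:
        mat = scipy.io.mmread(mtx_path)
    except Exception as e:  # malformed header / truncated entries
        raise FormatError(f"cannot parse {mtx_path}: {e}") from e
    genes = _read_id_column(path / "features.tsv")
    cells = _read_id_column(path / "barcodes.tsv")
    if mat.shape != (len(genes), len(cells)):
        raise FormatError(
            f"matrix.mtx is {mat.shape[0]} x {mat.shape[1]} but found "
            f"{len(genes)} features and {len(cells)} barcodes"
        )
    dense = np.asarray(
        mat.toarray() if scipy.sparse.issparse(mat) else mat, dtype=np.float64
    ).T  # stored genes x cells; pipeline orientation is cells x genes
    return ExpressionDataset(cell_ids=cells, gene_ids=genes, matrix=dense)


def write_dense(dataset: ExpressionDataset, path, sep: str = "\t") -> None:
    df = pd.DataFrame(dataset.matrix, index=dataset.cell_ids, columns=dataset.gene_ids)
    df.index.name = "cell_id"
    df.to_csv(path, sep=sep, float_format=_FLOAT_FMT, lineterminator="\n")


def write_mtx_triplet(dataset: ExpressionDataset, outdir) -> None:
    """Write the 10x-style triplet (matrix stored genes × cells)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(dataset.matrix.T)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), sparse)
    (outdir / "features.tsv").write_text(
        "".join(f"{g}\n" for g in dataset.gene_ids), encoding="utf-8"
    )
    (outdir / "barcodes.tsv").write_text(
        "".join(f"{c}\n" for c in dataset.cell_ids), encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

def attach_labels(dataset: ExpressionDataset, labels_path) -> ExpressionDataset:
    """Attach per-cell class labels from a two-column TSV (cell_id, class).

    Alignment is by cell id, not file order. Every dataset cell must appear
    exactly once; label-file cells absent from the dataset are ignored with
    a warning. ``class_names`` follows first-appearance order in the file.
    """
    mapping: dict = {}
    order: list = []
    with open(labels_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{labels_path}:{lineno + 1}: expected 2 tab-separated columns"
                )
            cell, klass = parts
            if lineno == 0 and cell == "cell_id":
                continue  # optional header
            if cell in mapping:
                raise FormatError(f"duplicate cell id in label file: {cell}")
            mapping[cell] = klass
            if klass not in order:
                order.append(klass)
    missing = [c for c in dataset.cell_ids if c not in mapping]
    if missing:
        raise ValidationError(
            f"label file missing {len(missing)} cell id(s): {missing[:10]}"
        )
    unknown = set(mapping) - set(dataset.cell_ids)
    if unknown:
        log.warning("label file has %d unknown cell id(s), ignored: %s",
                    len(unknown), sorted(unknown)[:10])
    labels = [mapping[c] for c in dataset.cell_ids]
    class_names = [k for k in order if k in set(labels)]
    return dataset.with_labels(labels, class_names=class_names)


def write_labels(dataset: ExpressionDataset, path) -> None:
    dataset.require_labels()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("cell_id\tclass\n")
        for cell, klass in zip(dataset.cell_ids, dataset.labels):
            fh.write(f"{cell}\t{klass}\n")


def read_labels(path) -> tuple[list, list, list]:
    """Return (cell_ids, labels, class_names) from a label TSV."""
    cells, labels, order = [], [], []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cell, klass = line.split("\t")
            if lineno == 0 and cell == "cell_id":
                continue
            cells.append(cell)
            labels.append(klass)
            if klass not in order:
                order.append(klass)
    return cells, labels, order


# ---------------------------------------------------------------------------
# feature lists
# ---------------------------------------------------------------------------

def write_feature_list(flist: FeatureList, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# method={flist.method}\n")
        if flist.backing:
            fh.write(f"# backing={flist.backing}\n")
        fh.write("rank\tgene_id\tscore\n")
        for rank, (gene, score) in enumerate(zip(flist.gene_ids, flist.scores), 1):
            fh.write(f"{rank}\t{gene}\t{_FLOAT_FMT % score}\n")


def read_feature_list(path) -> FeatureList:
    method, backing = "", ""
    genes, scores = [], []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("# method="):
                method = line.split("=", 1)[1]
                continue
            if line.startswith("# backing="):
                backing = line.split("=", 1)[1]
                continue
            parts = line.split("\t")
            if parts[0] == "rank":
                continue
            if len(parts) != 3:
                raise FormatError(f"bad feature-list row: {line!r}")
            genes.append(parts[1])
            scores.append(float(parts[2]))
    return FeatureList(method=method, gene_ids=genes, scores=np.array(scores),
                       backing=backing)


# ---------------------------------------------------------------------------
# IFS curves, selection reports, rule sets, intersections
# ---------------------------------------------------------------------------

def write_ifs_curve(curve, path) -> None:
    curve.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT,
                            lineterminator="\n")


def write_selection_report(report, path) -> None:
    _write_json(report.to_dict(), path)


def write_ruleset(ruleset, json_path, text_path=None) -> None:
    _write_json(ruleset.to_dict(), json_path)
    if text_path is not None:
        Path(text_path).write_text(ruleset.to_text(), encoding="utf-8")


def write_intersection(table, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def _write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=False)
        fh.write("\n")


def write_marker_truth(truth, path) -> None:
    _write_json({"markers": {k: list(v) for k, v in truth.markers.items()}}, path)


def read_marker_truth(path):
    from .simulate import MarkerTruth

    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    return MarkerTruth(markers={k: list(v) for k, v in obj["markers"].items()})
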