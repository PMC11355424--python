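"""Containers, format readers/writers, and round-trip identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scmarker_ifs import ExpressionDataset, FeatureList, FormatError, ValidationError
from scmarker_ifs import io as sio
from scmarker_ifs.dataset import ordered_feature_list


# ---------------------------------------------------------------------------
# container invariants
# ---------------------------------------------------------------------------

def test_dataset_rejects_structural_violations():
    good = dict(cell_ids=["c1", "c2"], gene_ids=["g1"], matrix=[[1.0], [2.0]])
    ExpressionDataset(**good)
    with pytest.raises(ValidationError):
        ExpressionDataset(cell_ids=["c1", "c1"], gene_ids=["g1"], matrix=[[1.0], [2.0]])
    with pytest.raises(ValidationError):
        ExpressionDataset(cell_ids=["c1", "c2"], gene_ids=["g1", "g1"],
                          matrix=[[1.0, 2.0], [3.0, 4.0]])
    with pytest.raises(ValidationError):
        ExpressionDataset(cell_ids=["c1", "c2"], gene_ids=["g1"], matrix=[[-1.0], [2.0]])
    with pytest.raises(ValidationError):
        ExpressionDataset(cell_ids=["c1"], gene_ids=["g1"], matrix=[[1.0], [2.0]])
    with pytest.raises(ValidationError):
        ExpressionDataset(**good, labels=["A"])


def test_feature_list_requires_sorted_nonnegative_scores():
    FeatureList(method="x", gene_ids=["a", "b"], scores=[2.0, 1.0])
    with pytest.raises(ValidationError):
        FeatureList(method="x", gene_ids=["a", "b"], scores=[1.0, 2.0])
    with pytest.raises(ValidationError):
        FeatureList(method="x", gene_ids=["a", "b"], scores=[1.0, -0.5])
    with pytest.raises(ValidationError):
        FeatureList(method="x", gene_ids=["a", "a"], scores=[1.0, 1.0])


def test_ordered_feature_list_tie_break_is_lexicographic():
    fl = ordered_feature_list("m", ["z", "a", "m"], [1.0, 1.0, 2.0])
    assert fl.gene_ids == ["m", "a", "z"]


# ---------------------------------------------------------------------------
# expression readers
# ---------------------------------------------------------------------------

def test_dense_round_trip_and_identity(tmp_path):
    ds = ExpressionDataset(
        cell_ids=["r1", "r2", "r3"], gene_ids=["g1", "g2"],
        matrix=[[1.0, 2.0], [3.0, 4.5], [0.0, 7.0]],
    )
    path = tmp_path / "m.tsv"
    sio.write_dense(ds, path)
    back = sio.read_expression(path, format="dense")
    assert back.equals(ds)


def test_dense_accepts_comma_delimiter(tmp_path):
    path = tmp_path / "m.csv"
    path.write_text("cell_id,g1,g2\nr1,1,2\nr2,3,4\n")
    ds = sio.read_expression(path)
    assert ds.gene_ids == ["g1", "g2"]
    assert ds.matrix.tolist() == [[1.0, 2.0], [3.0, 4.0]]


def test_mtx_triplet_coordinate_semantics(tmp_path):
    """2 genes × 3 cells, single nonzero at (gene 2, cell 3) = 7 →
    cells × genes matrix with entry [2, 1] = 7 and zeros elsewhere."""
    d = tmp_path / "mtx"
    d.mkdir()
    (d / "matrix.mtx").write_text(
        "%%MatrixMarket matrix coordinate real general\n2 3 1\n2 3 7\n"
    )
    (d / "features.tsv").write_text("g1\ng2\n")
    (d / "barcodes.tsv").write_text("c1\nc2\nc3\n")
    ds = sio.read_expression(d)
    expected = np.zeros((3, 2))
    expected[2, 1] = 7
    assert ds.cell_ids == ["c1", "c2", "c3"]
    assert np.array_equal(ds.matrix, expected)


def test_mtx_dimension_mismatch_is_format_error(tmp_path):
    d = tmp_path / "mtx"
    d.mkdir()
    (d / "matrix.mtx").write_text(
        "%%MatrixMarket matrix coordinate real general\n2 3 1\n2 3 7\n"
    )
    (d / "features.tsv").write_text("g1\ng2\ng3\n")
    (d / "barcodes.tsv").write_text("c1\nc2\nc3\n")
    with pytest.raises(FormatError):
        sio.read_expression(d)


def test_mtx_truncated_entries_is_format_error(tmp_path):
    d = tmp_path / "mtx"
    d.mkdir()
    (d / "matrix.mtx").write_text(
        "%%MatrixMarket matrix coordinate real general\n2 3 5\n1 1 1\n2 3 7\n"
    )
    (d / "features.tsv").write_text("g1\ng2\n")
    (d / "barcodes.tsv").write_text("c1\nc2\nc3\n")
    with pytest.raises(FormatError):
        sio.read_expression(d)


def test_dense_and_mtx_of_same_matrix_agree(tmp_path):
    rng = np.random.default_rng(1)
    ds = ExpressionDataset(
        cell_ids=[f"c{i}" for i in range(5)],
        gene_ids=[f"g{j}" for j in range(4)],
        matrix=np.round(rng.uniform(0, 9, (5, 4)) * (rng.random((5, 4)) > 0.4), 3),
    )
    sio.write_dense(ds, tmp_path / "dense.tsv")
    sio.write_mtx_triplet(ds, tmp_path / "mtx")
    a = sio.read_expression(tmp_path / "dense.tsv")
    b = sio.read_expression(tmp_path / "mtx")
    assert a.equals(b)


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

@pytest.fixture
def small_dataset():
    return ExpressionDataset(
        cell_ids=["c1", "c2", "c3"], gene_ids=["g1"],
        matrix=[[1.0], [2.0], [3.0]],
    )


def test_labels_aligned_by_id_not_order(tmp_path, small_dataset):
    fwd = tmp_path / "fwd.tsv"
    rev = tmp_path / "rev.tsv"
    fwd.write_text("c1\tX\nc2\tY\nc3\tX\n")
    rev.write_text("c3\tX\nc2\tY\nc1\tX\n")
    a = sio.attach_labels(small_dataset, fwd)
    b = sio.attach_labels(small_dataset, rev)
    assert a.labels == b.labels == ["X", "Y", "X"]


def test_missing_cell_named_in_error(tmp_path, small_dataset):
    path = tmp_path / "labels.tsv"
    path.write_text("c1\tX\nc3\tY\n")
    with pytest.raises(ValidationError, match="c2"):
        sio.attach_labels(small_dataset, path)


def test_unknown_cell_ignored_with_warning(tmp_path, small_dataset, caplog):
    path = tmp_path / "labels.tsv"
    path.write_text("c1\tX\nc2\tY\nc3\tX\nc9\tZ\n")
    with caplog.at_level("WARNING"):
        ds = sio.attach_labels(small_dataset, path)
    assert ds.labels == ["X", "Y", "X"]
    assert "c9" in caplog.text
    assert "Z" not in ds.class_names


def test_six_class_label_file(tmp_path):
    ds = ExpressionDataset(
        cell_ids=[f"c{i}" for i in range(6)], gene_ids=["g"],
        matrix=[[0.0]] * 6,
    )
    path = tmp_path / "labels.tsv"
    path.write_text("".join(f"c{i}\tk{i}\n" for i in range(6)))
    assert len(sio.attach_labels(ds, path).class_names) == 6


# ---------------------------------------------------------------------------
# artifact round-trips
# ---------------------------------------------------------------------------

def test_feature_list_round_trip_small(tmp_path):
    fl = ordered_feature_list("mcfs", ["a", "b", "c"], [3.0, 1.0, 2.0], backing="x")
    path = tmp_path / "fl.tsv"
    sio.write_feature_list(fl, path)
    lines = path.read_text().splitlines()
    assert lines[2] == "rank\tgene_id\tscore"
    assert len(lines) == 6
    assert sio.read_feature_list(path).equals(fl)


def test_feature_list_round_trip_1000_genes(tmp_path):
    rng = np.random.default_rng(0)
    fl = ordered_feature_list(
        "rf_mdi", [f"g{j:04d}" for j in range(1000)], rng.exponential(size=1000)
    )
    path = tmp_path / "fl.tsv"
    sio.write_feature_list(fl, path)
    back = sio.read_feature_list(path)
    assert back.gene_ids == fl.gene_ids
    assert np.allclose(back.scores, fl.scores, rtol=1e-12, atol=0)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.data())
def test_feature_list_round_trip_property(tmp_path_factory, data):
    n = data.draw(st.integers(1, 30))
    genes = [f"g{j}" for j in range(n)]
    scores = data.draw(
        st.lists(st.floats(0, 1e6, allow_nan=False, width=32), min_size=n, max_size=n)
    )
    fl = ordered_feature_list("m", genes, scores)
    path = tmp_path_factory.mktemp("fl") / "fl.tsv"
    sio.write_feature_list(fl, path)
    assert sio.read_feature_list(path).equals(fl)


def test_dense_and_label_round_trip_randomized(tmp_path):
    """100 random small datasets survive write → read bit-exactly."""
    rng = np.random.default_rng(99)
    for rep in range(100):
        n_cells = int(rng.integers(1, 8))
        n_genes = int(rng.integers(1, 6))
        classes = ["u", "v", "w"][: int(rng.integers(1, 4))]
        ds = ExpressionDataset(
            cell_ids=[f"c{rep}_{i}" for i in range(n_cells)],
            gene_ids=[f"g{j}" for j in range(n_genes)],
            matrix=rng.uniform(0, 100, size=(n_cells, n_genes)),
            labels=[classes[int(rng.integers(len(classes)))] for _ in range(n_cells)],
        )
        sio.write_dense(ds, tmp_path / "m.tsv")
        sio.write_labels(ds, tmp_path / "l.tsv")
        back = sio.attach_labels(sio.read_expression(tmp_path / "m.tsv"),
                                 tmp_path / "l.tsv")
        assert back.equals(ds)


def test_pipeline_stage_error_names_stage(tmp_path):
    from scmarker_ifs import RunConfig, run
    from scmarker_ifs.pipeline import StageError

    cfg = RunConfig(
        out_dir=str(tmp_path), seed=1,
        synthetic={"composition": {"a": 8, "b": 8}, "n_genes": 20,
                   "markers_per_class": 2, "seed": 0},
        methods=("mcfs",),
        grid={"step": 5, "max_k": 10},
        cv_folds=2,
        ranking_overrides={"mcfs": {"mcfs_m": 999}},   # projection > genes
    )
    with pytest.raises(StageError, match="rank:mcfs"):
        run(cfg)
    assert (tmp_path / "manifest.partial.json").exists()


def test_ruleset_with_zero_rules_serializes(tmp_path):
    from scmarker_ifs.rules import RuleSet

    rs = RuleSet(method="m", class_names=["A", "B"], rules=[])
    sio.write_ruleset(rs, tmp_path / "r.json", tmp_path / "r.txt")
    import json

    obj = json.loads((tmp_path / "r.json").read_text())
    assert obj["rules"] == []
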