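import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from surfscore.errors import FormatError, ValidationError
from surfscore.preprocess import (
    ExpressionMatrix,
    ProbeMatrix,
    _median_polish_block,
    collapse_duplicate_genes,
    log2_transform,
    median_polish_summarize,
    quantile_normalize,
    read_expression_tsv,
    read_geo_series_matrix,
    write_expression_tsv,
)


class TestExpressionMatrixInvariants:
    def test_rejects_nonfinite(self, matrix_factory):
        with pytest.raises(ValidationError, match="non-finite"):
            matrix_factory([[1.0, np.nan], [2.0, 3.0]], 1, 1)

    def test_rejects_unknown_group(self):
        with pytest.raises(ValidationError, match="unknown labels"):
            ExpressionMatrix(
                values=[[1.0, 2.0]],
                gene_ids=["g"],
                sample_ids=["a", "b"],
                groups=["tumor", "weird"],
            )

    def test_rejects_duplicate_samples(self):
        with pytest.raises(ValidationError, match="duplicate sample"):
            ExpressionMatrix(
                values=[[1.0, 2.0]],
                gene_ids=["g"],
                sample_ids=["a", "a"],
                groups=["tumor", "normal"],
            )


class TestQuantileNormalize:
    def test_two_by_two_known_answer(self, matrix_factory):
        # oracle: sorted-column means are (2, 3); each column becomes (2, 3)
        # in its own rank order
        m = matrix_factory([[1.0, 3.0], [2.0, 4.0]], 1, 1)
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values, [[2.0, 2.0], [3.0, 3.0]])

    def test_identical_columns_unchanged(self, matrix_factory):
        m = matrix_factory([[1.0, 1.0], [5.0, 5.0], [3.0, 3.0]], 1, 1)
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values, m.values)

    def test_constant_matrix_unchanged(self, matrix_factory):
        m = matrix_factory(np.full((4, 3), 2.5), 2, 1)
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values, m.values)

    def test_columns_share_sorted_distribution(self, rng, matrix_factory):
        m = matrix_factory(rng.normal(size=(50, 4)), 2, 2)
        out = quantile_normalize(m).values
        ref = np.sort(m.values, axis=0).mean(axis=1)
        for j in range(4):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)

    def test_rank_order_preserved(self, rng, matrix_factory):
        m = matrix_factory(rng.normal(size=(30, 3)), 2, 1)
        out = quantile_normalize(m).values
        for j in range(3):
            assert np.array_equal(np.argsort(m.values[:, j]), np.argsort(out[:, j]))

    def test_idempotent(self, rng, matrix_factory):
        m = matrix_factory(rng.normal(size=(40, 5)), 3, 2)
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_ties_stay_tied_and_share_reference_mean(self, matrix_factory):
        # tied values in a column get the mean reference value over their
        # tied rank span; note exact idempotence only holds for tie-free
        # columns (partial ties shift the column off the reference)
        values = np.array([[1.0, 2.0], [1.0, 5.0], [3.0, 5.0], [4.0, 0.0]])
        m = matrix_factory(values, 1, 1)
        out = quantile_normalize(m).values
        ref = np.sort(values, axis=0).mean(axis=1)  # (0.5, 1.5, 4.0, 4.5)
        assert out[0, 0] == out[1, 0] == pytest.approx(ref[:2].mean())
        assert out[1, 1] == out[2, 1] == pytest.approx(ref[2:].mean())
        for j in range(2):
            order_in = np.argsort(values[:, j], kind="stable")
            order_out = np.argsort(out[:, j], kind="stable")
            assert np.array_equal(order_in, order_out)

    def test_fully_constant_columns_idempotent(self, matrix_factory):
        values = np.array([[1.0, 7.0], [1.0, 7.0], [1.0, 7.0]])
        m = matrix_factory(values, 1, 1)
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_nonfinite_rejected(self):
        probes = ProbeMatrix(
            values=[[1.0, 2.0]],
            probe_ids=["p1"],
            sample_ids=["a", "b"],
            probe_to_gene={"p1": "g1"},
        )
        probes.values[0, 0] = np.inf
        with pytest.raises(ValidationError, match="non-finite"):
            quantile_normalize(probes)

    @settings(max_examples=30, deadline=None)
    @given(
        hnp.arrays(
            dtype=np.float64,
            shape=st.tuples(st.integers(2, 20), st.integers(1, 5)),
            elements=st.floats(-50, 50, allow_nan=False),
            unique=True,
        )
    )
    def test_idempotence_property_tie_free(self, values):
        from surfscore.preprocess import _quantile_normalize_values

        once = _quantile_normalize_values(values)
        twice = _quantile_normalize_values(once)
        np.testing.assert_allclose(twice, once, atol=1e-12)


def _probe_matrix(values, probe_to_gene):
    probes = list(probe_to_gene)
    return ProbeMatrix(
        values=values,
        probe_ids=probes,
        sample_ids=[f"s{j}" for j in range(np.asarray(values).shape[1])],
        probe_to_gene=probe_to_gene,
    )


class TestMedianPolish:
    def test_additive_block_exact(self):
        # a_ij = r_i + c_j is a fixed point: zero residuals, summaries
        # recover the column effects up to the overall constant
        r = np.array([0.0, 1.0, -2.0])
        c = np.array([10.0, 11.0, 12.0, 13.0])
        block = r[:, None] + c[None, :]
        overall, row_eff, col_eff, resid = _median_polish_block(block)
        np.testing.assert_allclose(resid, 0.0, atol=1e-12)
        np.testing.assert_allclose(overall + col_eff, c, atol=1e-12)

    def test_additive_converges_in_two_sweeps(self):
        block = np.arange(12, dtype=float).reshape(3, 4)
        _, _, _, resid = _median_polish_block(block, max_sweeps=2)
        np.testing.assert_allclose(resid, 0.0, atol=1e-12)

    def test_single_probe_gene_identity(self):
        values = np.array([[5.0, 6.0, 7.0]])
        pm = _probe_matrix(values, {"p1": "g1"})
        out = median_polish_summarize(pm)
        np.testing.assert_allclose(out.values, values, atol=1e-12)
        assert out.gene_ids == ["g1"]

    def test_outlier_robust_vs_column_mean(self):
        # oracle: hand-run median polish (2 sweeps) on the clean block;
        # the polished summary of the contaminated block stays near it
        # while the column mean is dragged by the outlier
        clean = np.array([[4.0, 5.0, 6.0], [4.1, 5.1, 6.1], [3.9, 4.9, 5.9]])
        dirty = clean.copy()
        dirty[1, 1] = 50.0  # gross outlier
        _, _, col_clean, _ = _median_polish_block(clean, max_sweeps=2)
        o_clean, _, c_clean, _ = _median_polish_block(clean)
        o_dirty, _, c_dirty, _ = _median_polish_block(dirty)
        polished_clean = o_clean + c_clean
        polished_dirty = o_dirty + c_dirty
        assert np.max(np.abs(polished_dirty - polished_clean)) < 0.2
        mean_dirty = dirty.mean(axis=0)
        assert np.max(np.abs(mean_dirty - polished_clean)) > 10.0
        np.testing.assert_allclose(col_clean, c_clean, atol=1e-9)

    def test_multi_gene_summarization_shape(self, rng):
        values = rng.normal(size=(6, 4))
        mapping = {f"p{i}": ("gA" if i < 4 else "gB") for i in range(6)}
        pm = _probe_matrix(values, mapping)
        out = median_polish_summarize(pm)
        assert out.gene_ids == ["gA", "gB"]
        assert out.values.shape == (2, 4)

    def test_empty_block_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            _median_polish_block(np.empty((0, 3)))


class TestCollapseDuplicates:
    def test_no_duplicates_identity(self, matrix_factory):
        m = matrix_factory([[1.0, 2.0], [3.0, 4.0]], 1, 1)
        out = collapse_duplicate_genes(m)
        assert out is m

    def test_highest_mean_kept(self, matrix_factory):
        m = matrix_factory(
            [[5.0, 5.0], [7.0, 7.0]], 1, 1, gene_ids=["G", "G"]
        )
        out = collapse_duplicate_genes(m)
        assert out.gene_ids == ["G"]
        np.testing.assert_allclose(out.values, [[7.0, 7.0]])

    def test_tie_keeps_first_row(self, matrix_factory):
        m = matrix_factory(
            [[5.0, 7.0], [6.0, 6.0]], 1, 1, gene_ids=["G", "G"]
        )
        out = collapse_duplicate_genes(m)
        np.testing.assert_allclose(out.values, [[5.0, 7.0]])


class TestIO:
    def test_roundtrip(self, tmp_path, rng, matrix_factory):
        m = matrix_factory(rng.normal(size=(10, 6)), 3, 3, dataset_id="DSX")
        expr, meta = tmp_path / "e.tsv", tmp_path / "m.tsv"
        write_expression_tsv(m, expr, meta)
        back = read_expression_tsv(expr, meta, dataset_id="DSX")
        np.testing.assert_allclose(back.values, m.values, atol=1e-6)
        assert back.gene_ids == m.gene_ids
        assert back.groups == m.groups

    def test_bad_expression_header(self, tmp_path):
        expr = tmp_path / "e.tsv"
        expr.write_text("wrong\ts1\ng1\t1.0\n")
        meta = tmp_path / "m.tsv"
        meta.write_text("sample_id\tgroup\ns1\ttumor\n")
        with pytest.raises(FormatError, match="gene_id"):
            read_expression_tsv(expr, meta)

    def test_missing_group_label(self, tmp_path):
        expr = tmp_path / "e.tsv"
        expr.write_text("gene_id\ts1\ts2\ng1\t1.0\t2.0\n")
        meta = tmp_path / "m.tsv"
        meta.write_text("sample_id\tgroup\ns1\ttumor\n")
        with pytest.raises(FormatError, match="without a group"):
            read_expression_tsv(expr, meta)

    def test_geo_series_matrix(self, tmp_path):
        path = tmp_path / "series.txt"
        path.write_text(
            "!Series_title\t\"demo\"\n"
            "!series_matrix_table_begin\n"
            '"ID_REF"\t"GSM1"\t"GSM2"\n'
            '"g1"\t1.5\t2.5\n'
            '"g2"\t3.0\t4.0\n'
            "!series_matrix_table_end\n"
        )
        frame = read_geo_series_matrix(path)
        assert frame.shape == (2, 2)
        assert frame.loc["g1", "GSM2"] == 2.5

    def test_geo_series_matrix_missing_markers(self, tmp_path):
        path = tmp_path / "series.txt"
        path.write_text("no markers here\n")
        with pytest.raises(FormatError):
            read_geo_series_matrix(path)


def test_log2_transform(matrix_factory):
    m = matrix_factory([[0.0, 1.0], [3.0, 7.0]], 1, 1)
    out = log2_transform(m)
    np.testing.assert_allclose(out.values, [[0.0, 1.0], [2.0, 3.0]])
    with pytest.raises(ValidationError):
        log2_transform(matrix_factory([[-2.0, 1.0]], 1, 1))
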