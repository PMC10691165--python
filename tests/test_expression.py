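import numpy as np
import pandas as pd
import pytest

import combosc as csc
from combosc.expression import FormatError, ValidationError

from conftest import make_matrix


class TestReadWrite:
    def test_mtx_round_trip_is_bit_exact(self, tmp_path):
        counts = np.array([[0, 3], [5, 0], [2, 7]])
        m = make_matrix(counts)
        csc.write_expression(m, tmp_path / "m.mtx", tmp_path / "c.txt",
                             tmp_path / "g.txt")
        back = csc.read_expression(tmp_path / "m.mtx", tmp_path / "c.txt",
                                   tmp_path / "g.txt", format="mtx")
        assert back.counts.shape == (3, 2)
        assert (back.counts != m.counts).nnz == 0
        assert list(back.cell_ids) == list(m.cell_ids)
        assert list(back.gene_ids) == list(m.gene_ids)

    def test_dense_genes_in_rows_is_transposed(self, tmp_path):
        (tmp_path / "m.tsv").write_text("1\t2\t3\n4\t5\t6\n")
        (tmp_path / "c.txt").write_text("c0\nc1\nc2\n")
        (tmp_path / "g.txt").write_text("G0\nG1\n")
        m = csc.read_expression(tmp_path / "m.tsv", tmp_path / "c.txt",
                                tmp_path / "g.txt", format="dense",
                                genes_in_rows=True)
        assert m.counts.shape == (3, 2)
        assert m.counts.toarray()[0].tolist() == [1, 4]

    def test_duplicate_gene_symbol_rejected(self, tmp_path):
        (tmp_path / "m.tsv").write_text("1\t2\n3\t4\n")
        (tmp_path / "c.txt").write_text("c0\nc1\n")
        (tmp_path / "g.txt").write_text("G0\nG0\n")
        with pytest.raises(ValidationError, match="duplicate gene"):
            csc.read_expression(tmp_path / "m.tsv", tmp_path / "c.txt",
                                tmp_path / "g.txt", format="dense")

    def test_dimension_mismatch_names_the_axis(self, tmp_path):
        (tmp_path / "m.tsv").write_text("1\t2\n3\t4\n")
        (tmp_path / "c.txt").write_text("c0\nc1\nc2\n")
        (tmp_path / "g.txt").write_text("G0\nG1\n")
        with pytest.raises(FormatError, match="cell axis"):
            csc.read_expression(tmp_path / "m.tsv", tmp_path / "c.txt",
                                tmp_path / "g.txt", format="dense")


class TestQC:
    def _matrix_with_cell(self, n_detected, mito_frac, n_genes=400):
        """One cell with the requested detected-gene count and mito share."""
        counts = np.zeros((1, n_genes))
        genes = [f"MT-{j}" for j in range(5)] + \
                [f"G{j}" for j in range(n_genes - 5)]
        # non-mito detected genes
        counts[0, 5:5 + n_detected - 1] = 10
        non_mito_total = counts.sum()
        counts[0, 0] = mito_frac / (1 - mito_frac) * non_mito_total
        return make_matrix(counts, gene_ids=genes)

    def test_cell_below_gene_threshold_removed(self):
        m = self._matrix_with_cell(n_detected=150, mito_frac=0.01)
        out, report = csc.qc_filter(m)
        assert out.n_cells == 0
        assert "fewer than 200 genes" in report["reason"].iloc[0]

    def test_exact_boundaries_retained(self):
        # exactly 200 detected genes and mito fraction exactly 5% both stay
        m = self._matrix_with_cell(n_detected=200, mito_frac=0.05)
        detected = (m.counts > 0).sum()
        assert detected == 200
        out, report = csc.qc_filter(m)
        assert out.n_cells == 1 and report.empty

    def test_high_mito_removed(self):
        m = self._matrix_with_cell(n_detected=300, mito_frac=0.30)
        out, report = csc.qc_filter(m)
        assert out.n_cells == 0
        assert "mito" in report["reason"].iloc[0]

    def test_empty_matrix_passes_through(self):
        m = make_matrix(np.zeros((0, 3)))
        out, report = csc.qc_filter(m)
        assert out.n_cells == 0 and report.empty

    def test_idempotent(self, bundle):
        once, rep1 = csc.qc_filter(bundle.matrix)
        twice, rep2 = csc.qc_filter(once)
        assert rep2.empty
        assert twice.n_cells == once.n_cells


class TestNormalize:
    def test_known_tpm_values(self):
        # total 1e5, so each count unit = 10 TPM-equivalents
        m = make_matrix(np.array([[1, 0, 3, 99996]]))
        m = csc.normalize_log2_tpm(m)
        # TPM 10 -> log2(2) = 1; TPM 0 -> 0; TPM 30 -> log2(4) = 2
        assert m.norm[0, 0] == pytest.approx(1.0)
        assert m.norm[0, 1] == 0.0
        assert m.norm[0, 2] == pytest.approx(2.0)

    def test_zero_count_cell_warns_and_zeroes(self):
        m = make_matrix(np.array([[0, 0], [1, 1]]))
        with pytest.warns(UserWarning, match="zero total"):
            m = csc.normalize_log2_tpm(m)
        assert m.norm[0].tolist() == [0.0, 0.0]

    def test_identical_count_rows_get_identical_norm(self):
        rng = np.random.default_rng(0)
        row = rng.integers(0, 20, size=30)
        m = csc.normalize_log2_tpm(make_matrix(np.vstack([row, row])))
        np.testing.assert_array_equal(m.norm[0], m.norm[1])

    def test_counts_unchanged(self, bundle):
        m = csc.normalize_log2_tpm(bundle.matrix)
        assert (m.counts != bundle.matrix.counts).nnz == 0


class TestInclusion:
    @staticmethod
    def _meta(n_mal, n_t, sample="s"):
        rows = [{"cell_id": f"m{i}", "sample_id": sample,
                 "cell_type": "Malignant", "is_malignant": True}
                for i in range(n_mal)]
        rows += [{"cell_id": f"t{i}", "sample_id": sample,
                  "cell_type": "T cell", "is_malignant": False}
                 for i in range(n_t)]
        return pd.DataFrame(rows, columns=["cell_id", "sample_id",
                                           "cell_type", "is_malignant"])

    @pytest.mark.parametrize("n_mal,n_t,included", [
        (99, 200, False),   # fewer than 100 malignant cells
        (100, 60, True),    # strict '<' boundary: both exact counts retained
        (200, 59, False),   # fewer than 60 T cells
    ])
    def test_boundaries(self, n_mal, n_t, included):
        v, = csc.check_sample_inclusion(self._meta(n_mal, n_t))
        assert v.included is included
        assert (v.n_malignant, v.n_t_cells) == (n_mal, n_t)

    def test_empty_sample_has_both_reasons(self):
        meta = self._meta(0, 0)
        meta.loc[0] = ["x", "s", "B cell", False]
        v, = csc.check_sample_inclusion(meta)
        assert not v.included and len(v.reasons) == 2
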