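import numpy as np
import pandas as pd
import pytest

import maitsig as m
from maitsig.io import (
    read_annotations,
    read_bulk_cohort,
    read_contigs,
    read_expression,
    write_annotations,
    write_bulk_cohort,
    write_expression,
)

from conftest import make_annotations


class TestExpressionIO:
    @pytest.mark.parametrize("fmt", ["tsv", "mtx"])
    def test_round_trip_random_matrix(self, tmp_path, fmt):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 20, size=(50, 20)).astype(float)
        mat = m.GeneExpressionMatrix(
            gene_ids=[f"g{i}" for i in range(50)],
            cell_ids=[f"c{i}" for i in range(20)],
            counts=counts,
        )
        path = str(tmp_path / ("mat.mtx" if fmt == "mtx" else "mat.tsv"))
        write_expression(mat, path, format=fmt)
        back = read_expression(path, format=fmt)
        assert back.gene_ids == mat.gene_ids
        assert back.cell_ids == mat.cell_ids
        np.testing.assert_array_equal(back.counts, counts)

    def test_tsv_small_integer_table(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("gene\tc1\tc2\nA\t1\t2\nB\t3\t4\nC\t5\t6\n")
        mat = read_expression(str(path), format="tsv")
        assert mat.counts.shape == (3, 2)
        assert mat.counts[2, 1] == 6

    def test_mtx_zero_nonzeros(self, tmp_path):
        stem = str(tmp_path / "z")
        (tmp_path / "z.mtx").write_text(
            "%%MatrixMarket matrix coordinate real general\n3 2 0\n"
        )
        (tmp_path / "z.genes.txt").write_text("a\nb\nc\n")
        (tmp_path / "z.cells.txt").write_text("x\ny\n")
        mat = read_expression(stem + ".mtx", format="mtx")
        assert mat.counts.shape == (3, 2)
        assert (mat.counts == 0).all()

    def test_sidecar_mismatch_rejected(self, tmp_path):
        (tmp_path / "z.mtx").write_text(
            "%%MatrixMarket matrix coordinate real general\n3 2 0\n"
        )
        (tmp_path / "z.genes.txt").write_text("a\nb\n")
        (tmp_path / "z.cells.txt").write_text("x\ny\n")
        with pytest.raises(m.StructuralError, match="sidecars"):
            read_expression(str(tmp_path / "z.mtx"), format="mtx")

    def test_duplicate_gene_symbols_rejected(self):
        with pytest.raises(m.StructuralError, match="duplicate gene"):
            m.GeneExpressionMatrix(
                gene_ids=["A", "A"], cell_ids=["c"], counts=np.ones((2, 1))
            )

    def test_at_least_one_layer_required(self):
        with pytest.raises(m.StructuralError):
            m.GeneExpressionMatrix(gene_ids=["A"], cell_ids=["c"])


class TestQcFilterCells:
    def _mat(self, umi_per_cell, n_genes=700, mito_cells=None):
        """Counts with controlled per-cell totals; detected genes ~ n_genes."""
        n = len(umi_per_cell)
        genes = [f"g{i}" for i in range(n_genes)] + ["MT-A", "MT-B"]
        counts = np.zeros((n_genes + 2, n))
        for j, total in enumerate(umi_per_cell):
            mito = 0
            if mito_cells and j in mito_cells:
                mito = int(round(mito_cells[j] * total))
                counts[n_genes, j] = mito
            body = int(total) - mito
            counts[:n_genes, j] = body // n_genes
            counts[0, j] += body % n_genes
        return m.GeneExpressionMatrix(
            gene_ids=genes, cell_ids=[f"c{j}" for j in range(n)], counts=counts
        )

    def test_low_umi_cell_removed_at_boundary(self):
        mat = self._mat([1000, 1200, 2000])
        ann = make_annotations(mat.cell_ids)
        out, out_ann = m.qc_filter_cells(mat, ann, min_umi=1200, max_umi=25000,
                                         min_genes=600, max_genes=4000)
        assert out.cell_ids == ["c1", "c2"]  # 1000 removed; 1200 kept (>= bound)
        assert list(out_ann["cell_id"]) == ["c1", "c2"]

    def test_high_mito_cell_removed(self):
        mat = self._mat([2000, 2000], mito_cells={1: 0.15})
        ann = make_annotations(mat.cell_ids)
        out, _ = m.qc_filter_cells(mat, ann, max_mito_frac=0.10)
        assert out.cell_ids == ["c0"]

    def test_all_within_bounds_unchanged_and_idempotent(self):
        mat = self._mat([2000, 3000, 5000])
        ann = make_annotations(mat.cell_ids)
        once, ann1 = m.qc_filter_cells(mat, ann)
        assert once.cell_ids == mat.cell_ids
        twice, _ = m.qc_filter_cells(once, ann1)
        assert twice.cell_ids == once.cell_ids
        np.testing.assert_array_equal(twice.counts, once.counts)

    def test_inverted_thresholds_rejected(self):
        mat = self._mat([2000])
        with pytest.raises(m.ConfigError):
            m.qc_filter_cells(mat, make_annotations(mat.cell_ids),
                              min_umi=5000, max_umi=1000)


class TestGeneFilterAndNormalization:
    def test_low_mean_gene_removed(self):
        counts = np.zeros((2, 200))
        counts[0, 0] = 1  # mean 0.005 < 0.01
        counts[1, :] = 1
        mat = m.GeneExpressionMatrix(
            gene_ids=["low", "high"],
            cell_ids=[f"c{i}" for i in range(200)],
            counts=counts,
        )
        out = m.filter_low_genes(mat, min_mean_count=0.01)
        assert out.gene_ids == ["high"]
        assert m.filter_low_genes(mat, min_mean_count=0).gene_ids == mat.gene_ids

    def test_log_cpm_closed_form(self):
        counts = np.array([[1.0], [3.0]])  # libsize 4
        norm = m.normalize_log_cpm(counts)
        assert norm[0, 0] == pytest.approx(np.log2(1e6 / 4 + 1), abs=1e-12)
        assert np.log2(250001) == pytest.approx(17.9316, abs=5e-5)

    def test_log_cpm_zero_and_scale_invariance(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 10, size=(30, 5)).astype(float)
        counts[0, :] += 1  # ensure positive library sizes
        norm = m.normalize_log_cpm(counts)
        assert (norm[counts == 0] == 0).all()
        np.testing.assert_allclose(m.normalize_log_cpm(counts * 7), norm, atol=1e-12)

    def test_zero_library_size_names_cell(self):
        counts = np.zeros((3, 2))
        counts[:, 0] = 1
        with pytest.raises(m.StructuralError, match="cellB"):
            m.normalize_log_cpm(counts, cell_ids=["cellA", "cellB"])


class TestAnnotationsAndCohortIO:
    def test_annotation_round_trip_and_enum_validation(self, tmp_path):
        ann = make_annotations(["c1", "c2"], tissue="blood", subset="MAIT")
        path = str(tmp_path / "ann.tsv")
        write_annotations(ann, path)
        back = read_annotations(path)
        pd.testing.assert_frame_equal(back, ann)
        bad = ann.copy()
        bad.loc[0, "tissue"] = "spleen"
        with pytest.raises(m.ConfigError, match="tissue"):
            m.validate_annotations(bad)

    def test_duplicate_cell_id_rejected(self):
        ann = make_annotations(["c1", "c1"])
        with pytest.raises(m.StructuralError, match="duplicate"):
            m.validate_annotations(ann)

    def test_bulk_cohort_round_trip_and_validation(self, tmp_path):
        ds = m.generate_bulk_cohort(m.SyntheticBulkConfig(seed=3, n_samples=40))
        e, c = str(tmp_path / "expr.tsv"), str(tmp_path / "clin.tsv")
        write_bulk_cohort(ds.cohort, e, c)
        back = read_bulk_cohort(e, c)
        np.testing.assert_allclose(
            back.expr.to_numpy(), ds.cohort.expr.to_numpy(), atol=1e-9
        )
        clin = ds.cohort.clinical.copy()
        clin.loc[clin.index[0], "os_event"] = 2
        with pytest.raises(m.StructuralError, match="binary"):
            m.BulkCohort(expr=ds.cohort.expr, clinical=clin)

    def test_contig_reader_parses_productive_flags(self, tmp_path):
        path = tmp_path / "contigs.tsv"
        path.write_text(
            "cell_id\tlocus\tv_gene\tj_gene\tcdr3_nt\tcdr3_aa\tproductive\n"
            "c1\tTRA\tTRAV1-2\tTRAJ33\tTGTGC\tCA\tTrue\n"
            "c1\tTRB\tTRBV6\tTRBJ2-1\tTGTGG\tCG\t1\n"
        )
        df = read_contigs(str(path))
        assert df["productive"].tolist() == [True, True]
        recs = m.records_from_contigs(df)
        assert len(recs) == 1 and recs[0].eligible


class TestGeneSetCatalog:
    def test_defaults_match_curated_lists(self):
        cat = m.GeneSetCatalog()
        assert cat["mait_signature"].genes == list(m.MAIT_SIGNATURE_GENES)
        assert len(cat["mait_signature"]) == 11
        assert cat["activation_genes"].genes == list(m.ACTIVATION_GENES)
        assert cat["exhaustion_genes"].genes == list(m.EXHAUSTION_GENES)
        assert cat["pan_t_genes"].genes == ["CD3D", "CD3E", "CD3G"]
        assert cat["nk_genes"].genes == list(m.NK_GENES)

    def test_yaml_round_trip_with_user_set(self, tmp_path):
        cat = m.GeneSetCatalog(extra={"custom": ["A", "B"]})
        path = str(tmp_path / "sets.yaml")
        cat.to_yaml(path)
        back = m.GeneSetCatalog.from_yaml(path)
        assert back["custom"].genes == ["A", "B"]
        with pytest.raises(m.ConfigError):
            back["nonexistent"]
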