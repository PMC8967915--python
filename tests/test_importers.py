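"""Importer exactness, orientation safety and dialect closure."""

import gzip
from pathlib import Path

import numpy as np
import pytest
import scipy.sparse as sp

import scqc
from scqc.errors import DuplicateFeatureError, FormatError, LayoutError, ParameterError
from scqc.importers import MEX_DIALECTS, import_mex_dialect
from scqc.simulate import SimulationSpec, simulate_droplet_data, write_fixture


def _write_mex(tmp: Path, mtx_body: str, barcodes: list, features: list,
               gz: bool = False):
    paths = {}
    for name, content in (
        ("matrix.mtx", mtx_body),
        ("barcodes.tsv", "\n".join(barcodes) + "\n"),
        ("features.tsv", "\n".join(features) + "\n"),
    ):
        p = tmp / (name + (".gz" if gz else ""))
        if gz:
            with gzip.open(p, "wt") as fh:
                fh.write(content)
        else:
            p.write_text(content)
        paths[name] = p
    return paths["matrix.mtx"], paths["barcodes.tsv"], paths["features.tsv"]


MTX_3x2 = """%%MatrixMarket matrix coordinate integer general
3 2 2
1 1 4
3 2 1
"""


class TestImportMex:
    def test_reads_counts_exactly(self, tmp_path):
        m, b, f = _write_mex(tmp_path, MTX_3x2, ["B1", "B2"], ["G1", "G2", "G3"])
        mat, features, barcodes = scqc.import_mex(m, b, f)
        assert mat.sum() == 5
        assert mat[0, 0] == 4 and mat[2, 1] == 1
        assert barcodes == ["B1", "B2"]

    def test_gzipped_inputs_give_identical_result(self, tmp_path):
        plain = tmp_path / "plain"
        gzdir = tmp_path / "gz"
        plain.mkdir(), gzdir.mkdir()
        args_plain = _write_mex(plain, MTX_3x2, ["B1", "B2"], ["G1", "G2", "G3"])
        args_gz = _write_mex(gzdir, MTX_3x2, ["B1", "B2"], ["G1", "G2", "G3"], gz=True)
        m1, _, _ = scqc.import_mex(*args_plain)
        m2, _, _ = scqc.import_mex(*args_gz)
        assert (m1 != m2).nnz == 0

    def test_sidecar_length_mismatch_is_format_error(self, tmp_path):
        m, b, f = _write_mex(
            tmp_path, MTX_3x2, ["B1", "B2"], ["G1", "G2", "G3", "G4"]
        )
        with pytest.raises(FormatError):
            scqc.import_mex(m, b, f)

    def test_orientation_resolved_from_sidecars_not_size(self, tmp_path):
        # on-disk matrix is barcodes x genes (2 x 3); sidecars say 3 genes
        body = """%%MatrixMarket matrix coordinate integer general
2 3 2
1 1 4
2 3 1
"""
        m, b, f = _write_mex(tmp_path, body, ["B1", "B2"], ["G1", "G2", "G3"])
        mat, _, _ = scqc.import_mex(m, b, f)
        assert mat.shape == (3, 2)
        assert mat[0, 0] == 4 and mat[2, 1] == 1

    def test_non_integer_entries_rejected(self, tmp_path):
        body = """%%MatrixMarket matrix coordinate real general
3 2 1
1 1 2.5
"""
        m, b, f = _write_mex(tmp_path, body, ["B1", "B2"], ["G1", "G2", "G3"])
        with pytest.raises(FormatError):
            scqc.import_mex(m, b, f)

    def test_duplicate_gene_ids_abort(self, tmp_path):
        m, b, f = _write_mex(tmp_path, MTX_3x2, ["B1", "B2"], ["G1", "G1", "G3"])
        with pytest.raises(DuplicateFeatureError):
            scqc.import_mex(m, b, f)


class TestImportDelimited:
    def test_csv_counts(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("gene,B1,B2\nG1,0,1\nG2,2,3\n")
        mat, genes, barcodes = scqc.import_delimited(p)
        assert mat.sum() == 6
        assert genes == ["G1", "G2"] and barcodes == ["B1", "B2"]

    def test_transposed_table_gives_identical_matrix(self, tmp_path):
        p1 = tmp_path / "a.csv"
        p1.write_text("gene,B1,B2\nG1,0,1\nG2,2,3\n")
        p2 = tmp_path / "b.csv"
        p2.write_text("barcode,G1,G2\nB1,0,2\nB2,1,3\n")
        m1, g1, b1 = scqc.import_delimited(p1)
        m2, g2, b2 = scqc.import_delimited(p2, genes_in_rows=False)
        assert (m1 != m2).nnz == 0 and g1 == g2 and b1 == b2

    def test_fractional_value_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("gene,B1\nG1,1.5\n")
        with pytest.raises(FormatError):
            scqc.import_delimited(p)


class TestImportH5ad:
    def test_round_trip_through_export(self, tmp_path, tiny_exp):
        exp = scqc.attach_cell_metric(tiny_exp, "m", [1.0, 2.0, 3.0])
        exp.set_reduced_dim("pca", np.arange(6).reshape(3, 2).astype(float))
        path = tmp_path / "t.h5ad"
        scqc.export_anndata(exp, path)
        back = scqc.import_h5ad(path)
        assert (back.matrix != exp.matrix).nnz == 0
        assert back.cell_annotations["m"].tolist() == [1.0, 2.0, 3.0]
        np.testing.assert_allclose(back.reduced_dims["pca"], exp.reduced_dims["pca"])

    def test_missing_sample_column_defaults_to_file_stem(self, tmp_path):
        import anndata

        a = anndata.AnnData(X=sp.csr_matrix(np.eye(3)))
        a.obs_names = ["c1", "c2", "c3"]
        a.var_names = ["g1", "g2", "g3"]
        path = tmp_path / "pbmc_small.h5ad"
        a.write_h5ad(path)
        exp = scqc.import_h5ad(path)
        assert set(exp.cell_annotations["sample"]) == {"pbmc_small"}

    def test_sparse_and_dense_encodings_agree(self, tmp_path):
        import anndata

        X = np.diag([1, 2, 3]).astype(float)
        for name, enc in (("s.h5ad", sp.csr_matrix(X)), ("d.h5ad", X)):
            a = anndata.AnnData(X=enc)
            a.obs_names = ["c1", "c2", "c3"]
            a.var_names = ["g1", "g2", "g3"]
            a.write_h5ad(tmp_path / name)
        e1 = scqc.import_h5ad(tmp_path / "s.h5ad", sample="x")
        e2 = scqc.import_h5ad(tmp_path / "d.h5ad", sample="x")
        assert (e1.matrix != e2.matrix).nnz == 0


@pytest.fixture(scope="module")
def small_sim():
    spec = SimulationSpec(
        n_genes=60, n_cell_types=2, cells_per_type=20,
        n_empty_droplets=100, doublet_fraction=0.0, seed=3,
    )
    return simulate_droplet_data(spec)[0]


class TestDialectClosure:
    @pytest.mark.parametrize("dialect", sorted(MEX_DIALECTS))
    def test_every_dialect_round_trips(self, tmp_path, small_sim, dialect):
        d = MEX_DIALECTS[dialect]
        sample_dir = write_fixture(small_sim, dialect, tmp_path / dialect)
        data_type = "Droplet" if d.raw_subdir is not None else "Cell"
        droplet, cell = import_mex_dialect(sample_dir, dialect, data_type, "s1")
        got = droplet if droplet is not None else cell
        assert got.gene_ids == small_sim.gene_ids
        assert got.barcode_ids == small_sim.barcode_ids
        assert (got.matrix != small_sim.matrix).nnz == 0

    def test_csv_and_h5ad_fixtures_round_trip(self, tmp_path, small_sim):
        csv_dir = write_fixture(small_sim, "csv", tmp_path / "csv")
        mat, genes, barcodes = scqc.import_delimited(csv_dir / "counts.csv")
        assert (mat != small_sim.matrix).nnz == 0
        h5_dir = write_fixture(small_sim, "h5ad", tmp_path / "h5")
        back = scqc.import_h5ad(h5_dir / "sample.h5ad")
        assert (back.matrix != small_sim.matrix).nnz == 0

    def test_v2_uses_plain_genes_tsv_and_v3_gzipped_features(
        self, tmp_path, small_sim
    ):
        v2 = write_fixture(small_sim, "cellranger_v2", tmp_path / "v2")
        assert (v2 / "raw_gene_bc_matrices" / "GRCh38" / "genes.tsv").exists()
        v3 = write_fixture(small_sim, "cellranger_v3", tmp_path / "v3")
        assert (v3 / "raw_feature_bc_matrix" / "features.tsv.gz").exists()

    def test_unknown_dialect_rejected(self, tmp_path, small_sim):
        with pytest.raises(ParameterError):
            write_fixture(small_sim, "alevin", tmp_path / "x")


class TestImportCellranger:
    def test_data_type_cell_reads_only_filtered(self, tmp_path, small_sim):
        write_fixture(small_sim, "cellranger_v3", tmp_path / "s1")
        spec = scqc.ImportSpec(
            tool="cellranger_v3",
            sample_dirs_or_files=[str(tmp_path / "s1")],
            sample_names=["s1"],
            data_type="Cell",
        )
        droplet, cell = scqc.import_cellranger(spec)
        assert droplet is None and cell is not None
        assert cell.level == scqc.MatrixLevel.CELL

    def test_missing_layout_names_the_path(self, tmp_path):
        (tmp_path / "empty_sample").mkdir()
        with pytest.raises(LayoutError, match="raw_feature_bc_matrix"):
            import_mex_dialect(
                tmp_path / "empty_sample", "cellranger_v3", "Droplet", "s1"
            )

    def test_v3_feature_type_column_filters_to_gene_expression(self, tmp_path):
        base = tmp_path / "s" / "raw_feature_bc_matrix"
        base.mkdir(parents=True)
        body = """%%MatrixMarket matrix coordinate integer general
3 2 3
1 1 4
2 1 7
3 2 1
"""
        with gzip.open(base / "matrix.mtx.gz", "wt") as fh:
            fh.write(body)
        with gzip.open(base / "barcodes.tsv.gz", "wt") as fh:
            fh.write("B1\nB2\n")
        with gzip.open(base / "features.tsv.gz", "wt") as fh:
            fh.write(
                "G1\tG1\tGene Expression\n"
                "AB1\tAB1\tAntibody Capture\n"
                "G3\tG3\tGene Expression\n"
            )
        droplet, _ = import_mex_dialect(tmp_path / "s", "cellranger_v3", "Droplet", "s1")
        assert droplet.gene_ids == ["G1", "G3"]
        assert droplet.matrix.sum() == 5

    def test_both_invalid_for_single_matrix_tools(self):
        with pytest.raises(ParameterError):
            scqc.ImportSpec(
                tool="bustools",
                sample_dirs_or_files=["x"],
                sample_names=["s"],
                data_type="Both",
            )
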