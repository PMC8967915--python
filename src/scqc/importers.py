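"""Importers for droplet/cell count matrices from preprocessing-tool outputs.

Supported layouts are CellRanger v2/v3 directory trees, the MEX-triple
outputs of STARsolo, BUStools and DropEst, generic MEX directories,
delimited text matrices and h5ad containers. The tool-specific layouts are
all MEX dialects that differ only in file naming, sub-directory structure
and feature-column count, so they are described by a data-driven manifest
rather than per-tool code paths.

All importers preserve counts exactly (no normalisation at import) and
decide matrix orientation from the sidecar file lengths, never from which
dimension happens to be larger. Duplicate gene identifiers abort the import:
silently uniquifying them would corrupt downstream gene-set lookups.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .container import MatrixLevel, QCExperiment, combine_samples
from .errors import (
    DuplicateFeatureError,
    FormatError,
    LayoutError,
    ParameterError,
)
from .provenance import ProvenanceLog

# ----------------------------------------------------------------------
# Dialect manifest: how each tool lays its MEX triple on disk.
#
# raw/filtered: sub-directory (template) holding the Droplet / Cell matrix,
# or None when the tool emits only one matrix. matrix/barcodes/features:
# file names inside that directory. gzipped: sidecars and matrix are
# gzip-compressed. feature_columns: number of tab-separated columns in the
# feature file (id [, symbol [, type]]).


@dataclass(frozen=True)
class MexDialect:
    name: str
    raw_subdir: str | None
    filtered_subdir: str | None
    matrix_file: str
    barcodes_file: str
    features_file: str
    gzipped: bool
    feature_columns: int


MEX_DIALECTS: dict[str, MexDialect] = {
    "cellranger_v2": MexDialect(
        "cellranger_v2",
        raw_subdir="raw_gene_bc_matrices/{genome}",
        filtered_subdir="filtered_gene_bc_matrices/{genome}",
        matrix_file="matrix.mtx",
        barcodes_file="barcodes.tsv",
        features_file="genes.tsv",
        gzipped=False,
        feature_columns=2,
    ),
    "cellranger_v3": MexDialect(
        "cellranger_v3",
        raw_subdir="raw_feature_bc_matrix",
        filtered_subdir="filtered_feature_bc_matrix",
        matrix_file="matrix.mtx.gz",
        barcodes_file="barcodes.tsv.gz",
        features_file="features.tsv.gz",
        gzipped=True,
        feature_columns=3,
    ),
    "starsolo": MexDialect(
        "starsolo",
        raw_subdir="Gene/raw",
        filtered_subdir="Gene/filtered",
        matrix_file="matrix.mtx",
        barcodes_file="barcodes.tsv",
        features_file="features.tsv",
        gzipped=False,
        feature_columns=2,
    ),
    "bustools": MexDialect(
        "bustools",
        raw_subdir="counts_unfiltered",
        filtered_subdir=None,
        matrix_file="output.mtx",
        barcodes_file="output.barcodes.txt",
        features_file="output.genes.txt",
        gzipped=False,
        feature_columns=1,
    ),
    "dropest": MexDialect(
        "dropest",
        raw_subdir=".",
        filtered_subdir=None,
        matrix_file="matrix.mtx",
        barcodes_file="barcodes.tsv",
        features_file="genes.tsv",
        gzipped=False,
        feature_columns=1,
    ),
    "mex": MexDialect(
        "mex",
        raw_subdir=None,
        filtered_subdir=".",
        matrix_file="matrix.mtx",
        barcodes_file="barcodes.tsv",
        features_file="features.tsv",
        gzipped=False,
        feature_columns=2,
    ),
}

#: Tools that emit both a Droplet (raw) and Cell (filtered) matrix.
TOOLS_WITH_BOTH = {"cellranger_v2", "cellranger_v3", "starsolo"}


@dataclass
class ImportSpec:
    """What to import: a tool/format, per-sample paths and matrix level."""

    tool: str
    sample_dirs_or_files: list[str]
    sample_names: list[str]
    data_type: str = "Cell"  # Droplet | Cell | Both

    def __post_init__(self) -> None:
        known = set(MEX_DIALECTS) | {"csv", "h5ad"}
        if self.tool not in known:
            raise ParameterError(f"unknown tool '{self.tool}'; one of {sorted(known)}")
        if len(self.sample_dirs_or_files) != len(self.sample_names):
            raise ParameterError("one sample name is required per input path")
        if self.data_type not in {"Droplet", "Cell", "Both"}:
            raise ParameterError("data_type must be Droplet, Cell or Both")
        if self.data_type == "Both" and self.tool not in TOOLS_WITH_BOTH:
            raise ParameterError(
                f"tool '{self.tool}' does not emit both Droplet and Cell matrices"
            )


# ----------------------------------------------------------------------
# Low-level readers


def _open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def _read_lines(path: str | Path) -> list[list[str]]:
    with _open_text(path) as fh:
        return [line.rstrip("\n").split("\t") for line in fh if line.strip()]


def import_mex(
    matrix_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
) -> tuple[sp.csc_matrix, pd.DataFrame, list[str]]:
    """Read a MatrixMarket triple into (genes x barcodes counts, features, barcodes).

    Orientation is resolved by matching the matrix dimensions against the
    sidecar lengths. Returns the sparse count matrix, a feature table whose
    index is the gene id (with optional ``symbol`` / ``feature_type``
    columns) and the barcode list.
    """
    for p in (matrix_path, barcodes_path, features_path):
        if not Path(p).exists():
            raise LayoutError(f"missing input file: {p}")
    with _open_text(matrix_path) as fh:
        try:
            mat = scipy.io.mmread(fh)
        except Exception as exc:  # malformed MatrixMarket header/body
            raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}")
    mat = sp.coo_matrix(mat)
    if mat.data.size and (
        np.any(mat.data < 0) or not np.array_equal(mat.data, np.floor(mat.data))
    ):
        raise FormatError(
            f"{matrix_path}: matrix entries must be non-negative integer counts"
        )

    barcodes = [row[0] for row in _read_lines(barcodes_path)]
    feat_rows = _read_lines(features_path)
    n_feat, n_bc = len(feat_rows), len(barcodes)

    if mat.shape == (n_feat, n_bc):
        pass
    elif mat.shape == (n_bc, n_feat) and mat.shape[0] != mat.shape[1]:
        mat = mat.T
    else:
        raise FormatError(
            f"matrix shape {mat.shape} matches neither features x barcodes "
            f"({n_feat} x {n_bc}) nor its transpose"
        )

    gene_ids = [row[0] for row in feat_rows]
    if len(set(gene_ids)) != len(gene_ids):
        dupes = pd.Series(gene_ids).value_counts()
        dupes = list(dupes.index[dupes > 1])[:5]
        raise DuplicateFeatureError(
            f"duplicate gene identifiers in {features_path} (e.g. {dupes}); "
            "fix the feature file rather than relying on silent uniquification"
        )
    features = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    if feat_rows and len(feat_rows[0]) >= 2:
        features["symbol"] = [row[1] if len(row) > 1 else row[0] for row in feat_rows]
    if feat_rows and len(feat_rows[0]) >= 3:
        features["feature_type"] = [
            row[2] if len(row) > 2 else "Gene Expression" for row in feat_rows
        ]
    return sp.csc_matrix(mat), features, barcodes


def _mex_to_experiment(
    mat: sp.csc_matrix,
    features: pd.DataFrame,
    barcodes: list[str],
    sample: str,
    level: MatrixLevel,
) -> QCExperiment:
    # CellRanger v3 feature files interleave assay modalities; only gene
    # expression rows are count data for this pipeline.
    if "feature_type" in features.columns:
        keep = features["feature_type"] == "Gene Expression"
        mat = mat[np.flatnonzero(keep.to_numpy()), :]
        features = features.loc[keep]
    if len(set(barcodes)) != len(barcodes):
        raise FormatError("duplicate barcode identifiers in barcode file")
    return QCExperiment(
        matrix=mat,
        gene_ids=list(features.index),
        barcode_ids=barcodes,
        level=level,
        sample=sample,
        gene_annotations=features,
    )


def _resolve_subdir(base: Path, template: str) -> Path:
    """Expand the ``{genome}`` placeholder in CellRanger v2 layouts."""
    if "{genome}" not in template:
        return base / template
    parent = base / template.split("/{genome}")[0]
    if not parent.is_dir():
        raise LayoutError(f"missing expected directory: {parent}")
    genomes = sorted(d for d in parent.iterdir() if d.is_dir())
    if not genomes:
        raise LayoutError(f"no genome sub-directory under {parent}")
    return genomes[0]


def import_mex_dialect(
    sample_dir: str | Path,
    dialect: MexDialect | str,
    data_type: str,
    sample: str,
) -> tuple[QCExperiment | None, QCExperiment | None]:
    """Read one sample directory in a given MEX dialect.

    Returns ``(droplet, cell)``; either may be ``None`` depending on
    *data_type* and on which matrices the dialect provides.
    """
    if isinstance(dialect, str):
        dialect = MEX_DIALECTS[dialect]
    base = Path(sample_dir)

    def read_one(template: str | None, level: MatrixLevel) -> QCExperiment:
        if template is None:
            raise LayoutError(
                f"dialect '{dialect.name}' does not provide a "
                f"{level.value}-level matrix"
            )
        sub = _resolve_subdir(base, template)
        if not sub.is_dir():
            raise LayoutError(f"missing expected directory: {sub}")
        mat, features, barcodes = import_mex(
            sub / dialect.matrix_file,
            sub / dialect.barcodes_file,
            sub / dialect.features_file,
        )
        return _mex_to_experiment(mat, features, barcodes, sample, level)

    droplet = cell = None
    if data_type in ("Droplet", "Both"):
        droplet = read_one(dialect.raw_subdir, MatrixLevel.DROPLET)
    if data_type in ("Cell", "Both"):
        # single-matrix dialects park their one matrix in whichever slot
        # exists; Cell requests on droplet-only tools read that matrix.
        template = dialect.filtered_subdir
        if template is None and data_type == "Cell":
            template = dialect.raw_subdir
        cell = read_one(template, MatrixLevel.CELL)
    return droplet, cell


def import_cellranger(
    spec: ImportSpec,
) -> tuple[QCExperiment | None, QCExperiment | None]:
    """Import one or more CellRanger (or MEX-dialect) sample directories.

    Samples are combined column-wise; the ``sample`` annotation records the
    origin of every barcode.
    """
    droplets, cells = [], []
    for path, name in zip(spec.sample_dirs_or_files, spec.sample_names):
        d, c = import_mex_dialect(path, spec.tool, spec.data_type, name)
        if d is not None:
            droplets.append(d)
        if c is not None:
            cells.append(c)
    droplet = combine_samples(droplets) if droplets else None
    cell = combine_samples(cells) if cells else None
    return droplet, cell


# ----------------------------------------------------------------------
# Delimited text and h5ad


def import_delimited(
    path: str | Path,
    delimiter: str = ",",
    genes_in_rows: bool = True,
) -> tuple[sp.csc_matrix, list[str], list[str]]:
    """Read a dense delimited count table into genes x barcodes sparse form.

    The table must be rectangular with a header of barcodes and a first
    column of gene identifiers (or the transpose, per *genes_in_rows*).
    """
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0)
    except Exception as exc:
        raise FormatError(f"cannot parse delimited file {path}: {exc}")
    if df.isna().any().any():
        raise FormatError(f"{path}: ragged or missing entries in count table")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"{path}: non-numeric entries in count table")
    if np.any(values < 0):
        raise FormatError(f"{path}: negative entries are not valid counts")
    if not np.array_equal(values, np.floor(values)):
        raise FormatError(f"{path}: non-integer entries are not valid counts")
    if not genes_in_rows:
        df = df.T
    gene_ids = [str(g) for g in df.index]
    if len(set(gene_ids)) != len(gene_ids):
        raise DuplicateFeatureError(f"duplicate gene identifiers in {path}")
    return (
        sp.csc_matrix(df.to_numpy()),
        gene_ids,
        [str(b) for b in df.columns],
    )


def import_h5ad(path: str | Path, sample: str | None = None) -> QCExperiment:
    """Read an h5ad container into a Cell-level experiment.

    The stored X (cells x genes) is transposed to the package's genes x
    barcodes orientation; ``obs``/``var`` become the cell/gene annotation
    tables, ``obsm`` entries become reduced dimensions and ``layers`` become
    extra assays. A missing ``sample`` column is filled with the file stem.
    """
    import anndata

    try:
        adata = anndata.read_h5ad(path)
    except Exception as exc:
        raise FormatError(f"cannot read h5ad file {path}: {exc}")
    if adata.obs.index.empty and adata.n_obs:
        raise FormatError(f"{path}: missing obs index")
    X = adata.X
    mat = sp.csc_matrix(X.T if not np.isscalar(X) else X)
    obs = adata.obs.copy()
    if "sample" not in obs.columns:
        obs["sample"] = sample if sample is not None else Path(path).stem
    provenance = None
    if "provenance" in adata.uns:
        raw = adata.uns["provenance"]
        if isinstance(raw, str):
            import yaml

            provenance = ProvenanceLog.from_list(yaml.safe_load(raw) or [])
    exp = QCExperiment(
        matrix=mat,
        gene_ids=[str(g) for g in adata.var.index],
        barcode_ids=[str(b) for b in adata.obs.index],
        level=MatrixLevel.CELL,
        cell_annotations=obs,
        gene_annotations=adata.var.copy(),
        reduced_dims={k: np.asarray(v) for k, v in adata.obsm.items()},
        extra_assays={k: sp.csc_matrix(sp.csr_matrix(v).T) for k, v in adata.layers.items()},
        provenance=provenance,
    )
    return exp


def import_samples(
    spec: ImportSpec,
) -> tuple[QCExperiment | None, QCExperiment | None]:
    """Dispatch an :class:`ImportSpec` to the right importer.

    Returns ``(droplet_experiment, cell_experiment)``, either possibly
    ``None`` depending on ``data_type`` and the tool's outputs.
    """
    if spec.tool in MEX_DIALECTS:
        return import_cellranger(spec)
    exps = []
    for path, name in zip(spec.sample_dirs_or_files, spec.sample_names):
        if spec.tool == "csv":
            mat, genes, barcodes = import_delimited(path)
            exps.append(
                QCExperiment(
                    matrix=mat,
                    gene_ids=genes,
                    barcode_ids=barcodes,
                    level=MatrixLevel(spec.data_type)
                    if spec.data_type != "Both"
                    else MatrixLevel.CELL,
                    sample=name,
                )
            )
        elif spec.tool == "h5ad":
            exps.append(import_h5ad(path, sample=name))
        else:  # pragma: no cover - guarded by ImportSpec validation
            raise ParameterError(f"unhandled tool '{spec.tool}'")
    combined = combine_samples(exps)
    if spec.data_type == "Droplet":
        combined.level = MatrixLevel.DROPLET
        return combined, None
    return None, combined
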