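"""Export annotated experiments to flat files and h5ad containers.

The flat-file export writes every assay as a MatrixMarket MEX triple with
barcode/feature sidecars, the annotation tables and each reduced dimension
as TSV, and the provenance log as YAML; a JSON manifest with SHA-256
checksums describes every file written. The h5ad export maps the primary
assay to ``X`` (transposed to cells x genes), extra assays to ``layers``,
gene/cell annotations to ``var``/``obs``, embeddings to ``obsm`` and the
provenance log to ``uns``.

For users of R single-cell frameworks the flat-file layout doubles as the
interchange format: ``counts`` maps to the object's assay slot,
``colData.tsv`` to per-cell metadata and each ``reducedDims_*`` file to a
dimensionality-reduction slot; the manifest records this mapping.
"""

from __future__ import annotations

import gzip
import hashlib
import io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .container import QCExperiment
from .errors import ParameterError


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_text(path: Path, text: str, use_gzip: bool) -> Path:
    if use_gzip:
        path = path.with_suffix(path.suffix + ".gz")
        # fixed mtime so identical content gives identical bytes
        with gzip.GzipFile(path, "wb", mtime=0) as fh:
            fh.write(text.encode())
    else:
        path.write_text(text)
    return path


def _write_mtx(path: Path, matrix: sp.spmatrix, use_gzip: bool) -> Path:
    buf = io.BytesIO()
    mat = sp.coo_matrix(matrix)
    if mat.data.size and np.array_equal(mat.data, np.floor(mat.data)):
        mat = mat.astype(np.int64)
    scipy.io.mmwrite(buf, mat)
    if use_gzip:
        path = path.with_suffix(path.suffix + ".gz")
        with gzip.GzipFile(path, "wb", mtime=0) as fh:
            fh.write(buf.getvalue())
    else:
        path.write_bytes(buf.getvalue())
    return path


def export_flatfiles(
    exp: QCExperiment,
    out_dir: str | Path,
    use_gzip: bool = True,
) -> dict:
    """Write all slots of an experiment as flat files; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    assays = {"counts": exp.matrix, **exp.extra_assays}
    for name, mat in assays.items():
        written.append(_write_mtx(out / f"{name}.mtx", mat, use_gzip))
    written.append(
        _write_text(out / "barcodes.tsv", "\n".join(exp.barcode_ids) + "\n", use_gzip)
    )
    feat_lines = []
    symbols = (
        exp.gene_annotations["symbol"]
        if "symbol" in exp.gene_annotations.columns
        else pd.Series(exp.gene_ids, index=exp.gene_annotations.index)
    )
    for gid, sym in zip(exp.gene_ids, symbols):
        feat_lines.append(f"{gid}\t{sym}")
    written.append(
        _write_text(out / "features.tsv", "\n".join(feat_lines) + "\n", use_gzip)
    )
    written.append(
        _write_text(
            out / "colData.tsv",
            exp.cell_annotations.to_csv(sep="\t", index_label="barcode"),
            use_gzip,
        )
    )
    written.append(
        _write_text(
            out / "rowData.tsv",
            exp.gene_annotations.to_csv(sep="\t", index_label="gene_id"),
            use_gzip,
        )
    )
    for name, emb in exp.reduced_dims.items():
        df = pd.DataFrame(
            emb,
            index=pd.Index(exp.barcode_ids, name="barcode"),
            columns=[f"dim{i + 1}" for i in range(emb.shape[1])],
        )
        written.append(
            _write_text(
                out / f"reducedDims_{name}.tsv", df.to_csv(sep="\t"), use_gzip
            )
        )
    written.append(
        _write_text(
            out / "metadata.yaml",
            yaml.safe_dump(
                {"level": exp.level.value, "provenance": exp.provenance.to_list()},
                sort_keys=False,
            ),
            use_gzip,
        )
    )

    manifest = {
        "level": exp.level.value,
        "n_genes": exp.n_genes,
        "n_barcodes": exp.n_barcodes,
        "slot_mapping": {
            "counts": "assay",
            "colData.tsv": "per-cell metadata (meta.data)",
            "rowData.tsv": "per-gene metadata",
            "reducedDims_*": "dimensionality reductions (reductions)",
            "metadata.yaml": "run provenance",
        },
        "files": [
            {"name": p.name, "sha256": _sha256(p), "bytes": p.stat().st_size}
            for p in written
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def import_flatfiles(in_dir: str | Path) -> QCExperiment:
    """Inverse of :func:`export_flatfiles` (gzipped or plain)."""
    from .container import MatrixLevel
    from .importers import import_mex
    from .provenance import ProvenanceLog

    d = Path(in_dir)

    def find(stem: str) -> Path:
        for cand in (d / stem, d / f"{stem}.gz"):
            if cand.exists():
                return cand
        raise FileNotFoundError(f"missing {stem}[.gz] in {d}")

    mat, features, barcodes = import_mex(
        find("counts.mtx"), find("barcodes.tsv"), find("features.tsv")
    )
    cell_annot = pd.read_csv(find("colData.tsv"), sep="\t", index_col=0)
    gene_annot = pd.read_csv(find("rowData.tsv"), sep="\t", index_col=0)
    meta_path = find("metadata.yaml")
    opener = gzip.open if meta_path.suffix == ".gz" else open
    with opener(meta_path, "rt") as fh:
        meta = yaml.safe_load(fh)
    reduced = {}
    for path in sorted(d.glob("reducedDims_*.tsv*")):
        name = path.name.split("reducedDims_")[1].split(".tsv")[0]
        reduced[name] = pd.read_csv(path, sep="\t", index_col=0).to_numpy()
    extra = {}
    for path in sorted(d.glob("*.mtx*")):
        name = path.name.split(".mtx")[0]
        if name == "counts":
            continue
        with (gzip.open(path, "rb") if path.suffix == ".gz" else open(path, "rb")) as fh:
            extra[name] = sp.csc_matrix(scipy.io.mmread(fh))
    return QCExperiment(
        matrix=mat,
        gene_ids=list(features.index),
        barcode_ids=barcodes,
        level=MatrixLevel(meta.get("level", "Cell")),
        cell_annotations=cell_annot,
        gene_annotations=gene_annot,
        reduced_dims=reduced,
        extra_assays=extra,
        provenance=ProvenanceLog.from_list(meta.get("provenance", [])),
    )


def export_anndata(
    exp: QCExperiment,
    out_path: str | Path,
    compression: str = "gzip",
) -> Path:
    """Write the experiment to an h5ad container (cells x genes)."""
    import anndata

    if compression not in ("gzip", "lzf", "none"):
        raise ParameterError("compression must be 'gzip', 'lzf' or 'none'")
    adata = anndata.AnnData(
        X=sp.csr_matrix(exp.matrix.T),
        obs=exp.cell_annotations.copy(),
        var=exp.gene_annotations.copy(),
    )
    adata.obs_names = exp.barcode_ids
    adata.var_names = exp.gene_ids
    for name, emb in exp.reduced_dims.items():
        adata.obsm[name] = np.asarray(emb)
    for name, mat in exp.extra_assays.items():
        adata.layers[name] = sp.csr_matrix(mat.T)
    adata.uns["provenance"] = yaml.safe_dump(
        exp.provenance.to_list(), sort_keys=False
    )
    adata.uns["level"] = exp.level.value
    out_path = Path(out_path)
    adata.write_h5ad(
        out_path, compression=None if compression == "none" else compression
    )
    return out_path
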