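"""Central data container for droplet-level single-cell QC.

The container holds one sparse gene x barcode count matrix together with
per-cell and per-gene annotation tables, named low-dimensional embeddings,
alternative assays of identical shape (e.g. decontaminated counts), and a
provenance log of every QC operation applied.

Matrix levels follow the Droplet / Cell / FilteredCell nomenclature:

* ``Droplet`` -- all barcodes, including empty droplets ("raw" in
  CellRanger terms);
* ``Cell`` -- barcodes called as real cells ("filtered");
* ``FilteredCell`` -- cells surviving additional quality filtering.

A level may only move forward, and only by column subsetting, so counts for
retained barcodes are never altered. Genes are rows and barcodes are
columns throughout the package; exporters transpose where a target format
requires the opposite orientation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import (
    DimensionError,
    IncompatibleFeaturesError,
    LevelTransitionError,
    NameCollisionError,
)
from .provenance import ProvenanceLog


class MatrixLevel(str, enum.Enum):
    DROPLET = "Droplet"
    CELL = "Cell"
    FILTERED_CELL = "FilteredCell"


#: Legal forward transitions (same-level subsetting is always allowed).
_LEVEL_TRANSITIONS = {
    (MatrixLevel.DROPLET, MatrixLevel.CELL),
    (MatrixLevel.CELL, MatrixLevel.FILTERED_CELL),
}


def _as_level(level: "MatrixLevel | str") -> MatrixLevel:
    return MatrixLevel(level)


@dataclass
class CountMatrix:
    """Sparse non-negative integer count matrix, genes x barcodes."""

    values: sp.csc_matrix
    gene_ids: list[str]
    barcode_ids: list[str]

    def __post_init__(self) -> None:
        self.values = sp.csc_matrix(self.values)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.barcode_ids = [str(b) for b in self.barcode_ids]
        n_genes, n_barcodes = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise DimensionError(
                f"{len(self.gene_ids)} gene ids for a matrix with {n_genes} rows"
            )
        if len(self.barcode_ids) != n_barcodes:
            raise DimensionError(
                f"{len(self.barcode_ids)} barcode ids for a matrix with "
                f"{n_barcodes} columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise DimensionError("gene identifiers are not unique")
        if len(set(self.barcode_ids)) != n_barcodes:
            raise DimensionError("barcode identifiers are not unique")
        data = self.values.data
        if data.size:
            if data.min() < 0:
                raise DimensionError("count matrix contains negative entries")
            if not np.array_equal(data, np.floor(data)):
                raise DimensionError("count matrix contains non-integer entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


class QCExperiment:
    """One count matrix plus its annotations, embeddings and provenance.

    Parameters
    ----------
    matrix
        Sparse genes x barcodes count matrix.
    gene_ids, barcode_ids
        Unique identifiers for rows and columns.
    level
        Filtering level of the matrix (``Droplet``, ``Cell`` or
        ``FilteredCell``).
    sample
        Sample label(s); scalar or per-barcode sequence. Stored in the
        mandatory ``sample`` cell-annotation column.
    """

    def __init__(
        self,
        matrix: sp.spmatrix | np.ndarray,
        gene_ids: Sequence[str],
        barcode_ids: Sequence[str],
        level: MatrixLevel | str = MatrixLevel.DROPLET,
        sample: str | Sequence[str] = "sample",
        cell_annotations: pd.DataFrame | None = None,
        gene_annotations: pd.DataFrame | None = None,
        reduced_dims: dict[str, np.ndarray] | None = None,
        extra_assays: dict[str, sp.spmatrix] | None = None,
        provenance: ProvenanceLog | None = None,
    ) -> None:
        cm = CountMatrix(sp.csc_matrix(matrix), list(gene_ids), list(barcode_ids))
        self.matrix = cm.values
        self.gene_ids = cm.gene_ids
        self.barcode_ids = cm.barcode_ids
        self.level = _as_level(level)

        if cell_annotations is None:
            cell_annotations = pd.DataFrame(index=pd.Index(self.barcode_ids))
        else:
            cell_annotations = cell_annotations.copy()
            if list(cell_annotations.index) != self.barcode_ids:
                if len(cell_annotations) != len(self.barcode_ids):
                    raise DimensionError(
                        "cell_annotations rows do not match barcodes"
                    )
                cell_annotations.index = pd.Index(self.barcode_ids)
        if "sample" not in cell_annotations.columns:
            if isinstance(sample, str):
                cell_annotations["sample"] = sample
            else:
                if len(sample) != len(self.barcode_ids):
                    raise DimensionError("sample labels do not match barcodes")
                cell_annotations["sample"] = list(sample)
        if cell_annotations["sample"].isna().any() or (
            cell_annotations["sample"].astype(str) == ""
        ).any():
            raise DimensionError("'sample' must be non-empty for every barcode")
        self.cell_annotations = cell_annotations

        if gene_annotations is None:
            gene_annotations = pd.DataFrame(index=pd.Index(self.gene_ids))
        else:
            gene_annotations = gene_annotations.copy()
            if len(gene_annotations) != len(self.gene_ids):
                raise DimensionError("gene_annotations rows do not match genes")
            gene_annotations.index = pd.Index(self.gene_ids)
        self.gene_annotations = gene_annotations

        self.reduced_dims: dict[str, np.ndarray] = {}
        for name, emb in (reduced_dims or {}).items():
            self.set_reduced_dim(name, emb)

        self.extra_assays: dict[str, sp.spmatrix] = {}
        for name, assay in (extra_assays or {}).items():
            self.set_assay(name, assay)

        self.provenance = provenance if provenance is not None else ProvenanceLog()

    # ------------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_barcodes(self) -> int:
        return self.matrix.shape[1]

    @property
    def samples(self) -> list[str]:
        """Unique sample labels in first-appearance order."""
        return list(dict.fromkeys(self.cell_annotations["sample"].astype(str)))

    def totals(self) -> np.ndarray:
        """Total counts per barcode."""
        return np.asarray(self.matrix.sum(axis=0)).ravel()

    def set_reduced_dim(self, name: str, embedding: np.ndarray) -> None:
        emb = np.asarray(embedding, dtype=float)
        if emb.ndim != 2 or emb.shape[0] != self.n_barcodes:
            raise DimensionError(
                f"embedding '{name}' must have one row per barcode"
            )
        self.reduced_dims[name] = emb

    def set_assay(self, name: str, assay: sp.spmatrix | np.ndarray) -> None:
        mat = sp.csc_matrix(assay)
        if mat.shape != self.matrix.shape:
            raise DimensionError(
                f"assay '{name}' shape {mat.shape} != matrix shape "
                f"{self.matrix.shape}"
            )
        self.extra_assays[name] = mat

    def copy(self) -> "QCExperiment":
        return QCExperiment(
            matrix=self.matrix.copy(),
            gene_ids=list(self.gene_ids),
            barcode_ids=list(self.barcode_ids),
            level=self.level,
            cell_annotations=self.cell_annotations.copy(),
            gene_annotations=self.gene_annotations.copy(),
            reduced_dims={k: v.copy() for k, v in self.reduced_dims.items()},
            extra_assays={k: v.copy() for k, v in self.extra_assays.items()},
            provenance=self.provenance.copy(),
        )

    def __repr__(self) -> str:
        return (
            f"QCExperiment({self.level.value}: {self.n_genes} genes x "
            f"{self.n_barcodes} barcodes, samples={self.samples}, "
            f"{len(self.cell_annotations.columns)} cell annotations)"
        )


# ----------------------------------------------------------------------
# Operations


def attach_cell_metric(
    exp: QCExperiment,
    name: str,
    values: Sequence[Any],
    overwrite: bool = False,
) -> QCExperiment:
    """Return a copy of *exp* with a per-barcode metric column appended."""
    values = np.asarray(values)
    if len(values) != exp.n_barcodes:
        raise DimensionError(
            f"metric '{name}' has {len(values)} values for {exp.n_barcodes} "
            "barcodes"
        )
    if name in exp.cell_annotations.columns and not overwrite:
        raise NameCollisionError(
            f"cell annotation '{name}' already exists (pass overwrite=True)"
        )
    out = exp.copy()
    out.cell_annotations[name] = values
    return out


def subset_cells(
    exp: QCExperiment,
    keep: Sequence[bool],
    new_level: MatrixLevel | str | None = None,
    operation: str = "subset_cells",
) -> QCExperiment:
    """Subset barcodes (columns), optionally advancing the matrix level.

    Column order is preserved; annotations, embeddings and extra assays are
    subset in lock-step; a provenance entry is appended.
    """
    keep = np.asarray(keep, dtype=bool)
    if keep.shape != (exp.n_barcodes,):
        raise DimensionError("keep mask length does not match barcodes")
    new_level = exp.level if new_level is None else _as_level(new_level)
    if new_level != exp.level and (exp.level, new_level) not in _LEVEL_TRANSITIONS:
        raise LevelTransitionError(
            f"cannot move from {exp.level.value} to {new_level.value}; levels "
            "advance one step at a time"
        )
    idx = np.flatnonzero(keep)
    out = QCExperiment(
        matrix=exp.matrix[:, idx],
        gene_ids=list(exp.gene_ids),
        barcode_ids=[exp.barcode_ids[i] for i in idx],
        level=new_level,
        cell_annotations=exp.cell_annotations.iloc[idx],
        gene_annotations=exp.gene_annotations,
        reduced_dims={k: v[idx] for k, v in exp.reduced_dims.items()},
        extra_assays={k: v[:, idx] for k, v in exp.extra_assays.items()},
        provenance=exp.provenance.copy(),
    )
    out.provenance.record(
        operation,
        {
            "n_before": int(exp.n_barcodes),
            "n_after": int(idx.size),
            "new_level": new_level.value,
        },
    )
    return out


def combine_samples(exps: Sequence[QCExperiment]) -> QCExperiment:
    """Concatenate experiments column-wise into one multi-sample experiment.

    All inputs must share an identical ordered gene universe and matrix
    level. Barcode identifiers that collide across inputs are made unique by
    prefixing with their sample label (``<sample>_<barcode>``).
    """
    if not exps:
        raise DimensionError("no experiments to combine")
    first = exps[0]
    for e in exps[1:]:
        if e.gene_ids != first.gene_ids:
            raise IncompatibleFeaturesError(
                "experiments do not share an identical gene universe"
            )
        if e.level != first.level:
            raise LevelTransitionError(
                "experiments are at different matrix levels"
            )

    all_barcodes: list[str] = []
    owners: list[str] = []
    for e in exps:
        all_barcodes.extend(e.barcode_ids)
        owners.extend(e.cell_annotations["sample"].astype(str))
    counts = pd.Series(all_barcodes).value_counts()
    colliding = set(counts.index[counts > 1])
    new_barcodes = [
        f"{owner}_{bc}" if bc in colliding else bc
        for bc, owner in zip(all_barcodes, owners)
    ]

    annot = pd.concat([e.cell_annotations for e in exps], axis=0)
    annot.index = pd.Index(new_barcodes)

    shared_dims = set(first.reduced_dims)
    for e in exps[1:]:
        shared_dims &= set(e.reduced_dims)
    reduced = {
        name: np.vstack([e.reduced_dims[name] for e in exps])
        for name in shared_dims
    }
    shared_assays = set(first.extra_assays)
    for e in exps[1:]:
        shared_assays &= set(e.extra_assays)
    assays = {
        name: sp.hstack([e.extra_assays[name] for e in exps], format="csc")
        for name in shared_assays
    }

    out = QCExperiment(
        matrix=sp.hstack([e.matrix for e in exps], format="csc"),
        gene_ids=list(first.gene_ids),
        barcode_ids=new_barcodes,
        level=first.level,
        cell_annotations=annot,
        gene_annotations=first.gene_annotations,
        reduced_dims=reduced,
        extra_assays=assays,
        provenance=first.provenance.copy(),
    )
    out.provenance.record(
        "combine_samples",
        {"n_samples": len(exps), "samples": [e.samples for e in exps]},
    )
    return out


def per_sample_apply(
    exp: QCExperiment,
    fn: Callable[[QCExperiment], pd.DataFrame],
) -> pd.DataFrame:
    """Apply a per-cell computation to each sample independently.

    QC algorithms operate within a sample; this helper slices the experiment
    by the ``sample`` column, applies *fn* to each single-sample view and
    re-assembles the per-barcode result in the original barcode order.
    *fn* must return a DataFrame indexed like the sub-experiment's barcodes.
    """
    sample_col = exp.cell_annotations["sample"].astype(str).to_numpy()
    pieces = []
    for name in exp.samples:
        mask = sample_col == name
        sub = subset_cells(exp, mask, operation="per_sample_view")
        res = fn(sub)
        res = res.set_axis(pd.Index(np.flatnonzero(mask)), axis=0)
        pieces.append(res)
    combined = pd.concat(pieces, axis=0).sort_index()
    combined.index = pd.Index(exp.barcode_ids)
    return combined
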