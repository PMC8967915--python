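"""Synthetic droplet-level data with known ground truth.

Generates a gene x barcode Droplet matrix containing empty droplets drawn
from a known ambient profile, true cells drawn from distinct cell-type
expression profiles with per-cell ambient contamination, and heterotypic
doublets formed by summing two singlet draws. Every quantity the QC
algorithms try to recover -- the ambient profile, cell-type memberships,
doublet labels and contamination fractions -- is returned as ground truth,
so all pipeline stages are testable without external data.

The generative model mirrors the decontamination model at the molecule
level: a singlet of type k with contamination fraction theta draws its
counts from Multinomial(total, (1 - theta) * phi_k + theta * ambient), and
the ambient profile is a uniform mixture of the cell-type profiles. A
mis-specified variant (:func:`simulate_misspecified_ambient`) draws the
ambient profile from an independent held-out Dirichlet instead, for
robustness checks.

The :func:`write_fixture` writer emits the dataset in every on-disk layout
the importers understand, and is the oracle for importer round-trip tests.
"""

from __future__ import annotations

import gzip
import io
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .container import MatrixLevel, QCExperiment
from .errors import ParameterError
from .importers import MEX_DIALECTS, MexDialect


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic droplet dataset.

    Defaults describe a small but realistic droplet run: 500 genes, three
    cell types of 300 cells each, 20,000 empty droplets whose totals are
    log-normal around ~20 UMIs, cell totals log-normal around ~2,000 UMIs,
    8% doublets among cell-containing droplets and per-cell contamination
    drawn from Beta(2, 18) (mean 10%).
    """

    n_genes: int = 500
    n_cell_types: int = 3
    cells_per_type: int = 300
    n_empty_droplets: int = 20000
    empty_total_logmean: float = math.log(20.0)
    empty_total_logsd: float = 0.6
    cell_total_logmean: float = math.log(2000.0)
    cell_total_logsd: float = 0.3
    doublet_fraction: float = 0.08
    contamination_a: float = 2.0
    contamination_b: float = 18.0
    type_profile_concentration: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.doublet_fraction < 1):
            raise ParameterError("doublet_fraction must be in [0, 1)")
        if self.n_cell_types < 1 or self.cells_per_type < 0:
            raise ParameterError("need at least one cell type")
        if self.n_genes < 2:
            raise ParameterError("need at least two genes")


@dataclass
class GroundTruth:
    """What was actually simulated, aligned with the barcode order."""

    kind: np.ndarray  # 'empty' | 'singlet' | 'doublet'
    type1: np.ndarray  # cell type index, -1 for empties
    type2: np.ndarray  # second type for doublets, else -1
    contamination: np.ndarray  # realised theta, NaN for empties
    ambient_profile: np.ndarray
    type_profiles: np.ndarray  # K x G

    @property
    def is_cell(self) -> np.ndarray:
        return self.kind != "empty"

    @property
    def is_doublet(self) -> np.ndarray:
        return self.kind == "doublet"


def _draw_totals(
    rng: np.random.Generator, n: int, logmean: float, logsd: float
) -> np.ndarray:
    totals = np.rint(rng.lognormal(logmean, logsd, size=n)).astype(np.int64)
    return np.maximum(totals, 1)


def simulate_droplet_data(
    spec: SimulationSpec = SimulationSpec(),
    sample: str = "sim_sample",
    ambient: np.ndarray | None = None,
) -> tuple[QCExperiment, GroundTruth]:
    """Generate a Droplet-level experiment plus its ground truth.

    Barcodes are shuffled so empties and cells interleave as they would in
    a real raw matrix. Pass *ambient* to override the profile empties and
    contamination are drawn from (used for mis-specification checks).
    """
    rng = np.random.default_rng(spec.seed)
    G, K = spec.n_genes, spec.n_cell_types

    type_profiles = rng.dirichlet(
        np.full(G, spec.type_profile_concentration), size=K
    )
    if ambient is None:
        ambient = type_profiles.mean(axis=0)
    ambient = np.asarray(ambient, dtype=float)
    ambient = ambient / ambient.sum()

    n_singlets = K * spec.cells_per_type
    f = spec.doublet_fraction
    n_doublets = int(round(f / (1 - f) * n_singlets)) if n_singlets else 0
    n_empty = spec.n_empty_droplets

    blocks: list[np.ndarray] = []
    kinds: list[str] = []
    t1: list[int] = []
    t2: list[int] = []
    thetas: list[float] = []

    def singlet_draw(ctype: int) -> tuple[np.ndarray, float]:
        total = _draw_totals(rng, 1, spec.cell_total_logmean, spec.cell_total_logsd)[0]
        theta = rng.beta(spec.contamination_a, spec.contamination_b)
        p = (1 - theta) * type_profiles[ctype] + theta * ambient
        return rng.multinomial(total, p), theta

    for k in range(K):
        for _ in range(spec.cells_per_type):
            counts, theta = singlet_draw(k)
            blocks.append(counts)
            kinds.append("singlet")
            t1.append(k)
            t2.append(-1)
            thetas.append(theta)

    for _ in range(n_doublets):
        if K >= 2:
            a, b = rng.choice(K, size=2, replace=False)
        else:
            a = b = 0
        ca, tha = singlet_draw(int(a))
        cb, thb = singlet_draw(int(b))
        counts = ca + cb
        blocks.append(counts)
        kinds.append("doublet")
        t1.append(int(a))
        t2.append(int(b))
        # effective contamination of the summed droplet
        tot = counts.sum()
        thetas.append((tha * ca.sum() + thb * cb.sum()) / max(tot, 1))

    if n_empty:
        empty_totals = _draw_totals(
            rng, n_empty, spec.empty_total_logmean, spec.empty_total_logsd
        )
        empty_counts = rng.multinomial(empty_totals, ambient)
        for row in empty_counts:
            blocks.append(row)
        kinds.extend(["empty"] * n_empty)
        t1.extend([-1] * n_empty)
        t2.extend([-1] * n_empty)
        thetas.extend([np.nan] * n_empty)

    matrix = np.vstack(blocks).T  # genes x barcodes
    n_barcodes = matrix.shape[1]
    order = rng.permutation(n_barcodes)
    matrix = matrix[:, order]
    truth = GroundTruth(
        kind=np.array(kinds, dtype=object)[order],
        type1=np.array(t1)[order],
        type2=np.array(t2)[order],
        contamination=np.array(thetas)[order],
        ambient_profile=ambient,
        type_profiles=type_profiles,
    )

    gene_ids = [f"GENE{i:05d}" for i in range(G)]
    barcode_ids = [f"BC{i:07d}" for i in range(n_barcodes)]
    exp = QCExperiment(
        matrix=sp.csc_matrix(matrix),
        gene_ids=gene_ids,
        barcode_ids=barcode_ids,
        level=MatrixLevel.DROPLET,
        sample=sample,
    )
    exp.provenance.record(
        "simulate_droplet_data",
        {k: getattr(spec, k) for k in spec.__dataclass_fields__},
        seed=spec.seed,
    )
    return exp, truth


def simulate_misspecified_ambient(
    spec: SimulationSpec = SimulationSpec(),
    sample: str = "sim_sample",
) -> tuple[QCExperiment, GroundTruth]:
    """Variant whose ambient profile is NOT a mixture of the type profiles.

    The ambient distribution is drawn from an independent Dirichlet, so the
    decontamination model's assumption about the ambient pool is violated;
    used to probe robustness.
    """
    rng = np.random.default_rng(spec.seed + 1)
    held_out = rng.dirichlet(np.full(spec.n_genes, 0.5))
    return simulate_droplet_data(spec, sample=sample, ambient=held_out)


def cell_view(
    exp: QCExperiment, truth: GroundTruth
) -> tuple[QCExperiment, GroundTruth]:
    """Restrict to the true cell-containing barcodes, at Cell level."""
    from .container import subset_cells

    keep = truth.is_cell
    sub = subset_cells(exp, keep, MatrixLevel.CELL, operation="truth_cell_view")
    idx = np.flatnonzero(keep)
    sub_truth = GroundTruth(
        kind=truth.kind[idx],
        type1=truth.type1[idx],
        type2=truth.type2[idx],
        contamination=truth.contamination[idx],
        ambient_profile=truth.ambient_profile,
        type_profiles=truth.type_profiles,
    )
    return sub, sub_truth


# ----------------------------------------------------------------------
# Fixture writer: one directory per importer dialect


def _write_lines(path: Path, lines: list[str], use_gzip: bool) -> None:
    text = "\n".join(lines) + "\n"
    if use_gzip:
        with gzip.GzipFile(path, "wb", mtime=0) as fh:
            fh.write(text.encode())
    else:
        path.write_text(text)


def _write_mex_triple(
    exp: QCExperiment, out: Path, dialect: MexDialect
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    buf = io.BytesIO()
    scipy.io.mmwrite(buf, sp.coo_matrix(exp.matrix).astype(np.int64))
    mtx_path = out / dialect.matrix_file
    if dialect.gzipped:
        with gzip.GzipFile(mtx_path, "wb", mtime=0) as fh:
            fh.write(buf.getvalue())
    else:
        mtx_path.write_bytes(buf.getvalue())

    _write_lines(out / dialect.barcodes_file, list(exp.barcode_ids), dialect.gzipped)
    if dialect.feature_columns == 1:
        feats = list(exp.gene_ids)
    elif dialect.feature_columns == 2:
        feats = [f"{g}\t{g}" for g in exp.gene_ids]
    else:
        feats = [f"{g}\t{g}\tGene Expression" for g in exp.gene_ids]
    _write_lines(out / dialect.features_file, feats, dialect.gzipped)


def write_fixture(
    exp: QCExperiment,
    dialect: str,
    out_dir: str | Path,
    cell_exp: QCExperiment | None = None,
    genome: str = "GRCh38",
) -> Path:
    """Write an experiment in one of the supported on-disk layouts.

    For dialects that provide both raw and filtered matrices, *exp* fills
    the raw (Droplet) slot and *cell_exp* (default: *exp*) the filtered
    slot. Returns the sample directory written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if dialect == "csv":
        dense = pd.DataFrame(
            np.asarray(exp.matrix.todense(), dtype=np.int64),
            index=exp.gene_ids,
            columns=exp.barcode_ids,
        )
        dense.to_csv(out / "counts.csv")
        return out
    if dialect == "h5ad":
        from .exporters import export_anndata

        export_anndata(exp, out / "sample.h5ad", compression="gzip")
        return out
    if dialect not in MEX_DIALECTS:
        raise ParameterError(f"unknown fixture dialect '{dialect}'")
    d = MEX_DIALECTS[dialect]
    if d.raw_subdir is not None:
        sub = d.raw_subdir.replace("{genome}", genome)
        _write_mex_triple(exp, out / sub, d)
    if d.filtered_subdir is not None:
        sub = d.filtered_subdir.replace("{genome}", genome)
        _write_mex_triple(cell_exp if cell_exp is not None else exp, out / sub, d)
    return out
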