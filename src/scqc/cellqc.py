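"""Standard per-cell QC metrics and robust outlier flagging.

Per-cell metrics are the total UMI count, the number of genes detected,
the percentage of the library occupied by the N most-expressed genes
(N in {50, 100, 200, 500} by default) and, for each supplied gene set
(typically mitochondrial genes), the percentage of counts falling in the
set. Outliers in any metric can be flagged with a median-absolute-deviation
rule, and any combination of thresholds turns the Cell matrix into a
FilteredCell matrix.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .container import (
    MatrixLevel,
    QCExperiment,
    attach_cell_metric,
    per_sample_apply,
    subset_cells,
)
from .errors import InsufficientDataError, MissingColumnError, ParameterError
from .genesets import GeneSet

DEFAULT_TOP_NS = (50, 100, 200, 500)

#: MAD -> SD consistency factor for a normal distribution.
MAD_SCALE = 1.4826


def per_cell_metrics(
    matrix: sp.spmatrix,
    gene_ids: Sequence[str],
    gene_sets: Sequence[GeneSet] = (),
    top_ns: Sequence[int] = DEFAULT_TOP_NS,
) -> pd.DataFrame:
    """Compute the standard per-cell metric table for a genes x cells matrix.

    ``percent_top_N`` is 100 when a cell detects fewer than N genes; gene-set
    percentages for all-zero cells follow the 0/0 := 0 convention.
    """
    X = sp.csc_matrix(matrix)
    n_cells = X.shape[1]
    totals = np.asarray(X.sum(axis=0)).ravel()
    detected = np.diff(X.indptr)

    out = pd.DataFrame(
        {"total": totals, "detected": detected.astype(np.int64)}
    )

    safe_totals = np.where(totals > 0, totals, 1.0)
    top_ns = sorted(int(n) for n in top_ns)
    top_sums = {n: np.zeros(n_cells) for n in top_ns}
    for j in range(n_cells):
        col = X.data[X.indptr[j] : X.indptr[j + 1]]
        if col.size == 0:
            continue
        desc = np.sort(col)[::-1]
        csum = np.cumsum(desc)
        for n in top_ns:
            top_sums[n][j] = csum[min(n, desc.size) - 1]
    for n in top_ns:
        pct = 100.0 * top_sums[n] / safe_totals
        pct[totals == 0] = 0.0
        out[f"percent_top_{n}"] = pct

    for gs in gene_sets:
        mask = gs.match_mask(list(gene_ids))
        if not mask.any():
            warnings.warn(
                f"gene set '{gs.name}' matched no genes; emitting zeros",
                stacklevel=2,
            )
            subset_counts = np.zeros(n_cells)
        else:
            subset_counts = np.asarray(
                X[np.flatnonzero(mask), :].sum(axis=0)
            ).ravel()
        pct = 100.0 * subset_counts / safe_totals
        pct[totals == 0] = 0.0
        out[f"{gs.name}_percent"] = pct
        out[f"{gs.name}_sum"] = subset_counts
    return out


def per_cell_qc(
    exp: QCExperiment,
    gene_sets: Sequence[GeneSet] = (),
    top_ns: Sequence[int] = DEFAULT_TOP_NS,
) -> QCExperiment:
    """Append per-cell QC metric columns to a Cell-level experiment.

    Metrics are computed within each sample independently (they are
    per-cell quantities, so this is equivalent to a joint computation, but
    keeps the per-sample contract uniform across QC operations).
    """
    if exp.level == MatrixLevel.DROPLET:
        raise ParameterError("per_cell_qc expects a Cell or FilteredCell matrix")

    def one_sample(sub: QCExperiment) -> pd.DataFrame:
        df = per_cell_metrics(sub.matrix, sub.gene_ids, gene_sets, top_ns)
        df.index = pd.Index(sub.barcode_ids)
        return df

    table = per_sample_apply(exp, one_sample)
    out = exp
    for col in table.columns:
        out = attach_cell_metric(out, col, table[col].to_numpy(), overwrite=True)
    matched = {
        gs.name: int(gs.match_mask(list(exp.gene_ids)).sum()) for gs in gene_sets
    }
    out.provenance.record(
        "per_cell_qc",
        {
            "top_ns": list(top_ns),
            "gene_sets": [gs.name for gs in gene_sets],
            "gene_set_matches": matched,
        },
    )
    return out


def detect_cell_outlier(
    values: Sequence[float],
    nmads: float = 3.0,
    on_log: bool = True,
    direction: str = "both",
    samples: Sequence[str] | None = None,
) -> np.ndarray:
    """Flag outliers by deviation from the median in MAD units.

    A value is an outlier when it deviates from the (per-sample) median by
    more than ``nmads`` times the scaled median absolute deviation
    (MAD x 1.4826), optionally after a log2(x + 1) transform, in the
    requested direction (``lower``, ``higher`` or ``both``). A zero MAD
    (degenerate spread) flags nothing and emits a warning.
    """
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 1 or vals.size < 3:
        raise InsufficientDataError("need at least 3 finite values")
    if not np.all(np.isfinite(vals)):
        raise ParameterError("values must be finite")
    if direction not in ("lower", "higher", "both"):
        raise ParameterError("direction must be lower, higher or both")

    if samples is None:
        groups = np.zeros(vals.size, dtype=int)
    else:
        _, groups = np.unique(np.asarray(samples, dtype=str), return_inverse=True)

    x = np.log2(vals + 1.0) if on_log else vals
    out = np.zeros(vals.size, dtype=bool)
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        med = np.median(x[idx])
        mad = MAD_SCALE * np.median(np.abs(x[idx] - med))
        if mad == 0:
            warnings.warn(
                "MAD is zero (degenerate spread); no outliers flagged",
                stacklevel=2,
            )
            continue
        dev = x[idx] - med
        flag = np.zeros(idx.size, dtype=bool)
        if direction in ("lower", "both"):
            flag |= dev < -nmads * mad
        if direction in ("higher", "both"):
            flag |= dev > nmads * mad
        out[idx] = flag
    return out


def filter_cells_by_thresholds(
    exp: QCExperiment,
    rules: Sequence[dict],
) -> QCExperiment:
    """Apply min/max rules on metric columns, producing a FilteredCell matrix.

    Each rule is ``{"column": name, "min": x}`` and/or ``{"column": name,
    "max": y}``; cells must satisfy every rule (conjunction). Per-rule
    removal counts are recorded in the provenance log.
    """
    keep = np.ones(exp.n_barcodes, dtype=bool)
    removal_counts = {}
    for rule in rules:
        col = rule.get("column")
        if col not in exp.cell_annotations.columns:
            raise MissingColumnError(f"unknown metric column '{col}'")
        vals = exp.cell_annotations[col].to_numpy(dtype=float)
        ok = np.ones_like(keep)
        if "min" in rule and rule["min"] is not None:
            ok &= vals >= rule["min"]
        if "max" in rule and rule["max"] is not None:
            ok &= vals <= rule["max"]
        removal_counts[col] = int((~ok).sum())
        keep &= ok
    new_level = (
        MatrixLevel.FILTERED_CELL
        if exp.level == MatrixLevel.CELL
        else exp.level
    )
    out = subset_cells(exp, keep, new_level, operation="filter_cells_by_thresholds")
    out.provenance.entries[-1].parameters["removed_per_rule"] = removal_counts
    out.provenance.entries[-1].parameters["rules"] = [dict(r) for r in rules]
    return out
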