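"""Ambient-RNA contamination estimation and count deconvolution.

Cell-free transcripts in the suspension contaminate every droplet, so a
cell's observed counts are a mixture of its native expression and an
ambient profile. Each cell ``c`` belonging to expression cluster ``k(c)``
is modelled as

    counts_c ~ Multinomial(total_c, theta_c * eta_k(c) + (1 - theta_c) * phi_k(c))

where ``phi_k`` is the native gene distribution of cluster k, ``theta_c``
the cell's contamination fraction, and ``eta_k`` the contamination source
distribution seen by cluster k, estimated from the pooled expression of
all *other* clusters. Pinning the contamination source to out-of-cluster
expression is what makes the model identifiable: with a single shared,
freely re-estimated ambient distribution, each cluster profile can absorb
its own contamination and the likelihood is flat in ``theta`` (contamination
is only recognisable through genes a cell type does not itself express).

With ``eta`` fixed, ``theta`` and ``phi`` are estimated by
expectation-maximisation (a textbook EM, so the observed-data
log-likelihood is non-decreasing across iterations) with a small Dirichlet
smoothing on the profiles. The posterior split of each observed count into
ambient and native portions yields a decontaminated count matrix; ambient
and native portions sum to the observed counts exactly.

The model is unidentifiable with a single cluster (there is no
out-of-cluster expression to define the contamination source), so at
least two clusters must be present or derivable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._utils import normalized_pcs
from .container import (
    MatrixLevel,
    QCExperiment,
    attach_cell_metric,
    per_sample_apply,
)
from .errors import CannotEstimateError, ParameterError
from .provenance import derive_seed

#: Dirichlet smoothing added to profile estimates each M-step.
PROFILE_SMOOTHING = 1e-2


@dataclass
class DecontResult:
    """Estimated contamination and the decontaminated count matrix."""

    contamination: np.ndarray  # theta per cell, in [0, 1]
    cluster: np.ndarray  # integer labels per cell
    native_counts: sp.csc_matrix  # real-valued, same shape/sparsity as input
    ambient_dist: np.ndarray  # eta, sums to 1
    converged: bool
    n_iterations: int
    log_likelihood: list[float] = field(default_factory=list)


def derive_clusters(
    X: sp.spmatrix,
    k_range: range = range(2, 11),
    n_pcs: int = 30,
    seed: int = 0,
) -> np.ndarray:
    """Cluster cells by k-means in PCA space, choosing k by silhouette."""
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    n_cells = X.shape[1]
    pcs = normalized_pcs(X, n_pcs=n_pcs, seed=seed)
    best_labels, best_sil = None, -np.inf
    for k in k_range:
        if k >= n_cells:
            break
        km = KMeans(n_clusters=k, random_state=seed, n_init=5)
        labels = km.fit_predict(pcs)
        if len(np.unique(labels)) < 2:
            continue
        sil = silhouette_score(pcs, labels)
        if sil > best_sil:
            best_sil, best_labels = sil, labels
    if best_labels is None:
        raise CannotEstimateError("could not derive at least two clusters")
    return best_labels


def decontx(
    exp: QCExperiment,
    clusters: np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-3,
    seed: int | None = None,
) -> DecontResult:
    """Estimate per-cell contamination fractions by EM.

    Parameters
    ----------
    clusters
        Optional per-cell integer/str labels; derived by PCA + k-means
        (k chosen by silhouette) when absent.
    tol
        Convergence tolerance on the mean absolute change of the
        contamination fractions between iterations.
    """
    if exp.level == MatrixLevel.DROPLET:
        raise ParameterError("decontx expects a Cell or FilteredCell matrix")
    if seed is None:
        seed = 0
    X = sp.csc_matrix(exp.matrix, dtype=float)
    n_genes, n_cells = X.shape

    if clusters is None:
        z = derive_clusters(X, seed=seed)
    else:
        clusters = np.asarray(clusters)
        if clusters.shape != (n_cells,):
            raise ParameterError("cluster labels must be one per cell")
        _, z = np.unique(clusters, return_inverse=True)
        if len(np.unique(z)) < 2:
            raise CannotEstimateError(
                "ambient contamination is unidentifiable with a single "
                "cluster; supply at least two clusters"
            )
    K = int(z.max()) + 1

    coo = sp.coo_matrix(X)
    g_idx, c_idx, v = coo.row, coo.col, coo.data
    totals = np.asarray(X.sum(axis=0)).ravel()
    safe_totals = np.where(totals > 0, totals, 1.0)

    # contamination source per cluster: pooled observed expression of all
    # other clusters (fixed); native profiles start at cluster means
    cluster_sums = np.vstack(
        [
            np.asarray(X[:, np.flatnonzero(z == k)].sum(axis=1)).ravel()
            for k in range(K)
        ]
    )
    grand = cluster_sums.sum(axis=0)
    eta = np.empty((K, n_genes))
    for k in range(K):
        src = grand - cluster_sums[k] + PROFILE_SMOOTHING
        eta[k] = src / src.sum()
    phi = cluster_sums + PROFILE_SMOOTHING
    phi /= phi.sum(axis=1, keepdims=True)
    theta = np.full(n_cells, 0.1)

    zc = z[c_idx]
    ll_trace: list[float] = []
    converged = False
    a = np.zeros_like(v)
    it = 0
    for it in range(1, max_iter + 1):
        amb = theta[c_idx] * eta[zc, g_idx]
        nat = (1.0 - theta[c_idx]) * phi[zc, g_idx]
        mix = amb + nat
        ll_trace.append(float(np.sum(v * np.log(mix + 1e-300))))
        a = amb / (mix + 1e-300)

        new_theta = np.bincount(c_idx, weights=v * a, minlength=n_cells) / safe_totals
        phi_num = np.bincount(
            zc * n_genes + g_idx, weights=v * (1.0 - a),
            minlength=K * n_genes,
        ).reshape(K, n_genes) + PROFILE_SMOOTHING
        phi = phi_num / phi_num.sum(axis=1, keepdims=True)

        delta = float(np.mean(np.abs(new_theta - theta)))
        theta = new_theta
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"decontamination EM did not converge in {max_iter} iterations",
            stacklevel=2,
        )

    native = sp.csc_matrix(
        sp.coo_matrix((v * (1.0 - a), (g_idx, c_idx)), shape=X.shape)
    )
    # summary ambient distribution: cluster-size-weighted average of the
    # per-cluster contamination sources
    weights = cluster_sums.sum(axis=1)
    ambient = (eta * (weights / weights.sum())[:, None]).sum(axis=0)
    ambient = ambient / ambient.sum()
    return DecontResult(
        contamination=np.clip(theta, 0.0, 1.0),
        cluster=z,
        native_counts=native,
        ambient_dist=ambient,
        converged=converged,
        n_iterations=it,
        log_likelihood=ll_trace,
    )


def decontx_umap(exp: QCExperiment, seed: int | None = None) -> np.ndarray:
    """2-D UMAP embedding of the normalised matrix for report plots."""
    import umap

    if seed is None:
        seed = 0
    pcs = normalized_pcs(exp.matrix, seed=seed)
    n_neighbors = int(min(15, max(2, exp.n_barcodes - 1)))
    reducer = umap.UMAP(
        n_components=2, random_state=seed, n_neighbors=n_neighbors
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        emb = reducer.fit_transform(pcs)
    return np.asarray(emb, dtype=float)


def run_decontx(
    exp: QCExperiment,
    clusters: np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-3,
    seed: int | None = None,
    with_umap: bool = True,
) -> QCExperiment:
    """Per-sample contamination estimation, attached to the experiment.

    Appends ``decontX_contamination`` and ``decontX_clusters`` columns,
    stores the decontaminated matrix as the ``decontX_counts`` assay and
    (optionally) a per-sample 2-D embedding as ``decontX_UMAP``.
    """
    if seed is None:
        seed = 0
    native_cols: dict[str, sp.csc_matrix] = {}

    def one_sample(sub: QCExperiment) -> pd.DataFrame:
        sample = sub.samples[0]
        sub_clusters = None
        if clusters is not None:
            lookup = dict(zip(exp.barcode_ids, np.asarray(clusters)))
            sub_clusters = np.array([lookup[b] for b in sub.barcode_ids])
        res = decontx(
            sub,
            clusters=sub_clusters,
            max_iter=max_iter,
            tol=tol,
            seed=derive_seed(seed, f"decontx:{sample}"),
        )
        native_cols[sample] = res.native_counts
        table = pd.DataFrame(
            {
                "decontX_contamination": res.contamination,
                "decontX_clusters": res.cluster,
            },
            index=pd.Index(sub.barcode_ids),
        )
        if with_umap:
            emb = decontx_umap(sub, seed=derive_seed(seed, f"decontx_umap:{sample}"))
            table["_umap1"] = emb[:, 0]
            table["_umap2"] = emb[:, 1]
        return table

    table = per_sample_apply(exp, one_sample)
    out = exp
    for col in ("decontX_contamination", "decontX_clusters"):
        out = attach_cell_metric(out, col, table[col].to_numpy(), overwrite=True)

    # reassemble the full-width decontaminated matrix in barcode order
    sample_col = exp.cell_annotations["sample"].astype(str).to_numpy()
    native = sp.lil_matrix(exp.matrix.shape)
    for sample, block in native_cols.items():
        idx = np.flatnonzero(sample_col == sample)
        native[:, idx] = block
    out.set_assay("decontX_counts", sp.csc_matrix(native))
    if with_umap:
        out.set_reduced_dim(
            "decontX_UMAP", table[["_umap1", "_umap2"]].to_numpy()
        )
    out.provenance.record(
        "run_decontx",
        {"max_iter": max_iter, "tol": tol, "user_clusters": clusters is not None},
        seed=seed,
    )
    return out
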