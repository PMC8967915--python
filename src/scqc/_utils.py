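"""Shared numeric helpers: normalisation, feature selection, embeddings."""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def normalize_log(X: sp.spmatrix, target_sum: float = 1e4) -> sp.csc_matrix:
    """Counts-per-``target_sum`` library-size normalisation, then log1p.

    Input and output are genes x cells; all-zero cells pass through as
    zeros.
    """
    X = sp.csc_matrix(X, dtype=float, copy=True)
    totals = np.asarray(X.sum(axis=0)).ravel()
    scale = np.divide(
        target_sum, totals, out=np.zeros_like(totals, dtype=float),
        where=totals > 0,
    )
    X = X @ sp.diags(scale)
    X.data = np.log1p(X.data)
    return sp.csc_matrix(X)


def top_variable_genes(logX: sp.spmatrix, n_top: int = 2000) -> np.ndarray:
    """Indices of the *n_top* genes with the largest log-expression variance."""
    X = sp.csr_matrix(logX)
    mean = np.asarray(X.mean(axis=1)).ravel()
    sq = X.copy()
    sq.data **= 2
    var = np.asarray(sq.mean(axis=1)).ravel() - mean**2
    n_top = min(n_top, X.shape[0])
    return np.sort(np.argsort(var)[::-1][:n_top])


def pca_embed(
    features: np.ndarray, n_pcs: int = 30, seed: int = 0
) -> np.ndarray:
    """PCA of a cells x features matrix, capped at the feasible rank."""
    from sklearn.decomposition import PCA

    n_pcs = int(min(n_pcs, features.shape[0] - 1, features.shape[1]))
    n_pcs = max(n_pcs, 1)
    pca = PCA(n_components=n_pcs, random_state=seed, svd_solver="randomized")
    return pca.fit_transform(features)


def normalized_pcs(
    X: sp.spmatrix,
    n_pcs: int = 30,
    n_top_genes: int = 2000,
    seed: int = 0,
) -> np.ndarray:
    """Normalise, select variable genes and embed cells into PC space."""
    logX = normalize_log(X)
    hvg = top_variable_genes(logX, n_top_genes)
    dense = np.asarray(logX[hvg, :].todense()).T
    return pca_embed(dense, n_pcs=n_pcs, seed=seed)


def minmax(values: np.ndarray) -> np.ndarray:
    """Scale to [0, 1]; a constant vector maps to zeros."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)
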