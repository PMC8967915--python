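"""Doublet detection: simulation-kNN, co-expression, classifier and hybrid.

Droplet protocols occasionally capture two cells in one droplet, producing
a hybrid expression profile. Four scorers are provided:

* :func:`doublet_knn` -- simulate artificial doublets by summing the raw
  counts of random cell pairs, embed observed and simulated cells jointly
  in PCA space, and score each observed cell by the (mixing-ratio
  corrected) fraction of simulated doublets among its k nearest
  neighbours.
* :func:`doublet_cxds` -- a deterministic co-expression score: gene pairs
  that are almost never expressed in the same cell (mutually exclusive
  markers) are strong doublet witnesses, so a cell co-expressing many such
  pairs is suspicious.
* :func:`doublet_bcds` -- a gradient-boosted classifier trained to
  discriminate observed cells from simulated doublets; scores are
  out-of-fold predicted probabilities.
* :func:`doublet_hybrid` -- sum of the min-max-normalised cxds and bcds
  scores.

Each scorer derives a call threshold from a two-component Gaussian mixture
fit to its score distribution (falling back to an upper quantile when the
mixture is degenerate), and a consensus call combines the per-algorithm
calls by voting. Homotypic doublets (two cells of the same type) have no
mixed profile and are invisible to all expression-based scorers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._utils import minmax, normalize_log, pca_embed, top_variable_genes
from .container import (
    MatrixLevel,
    QCExperiment,
    attach_cell_metric,
    per_sample_apply,
)
from .errors import DegenerateInputError, InsufficientDataError, ParameterError
from .provenance import derive_seed


@dataclass
class DoubletResult:
    """Per-cell doublet score (higher = more doublet-like) and call."""

    algorithm: str
    score: np.ndarray
    threshold: float
    call: np.ndarray

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        self.call = np.asarray(self.call, dtype=bool)
        if not np.all(np.isfinite(self.score)):
            raise ParameterError("doublet scores must be finite")
        if not np.array_equal(self.call, self.score >= self.threshold):
            raise ParameterError("call must equal (score >= threshold)")


def derive_threshold(
    scores: np.ndarray,
    expected_rate: float = 0.05,
    random_state: int = 0,
) -> float:
    """Call threshold separating the singlet bulk from the doublet mode.

    A kernel density estimate of the score distribution is scanned for the
    minimum-density valley between the main (singlet) mode and the
    right-most secondary (doublet) mode. When the distribution shows no
    usable second mode -- or the valley would call a majority of cells --
    the (1 - expected_rate) upper quantile is used instead. Deterministic
    for a given score vector.
    """
    from scipy.signal import argrelextrema
    from scipy.stats import gaussian_kde

    scores = np.asarray(scores, dtype=float)
    fallback = float(np.quantile(scores, 1.0 - expected_rate))
    if np.ptp(scores) == 0 or np.unique(scores).size < 10:
        return fallback
    try:
        kde = gaussian_kde(scores)
    except Exception:
        return fallback
    grid = np.linspace(scores.min(), scores.max(), 512)
    dens = kde(grid)
    maxima = argrelextrema(dens, np.greater_equal, order=5)[0]
    # prominent modes only: at least 5% of the peak density
    maxima = [m for m in maxima if dens[m] > 0.05 * dens.max()]
    if len(maxima) < 2:
        return fallback
    main = max(maxima, key=lambda m: dens[m])
    upper_modes = [m for m in maxima if grid[m] > grid[main]]
    if not upper_modes:
        return fallback
    upper = upper_modes[-1]
    valley_seg = slice(main, upper + 1)
    threshold = float(grid[main + int(np.argmin(dens[valley_seg]))])
    if float(np.mean(scores >= threshold)) > 0.5:
        return fallback
    return threshold


def _result(algorithm: str, scores: np.ndarray, threshold: float) -> DoubletResult:
    return DoubletResult(
        algorithm=algorithm,
        score=scores,
        threshold=threshold,
        call=scores >= threshold,
    )


# ----------------------------------------------------------------------
# Doublet simulation


def simulate_doublets(
    X: sp.spmatrix, n_sim: int, rng: np.random.Generator
) -> sp.csc_matrix:
    """Sum the raw counts of *n_sim* random distinct cell pairs."""
    X = sp.csc_matrix(X)
    n = X.shape[1]
    first = rng.integers(0, n, size=n_sim)
    second = rng.integers(0, n - 1, size=n_sim)
    second[second >= first] += 1  # distinct partner, uniform over pairs
    return sp.csc_matrix(X[:, first] + X[:, second])


# ----------------------------------------------------------------------
# Algorithms


def doublet_knn(
    exp: QCExperiment,
    sim_ratio: float = 1.0,
    n_pcs: int = 30,
    k: int | None = None,
    expected_rate: float = 0.05,
    seed: int | None = None,
) -> DoubletResult:
    """Simulation + k-nearest-neighbour doublet score.

    Observed cells and simulated doublets are normalised, log-transformed
    and embedded jointly with PCA. For each observed cell, ``q`` is the
    fraction of simulated doublets among its k nearest neighbours; the
    score corrects ``q`` for the simulated:observed mixing fraction ``r``
    so it estimates the local probability that the neighbourhood is
    doublet-dominated: ``score = q(1-r) / (q(1-r) + (1-q)r)``.
    """
    from sklearn.neighbors import NearestNeighbors

    if exp.level == MatrixLevel.DROPLET:
        raise ParameterError("doublet_knn expects a Cell-level experiment")
    n = exp.n_barcodes
    if n < 50:
        raise InsufficientDataError(f"need at least 50 cells, got {n}")
    if k is None:
        k = max(5, int(round(np.sqrt(n))))
    if k >= n:
        raise ParameterError(f"k={k} must be smaller than the number of cells")
    if seed is None:
        seed = 0
    rng = np.random.default_rng(seed)

    n_sim = int(round(sim_ratio * n))
    sims = simulate_doublets(exp.matrix, n_sim, rng)
    joint = sp.hstack([exp.matrix, sims], format="csc")
    logX = normalize_log(joint)
    hvg = top_variable_genes(logX, 2000)
    dense = np.asarray(logX[hvg, :].todense()).T
    pcs = pca_embed(dense, n_pcs=n_pcs, seed=seed)

    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs[:n])
    neigh = idx[:, 1:]  # drop self
    q = (neigh >= n).mean(axis=1)
    r = n_sim / (n_sim + n)
    score = q * (1 - r) / (q * (1 - r) + (1 - q) * r + 1e-12)
    threshold = derive_threshold(score, expected_rate, random_state=seed)
    return _result("knn", score, threshold)


def doublet_cxds(
    exp: QCExperiment,
    n_top_pairs: int = 500,
    n_top_genes: int = 500,
    expected_rate: float = 0.05,
) -> DoubletResult:
    """Co-expression doublet score over mutually exclusive gene pairs.

    Genes are binarised at their per-cell-median count (which reduces to
    "detected" for genes expressed in fewer than half the cells). For each
    pair of genes the deficit of observed co-expression relative to the
    independence expectation is scored as a z-statistic; a cell's score is
    the sum of the pair statistics over the top *n_top_pairs* pairs it
    co-expresses. Fully deterministic.
    """
    if exp.level == MatrixLevel.DROPLET:
        raise ParameterError("doublet_cxds expects a Cell-level experiment")
    X = sp.csr_matrix(exp.matrix)
    n_cells = X.shape[1]
    dense = np.asarray(X.todense())
    med = np.median(dense, axis=1, keepdims=True)
    B = dense > med
    p = B.mean(axis=1)
    variable = (p > 0) & (p < 1)
    if variable.sum() < 2:
        raise DegenerateInputError(
            "all genes binarise to a constant; co-expression score undefined"
        )
    B = B[variable]
    p = p[variable]
    # keep the most variable binarised genes to bound the pair computation
    order = np.argsort(p * (1 - p))[::-1][: min(n_top_genes, B.shape[0])]
    B = B[np.sort(order)]
    p = p[np.sort(order)]

    Bf = B.astype(float)
    obs = Bf @ Bf.T
    exp_co = n_cells * np.outer(p, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (exp_co - obs) / np.sqrt(exp_co * (1 - np.outer(p, p)) + 1e-12)
    iu = np.triu_indices_from(z, k=1)
    pair_scores = z[iu]
    keep = np.argsort(pair_scores)[::-1][: min(n_top_pairs, pair_scores.size)]
    keep = keep[pair_scores[keep] > 0]
    if keep.size == 0:
        raise DegenerateInputError("no under-co-expressed gene pairs found")
    gi, gj = iu[0][keep], iu[1][keep]
    w = pair_scores[keep]
    score = np.einsum("pc,p->c", Bf[gi] * Bf[gj], w)
    threshold = derive_threshold(score, expected_rate, random_state=0)
    return _result("cxds", score, threshold)


def doublet_bcds(
    exp: QCExperiment,
    sim_ratio: float = 1.0,
    n_top_genes: int = 2000,
    n_folds: int = 3,
    expected_rate: float = 0.05,
    seed: int | None = None,
) -> DoubletResult:
    """Classifier-boosted doublet score.

    Labels observed cells 0 and simulated doublets 1, trains a
    gradient-boosted tree classifier on normalised variable-gene features
    and scores each observed cell by its out-of-fold predicted doublet
    probability.
    """
    from sklearn.model_selection import StratifiedKFold
    from xgboost import XGBClassifier

    if exp.level == MatrixLevel.DROPLET:
        raise ParameterError("doublet_bcds expects a Cell-level experiment")
    n = exp.n_barcodes
    if n < 100:
        raise InsufficientDataError(f"need at least 100 cells, got {n}")
    if seed is None:
        seed = 0
    rng = np.random.default_rng(seed)

    n_sim = int(round(sim_ratio * n))
    sims = simulate_doublets(exp.matrix, n_sim, rng)
    joint = sp.hstack([exp.matrix, sims], format="csc")
    logX = normalize_log(joint)
    hvg = top_variable_genes(logX, n_top_genes)
    features = np.asarray(logX[hvg, :].todense()).T
    labels = np.concatenate([np.zeros(n), np.ones(n_sim)])

    score = np.zeros(n + n_sim)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for train, test in skf.split(features, labels):
        clf = XGBClassifier(
            n_estimators=100,
            max_depth=4,
            learning_rate=0.3,
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
        clf.fit(features[train], labels[train])
        score[test] = clf.predict_proba(features[test])[:, 1]
    score = score[:n]
    threshold = derive_threshold(score, expected_rate, random_state=seed)
    return _result("bcds", score, threshold)


def doublet_hybrid(
    cxds: DoubletResult,
    bcds: DoubletResult,
    expected_rate: float = 0.05,
) -> DoubletResult:
    """Sum of min-max-normalised cxds and bcds scores, rethresholded."""
    if cxds.score.size != bcds.score.size:
        raise ParameterError("component scores have different lengths")
    score = minmax(cxds.score) + minmax(bcds.score)
    threshold = derive_threshold(score, expected_rate, random_state=0)
    return _result("cxds_bcds_hybrid", score, threshold)


def doublet_consensus(
    results: Sequence[DoubletResult], min_votes: int = 2
) -> np.ndarray:
    """Cells called doublets by at least *min_votes* algorithms."""
    if not results:
        raise ParameterError("no doublet results to combine")
    votes = np.sum([r.call.astype(int) for r in results], axis=0)
    return votes >= min_votes


# ----------------------------------------------------------------------
# Pipeline wrapper

DEFAULT_DOUBLET_ALGORITHMS = ("knn", "cxds", "bcds", "cxds_bcds_hybrid")


def run_doublet_qc(
    exp: QCExperiment,
    algorithms: Sequence[str] = DEFAULT_DOUBLET_ALGORITHMS,
    expected_rate: float = 0.05,
    min_votes: int = 2,
    seed: int | None = None,
) -> QCExperiment:
    """Run the requested doublet scorers per sample and attach results.

    Appends ``<algo>_doublet_score`` / ``<algo>_doublet_call`` columns per
    algorithm plus ``doublet_consensus_call``.
    """
    if seed is None:
        seed = 0

    def one_sample(sub: QCExperiment) -> pd.DataFrame:
        sample = sub.samples[0]
        results: dict[str, DoubletResult] = {}
        if "knn" in algorithms:
            results["knn"] = doublet_knn(
                sub, expected_rate=expected_rate,
                seed=derive_seed(seed, f"doublet_knn:{sample}"),
            )
        if "cxds" in algorithms or "cxds_bcds_hybrid" in algorithms:
            results["cxds"] = doublet_cxds(sub, expected_rate=expected_rate)
        if "bcds" in algorithms or "cxds_bcds_hybrid" in algorithms:
            results["bcds"] = doublet_bcds(
                sub, expected_rate=expected_rate,
                seed=derive_seed(seed, f"doublet_bcds:{sample}"),
            )
        if "cxds_bcds_hybrid" in algorithms:
            results["cxds_bcds_hybrid"] = doublet_hybrid(
                results["cxds"], results["bcds"], expected_rate=expected_rate
            )
        results = {k: v for k, v in results.items() if k in algorithms}
        table = {}
        for name, res in results.items():
            table[f"{name}_doublet_score"] = res.score
            table[f"{name}_doublet_call"] = res.call
        table["doublet_consensus_call"] = doublet_consensus(
            list(results.values()), min_votes=min(min_votes, len(results))
        )
        return pd.DataFrame(table, index=pd.Index(sub.barcode_ids))

    table = per_sample_apply(exp, one_sample)
    out = exp
    for col in table.columns:
        out = attach_cell_metric(out, col, table[col].to_numpy(), overwrite=True)
    out.provenance.record(
        "run_doublet_qc",
        {
            "algorithms": list(algorithms),
            "expected_rate": expected_rate,
            "min_votes": min_votes,
        },
        seed=seed,
    )
    return out
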