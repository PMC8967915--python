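"""Empty-droplet detection on the Droplet matrix.

Two complementary approaches are provided:

* **Barcode ranks** -- barcodes are ranked by total UMI count and the knee
  and inflection points of the log-log rank/total curve are located. Cells
  are expected to sit on the high-count plateau above the knee; barcodes
  below it are treated as empty droplets.

* **Empty-drops test** -- a Monte-Carlo multinomial goodness-of-fit test.
  Low-count barcodes (total <= ``lower``) are pooled into an ambient RNA
  profile. Each remaining barcode's counts are scored by their multinomial
  log-likelihood under that profile conditioned on the barcode's total; a
  p-value is obtained by comparing against simulated draws from the ambient
  multinomial at the same total. Barcodes whose expression deviates from
  ambient (small q-value after Benjamini-Hochberg correction), or whose
  totals exceed a retain threshold, are called cells.

The simulation is stratified by observed total: one null log-likelihood
distribution is built per distinct total and shared across all barcodes
with that total. The ``n_iters`` parallel null droplets are grown
item-by-item from the ambient distribution, which makes every intermediate
snapshot an exact multinomial sample at its total while costing
O(max_total * n_iters) overall instead of O(n_totals * n_iters * n_genes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import make_smoothing_spline
from scipy.special import gammaln
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .container import MatrixLevel, QCExperiment, attach_cell_metric, subset_cells
from .errors import (
    AmbientPoolError,
    InsufficientDataError,
    MissingResultError,
    ParameterError,
)
from .provenance import derive_seed

# ----------------------------------------------------------------------
# Results


@dataclass
class BarcodeRankResult:
    """Per-barcode rank/total curve with knee and inflection points."""

    rank: np.ndarray  # average rank by descending total (ties share rank)
    total: np.ndarray
    knee_total: float
    inflection_total: float


@dataclass
class EmptyDropsResult:
    """Per-barcode ambient-model test results.

    Barcodes with total <= ``lower`` form the ambient pool and are not
    tested; their ``log_prob``/``p_value``/``q_value`` are NaN, ``limited``
    and ``is_cell`` are False.
    """

    total: np.ndarray
    log_prob: np.ndarray
    p_value: np.ndarray
    q_value: np.ndarray
    limited: np.ndarray
    is_cell: np.ndarray
    lower: float
    n_iters: int
    fdr: float
    retain: float | None
    seed: int


# ----------------------------------------------------------------------
# Barcode ranks


def _unique_curve(totals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Log-log curve over unique totals: (log10 rank, log10 total)."""
    uniq, counts = np.unique(totals, return_counts=True)
    uniq = uniq[::-1]
    counts = counts[::-1]
    # average rank of each run of tied barcodes
    ends = np.cumsum(counts)
    starts = ends - counts + 1
    avg_rank = (starts + ends) / 2.0
    return np.log10(avg_rank), np.log10(uniq)


def barcode_ranks(
    exp: QCExperiment,
    lower: float = 100,
    min_barcodes: int = 100,
) -> BarcodeRankResult:
    """Rank barcodes by total counts and locate knee and inflection points.

    The knee is the point of minimum signed curvature of a smoothing-spline
    fit to the unique-value log-log curve (restricted to totals above
    *lower*); the inflection is the point of steepest descent of the raw
    unique-value curve at or below the knee. Both are reported as count
    values. With fewer than five unique totals the discrete curve is used
    directly; a flat curve degenerates to knee == inflection == the count.
    """
    if exp.level != MatrixLevel.DROPLET:
        raise ParameterError("barcode_ranks expects a Droplet-level experiment")
    totals = exp.totals().astype(float)
    above = totals[totals > lower]
    if above.size < min_barcodes:
        raise InsufficientDataError(
            f"only {above.size} barcodes above lower={lower}; "
            f"need at least {min_barcodes}"
        )
    rank = rankdata(-totals, method="average")

    x, y = _unique_curve(above)
    if np.unique(above).size == 1:
        v = float(above[0])
        return BarcodeRankResult(rank, totals, v, v)

    if x.size >= 5:
        # smoothing-spline fit; lam picked by generalised cross-validation
        order = np.argsort(x)
        xs, ys = x[order], y[order]
        try:
            spline = make_smoothing_spline(xs, ys)
            grid = np.linspace(xs[0], xs[-1], 1000)
            d1 = spline.derivative(1)(grid)
            d2 = spline.derivative(2)(grid)
            curvature = d2 / (1 + d1**2) ** 1.5
            knee_idx = int(np.argmin(curvature))
            knee_total = float(10 ** spline(grid[knee_idx]))
            knee_x = grid[knee_idx]
        except Exception:
            knee_total, knee_x = _discrete_knee(x, y)
    else:
        knee_total, knee_x = _discrete_knee(x, y)

    # steepest descent of the raw unique curve at or beyond the knee
    d1 = np.gradient(y, x)
    right = x >= knee_x
    if right.sum() >= 2:
        seg = np.flatnonzero(right)
        infl_idx = seg[int(np.argmin(d1[seg]))]
    else:
        infl_idx = int(np.argmin(d1))
    inflection_total = float(10 ** y[infl_idx])
    inflection_total = min(inflection_total, knee_total)
    inflection_total = max(inflection_total, float(lower))
    knee_total = max(knee_total, inflection_total)
    return BarcodeRankResult(rank, totals, knee_total, inflection_total)


def _discrete_knee(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Knee from discrete second differences when the curve is tiny."""
    d1 = np.gradient(y, x)
    d2 = np.gradient(d1, x)
    curvature = d2 / (1 + d1**2) ** 1.5
    idx = int(np.argmin(curvature))
    return float(10 ** y[idx]), float(x[idx])


# ----------------------------------------------------------------------
# Ambient profile and the Monte-Carlo test

#: Pseudo-count added to each gene when forming the ambient profile.
AMBIENT_PSEUDOCOUNT = 0.5


def ambient_profile(
    exp: QCExperiment,
    lower: float = 100,
) -> np.ndarray:
    """Estimate the ambient RNA profile from the low-count barcode pool.

    Counts over all barcodes with total <= *lower* are summed per gene, a
    pseudo-count of 0.5 is added, and the vector is normalised to sum to 1.
    """
    if exp.level != MatrixLevel.DROPLET:
        raise ParameterError("ambient_profile expects a Droplet-level experiment")
    totals = exp.totals()
    pool = totals <= lower
    if not pool.any():
        raise AmbientPoolError(
            f"no barcodes with total <= {lower} to form an ambient pool"
        )
    pooled = np.asarray(
        exp.matrix[:, np.flatnonzero(pool)].sum(axis=1)
    ).ravel()
    smoothed = pooled + AMBIENT_PSEUDOCOUNT
    return smoothed / smoothed.sum()


def _observed_logprob(
    X: sp.csc_matrix, cols: np.ndarray, log_p: np.ndarray
) -> np.ndarray:
    """Multinomial log-likelihood of selected columns under profile p."""
    sub = sp.csc_matrix(X[:, cols])
    totals = np.asarray(sub.sum(axis=0)).ravel()
    data = sub.data
    rows = sub.indices
    ptr = sub.indptr
    term = data * log_p[rows] - gammaln(data + 1)
    persum = np.zeros(sub.shape[1])
    nz = np.diff(ptr) > 0
    if term.size:
        sums = np.add.reduceat(term, ptr[:-1][nz])
        persum[nz] = sums
    return gammaln(totals + 1) + persum


def _null_logprob_tails(
    ambient: np.ndarray,
    totals_to_obs: dict[int, np.ndarray],
    n_iters: int,
    rng: np.random.Generator,
) -> dict[int, tuple[np.ndarray, int]]:
    """Monte-Carlo tail counts, stratified by total.

    For each distinct total T (key of *totals_to_obs*, mapping to the
    observed log-likelihoods at that total), returns the per-barcode count
    of simulated ambient droplets with log-likelihood <= observed, plus the
    number of iterations. ``n_iters`` null droplets are grown item by item;
    each snapshot at total T is an exact Multinomial(T, ambient) draw.
    """
    G = ambient.size
    log_p = np.log(ambient)
    cum_p = np.cumsum(ambient)
    cum_p[-1] = 1.0
    counts = np.zeros((n_iters, G), dtype=np.int64)
    ll = np.zeros(n_iters)
    rows = np.arange(n_iters)
    out: dict[int, tuple[np.ndarray, int]] = {}
    t = 0
    for target in sorted(totals_to_obs):
        dt = target - t
        if dt >= 2 * G:
            # bulk increment: one multinomial draw per simulation
            draw = rng.multinomial(dt, ambient, size=n_iters)
            ll += (
                gammaln(target + 1)
                - gammaln(t + 1)
                - (gammaln(counts + draw + 1) - gammaln(counts + 1)).sum(axis=1)
                + draw @ log_p
            )
            counts += draw
        else:
            for _ in range(dt):
                g = np.searchsorted(cum_p, rng.random(n_iters))
                c_prev = counts[rows, g]
                ll += log_p[g] - np.log(c_prev + 1.0) + np.log(t + 1.0)
                counts[rows, g] = c_prev + 1
                t += 1
        t = target
        obs = totals_to_obs[target]
        ll_sorted = np.sort(ll)
        tails = np.searchsorted(ll_sorted, obs + 1e-9, side="right")
        out[target] = (tails, n_iters)
    return out


def empty_drops_single(
    exp: QCExperiment,
    lower: float = 100,
    n_iters: int = 10000,
    fdr: float = 0.01,
    retain: float | None = None,
    seed: int | None = None,
) -> EmptyDropsResult:
    """Run the empty-droplet test on a single-sample Droplet experiment.

    Parameters
    ----------
    retain
        Total-count threshold above which barcodes are always called cells
        regardless of their q-value. ``None`` derives it from the
        barcode-rank knee; pass ``0`` (or a negative number) to disable.
    """
    if exp.level != MatrixLevel.DROPLET:
        raise ParameterError("empty_drops expects a Droplet-level experiment")
    if n_iters < 100:
        raise ParameterError("n_iters must be at least 100")
    if seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
    rng = np.random.default_rng(seed)

    totals = exp.totals().astype(np.int64)
    ambient = ambient_profile(exp, lower=lower)
    log_p = np.log(ambient)

    tested = np.flatnonzero(totals > lower)
    n = exp.n_barcodes
    log_prob = np.full(n, np.nan)
    p_value = np.full(n, np.nan)
    q_value = np.full(n, np.nan)
    limited = np.zeros(n, dtype=bool)
    is_cell = np.zeros(n, dtype=bool)

    if retain is None:
        try:
            ranks = barcode_ranks(exp, lower=lower)
            retain_val: float | None = ranks.knee_total
        except InsufficientDataError:
            retain_val = None
    elif retain <= 0:
        retain_val = None
    else:
        retain_val = float(retain)

    if tested.size:
        obs_ll = _observed_logprob(exp.matrix, tested, log_p)
        log_prob[tested] = obs_ll

        totals_to_obs: dict[int, np.ndarray] = {}
        totals_to_idx: dict[int, np.ndarray] = {}
        for tot in np.unique(totals[tested]):
            idx = tested[totals[tested] == tot]
            totals_to_idx[int(tot)] = idx
            totals_to_obs[int(tot)] = log_prob[idx]

        tails = _null_logprob_tails(ambient, totals_to_obs, n_iters, rng)
        for tot, idx in totals_to_idx.items():
            b, r = tails[tot]
            p_value[idx] = (1.0 + b) / (1.0 + r)
            limited[idx] = b == 0

        _, q, _, _ = multipletests(p_value[tested], method="fdr_bh")
        q_value[tested] = q
        is_cell[tested] = q <= fdr
        if retain_val is not None:
            is_cell[tested] |= totals[tested] >= retain_val

    return EmptyDropsResult(
        total=totals.astype(float),
        log_prob=log_prob,
        p_value=p_value,
        q_value=q_value,
        limited=limited,
        is_cell=is_cell,
        lower=lower,
        n_iters=n_iters,
        fdr=fdr,
        retain=retain_val,
        seed=seed,
    )


# ----------------------------------------------------------------------
# Pipeline-facing wrappers: per-sample application + annotation columns

RANK_COLUMNS = (
    "dropletUtils_barcodeRank_rank",
    "dropletUtils_barcodeRank_total",
    "dropletUtils_barcodeRank_knee",
    "dropletUtils_barcodeRank_inflection",
)
EMPTYDROPS_COLUMNS = (
    "dropletUtils_emptyDrops_total",
    "dropletUtils_emptyDrops_logprob",
    "dropletUtils_emptyDrops_pvalue",
    "dropletUtils_emptyDrops_fdr",
    "dropletUtils_emptyDrops_limited",
    "dropletUtils_emptyDrops_is_cell",
)


def run_droplet_qc(
    exp: QCExperiment,
    lower: float = 100,
    n_iters: int = 10000,
    fdr: float = 0.01,
    retain: float | None = None,
    seed: int | None = None,
) -> QCExperiment:
    """Barcode ranks + empty-droplet test, applied per sample.

    Appends the ``dropletUtils_barcodeRank_*`` and
    ``dropletUtils_emptyDrops_*`` annotation columns and records both
    operations in the provenance log.
    """
    import pandas as pd

    from .container import per_sample_apply

    if seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0] % (2**31))

    def one_sample(sub: QCExperiment) -> pd.DataFrame:
        sample = sub.samples[0]
        sample_seed = derive_seed(seed, f"empty_drops:{sample}")
        res = empty_drops_single(
            sub, lower=lower, n_iters=n_iters, fdr=fdr, retain=retain,
            seed=sample_seed,
        )
        try:
            ranks = barcode_ranks(sub, lower=lower)
            rank_cols = {
                RANK_COLUMNS[0]: ranks.rank,
                RANK_COLUMNS[1]: ranks.total,
                RANK_COLUMNS[2]: ranks.knee_total,
                RANK_COLUMNS[3]: ranks.inflection_total,
            }
        except InsufficientDataError:
            rank_cols = {c: np.nan for c in RANK_COLUMNS}
        return pd.DataFrame(
            {
                **rank_cols,
                EMPTYDROPS_COLUMNS[0]: res.total,
                EMPTYDROPS_COLUMNS[1]: res.log_prob,
                EMPTYDROPS_COLUMNS[2]: res.p_value,
                EMPTYDROPS_COLUMNS[3]: res.q_value,
                EMPTYDROPS_COLUMNS[4]: res.limited,
                EMPTYDROPS_COLUMNS[5]: res.is_cell,
            },
            index=pd.Index(sub.barcode_ids),
        )

    table = per_sample_apply(exp, one_sample)
    out = exp
    for col in table.columns:
        out = attach_cell_metric(out, col, table[col].to_numpy(), overwrite=True)
    out.provenance.record(
        "run_droplet_qc",
        {"lower": lower, "n_iters": n_iters, "fdr": fdr, "retain": retain},
        seed=seed,
    )
    return out


def filter_to_cells(
    exp: QCExperiment,
    method: str = "emptydrops",
) -> QCExperiment:
    """Filter a Droplet experiment down to its called cells.

    ``emptydrops`` keeps barcodes called by the ambient test;
    ``barcoderanks_knee`` / ``barcoderanks_inflection`` keep barcodes whose
    totals exceed the respective point.
    """
    cols = exp.cell_annotations
    if method == "emptydrops":
        col = EMPTYDROPS_COLUMNS[5]
        if col not in cols:
            raise MissingResultError(
                "empty-drops results not present; run run_droplet_qc first"
            )
        keep = cols[col].fillna(False).astype(bool).to_numpy()
    elif method in ("barcoderanks_knee", "barcoderanks_inflection"):
        which = RANK_COLUMNS[2] if method.endswith("knee") else RANK_COLUMNS[3]
        if which not in cols:
            raise MissingResultError(
                "barcode-rank results not present; run run_droplet_qc first"
            )
        totals = exp.totals()
        keep = totals > cols[which].to_numpy()
    else:
        raise ParameterError(f"unknown filtering method '{method}'")
    new_level = (
        MatrixLevel.CELL if exp.level == MatrixLevel.DROPLET else exp.level
    )
    return subset_cells(exp, keep, new_level, operation=f"filter_to_cells[{method}]")
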