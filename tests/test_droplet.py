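"""Barcode-rank curve analysis and the ambient Monte-Carlo test.

The Monte-Carlo p-values are checked against an exhaustive enumeration
oracle on a small instance, and their null calibration is checked on data
drawn from the ambient model itself.
"""

import itertools
import math

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.stats import kstest

import scqc
from scqc.droplet import _observed_logprob, barcode_ranks, empty_drops_single
from scqc.errors import AmbientPoolError, InsufficientDataError, ParameterError


def _droplet_exp(columns, lower_pool=None):
    """Droplet experiment from a list of count columns (genes x 1 each)."""
    cols = [np.asarray(c) for c in columns]
    if lower_pool:
        cols = [np.asarray(c) for c in lower_pool] + cols
    mat = np.column_stack(cols)
    return scqc.QCExperiment(
        sp.csc_matrix(mat),
        gene_ids=[f"G{i}" for i in range(mat.shape[0])],
        barcode_ids=[f"B{i}" for i in range(mat.shape[1])],
        level="Droplet",
        sample="s1",
    )


# ----------------------------------------------------------------------
# Enumeration oracle


def exact_ambient_pvalue(counts: np.ndarray, profile: np.ndarray) -> float:
    """Exhaustive multinomial tail probability.

    P(logL(X) <= logL(counts)) for X ~ Multinomial(sum(counts), profile),
    enumerating every composition of the total over the genes.
    """
    total = int(counts.sum())
    G = len(profile)
    obs_ll = _loglik(counts, profile)
    p = 0.0
    for comp in _compositions(total, G):
        ll = _loglik(np.array(comp), profile)
        if ll <= obs_ll + 1e-9:
            p += math.exp(ll)
    return min(p, 1.0)


def _loglik(c, profile):
    return (
        math.lgamma(c.sum() + 1)
        - sum(math.lgamma(x + 1) for x in c)
        + float(np.sum(c * np.log(profile)))
    )


def _compositions(total, bins):
    if bins == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, bins - 1):
            yield (first,) + rest


class TestEmptyDropsOracle:
    def _tiny_run(self):
        # ambient pool fixes the profile; tested barcodes have totals 3..6
        pool = [[1, 0, 0]] * 8 + [[0, 1, 0]] * 5 + [[0, 0, 1]] * 3
        tested = [
            [3, 0, 0],
            [0, 0, 3],
            [2, 1, 1],
            [1, 2, 2],
            [0, 0, 6],
            [3, 2, 1],
            [6, 0, 0],
        ]
        exp = _droplet_exp(tested, lower_pool=pool)
        profile = scqc.ambient_profile(exp, lower=2)
        res = empty_drops_single(exp, lower=2, n_iters=10000, retain=0, seed=123)
        return exp, profile, res, len(pool), tested

    def test_monte_carlo_matches_enumeration(self):
        _, profile, res, n_pool, tested = self._tiny_run()
        n_iters = 10000
        for j, counts in enumerate(tested):
            idx = n_pool + j
            p_exact = exact_ambient_pvalue(np.array(counts), profile)
            p_mc = res.p_value[idx]
            se = math.sqrt(p_exact * (1 - p_exact) / n_iters)
            assert abs(p_mc - p_exact) <= 3 * se + 2 / n_iters, (
                f"barcode {counts}: MC {p_mc:.4f} vs exact {p_exact:.4f}"
            )

    def test_expectation_like_barcode_has_top_pvalue_at_its_total(self):
        # counts proportional to the ambient profile maximise the likelihood,
        # so the enumeration p-value is ~1 and the MC p-value must agree
        _, profile, res, n_pool, tested = self._tiny_run()
        # [3,2,1] is close to 6 * profile (profile ~ [0.5, 0.32, 0.2])
        idx = n_pool + tested.index([3, 2, 1])
        same_total = [n_pool + j for j, t in enumerate(tested) if sum(t) == 6]
        assert res.p_value[idx] == max(res.p_value[k] for k in same_total)

    def test_pool_barcodes_are_untested(self):
        _, _, res, n_pool, _ = self._tiny_run()
        assert np.isnan(res.p_value[:n_pool]).all()
        assert not res.is_cell[:n_pool].any()


class TestLogProbMonotonicity:
    def test_shifting_counts_to_rare_genes_lowers_logprob(self):
        profile = np.array([0.7, 0.2, 0.1])
        log_p = np.log(profile)
        base = np.array([[7], [2], [1]])
        worse = np.array([[7], [1], [2]])  # one count moved to the rarest gene
        worst = np.array([[1], [2], [7]])
        lls = [
            _observed_logprob(sp.csc_matrix(c), np.array([0]), log_p)[0]
            for c in (base, worse, worst)
        ]
        assert lls[0] > lls[1] > lls[2]


@pytest.fixture(scope="module")
def ambient_null_run():
    """Pool + 1,000 barcodes drawn from the ambient profile itself."""
    rng = np.random.default_rng(42)
    G = 40
    raw_profile = rng.dirichlet(np.ones(G))
    pool_totals = rng.integers(1, 80, size=3000)
    pool = rng.multinomial(pool_totals, raw_profile).T
    exp0 = scqc.QCExperiment(
        sp.csc_matrix(pool),
        gene_ids=[f"G{i}" for i in range(G)],
        barcode_ids=[f"P{i}" for i in range(pool.shape[1])],
        level="Droplet",
        sample="s1",
    )
    profile = scqc.ambient_profile(exp0, lower=100)
    tested_totals = rng.integers(150, 400, size=1000)
    tested = rng.multinomial(tested_totals, profile).T
    mat = np.concatenate([pool, tested], axis=1)
    exp = scqc.QCExperiment(
        sp.csc_matrix(mat),
        gene_ids=[f"G{i}" for i in range(G)],
        barcode_ids=[f"B{i}" for i in range(mat.shape[1])],
        level="Droplet",
        sample="s1",
    )
    res = empty_drops_single(exp, lower=100, n_iters=10000, retain=0, seed=7)
    tested_mask = np.zeros(mat.shape[1], dtype=bool)
    tested_mask[pool.shape[1]:] = True
    return res, tested_mask


class TestNullCalibration:
    def test_pvalues_super_uniform_under_ambient_model(self, ambient_null_run):
        res, tested = ambient_null_run
        pvals = res.p_value[tested]
        # reject only if p-values are anti-conservative (stochastically
        # smaller than uniform)
        stat = kstest(pvals, "uniform", alternative="greater")
        assert stat.pvalue > 0.01

    def test_false_call_rate_within_nominal_fdr(self, ambient_null_run):
        res, tested = ambient_null_run
        rate = res.is_cell[tested].mean()
        n = tested.sum()
        se = math.sqrt(0.01 * 0.99 / n)
        assert rate <= 0.01 + 3 * se


class TestDeterminismAndValidation:
    def test_same_seed_identical_results(self):
        rng = np.random.default_rng(1)
        mat = rng.poisson(0.6, (30, 400))
        mat[:, :25] += rng.poisson(8, (30, 25))
        exp = scqc.QCExperiment(
            sp.csc_matrix(mat), [f"G{i}" for i in range(30)],
            [f"B{i}" for i in range(400)], level="Droplet", sample="s1",
        )
        r1 = empty_drops_single(exp, lower=30, n_iters=500, retain=0, seed=5)
        r2 = empty_drops_single(exp, lower=30, n_iters=500, retain=0, seed=5)
        np.testing.assert_array_equal(r1.p_value, r2.p_value)
        np.testing.assert_array_equal(r1.is_cell, r2.is_cell)

    def test_too_few_iterations_rejected(self, default_fixture):
        exp, _ = default_fixture
        with pytest.raises(ParameterError):
            empty_drops_single(exp, n_iters=50)

    def test_empty_ambient_pool_rejected(self):
        exp = _droplet_exp([[500, 500], [400, 600]])
        with pytest.raises(AmbientPoolError):
            scqc.ambient_profile(exp, lower=10)


class TestAmbientProfile:
    def test_pseudocount_arithmetic(self):
        # pooled per-gene counts over the three columns: [8, 2, 0]
        exp = _droplet_exp([[5, 1, 0], [3, 1, 0], [0, 0, 0]])
        profile = scqc.ambient_profile(exp, lower=100)
        np.testing.assert_allclose(profile, np.array([8.5, 2.5, 0.5]) / 11.5)
        assert abs(profile.sum() - 1.0) < 1e-12

    def test_barcode_order_irrelevant(self):
        cols = [[5, 1, 0], [3, 1, 0], [0, 0, 0]]
        p1 = scqc.ambient_profile(_droplet_exp(cols), lower=100)
        p2 = scqc.ambient_profile(_droplet_exp(cols[::-1]), lower=100)
        np.testing.assert_allclose(p1, p2)


class TestBarcodeRanks:
    def _two_plateau(self, seed=0):
        rng = np.random.default_rng(seed)
        cells = np.rint(rng.lognormal(np.log(5000), 0.3, 1000))
        empty = np.maximum(np.rint(rng.lognormal(np.log(10), 0.5, 100000)), 1)
        totals = np.concatenate([cells, empty]).astype(int)
        mat = sp.csc_matrix(totals[None, :].astype(float))
        exp = scqc.QCExperiment(
            mat, ["G1"], [f"B{i}" for i in range(totals.size)],
            level="Droplet", sample="s1",
        )
        return exp, cells, empty

    def test_knee_and_inflection_separate_the_plateaus(self):
        exp, cells, empty = self._two_plateau()
        res = barcode_ranks(exp, lower=5)
        gm = math.sqrt(5000 * 10)
        assert res.knee_total >= res.inflection_total
        # inflection sits mid-cliff, near the geometric mean of the plateaus
        assert gm / 3 <= res.inflection_total <= gm * 3
        # knee lies strictly between the plateau levels
        assert np.median(empty) < res.knee_total < np.median(cells)
        # the inflection threshold separates cells from empties
        assert (cells > res.inflection_total).mean() >= 0.99
        assert (empty > res.inflection_total).mean() <= 0.001

    def test_flat_curve_degenerates_to_the_single_count(self):
        mat = sp.csc_matrix(np.full((1, 300), 200.0))
        exp = scqc.QCExperiment(
            mat, ["G1"], [f"B{i}" for i in range(300)], level="Droplet",
            sample="s1",
        )
        res = barcode_ranks(exp, lower=100)
        assert res.knee_total == res.inflection_total == 200

    def test_rank_sorted_totals_are_non_increasing(self):
        exp, _, _ = self._two_plateau(seed=3)
        res = barcode_ranks(exp, lower=5)
        order = np.argsort(res.rank)
        assert (np.diff(res.total[order]) <= 0).all()

    def test_insufficient_barcodes_rejected(self):
        mat = sp.csc_matrix(np.full((1, 20), 500.0))
        exp = scqc.QCExperiment(
            mat, ["G1"], [f"B{i}" for i in range(20)], level="Droplet",
            sample="s1",
        )
        with pytest.raises(InsufficientDataError):
            barcode_ranks(exp, lower=100)


class TestFilterToCells:
    def test_knee_rule_keeps_exactly_above_knee(self, droplet_qc_result):
        exp, _ = droplet_qc_result
        out = scqc.filter_to_cells(exp, "barcoderanks_knee")
        knee = exp.cell_annotations["dropletUtils_barcodeRank_knee"].iloc[0]
        expected = (exp.totals() > knee).sum()
        assert out.n_barcodes == expected

    def test_filtering_twice_is_idempotent(self, droplet_qc_result):
        exp, _ = droplet_qc_result
        once = scqc.filter_to_cells(exp, "emptydrops")
        twice = scqc.filter_to_cells(once, "emptydrops")
        assert twice.n_barcodes == once.n_barcodes
        assert once.level == scqc.MatrixLevel.CELL

    def test_missing_results_raise(self, default_fixture):
        exp, _ = default_fixture
        from scqc.errors import MissingResultError

        with pytest.raises(MissingResultError):
            scqc.filter_to_cells(exp, "emptydrops")
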