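"""Doublet scorers: determinism, toy oracles, and fixture-based accuracy."""

import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.metrics import roc_auc_score

import scqc
from scqc.doublets import DoubletResult, simulate_doublets
from scqc.errors import InsufficientDataError, ParameterError
from scqc.simulate import SimulationSpec, cell_view, simulate_droplet_data


def _cell_exp(mat, sample="s1"):
    mat = np.asarray(mat)
    return scqc.QCExperiment(
        sp.csc_matrix(mat),
        gene_ids=[f"G{i}" for i in range(mat.shape[0])],
        barcode_ids=[f"B{i}" for i in range(mat.shape[1])],
        level="Cell",
        sample=sample,
    )


class TestDoubletResultContract:
    def test_call_must_match_threshold(self):
        with pytest.raises(ParameterError):
            DoubletResult("x", np.array([0.1, 0.9]), 0.5, np.array([True, True]))

    def test_every_fixture_result_satisfies_contract(self, doublet_results):
        for res in doublet_results.values():
            np.testing.assert_array_equal(res.call, res.score >= res.threshold)
            assert np.all(np.isfinite(res.score))

    def test_hybrid_score_bounded_by_two(self, doublet_results):
        hybrid = doublet_results["cxds_bcds_hybrid"]
        assert hybrid.score.min() >= 0 and hybrid.score.max() <= 2


class TestSimulateDoublets:
    def test_doublet_counts_are_sums_of_two_distinct_cells(self):
        rng = np.random.default_rng(0)
        X = sp.csc_matrix(np.diag([1, 2, 3, 4]))
        sims = simulate_doublets(X, 50, rng)
        # every simulated column must be the sum of two distinct diagonal
        # cells, so it has exactly two nonzero entries
        assert (np.diff(sims.tocsc().indptr) == 2).all()


class TestKnnScorer:
    def test_fixture_auroc(self, doublet_fixture, doublet_results):
        _, truth = doublet_fixture
        auc = roc_auc_score(truth.is_doublet, doublet_results["knn"].score)
        assert auc >= 0.90

    def test_deterministic_under_fixed_seed(self, doublet_fixture):
        cell, _ = doublet_fixture
        sub = scqc.subset_cells(cell, np.arange(cell.n_barcodes) < 300)
        r1 = scqc.doublet_knn(sub, seed=9)
        r2 = scqc.doublet_knn(sub, seed=9)
        np.testing.assert_array_equal(r1.score, r2.score)

    def test_homotypic_doublets_much_harder_than_heterotypic(
        self, doublet_fixture, doublet_results
    ):
        # a single cell type: summing two same-type multinomial draws gives
        # another multinomial draw, so the mixed-profile signal vanishes and
        # only the doubled library size leaks information
        spec = SimulationSpec(
            n_genes=200, n_cell_types=1, cells_per_type=400,
            n_empty_droplets=100, doublet_fraction=0.10, seed=8,
        )
        exp, truth = simulate_droplet_data(spec)
        cell, ctruth = cell_view(exp, truth)
        res = scqc.doublet_knn(cell, seed=1)
        auc_homo = roc_auc_score(ctruth.is_doublet, res.score)
        _, hetero_truth = doublet_fixture
        auc_hetero = roc_auc_score(
            hetero_truth.is_doublet, doublet_results["knn"].score
        )
        assert auc_homo <= auc_hetero - 0.10

    def test_too_few_cells_rejected(self):
        exp = _cell_exp(np.eye(10))
        with pytest.raises(InsufficientDataError):
            scqc.doublet_knn(exp)


class TestCxdsScorer:
    def test_engineered_coexpressing_cell_scores_highest(self):
        # gene pairs A/B and C/D are mutually exclusive across cells 0..4;
        # only cell 5 co-expresses both members of each pair
        mat = np.array(
            #      c0  c1  c2  c3  c4  c5
            [
                [9, 0, 9, 0, 0, 9],  # A  (on in 0, 2, 5)
                [0, 9, 0, 9, 0, 9],  # B  (on in 1, 3, 5)
                [9, 0, 0, 9, 0, 9],  # C  (on in 0, 3, 5)
                [0, 9, 9, 0, 0, 9],  # D  (on in 1, 2, 5)
            ]
        )
        res = scqc.doublet_cxds(_cell_exp(mat), n_top_pairs=10)
        assert res.score.argmax() == 5

    def test_cell_permutation_permutes_scores(self, doublet_fixture):
        cell, _ = doublet_fixture
        sub = scqc.subset_cells(cell, np.arange(cell.n_barcodes) < 200)
        rng = np.random.default_rng(0)
        perm = rng.permutation(sub.n_barcodes)
        permuted = scqc.QCExperiment(
            sub.matrix[:, perm],
            gene_ids=sub.gene_ids,
            barcode_ids=[sub.barcode_ids[i] for i in perm],
            level="Cell",
            sample="s1",
        )
        r1 = scqc.doublet_cxds(sub)
        r2 = scqc.doublet_cxds(permuted)
        np.testing.assert_allclose(r1.score[perm], r2.score)

    def test_fixture_auroc(self, doublet_fixture, doublet_results):
        _, truth = doublet_fixture
        auc = roc_auc_score(truth.is_doublet, doublet_results["cxds"].score)
        assert auc >= 0.80


class TestBcdsScorer:
    def test_fixture_auroc(self, doublet_fixture, doublet_results):
        _, truth = doublet_fixture
        auc = roc_auc_score(truth.is_doublet, doublet_results["bcds"].score)
        assert auc >= 0.85

    def test_deterministic_under_fixed_seed(self, doublet_fixture):
        cell, _ = doublet_fixture
        sub = scqc.subset_cells(cell, np.arange(cell.n_barcodes) < 250)
        r1 = scqc.doublet_bcds(sub, seed=4)
        r2 = scqc.doublet_bcds(sub, seed=4)
        np.testing.assert_array_equal(r1.score, r2.score)

    def test_shuffled_labels_have_no_signal(self):
        """With randomised training labels the classifier cannot beat chance."""
        from sklearn.model_selection import cross_val_predict
        from xgboost import XGBClassifier

        rng = np.random.default_rng(5)
        spec = SimulationSpec(
            n_genes=150, n_cell_types=2, cells_per_type=150,
            n_empty_droplets=100, doublet_fraction=0.10, seed=5,
        )
        exp, truth = simulate_droplet_data(spec)
        cell, ctruth = cell_view(exp, truth)
        from scqc._utils import normalize_log, top_variable_genes

        logX = normalize_log(cell.matrix)
        hvg = top_variable_genes(logX, 500)
        feats = np.asarray(logX[hvg, :].todense()).T
        labels = rng.permutation(ctruth.is_doublet.astype(int))
        clf = XGBClassifier(n_estimators=50, max_depth=3, random_state=0,
                            n_jobs=1, verbosity=0)
        probs = cross_val_predict(
            clf, feats, labels, cv=3, method="predict_proba"
        )[:, 1]
        # out-of-fold predictions cannot recover their own shuffled labels
        auc = roc_auc_score(labels, probs)
        assert 0.35 <= auc <= 0.65

    def test_small_dataset_rejected(self):
        exp = _cell_exp(np.eye(60))
        with pytest.raises(InsufficientDataError):
            scqc.doublet_bcds(exp)


class TestHybridAndConsensus:
    def test_hybrid_zero_when_both_components_zero(self):
        cx = DoubletResult("cxds", np.array([0.0, 1.0, 4.0]), 5.0,
                           np.array([False, False, False]))
        bc = DoubletResult("bcds", np.array([0.0, 0.5, 1.0]), 2.0,
                           np.array([False, False, False]))
        hy = scqc.doublet_hybrid(cx, bc)
        assert hy.score[0] == 0.0

    def test_constant_component_reduces_to_other_ranking(self):
        cx = DoubletResult("cxds", np.full(5, 3.0), 99.0, np.zeros(5, bool))
        bc = DoubletResult("bcds", np.array([0.1, 0.9, 0.4, 0.2, 0.7]), 99.0,
                           np.zeros(5, bool))
        hy = scqc.doublet_hybrid(cx, bc)
        assert np.argsort(hy.score).tolist() == np.argsort(bc.score).tolist()

    def test_hybrid_auroc_close_to_best_component(
        self, doublet_fixture, doublet_results
    ):
        _, truth = doublet_fixture
        aucs = {
            k: roc_auc_score(truth.is_doublet, r.score)
            for k, r in doublet_results.items()
        }
        assert aucs["cxds_bcds_hybrid"] >= max(aucs["cxds"], aucs["bcds"]) - 0.05

    def test_vote_counting(self):
        def res(calls):
            calls = np.array(calls)
            return DoubletResult("x", calls.astype(float), 0.5, calls)

        results = [res([True]), res([True]), res([False])]
        assert scqc.doublet_consensus(results, min_votes=2).tolist() == [True]
        union = scqc.doublet_consensus(results, min_votes=1)
        inter = scqc.doublet_consensus(results, min_votes=3)
        assert union.tolist() == [True] and inter.tolist() == [False]

    def test_consensus_improves_precision_on_fixture(
        self, doublet_fixture, doublet_results
    ):
        _, truth = doublet_fixture
        cons = scqc.doublet_consensus(list(doublet_results.values()), 2)

        def precision(call):
            called = call.sum()
            return (call & truth.is_doublet).sum() / called if called else 0.0

        best_single = max(precision(r.call) for r in doublet_results.values())
        assert precision(cons) >= best_single - 0.10


class TestDoubletRates:
    def test_all_algorithms_estimate_plausible_rates(self, doublet_results):
        # fixture holds 10% true doublets
        for name, res in doublet_results.items():
            rate = res.call.mean()
            assert 0.03 <= rate <= 0.25, f"{name} rate {rate:.3f}"
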