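import math

import numpy as np
import pytest

from qmdr import (
    MDR,
    QMDR,
    Dataset,
    exhaustive_order_k,
    make_folds,
    select_overall_best,
    t_statistic,
)
from qmdr.search import CVSummary
from conftest import random_dataset
from naive_search import naive_exhaustive_order_k


class TestOracleEquivalence:
    """The vectorized engine must agree with a naive loop-and-dict search."""

    @pytest.mark.parametrize("trait_kind", ["quantitative", "binary"])
    @pytest.mark.parametrize("m,n,k", [(4, 40, 1), (5, 50, 2), (6, 60, 2), (6, 40, 3)])
    def test_matches_naive_search(self, m, n, k, trait_kind):
        rng = np.random.default_rng(1000 * m + 10 * n + k)
        ds = random_dataset(rng, n, m, trait_kind)
        folds = make_folds(n, 10, seed=rng)
        summary = exhaustive_order_k(ds, k, folds)
        winners, train_scores, pooled = naive_exhaustive_order_k(ds, k, folds)
        assert [fr.best_model for fr in summary.fold_results] == winners
        for fr, ts in zip(summary.fold_results, train_scores):
            assert fr.training_score == pytest.approx(ts, abs=1e-9)
        assert summary.pooled_testing_score == pytest.approx(pooled, abs=1e-9)

    def test_matches_naive_on_signal_data(self):
        rng = np.random.default_rng(7)
        from qmdr import generate_pure_epistasis_model, simulate_quantitative_dataset

        model = generate_pure_epistasis_model(0.3, 0.4, seed=rng)
        ds, _ = simulate_quantitative_dataset(model, 60, m_noise=3, seed=rng)
        folds = make_folds(60, 10, seed=rng)
        summary = exhaustive_order_k(ds, 2, folds)
        winners, _, pooled = naive_exhaustive_order_k(ds, 2, folds)
        assert [fr.best_model for fr in summary.fold_results] == winners
        assert summary.pooled_testing_score == pytest.approx(pooled, abs=1e-9)


class TestExhaustiveOrderK:
    def test_candidate_count_is_m_choose_k(self, rng):
        ds = random_dataset(rng, 40, 4)
        summary = exhaustive_order_k(ds, 2, make_folds(40, 10, seed=0))
        assert summary.n_candidates == 6

    def test_deterministic_given_seed(self, rng):
        ds = random_dataset(rng, 50, 6)
        a = exhaustive_order_k(ds, 2, make_folds(50, 10, seed=9))
        b = exhaustive_order_k(ds, 2, make_folds(50, 10, seed=9))
        assert a.pooled_testing_score == b.pooled_testing_score
        assert [f.best_model for f in a.fold_results] == [f.best_model for f in b.fold_results]
        assert (a.modal_model, a.cvc) == (b.modal_model, b.cvc)

    def test_infeasible_order_rejected(self, rng):
        ds = random_dataset(rng, 40, 3)
        with pytest.raises(ValueError):
            exhaustive_order_k(ds, 4, make_folds(40, 10, seed=0))

    def test_snp_column_permutation_only_relabels(self, rng):
        n, m = 60, 5
        ds = random_dataset(rng, n, m)
        perm = np.array([3, 0, 4, 1, 2])
        ds_p = Dataset(ds.genotypes[:, perm], ds.trait, ds.snp_names, "quantitative")
        folds = make_folds(n, 10, seed=4)
        a = exhaustive_order_k(ds, 2, folds)
        b = exhaustive_order_k(ds_p, 2, folds)
        assert a.pooled_testing_score == pytest.approx(b.pooled_testing_score, abs=1e-9)
        inv = np.argsort(perm)  # original column j sits at position inv[j]
        for fa, fb in zip(a.fold_results, b.fold_results):
            assert tuple(sorted(inv[list(fa.best_model)])) == fb.best_model

    def test_null_pooled_scores_center_near_zero(self):
        from qmdr import simulate_null_dataset

        root = np.random.SeedSequence(77)
        scores = []
        for ss in root.spawn(500):
            rng = np.random.default_rng(ss)
            ds = simulate_null_dataset(400, 10, rng)
            folds = make_folds(400, 10, seed=rng)
            scores.append(exhaustive_order_k(ds, 2, folds).pooled_testing_score)
        assert abs(np.mean(scores)) < 0.15

    def test_strong_pair_recovered_with_high_consistency(self):
        from qmdr import generate_pure_epistasis_model, simulate_quantitative_dataset

        root = np.random.SeedSequence(404)
        hits = 0
        reps = 100
        for ss in root.spawn(reps):
            rng = np.random.default_rng(ss)
            model = generate_pure_epistasis_model(0.4, 0.4, seed=rng)
            ds, truth = simulate_quantitative_dataset(model, 1600, m_noise=18, seed=rng)
            folds = make_folds(1600, 10, seed=rng)
            s = exhaustive_order_k(ds, 2, folds)
            hits += s.modal_model == truth and s.cvc >= 8
        assert hits / reps >= 0.95


class TestPooledScore:
    def test_noiseless_two_group_trait_recovers_full_sample_t(self):
        # one SNP pair deterministically splits the trait into 10s and 0s
        rng = np.random.default_rng(5)
        n = 200
        geno = rng.integers(0, 3, size=(n, 4))
        trait = np.where((geno[:, 0] + geno[:, 1]) % 2 == 1, 10.0, 0.0)
        trait += rng.normal(0, 1e-6, n)  # break exact-tie degeneracy
        ds = Dataset(geno, trait, ("A", "B", "C", "D"), "quantitative")
        folds = make_folds(n, 10, seed=1)
        summary = exhaustive_order_k(ds, 2, folds)
        assert all(fr.best_model == (0, 1) for fr in summary.fold_results)
        truth_high = (geno[:, 0] + geno[:, 1]) % 2 == 1
        expected = t_statistic(trait[truth_high], trait[~truth_high])
        assert summary.pooled_testing_score == pytest.approx(expected, rel=1e-6)

    def test_binary_perfect_prediction_scores_one(self, rng):
        n = 100
        geno = rng.integers(0, 3, size=(n, 3))
        trait = (geno[:, 2] > 0).astype(int)
        ds = Dataset(geno, trait, ("A", "B", "C"), "binary")
        summary = exhaustive_order_k(ds, 1, make_folds(n, 10, seed=2))
        assert summary.pooled_testing_score == pytest.approx(1.0)


def _stub(order, score, cvc, model):
    return CVSummary(
        order=order,
        fold_results=[],
        pooled_testing_score=score,
        cvc=cvc,
        modal_model=model,
        n_candidates=0,
    )


class TestSelectOverallBest:
    def test_max_testing_score_wins(self):
        best = select_overall_best(
            [_stub(2, 3.0, 5, (0, 1)), _stub(3, 2.0, 9, (0, 1, 2))]
        )
        assert best.order == 2 and best.snp_indices == (0, 1)

    def test_cvc_breaks_score_ties(self):
        best = select_overall_best(
            [_stub(2, 3.0, 5, (0, 1)), _stub(3, 3.0, 8, (0, 1, 2))]
        )
        assert best.order == 3

    def test_parsimony_breaks_remaining_ties(self):
        best = select_overall_best(
            [_stub(3, 3.0, 8, (0, 1, 2)), _stub(2, 3.0, 8, (0, 1))]
        )
        assert best.order == 2


class TestEstimators:
    def test_qmdr_finds_planted_pair_and_exposes_sklearn_api(self):
        from qmdr import generate_pure_epistasis_model, simulate_quantitative_dataset

        rng = np.random.default_rng(11)
        model = generate_pure_epistasis_model(0.4, 0.4, seed=rng)
        ds, truth = simulate_quantitative_dataset(model, 800, m_noise=8, seed=rng)
        est = QMDR(min_order=1, max_order=2, random_state=0)
        est.fit(ds.genotypes, ds.trait)
        assert est.best_snps_ == truth
        assert est.best_order_ == 2
        attr = est.transform(ds.genotypes)
        assert attr.shape == (800, 1) and set(np.unique(attr)) <= {0, 1}
        assert est.score(ds.genotypes, ds.trait) > 5
        assert est.get_params()["max_order"] == 2

    def test_qmdr_affine_trait_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 3, size=(60, 5))
        y = rng.standard_normal(60)
        a = QMDR(min_order=1, max_order=2, random_state=7).fit(X, y)
        b = QMDR(min_order=1, max_order=2, random_state=7).fit(X, 3.5 - 2.0 * -y * -1)
        assert a.best_snps_ == b.best_snps_
        assert a.best_score_ == pytest.approx(b.best_score_, abs=1e-9)

    def test_mdr_predicts_case_for_high_risk_cells(self, rng):
        n = 200
        geno = rng.integers(0, 3, size=(n, 4))
        y = ((geno[:, 0] * geno[:, 1]) % 2 == 1).astype(int)
        if y.sum() in (0, n):
            pytest.skip("degenerate draw")
        est = MDR(min_order=2, max_order=2, random_state=0).fit(geno, y)
        assert est.best_snps_ == (0, 1)
        assert est.score(geno, y) == pytest.approx(1.0)

    def test_estimator_clones(self):
        from sklearn.base import clone

        est = QMDR(min_order=2, max_order=3, n_folds=5, random_state=1)
        c = clone(est)
        assert c.get_params() == est.get_params()
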