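import math

import numpy as np
import pytest
from scipy import stats

from qmdr import (
    ConfusionCounts,
    Dataset,
    assign_labels,
    balanced_accuracy,
    label_cells_binary,
    label_cells_quantitative,
    t_statistic,
    tabulate_cells,
)
from qmdr.induction import CellStats, CellTable
from conftest import random_dataset


def _quant_ds(geno, trait):
    geno = np.atleast_2d(np.asarray(geno))
    names = tuple(f"SNP{i+1}" for i in range(geno.shape[1]))
    return Dataset(geno, np.asarray(trait, dtype=float), names, "quantitative")


class TestTabulateCells:
    def test_single_snp_counts(self):
        ds = _quant_ds(np.array([[0], [0], [1], [2]]), [1.0, 2.0, 3.0, 4.0])
        table = tabulate_cells(ds, (0,))
        assert {c: s.n_obs for c, s in table.cells.items()} == {(0,): 2, (1,): 1, (2,): 1}

    def test_all_samples_one_cell(self):
        ds = _quant_ds(np.zeros((4, 2), dtype=int), [1.0, 3.0, 2.0, 0.0])
        table = tabulate_cells(ds, (0, 1))
        assert list(table.cells) == [(0, 0)]
        assert table.cells[(0, 0)].n_obs == 4

    def test_cell_trait_mean(self):
        ds = _quant_ds(np.zeros((2, 1), dtype=int), [1.0, 3.0])
        table = tabulate_cells(ds, (0,))
        assert table.cells[(0,)].trait_mean == pytest.approx(2.0)

    def test_order_above_snp_count_rejected(self, rng):
        ds = random_dataset(rng, 30, 2)
        with pytest.raises(ValueError):
            tabulate_cells(ds, (0, 1, 2))

    def test_binary_counts_split_cases_and_controls(self, tiny_binary_dataset):
        table = tabulate_cells(tiny_binary_dataset, (0,))
        st0 = table.cells[(0,)]
        assert (st0.n_cases, st0.n_controls) == (1, 1)


class TestLabeling:
    @pytest.mark.parametrize(
        "cases, controls, expect_high",
        [(3, 1, True), (2, 2, False), (1, 0, True)],  # tie goes low; 1:0 is infinite ratio
    )
    def test_binary_rule_at_ratio_one(self, cases, controls, expect_high):
        table = CellTable((0,), {(0,): CellStats(cases + controls, cases, controls)}, cases + controls)
        model = label_cells_binary(table, R=1.0)
        assert (model.label((0,)) == "high") is expect_high

    def test_quantitative_rule_is_strict(self):
        cells = {
            (0,): CellStats(n_obs=1, trait_sum=2.0),
            (1,): CellStats(n_obs=1, trait_sum=1.0),
        }
        model = label_cells_quantitative(CellTable((0,), cells, 2), overall_mean=1.0)
        assert model.label((0,)) == "high"
        assert model.label((1,)) == "low"  # mean equal to threshold
        assert model.label((2,)) == "empty"

    def test_binary_quantitative_equivalence_on_01_trait(self, rng):
        # on a 0/1 trait, cell mean > overall mean iff case ratio > R
        for _ in range(200):
            n = int(rng.integers(10, 40))
            k = int(rng.integers(1, 3))
            ds = random_dataset(rng, n, 2, "binary")
            idx = tuple(sorted(rng.choice(2, size=k, replace=False)))
            table = tabulate_cells(ds, idx)
            n_case = int(ds.trait.sum())
            bin_model = label_cells_binary(table, n_case / (n - n_case))
            # binary tabulation has no trait sums; rebuild them from cases
            for st_ in table.cells.values():
                st_.trait_sum = float(st_.n_cases)
            quant_model = label_cells_quantitative(table, n_case / n)
            assert bin_model.labels == quant_model.labels


class TestBalancedAccuracy:
    @pytest.mark.parametrize(
        "c, expected",
        [
            (ConfusionCounts(TP=50, TN=50, FP=0, FN=0), 1.0),
            (ConfusionCounts(TP=0, TN=0, FP=50, FN=50), 0.0),
            (ConfusionCounts(TP=30, TN=40, FP=10, FN=20), 0.7),
        ],
    )
    def test_worked_values(self, c, expected):
        assert balanced_accuracy(c) == pytest.approx(expected, abs=1e-12)

    def test_class_swap_invariance(self, rng):
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(1, 50, size=4)
            a = balanced_accuracy(ConfusionCounts(tp, tn, fp, fn))
            b = balanced_accuracy(ConfusionCounts(tn, tp, fn, fp))
            assert a == pytest.approx(b)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy(ConfusionCounts(TP=0, TN=5, FP=5, FN=0))


class TestAssignLabels:
    def test_lookup_and_empty_cell_convention(self):
        train = _quant_ds(np.array([[0], [1]]), [5.0, 1.0])
        model = label_cells_quantitative(tabulate_cells(train, (0,)), 3.0)
        test = _quant_ds(np.array([[0], [1], [2]]), [0.0, 0.0, 0.0])
        high = assign_labels(model, test)
        # cell 0 high, cell 1 low, cell 2 unobserved in training -> low
        assert high.tolist() == [True, False, False]


class TestTStatistic:
    def test_equal_means_give_zero(self):
        assert t_statistic([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_computed_sqrt3(self):
        # pooled t for (2,4,6,8) vs (1,2,3,4): hand computation gives sqrt(3)
        assert t_statistic([2, 4, 6, 8], [1, 2, 3, 4]) == pytest.approx(
            math.sqrt(3.0), abs=1e-9
        )

    def test_matches_scipy_pooled_t(self, rng):
        for _ in range(50):
            hi = rng.standard_normal(int(rng.integers(2, 20)))
            lo = rng.standard_normal(int(rng.integers(2, 20)))
            expected = stats.ttest_ind(hi, lo, equal_var=True).statistic
            assert t_statistic(hi, lo) == pytest.approx(expected, abs=1e-9)

    def test_empty_group_gives_zero(self):
        assert t_statistic([], [1.0, 2.0]) == 0.0
        assert t_statistic([1.0, 2.0], []) == 0.0

    def test_antisymmetry(self, rng):
        hi = rng.standard_normal(8)
        lo = rng.standard_normal(5)
        assert t_statistic(hi, lo) == pytest.approx(-t_statistic(lo, hi), abs=1e-12)

    def test_zero_variance_separated_groups_get_sentinel(self):
        t = t_statistic([2.0, 2.0], [1.0, 1.0])
        assert t == np.finfo(np.float64).max


class TestAffineInvariance:
    def test_labels_and_t_invariant_under_affine_trait_transform(self, rng):
        for _ in range(100):
            n = int(rng.integers(20, 60))
            ds = random_dataset(rng, n, 3)
            a, b = rng.normal(), rng.uniform(0.1, 5)
            ds2 = ds.with_trait(a + b * ds.trait)
            idx = (0, 1)
            m1 = label_cells_quantitative(tabulate_cells(ds, idx), ds.trait.mean())
            m2 = label_cells_quantitative(tabulate_cells(ds2, idx), ds2.trait.mean())
            assert m1.labels == m2.labels
            hi = assign_labels(m1, ds)
            t1 = t_statistic(ds.trait[hi], ds.trait[~hi])
            t2 = t_statistic(ds2.trait[hi], ds2.trait[~hi])
            assert t1 == pytest.approx(t2, abs=1e-9)
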