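"""Naive reference implementation of the cross-validated exhaustive search.

Deliberately plain: dictionaries, per-sample loops, and scipy's t-test,
with no caching or vectorization, so it can serve as an independent oracle
for the bincount-based engine in ``qmdr.search``.
"""

import itertools

import numpy as np
from scipy import stats


def _pooled_t(high_vals, low_vals):
    if len(high_vals) == 0 or len(low_vals) == 0:
        return 0.0
    t = stats.ttest_ind(high_vals, low_vals, equal_var=True).statistic
    return float(t)


def _fit_cells_quantitative(geno, y, train_idx, combo):
    cells = {}
    for i in train_idx:
        key = tuple(int(geno[i, j]) for j in combo)
        cells.setdefault(key, []).append(float(y[i]))
    overall = float(np.mean([y[i] for i in train_idx]))
    high = {c for c, vals in cells.items() if np.mean(vals) > overall}
    return high


def _fit_cells_binary(geno, y, train_idx, combo):
    cells = {}
    for i in train_idx:
        key = tuple(int(geno[i, j]) for j in combo)
        cases, ctrls = cells.setdefault(key, [0, 0])
        cells[key] = [cases + (y[i] == 1), ctrls + (y[i] == 0)]
    n_case = sum(1 for i in train_idx if y[i] == 1)
    n_ctrl = len(train_idx) - n_case
    high = set()
    for c, (cases, ctrls) in cells.items():
        if ctrls == 0:
            if cases > 0:
                high.add(c)
        elif cases / ctrls > n_case / n_ctrl:
            high.add(c)
    return high


def _labels(geno, idx, combo, high):
    return np.array(
        [tuple(int(geno[i, j]) for j in combo) in high for i in idx], dtype=bool
    )


def _train_score(geno, y, train_idx, combo, binary):
    if binary:
        high_cells = _fit_cells_binary(geno, y, train_idx, combo)
        pred = _labels(geno, train_idx, combo, high_cells)
        truth = np.array([y[i] == 1 for i in train_idx])
        sens = np.sum(pred & truth) / np.sum(truth)
        spec = np.sum(~pred & ~truth) / np.sum(~truth)
        return 0.5 * (sens + spec), high_cells
    high_cells = _fit_cells_quantitative(geno, y, train_idx, combo)
    lab = _labels(geno, train_idx, combo, high_cells)
    yt = np.array([y[i] for i in train_idx])
    return _pooled_t(yt[lab], yt[~lab]), high_cells


def naive_exhaustive_order_k(dataset, k, folds):
    """Fold winners, training scores and pooled testing score, the slow way."""
    geno, y = dataset.genotypes, dataset.trait
    binary = dataset.trait_kind == "binary"
    n = dataset.n_samples
    winners, train_scores = [], []
    pooled = np.zeros(n, dtype=bool)
    for f in range(1, folds.n_folds + 1):
        train_idx = folds.train_indices(f)
        test_idx = folds.test_indices(f)
        best, best_score, best_high = None, -np.inf, None
        for combo in itertools.combinations(range(dataset.n_snps), k):
            score, high_cells = _train_score(geno, y, train_idx, combo, binary)
            if score > best_score:
                best, best_score, best_high = combo, score, high_cells
        winners.append(best)
        train_scores.append(best_score)
        pooled[test_idx] = _labels(geno, test_idx, best, best_high)
    if binary:
        truth = y.astype(bool)
        sens = np.sum(pooled & truth) / np.sum(truth)
        spec = np.sum(~pooled & ~truth) / np.sum(~truth)
        pooled_score = 0.5 * (sens + spec)
    else:
        pooled_score = _pooled_t(y[pooled], y[~pooled])
    return winners, train_scores, pooled_score
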