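"""Exhaustive k-way interaction search under cross-validation.

For each CV fold, every one of the C(m, k) candidate SNP subsets is scored on
the 9/10 training split (training T-statistic for a quantitative trait,
training balanced accuracy for a binary trait); the fold's best candidate then
labels the held-out samples high/low.  Pooling the held-out labels over all
folds yields one testing score per interaction order, and the number of folds
in which the modal candidate won is the cross-validation consistency (CVC).
The overall best model maximizes the pooled testing score, with CVC, then
parsimony (smaller order), then lexicographic SNP order as tie-breaks.

The per-fold scan is fully vectorized: each candidate's k-SNP genotype is
packed into a base-3 cell code, and per-fold per-cell counts / trait sums /
sums of squares for *all* candidates are accumulated with a handful of
``bincount`` calls, so a 10-fold exhaustive scan of hundreds of candidates
takes milliseconds.  Candidates are processed in blocks to bound memory at
large C(m, k).
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .data import Dataset, FoldAssignment, make_folds
from .induction import (
    T_SENTINEL,
    ConfusionCounts,
    InductionModel,
    assign_labels,
    balanced_accuracy,
    label_cells_binary,
    label_cells_quantitative,
    t_statistic,
    tabulate_cells,
)

__all__ = [
    "CandidateModel",
    "FoldResult",
    "CVSummary",
    "BestModel",
    "score_training",
    "exhaustive_order_k",
    "pool_testing_score",
    "select_overall_best",
    "QMDR",
    "MDR",
]

# candidate block size bound: F * block * 3^k cells kept in memory at once
_MAX_CELLS_PER_BLOCK = 4_000_000


@dataclass(frozen=True)
class CandidateModel:
    """An order-k SNP subset, indices strictly increasing."""

    snp_indices: tuple[int, ...]

    def __post_init__(self):
        idx = tuple(int(i) for i in self.snp_indices)
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("snp_indices must be strictly increasing")
        object.__setattr__(self, "snp_indices", idx)

    @property
    def order(self) -> int:
        return len(self.snp_indices)


@dataclass
class FoldResult:
    fold_id: int
    best_model: tuple[int, ...]
    training_score: float
    test_indices: np.ndarray
    testing_high: np.ndarray  # bool, aligned with test_indices


@dataclass
class CVSummary:
    """Outcome of the exhaustive order-k search over all CV folds."""

    order: int
    fold_results: list[FoldResult]
    pooled_testing_score: float
    cvc: int
    modal_model: tuple[int, ...]
    n_candidates: int


@dataclass(frozen=True)
class BestModel:
    snp_indices: tuple[int, ...]
    order: int
    pooled_testing_score: float
    cvc: int


def _cell_codes(genotypes: np.ndarray, combos: np.ndarray) -> np.ndarray:
    """Base-3 multilocus cell code for every (sample, candidate) pair."""
    n = genotypes.shape[0]
    k = combos.shape[1]
    codes = np.zeros((n, combos.shape[0]), dtype=np.int64)
    for j in range(k):
        codes *= 3
        codes += genotypes[:, combos[:, j]]
    return codes


def _fold_cell_tables(codes, fold0, n_folds, n_cells, weights=None):
    """(F, C, n_cells) per-fold per-candidate per-cell accumulations."""
    n, C = codes.shape
    idx = (fold0[:, None] * C + np.arange(C)[None, :]) * n_cells + codes
    w = None if weights is None else np.repeat(weights, C)
    out = np.bincount(idx.ravel(), weights=w, minlength=n_folds * C * n_cells)
    return out.reshape(n_folds, C, n_cells)


def _training_t_scores(tr_counts, tr_sums, tr_ss, n_tr, ysum_tr, yss_tr):
    """Training pooled t for every (fold, candidate); returns (t, high)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        cell_mean = np.where(tr_counts > 0, tr_sums / np.maximum(tr_counts, 1), -np.inf)
        mean_tr = (ysum_tr / n_tr)[:, None, None]
        high = cell_mean > mean_tr

        nh = np.einsum("fcs,fcs->fc", tr_counts, high)
        sh = np.einsum("fcs,fcs->fc", tr_sums, high)
        ssh = np.einsum("fcs,fcs->fc", tr_ss, high)
        nl = n_tr[:, None] - nh
        sl = ysum_tr[:, None] - sh
        ssl = yss_tr[:, None] - ssh

        mh = sh / np.maximum(nh, 1)
        ml = sl / np.maximum(nl, 1)
        ss = np.maximum(ssh - nh * mh * mh, 0.0) + np.maximum(ssl - nl * ml * ml, 0.0)
        df = (n_tr - 2)[:, None]
        sp2 = ss / df
        t = (mh - ml) / np.sqrt(sp2 * (1.0 / np.maximum(nh, 1) + 1.0 / np.maximum(nl, 1)))
    # degenerate conventions, identical to induction.t_statistic
    zero_var = ss <= 1e-12 * np.maximum(yss_tr[:, None], 1.0)
    t = np.where(zero_var & (mh > ml), T_SENTINEL, t)
    t = np.where(zero_var & (mh <= ml), np.where(mh < ml, -T_SENTINEL, 0.0), t)
    t = np.where((nh == 0) | (nl == 0), 0.0, t)
    return t, high


def _training_ba_scores(tr_counts, tr_cases, n_case_tr, n_ctrl_tr):
    """Training balanced accuracy for every (fold, candidate); returns (ba, high)."""
    if (n_case_tr == 0).any() or (n_ctrl_tr == 0).any():
        raise ValueError("a CV training split lost one of the two classes")
    tr_ctrl = tr_counts - tr_cases
    # exact integer comparison of cases/controls > R = N_case/N_ctrl
    high = (tr_cases * n_ctrl_tr[:, None, None] > tr_ctrl * n_case_tr[:, None, None]) & (
        tr_counts > 0
    )
    tp = np.einsum("fcs,fcs->fc", tr_cases, high)
    fp = np.einsum("fcs,fcs->fc", tr_ctrl, high)
    tn = n_ctrl_tr[:, None] - fp
    ba = 0.5 * (tp / n_case_tr[:, None] + tn / n_ctrl_tr[:, None])
    return ba, high


def exhaustive_order_k(
    dataset: Dataset, k: int, folds: FoldAssignment
) -> CVSummary:
    """Evaluate all C(m, k) order-k candidates under F-fold cross-validation."""
    m = dataset.n_snps
    if k < 1 or k > m:
        raise ValueError(f"order {k} infeasible with {m} SNPs")
    n = dataset.n_samples
    if folds.fold_id.shape[0] != n:
        raise ValueError("fold assignment does not match the dataset")
    F = folds.n_folds
    binary = dataset.trait_kind == "binary"
    geno = dataset.genotypes.astype(np.int64)
    y = dataset.trait.astype(np.float64)
    fold0 = folds.fold_id - 1
    fold_sizes = np.bincount(fold0, minlength=F).astype(np.int64)
    n_tr = (n - fold_sizes).astype(np.float64)
    n_cells = 3**k

    fold_ysum = np.bincount(fold0, weights=y, minlength=F)
    fold_yss = np.bincount(fold0, weights=y * y, minlength=F)
    ysum_tr = y.sum() - fold_ysum
    yss_tr = (y * y).sum() - fold_yss
    if binary:
        n_case_tr = y.sum() - fold_ysum  # y is 0/1
        n_ctrl_tr = n_tr - n_case_tr

    all_combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(m), k)),
        dtype=np.int64,
    ).reshape(-1, k)
    n_candidates = all_combos.shape[0]
    block = max(1, _MAX_CELLS_PER_BLOCK // (F * n_cells))

    best_score = np.full(F, -np.inf)
    best_idx = np.zeros(F, dtype=np.int64)
    for start in range(0, n_candidates, block):
        combos = all_combos[start : start + block]
        codes = _cell_codes(geno, combos)
        counts = _fold_cell_tables(codes, fold0, F, n_cells).astype(np.float64)
        tr_counts = counts.sum(axis=0) - counts
        if binary:
            cases = _fold_cell_tables(codes, fold0, F, n_cells, weights=y)
            tr_cases = cases.sum(axis=0) - cases
            scores, _ = _training_ba_scores(tr_counts, tr_cases, n_case_tr, n_ctrl_tr)
        else:
            sums = _fold_cell_tables(codes, fold0, F, n_cells, weights=y)
            ss = _fold_cell_tables(codes, fold0, F, n_cells, weights=y * y)
            tr_sums = sums.sum(axis=0) - sums
            tr_ss = ss.sum(axis=0) - ss
            scores, _ = _training_t_scores(tr_counts, tr_sums, tr_ss, n_tr, ysum_tr, yss_tr)
        blk_best = np.argmax(scores, axis=1)  # first max -> lexicographic tie-break
        blk_score = scores[np.arange(F), blk_best]
        improve = blk_score > best_score  # strict: earlier block wins ties
        best_score = np.where(improve, blk_score, best_score)
        best_idx = np.where(improve, start + blk_best, best_idx)

    # second pass: recompute cell labels for the (at most F distinct) winners
    winner_ids, inverse = np.unique(best_idx, return_inverse=True)
    combos = all_combos[winner_ids]
    codes = _cell_codes(geno, combos)
    counts = _fold_cell_tables(codes, fold0, F, n_cells).astype(np.float64)
    tr_counts = counts.sum(axis=0) - counts
    if binary:
        cases = _fold_cell_tables(codes, fold0, F, n_cells, weights=y)
        tr_cases = cases.sum(axis=0) - cases
        _, high = _training_ba_scores(tr_counts, tr_cases, n_case_tr, n_ctrl_tr)
    else:
        sums = _fold_cell_tables(codes, fold0, F, n_cells, weights=y)
        ss = _fold_cell_tables(codes, fold0, F, n_cells, weights=y * y)
        tr_sums = sums.sum(axis=0) - sums
        tr_ss = ss.sum(axis=0) - ss
        _, high = _training_t_scores(tr_counts, tr_sums, tr_ss, n_tr, ysum_tr, yss_tr)

    fold_results = []
    pooled_high = np.zeros(n, dtype=bool)
    for f in range(F):
        w = inverse[f]
        test_idx = np.flatnonzero(fold0 == f)
        lab = high[f, w, codes[test_idx, w]]
        pooled_high[test_idx] = lab
        fold_results.append(
            FoldResult(
                fold_id=f + 1,
                best_model=tuple(int(i) for i in all_combos[best_idx[f]]),
                training_score=float(best_score[f]),
                test_indices=test_idx,
                testing_high=lab,
            )
        )

    pooled = pool_testing_score(fold_results, dataset)
    tally = Counter(fr.best_model for fr in fold_results)
    cvc = max(tally.values())
    modal = min(model for model, c in tally.items() if c == cvc)
    return CVSummary(
        order=k,
        fold_results=fold_results,
        pooled_testing_score=pooled,
        cvc=cvc,
        modal_model=modal,
        n_candidates=n_candidates,
    )


def pool_testing_score(fold_results, dataset: Dataset) -> float:
    """One statistic over all held-out samples, each labeled by the model
    trained without it: pooled t (quantitative) or balanced accuracy (binary)."""
    n = dataset.n_samples
    high = np.zeros(n, dtype=bool)
    seen = np.zeros(n, dtype=bool)
    for fr in fold_results:
        if seen[fr.test_indices].any():
            raise ValueError("a sample appears in more than one testing fold")
        seen[fr.test_indices] = True
        high[fr.test_indices] = fr.testing_high
    if not seen.all():
        raise ValueError("every sample must appear in exactly one testing fold")
    y = dataset.trait
    if dataset.trait_kind == "binary":
        truth = y.astype(bool)
        c = ConfusionCounts(
            TP=int(np.sum(truth & high)),
            TN=int(np.sum(~truth & ~high)),
            FP=int(np.sum(~truth & high)),
            FN=int(np.sum(truth & ~high)),
        )
        return balanced_accuracy(c)
    return t_statistic(y[high], y[~high])


def score_training(dataset: Dataset, model: CandidateModel | tuple, training_subset) -> float:
    """Training score of one candidate on one training subset (plain path).

    Quantitative: label cells against the training overall mean, pooled t
    between high and low training samples.  Binary: balanced accuracy of the
    high(=case)/low(=control) prediction on the training samples.
    """
    idx = model.snp_indices if isinstance(model, CandidateModel) else tuple(model)
    training_subset = np.asarray(training_subset)
    table = tabulate_cells(dataset, idx, training_subset)
    y = dataset.trait[training_subset]
    if dataset.trait_kind == "binary":
        n_case = int(y.sum())
        n_ctrl = y.size - n_case
        if n_case == 0 or n_ctrl == 0:
            raise ValueError("training subset must contain both classes")
        fitted = label_cells_binary(table, n_case / n_ctrl)
        high = assign_labels(fitted, dataset, training_subset)
        truth = y.astype(bool)
        return balanced_accuracy(
            ConfusionCounts(
                TP=int(np.sum(truth & high)),
                TN=int(np.sum(~truth & ~high)),
                FP=int(np.sum(~truth & high)),
                FN=int(np.sum(truth & ~high)),
            )
        )
    fitted = label_cells_quantitative(table, float(y.mean()))
    high = assign_labels(fitted, dataset, training_subset)
    return t_statistic(y[high], y[~high])


def select_overall_best(summaries) -> BestModel:
    """Pick the overall model: max pooled testing score, then max CVC, then
    the more parsimonious order, then lexicographic SNP tuple."""
    summaries = list(summaries)
    if not summaries:
        raise ValueError("need at least one per-order summary")
    best = min(
        summaries,
        key=lambda s: (-s.pooled_testing_score, -s.cvc, s.order, s.modal_model),
    )
    return BestModel(
        snp_indices=best.modal_model,
        order=best.order,
        pooled_testing_score=best.pooled_testing_score,
        cvc=best.cvc,
    )


class _BaseInteractionSearchCV(BaseEstimator, TransformerMixin):
    """Shared fit machinery for the QMDR / MDR estimators."""

    _trait_kind: str

    def __init__(self, min_order=1, max_order=2, n_folds=10, random_state=None):
        self.min_order = min_order
        self.max_order = max_order
        self.n_folds = n_folds
        self.random_state = random_state

    def _validate(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x SNPs)")
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        if X.shape[0] < 2 * self.n_folds:
            raise ValueError(
                f"need at least {2 * self.n_folds} samples for {self.n_folds}-fold CV"
            )
        if not (1 <= self.min_order <= self.max_order <= X.shape[1]):
            raise ValueError("require 1 <= min_order <= max_order <= n_snps")
        names = tuple(f"SNP{i + 1}" for i in range(X.shape[1]))
        return Dataset(X, y, names, self._trait_kind)

    def fit(self, X, y):
        """Run the exhaustive CV search over all orders and select the best model."""
        dataset = self._validate(X, y)
        folds = make_folds(dataset.n_samples, self.n_folds, seed=self.random_state)
        self.summaries_ = {
            k: exhaustive_order_k(dataset, k, folds)
            for k in range(self.min_order, self.max_order + 1)
        }
        best = select_overall_best(self.summaries_.values())
        self.best_model_ = best
        self.best_snps_ = best.snp_indices
        self.best_order_ = best.order
        self.best_score_ = best.pooled_testing_score
        self.cvc_ = best.cvc
        # final high/low attribute: the selected SNP set refit on all samples
        table = tabulate_cells(dataset, best.snp_indices)
        if self._trait_kind == "binary":
            n_case = int(dataset.trait.sum())
            self.induction_model_ = label_cells_binary(
                table, n_case / (dataset.n_samples - n_case)
            )
        else:
            self.induction_model_ = label_cells_quantitative(
                table, float(dataset.trait.mean())
            )
        self.n_features_in_ = dataset.n_snps
        return self

    def transform(self, X):
        """Map genotypes to the constructed binary attribute (1 = high)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "induction_model_")
        X = np.asarray(X)
        ds = Dataset(
            X,
            np.zeros(X.shape[0]),
            tuple(f"SNP{i + 1}" for i in range(X.shape[1])),
            "quantitative",
        )
        return assign_labels(self.induction_model_, ds).astype(np.int64)[:, None]


class QMDR(_BaseInteractionSearchCV):
    """Quantitative-trait MDR with T-statistic scoring.

    Exhaustively searches SNP subsets of each order in
    ``min_order..max_order`` under ``n_folds``-fold CV, scoring candidates by
    the pooled two-sample T-statistic between the high- and low-mean genotype
    groups, and selects the model with the maximum pooled testing score.

    Attributes (after ``fit``): ``best_snps_``, ``best_order_``,
    ``best_score_`` (pooled testing T), ``cvc_``, ``summaries_`` (per-order
    :class:`CVSummary`), ``induction_model_`` (full-data high/low labeling).
    """

    _trait_kind = "quantitative"

    def score(self, X, y):
        """Pooled t between high/low groups of the fitted attribute on (X, y)."""
        high = self.transform(X).ravel().astype(bool)
        y = np.asarray(y, dtype=np.float64)
        return t_statistic(y[high], y[~high])


class MDR(_BaseInteractionSearchCV):
    """Binary-trait MDR with balanced-accuracy scoring.

    The classical case/control variant: cells are labeled high when their
    case:control ratio exceeds the overall ratio, candidates are ranked by
    training balanced accuracy, and the overall model maximizes the pooled
    testing balanced accuracy.
    """

    _trait_kind = "binary"

    def predict(self, X):
        """Predict case (1) for samples in high-risk cells, control (0) otherwise."""
        return self.transform(X).ravel()

    def score(self, X, y):
        """Balanced accuracy of the high-risk prediction on (X, y)."""
        pred = self.predict(X).astype(bool)
        truth = np.asarray(y).astype(bool)
        return balanced_accuracy(
            ConfusionCounts(
                TP=int(np.sum(truth & pred)),
                TN=int(np.sum(~truth & ~pred)),
                FP=int(np.sum(~truth & pred)),
                FN=int(np.sum(truth & ~pred)),
            )
        )
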