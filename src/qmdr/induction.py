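"""Constructive induction: collapse a k-SNP genotype table to one high/low attribute.

For a chosen set of k SNPs, each of the up-to-3^k multilocus genotype cells is
labeled *high* or *low* by comparing a cell summary against a whole-training-set
threshold: the case:control ratio R for a binary trait, or the overall trait
mean for a quantitative trait.  The resulting two-level attribute is scored
with balanced accuracy (binary) or a pooled two-sample T-statistic
(quantitative).

These routines are the plain, readable implementations used for single models
and small analyses; the exhaustive cross-validated search in
:mod:`qmdr.search` uses an equivalent vectorized engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellStats",
    "CellTable",
    "ConfusionCounts",
    "InductionModel",
    "tabulate_cells",
    "label_cells_binary",
    "label_cells_quantitative",
    "balanced_accuracy",
    "assign_labels",
    "t_statistic",
    "T_SENTINEL",
]

HIGH = "high"
LOW = "low"
EMPTY = "empty"

# Score reported when the two groups have different means but zero pooled
# variance (a perfectly separating attribute): the largest representable
# finite score, so ranking stays total.
T_SENTINEL = float(np.finfo(np.float64).max)


@dataclass
class CellStats:
    """Per-genotype-cell summaries over a training subset."""

    n_obs: int = 0
    n_cases: int = 0
    n_controls: int = 0
    trait_sum: float = 0.0

    @property
    def trait_mean(self) -> float:
        if self.n_obs == 0:
            raise ValueError("empty cell has no trait mean")
        return self.trait_sum / self.n_obs


@dataclass
class CellTable:
    """Contingency table over the multilocus genotypes of k chosen SNPs."""

    snp_indices: tuple[int, ...]
    cells: dict[tuple[int, ...], CellStats]
    n_samples: int

    @property
    def order(self) -> int:
        return len(self.snp_indices)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int


@dataclass
class InductionModel:
    """A fitted high/low labeling of genotype cells for one SNP set.

    ``labels`` maps every training-observed cell to "high" or "low";
    unobserved cells are implicitly "empty" and are treated as low when new
    samples fall into them.  ``threshold`` is the overall case:control ratio
    (binary mode) or the overall training-set trait mean (quantitative mode).
    """

    snp_indices: tuple[int, ...]
    labels: dict[tuple[int, ...], str]
    threshold: float
    mode: str
    high_cells: frozenset = field(init=False)

    def __post_init__(self):
        self.high_cells = frozenset(c for c, l in self.labels.items() if l == HIGH)

    def label(self, cell: tuple[int, ...]) -> str:
        return self.labels.get(tuple(cell), EMPTY)


def tabulate_cells(dataset, snp_indices, sample_subset=None) -> CellTable:
    """Count samples (and accumulate traits) per multilocus genotype cell."""
    snp_indices = tuple(int(i) for i in snp_indices)
    if len(snp_indices) < 1:
        raise ValueError("need at least one SNP")
    if len(snp_indices) > dataset.n_snps:
        raise ValueError("interaction order exceeds the number of SNPs")
    if sample_subset is None:
        sample_subset = np.arange(dataset.n_samples)
    sample_subset = np.asarray(sample_subset)
    if sample_subset.size == 0:
        raise ValueError("sample subset is empty")
    binary = dataset.trait_kind == "binary"
    cells: dict[tuple[int, ...], CellStats] = {}
    geno = dataset.genotypes[np.ix_(sample_subset, snp_indices)]
    trait = dataset.trait[sample_subset]
    for row, y in zip(geno, trait):
        key = tuple(int(v) for v in row)
        st = cells.setdefault(key, CellStats())
        st.n_obs += 1
        if binary:
            if y == 1:
                st.n_cases += 1
            else:
                st.n_controls += 1
        else:
            st.trait_sum += float(y)
    return CellTable(snp_indices, cells, int(sample_subset.size))


def label_cells_binary(table: CellTable, R: float) -> InductionModel:
    """Label each cell high when its case:control ratio strictly exceeds R.

    Ties go low.  A cell with cases but zero controls has infinite ratio and
    is high.  R is the whole-training-set case:control ratio.
    """
    if not np.isfinite(R) or R <= 0:
        raise ValueError("case:control ratio R must be finite and positive")
    labels = {}
    for cell, st in table.cells.items():
        if st.n_controls == 0:
            labels[cell] = HIGH if st.n_cases > 0 else LOW
        else:
            labels[cell] = HIGH if st.n_cases / st.n_controls > R else LOW
    return InductionModel(table.snp_indices, labels, float(R), "binary")


def label_cells_quantitative(table: CellTable, overall_mean: float) -> InductionModel:
    """Label each cell high when its trait mean strictly exceeds the overall mean."""
    labels = {
        cell: (HIGH if st.trait_mean > overall_mean else LOW)
        for cell, st in table.cells.items()
    }
    return InductionModel(table.snp_indices, labels, float(overall_mean), "quantitative")


def balanced_accuracy(c: ConfusionCounts) -> float:
    """Arithmetic mean of sensitivity and specificity."""
    if c.TP + c.FN == 0 or c.TN + c.FP == 0:
        raise ValueError("balanced accuracy requires both classes among scored samples")
    return 0.5 * (c.TP / (c.TP + c.FN) + c.TN / (c.TN + c.FP))


def assign_labels(model: InductionModel, dataset, sample_subset=None) -> np.ndarray:
    """Map samples through their genotype cell's label.

    Returns a boolean vector (True = high).  Samples whose cell was
    unobserved in training are labeled low.
    """
    if sample_subset is None:
        sample_subset = np.arange(dataset.n_samples)
    sample_subset = np.asarray(sample_subset)
    geno = dataset.genotypes[np.ix_(sample_subset, np.asarray(model.snp_indices))]
    high = model.high_cells
    return np.fromiter(
        (tuple(int(v) for v in row) in high for row in geno),
        dtype=bool,
        count=sample_subset.size,
    )


def t_statistic(high_values, low_values) -> float:
    """Pooled-variance two-sample t between high and low groups, high minus low.

    Degenerate conventions keep the search total and rank-stable:

    * either group empty -> 0 (the attribute has no discriminating power);
    * zero pooled variance with equal means -> 0;
    * zero pooled variance with unequal means -> the largest finite score.
    """
    hi = np.asarray(high_values, dtype=np.float64)
    lo = np.asarray(low_values, dtype=np.float64)
    nh, nl = hi.size, lo.size
    if nh == 0 or nl == 0:
        return 0.0
    mh, ml = hi.mean(), lo.mean()
    ss = np.sum((hi - mh) ** 2) + np.sum((lo - ml) ** 2)
    df = nh + nl - 2
    if df <= 0 or ss == 0.0:
        if mh == ml:
            return 0.0
        return T_SENTINEL if mh > ml else -T_SENTINEL
    sp2 = ss / df
    return float((mh - ml) / np.sqrt(sp2 * (1.0 / nh + 1.0 / nl)))
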