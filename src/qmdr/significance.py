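"""Empirical-null and permutation significance for cross-validated testing scores.

Under the null (trait independent of all genotypes), the pooled testing
T-score of the best cross-validated model has an empirical distribution that
is nearly invariant to the SNP count, the sample size and the interaction
order, so a score archive simulated once can stand in for per-dataset
permutation testing.  This module builds, stores and queries such archives,
and also runs the full permutation test for comparison.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

from .data import Dataset, make_folds
from .search import exhaustive_order_k, select_overall_best
from .simulate import simulate_null_dataset

__all__ = [
    "NullDistribution",
    "build_null_distribution",
    "null_quantile",
    "empirical_pvalue",
    "permutation_test",
    "type_I_error",
    "load_packaged_null",
]


@dataclass
class NullDistribution:
    """Archive of null pooled testing scores, keyed by (m, n, order)."""

    scores: dict[tuple[int, int, int], np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for key, v in self.scores.items():
            v = np.asarray(v, dtype=np.float64)
            if not np.isfinite(v).all():
                raise ValueError(f"non-finite null scores under key {key}")
            clean[tuple(int(x) for x in key)] = v
        self.scores = clean

    def _lookup(self, m, n, order) -> np.ndarray:
        key = (int(m), int(n), int(order))
        if key not in self.scores:
            raise KeyError(
                f"no null scores for (m={m}, n={n}, order={order}); "
                f"available: {sorted(self.scores)}"
            )
        return self.scores[key]

    def save(self, path) -> None:
        """Write the archive as tab-delimited text with a metadata header."""
        with open(path, "w") as fh:
            fh.write("# qmdr-null-archive\tv1\n")
            for k, v in sorted(self.metadata.items()):
                fh.write(f"# {k}\t{v}\n")
            for (m, n, order), v in sorted(self.scores.items()):
                body = " ".join(format(x, ".5g") for x in v)
                fh.write(f"{m}\t{n}\t{order}\t{body}\n")

    @classmethod
    def load(cls, path_or_file) -> "NullDistribution":
        if hasattr(path_or_file, "read"):
            lines = path_or_file.read().splitlines()
        else:
            with open(path_or_file) as fh:
                lines = fh.read().splitlines()
        meta, scores = {}, {}
        for ln in lines:
            if not ln.strip():
                continue
            if ln.startswith("#"):
                parts = ln[1:].strip().split("\t", 1)
                if len(parts) == 2 and parts[0] != "qmdr-null-archive":
                    meta[parts[0]] = parts[1]
                continue
            m, n, order, body = ln.split("\t", 3)
            scores[(int(m), int(n), int(order))] = np.fromstring(body, sep=" ")
        return cls(scores, meta)


def build_null_distribution(
    m_list, n_list, orders, reps: int, seed=None
) -> NullDistribution:
    """Simulate ``reps`` independent null datasets per (m, n) and record the
    pooled testing score of the exhaustive search at each requested order.

    All orders are run on the same simulated datasets (one search per order),
    mirroring a single study that scans several interaction orders.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    orders = [int(k) for k in orders]
    scores = {
        (int(m), int(n), k): np.empty(reps) for m in m_list for n in n_list for k in orders
    }
    root = np.random.SeedSequence(seed)
    for m in m_list:
        if max(orders) > m:
            raise ValueError(f"order {max(orders)} infeasible with m={m} SNPs")
        for n in n_list:
            child = root.spawn(1)[0]
            rngs = child.spawn(reps)
            for r in range(reps):
                rng = np.random.default_rng(rngs[r])
                ds = simulate_null_dataset(int(n), int(m), rng)
                folds = make_folds(ds.n_samples, 10, seed=rng)
                for k in orders:
                    s = exhaustive_order_k(ds, k, folds)
                    scores[(int(m), int(n), k)][r] = s.pooled_testing_score
    return NullDistribution(
        scores,
        metadata={
            "seed": seed,
            "reps": reps,
            "maf_law": "Uniform(0.1,0.5)",
            "trait_law": "N(0,1)",
            "folds": 10,
        },
    )


def null_quantile(nd: NullDistribution, m, n, order, q: float) -> float:
    """Empirical quantile (linear interpolation) of the stored null scores."""
    if not 0 < q < 1:
        raise ValueError("q must lie strictly between 0 and 1")
    return float(np.quantile(nd._lookup(m, n, order), q))


def empirical_pvalue(score: float, nd: NullDistribution, m, n, order) -> float:
    """Add-one empirical p-value (r + 1) / (B + 1), r = #null scores >= score."""
    v = nd._lookup(m, n, order)
    if v.size < 19:
        raise ValueError("need at least 19 null scores for an empirical p-value")
    r = int(np.sum(v >= score))
    return (r + 1) / (v.size + 1)


def permutation_test(dataset: Dataset, orders, B: int, seed=None):
    """Permutation p-value for the overall best cross-validated model.

    The observed score is the pooled testing score of the overall best model
    over the requested orders.  Each of the B permutations shuffles the trait
    against the genotype rows and reruns the full search + CV + selection
    pipeline; p = (#permuted scores >= observed + 1) / (B + 1).

    Returns ``(pvalue, observed BestModel, permuted score vector)``.
    """
    if B < 19:
        raise ValueError("need at least 19 permutations")
    orders = [int(k) for k in orders]
    root = np.random.SeedSequence(seed)
    obs_seed, *perm_seeds = root.spawn(B + 1)
    folds = make_folds(dataset.n_samples, 10, seed=np.random.default_rng(obs_seed))
    observed = select_overall_best(
        exhaustive_order_k(dataset, k, folds) for k in orders
    )
    perm_scores = np.empty(B)
    for b, ss in enumerate(perm_seeds):
        rng = np.random.default_rng(ss)
        y_perm = rng.permutation(dataset.trait)
        ds = dataset.with_trait(y_perm)
        folds_b = make_folds(ds.n_samples, 10, seed=rng)
        best = select_overall_best(
            exhaustive_order_k(ds, k, folds_b) for k in orders
        )
        perm_scores[b] = best.pooled_testing_score
    r = int(np.sum(perm_scores >= observed.pooled_testing_score))
    return (r + 1) / (B + 1), observed, perm_scores


def type_I_error(
    nd_threshold: NullDistribution,
    nd_eval: NullDistribution,
    m: int,
    n: int,
    order: int,
    q: float = 0.95,
) -> float:
    """Fraction of evaluation-batch null scores exceeding the q-quantile
    threshold derived from an independent n=400 null batch with the same m
    and order."""
    threshold = null_quantile(nd_threshold, m, 400, order, q)
    v = nd_eval._lookup(m, n, order)
    return float(np.mean(v > threshold))


def load_packaged_null() -> NullDistribution:
    """Load the score archive shipped with the package (m=10, n=400,
    orders 2-4, 2000 replicates), for empirical p-values without re-simulation."""
    ref = importlib.resources.files("qmdr").joinpath("data/null_archive.tsv")
    with ref.open("r") as fh:
        return NullDistribution.load(fh)
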