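"""Experiment drivers: main-effect screening, residual adjustment, full
single-dataset analysis, and the two reproducible simulation studies
(null-score calibration and power/success-rate comparison)."""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .data import Dataset, make_folds, median_dichotomize, read_mdr_file
from .search import BestModel, exhaustive_order_k, select_overall_best
from .significance import (
    NullDistribution,
    build_null_distribution,
    empirical_pvalue,
    permutation_test,
    type_I_error,
)
from .simulate import generate_pure_epistasis_model, simulate_quantitative_dataset

__all__ = [
    "AnalysisReport",
    "screen_main_effects",
    "residualize",
    "run_analysis",
    "run_simulation_I",
    "run_simulation_II",
]

log = logging.getLogger("qmdr")


def screen_main_effects(dataset: Dataset, alpha: float = 0.05) -> list[int]:
    """One-way ANOVA F-test of the trait across each SNP's genotype groups;
    returns the indices of SNPs with p < alpha (a significant main effect)."""
    if dataset.trait_kind != "quantitative":
        raise ValueError("main-effect screening requires a quantitative trait")
    flagged = []
    y = dataset.trait
    for j in range(dataset.n_snps):
        g = dataset.genotypes[:, j]
        groups = [y[g == v] for v in (0, 1, 2) if np.any(g == v)]
        if len(groups) < 2:
            warnings.warn(
                f"SNP {dataset.snp_names[j]!r} has a single genotype class; skipped"
            )
            continue
        _, p = stats.f_oneway(*groups)
        if p < alpha:
            flagged.append(j)
    return flagged


def residualize(dataset: Dataset, flagged_snps) -> Dataset:
    """Replace the trait by residuals of an OLS fit on genotype-class
    indicators (two indicators per flagged SNP, genotype 0 as reference)."""
    flagged_snps = list(flagged_snps)
    if not flagged_snps:
        return dataset
    cols = [np.ones(dataset.n_samples)]
    for j in flagged_snps:
        g = dataset.genotypes[:, j]
        for v in (1, 2):
            ind = (g == v).astype(np.float64)
            if ind.sum() == 0:
                warnings.warn(
                    f"genotype {v} of SNP {dataset.snp_names[j]!r} unobserved; "
                    "indicator dropped"
                )
                continue
            cols.append(ind)
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, dataset.trait, rcond=None)
    resid = dataset.trait - X @ beta
    return dataset.with_trait(resid)


@dataclass
class AnalysisReport:
    """Results of one full QMDR/MDR analysis run."""

    per_order: dict[int, dict]
    best: BestModel
    best_snp_names: tuple[str, ...]
    empirical_p: float | None = None
    permutation_p: float | None = None
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_order": self.per_order,
            "best": {
                "snps": list(self.best_snp_names),
                "order": self.best.order,
                "testing_score": self.best.pooled_testing_score,
                "cvc": self.best.cvc,
            },
            "empirical_p": self.empirical_p,
            "permutation_p": self.permutation_p,
            "metadata": self.metadata,
        }

    def to_text(self) -> str:
        lines = ["QMDR analysis report", "===================="]
        for k, v in sorted(self.metadata.items()):
            lines.append(f"{k}: {v}")
        lines.append("")
        lines.append("order\tbest model\ttesting score\tCVC")
        for k, row in sorted(self.per_order.items()):
            lines.append(
                f"{k}\t{' & '.join(row['snps'])}\t{row['testing_score']:.4g}\t{row['cvc']}"
            )
        lines.append("")
        lines.append(
            f"overall best: {' & '.join(self.best_snp_names)} "
            f"(order {self.best.order}, testing score "
            f"{self.best.pooled_testing_score:.4g}, CVC {self.best.cvc})"
        )
        if self.empirical_p is not None:
            lines.append(f"empirical p-value: {self.empirical_p:.4g}")
        if self.permutation_p is not None:
            lines.append(f"permutation p-value: {self.permutation_p:.4g}")
        return "\n".join(lines) + "\n"


def _nearest_null_key(nd: NullDistribution, m: int, n: int, order: int):
    """Exact key if stored, else the nearest stored key at the same order
    (the null is close to invariant in m and n, which is what makes a
    precomputed archive reusable)."""
    key = (m, n, order)
    if key in nd.scores:
        return key
    same_order = [k for k in nd.scores if k[2] == order]
    if not same_order:
        raise KeyError(f"null archive has no scores for order {order}")
    return min(same_order, key=lambda k: (abs(k[1] - n), abs(k[0] - m)))


def run_analysis(
    source,
    min_order: int = 2,
    max_order: int = 4,
    n_folds: int = 10,
    seed=None,
    trait_kind: str = "quantitative",
    screen_alpha: float | None = None,
    null_archive: NullDistribution | None = None,
    permutations: int | None = None,
) -> AnalysisReport:
    """Full pipeline on one dataset: (optional) main-effect screen and
    residual adjustment, exhaustive CV search per order, overall model
    selection, and empirical and/or permutation p-values."""
    if isinstance(source, Dataset):
        dataset = source
        source_name = "<in-memory>"
    else:
        dataset = read_mdr_file(source, trait_kind)
        source_name = str(source)
    digest = hashlib.sha256(
        dataset.genotypes.tobytes() + np.asarray(dataset.trait).tobytes()
    ).hexdigest()[:12]

    screened = []
    if screen_alpha is not None:
        screened = screen_main_effects(dataset, screen_alpha)
        if screened:
            log.info(
                "screened main effects: %s",
                [dataset.snp_names[j] for j in screened],
            )
        dataset = residualize(dataset, screened)

    orders = range(min_order, max_order + 1)
    root = np.random.SeedSequence(seed)
    fold_seed, perm_seed = root.spawn(2)
    folds = make_folds(dataset.n_samples, n_folds, seed=np.random.default_rng(fold_seed))
    log.info("search seed: %s; orders %d-%d; %d folds", seed, min_order, max_order, n_folds)
    summaries = {k: exhaustive_order_k(dataset, k, folds) for k in orders}
    for k, s in summaries.items():
        log.info(
            "order %d: %d candidates, modal model %s, testing score %.4g, cvc %d",
            k, s.n_candidates, s.modal_model, s.pooled_testing_score, s.cvc,
        )
        for fr in s.fold_results:
            log.debug(
                "order %d fold %d winner %s (training score %.4g)",
                k, fr.fold_id, fr.best_model, fr.training_score,
            )
    best = select_overall_best(summaries.values())

    empirical_p = None
    if null_archive is not None:
        key = _nearest_null_key(
            null_archive, dataset.n_snps, dataset.n_samples, best.order
        )
        empirical_p = empirical_pvalue(
            best.pooled_testing_score, null_archive, *key
        )
    permutation_p = None
    if permutations:
        permutation_p, _, _ = permutation_test(
            dataset, list(orders), permutations,
            seed=int(perm_seed.generate_state(1)[0] % (2**31)),
        )

    per_order = {
        k: {
            "snps": [dataset.snp_names[j] for j in s.modal_model],
            "testing_score": s.pooled_testing_score,
            "cvc": s.cvc,
            "n_candidates": s.n_candidates,
        }
        for k, s in summaries.items()
    }
    return AnalysisReport(
        per_order=per_order,
        best=best,
        best_snp_names=tuple(dataset.snp_names[j] for j in best.snp_indices),
        empirical_p=empirical_p,
        permutation_p=permutation_p,
        metadata={
            "input": source_name,
            "input_digest": digest,
            "n_samples": dataset.n_samples,
            "n_snps": dataset.n_snps,
            "orders": f"{min_order}-{max_order}",
            "folds": n_folds,
            "seed": seed,
            "screened_snps": [dataset.snp_names[j] for j in screened],
        },
    )


def run_simulation_I(
    m_list=(10,),
    n_list=(200, 400),
    orders=(2, 3, 4),
    reps: int = 2000,
    seed=None,
    out_dir=None,
    threshold_reps: int | None = None,
):
    """Null-score calibration study: build the empirical null archive and a
    type-I-error table using 95th-quantile thresholds from an independent
    batch of n=400 null datasets.

    Returns ``(archive, threshold_archive, type-I DataFrame)``; if ``out_dir``
    is given, writes ``null_archive.tsv`` and ``type_I_error.tsv`` there.
    """
    root = np.random.SeedSequence(seed)
    main_seed, thr_seed = (int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(2))
    for m in m_list:
        for k in orders:
            from math import comb

            work = comb(m, k) * reps * 10
            if work > 5e8:
                warnings.warn(
                    f"(m={m}, order={k}, reps={reps}) implies ~{work:.2g} "
                    "candidate-fold evaluations; consider reducing reps"
                )
    nd = build_null_distribution(m_list, n_list, orders, reps, seed=main_seed)
    nd_thr = build_null_distribution(
        m_list, [400], orders, threshold_reps or reps, seed=thr_seed
    )
    rows = []
    for m in m_list:
        for k in orders:
            for n in n_list:
                rows.append(
                    {
                        "m": m,
                        "order": k,
                        "n": n,
                        "type_I_error": type_I_error(nd_thr, nd, m, n, k),
                    }
                )
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        nd.save(out / "null_archive.tsv")
        nd_thr.save(out / "null_archive_thresholds.tsv")
        table.to_csv(out / "type_I_error.tsv", sep="\t", index=False)
    return nd, nd_thr, table


def run_simulation_II(
    h2_list=(0.01, 0.02, 0.05, 0.1, 0.2, 0.3, 0.4),
    maf_list=(0.2, 0.4),
    n_list=(400, 800, 1600),
    models_per_cell: int = 5,
    reps_per_model: int = 100,
    m_noise: int = 18,
    orders=(1, 2, 3),
    seed=None,
    out_path=None,
) -> pd.DataFrame:
    """Power study: success rates of QMDR (continuous trait) versus binary
    MDR on the median-dichotomized trait, over purely epistatic two-locus
    models embedded among ``m_noise`` independent noise SNPs.

    Success for a dataset means the overall best model (over ``orders``) is
    exactly the functional SNP pair.  Returns a tidy DataFrame with columns
    n, h2, method, success_rate, reps.
    """
    orders = list(orders)
    root = np.random.SeedSequence(seed)
    records = {(n, h2, meth): [] for n in n_list for h2 in h2_list for meth in ("QMDR", "MDR")}
    for h2 in h2_list:
        for maf in maf_list:
            cell_seed = root.spawn(1)[0]
            model_seeds = cell_seed.spawn(models_per_cell)
            for ms in model_seeds:
                model = generate_pure_epistasis_model(
                    h2, maf, seed=np.random.default_rng(ms)
                )
                for n in n_list:
                    data_seeds = ms.spawn(reps_per_model)
                    for dsd in data_seeds:
                        rng = np.random.default_rng(dsd)
                        ds, truth = simulate_quantitative_dataset(
                            model, n, m_noise, seed=rng
                        )
                        folds = make_folds(n, 10, seed=rng)
                        best_q = select_overall_best(
                            exhaustive_order_k(ds, k, folds) for k in orders
                        )
                        records[(n, h2, "QMDR")].append(best_q.snp_indices == truth)
                        ds_bin = ds.with_trait(
                            median_dichotomize(ds.trait), "binary"
                        )
                        best_b = select_overall_best(
                            exhaustive_order_k(ds_bin, k, folds) for k in orders
                        )
                        records[(n, h2, "MDR")].append(best_b.snp_indices == truth)
    rows = [
        {
            "n": n,
            "h2": h2,
            "method": meth,
            "success_rate": float(np.mean(v)),
            "reps": len(v),
        }
        for (n, h2, meth), v in records.items()
    ]
    table = pd.DataFrame(rows).sort_values(["n", "h2", "method"]).reset_index(drop=True)
    if out_path is not None:
        table.to_csv(out_path, sep="\t", index=False)
    return table
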