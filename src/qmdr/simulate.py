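"""Synthetic genotype/trait generators.

Two study designs are covered:

* **Null calibration** — independent SNPs under Hardy-Weinberg equilibrium
  with minor allele frequencies drawn from Uniform(0.1, 0.5) and a standard
  normal trait independent of all genotypes, used to build the empirical null
  distribution of the cross-validated testing score.

* **Power / success-rate studies** — a pair of functional interacting SNPs
  with a *purely epistatic* 3x3 penetrance table (no marginal effects under
  HWE weights) embedded among independent noise SNPs; the quantitative trait
  is normal around the cell mean of the sample's two-locus genotype, with the
  noise variance set so the genetic variance fraction equals a target
  broad-sense heritability h2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Dataset

__all__ = [
    "PenetranceModel",
    "simulate_genotypes",
    "simulate_null_dataset",
    "generate_pure_epistasis_model",
    "simulate_quantitative_dataset",
    "success_rate",
]


def _hwe_weights(maf: float) -> np.ndarray:
    p = float(maf)
    return np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])


@dataclass(frozen=True)
class PenetranceModel:
    """A two-locus epistatic trait model.

    ``f[i, j]`` is the mean trait value for genotype (i, j) at the two
    functional loci (i, j = minor-allele counts 0/1/2).  Under HWE genotype
    frequencies at the shared ``maf``, the table has no marginal effects:
    every frequency-weighted row mean and column mean is equal, so neither
    locus alone predicts the trait.  The trait is Normal(f[i, j], noise_sd^2),
    and the broad-sense heritability Var_g / (Var_g + noise_sd^2) equals h2.
    """

    f: np.ndarray
    maf: float
    h2: float
    noise_sd: float

    def __post_init__(self):
        f = np.asarray(self.f, dtype=np.float64)
        if f.shape != (3, 3):
            raise ValueError("penetrance table must be 3x3")
        object.__setattr__(self, "f", f)

    def marginal_deviation(self) -> float:
        """Largest absolute deviation of any HWE-weighted row/column mean
        from the grand mean (0 for a purely epistatic model)."""
        w = _hwe_weights(self.maf)
        grand = w @ self.f @ w
        rows = self.f @ w
        cols = w @ self.f
        return float(max(np.abs(rows - grand).max(), np.abs(cols - grand).max()))

    def genetic_variance(self) -> float:
        w = _hwe_weights(self.maf)
        grand = w @ self.f @ w
        return float(np.outer(w, w).ravel() @ ((self.f - grand) ** 2).ravel())

    def achieved_h2(self) -> float:
        vg = self.genetic_variance()
        return vg / (vg + self.noise_sd**2)

    def to_text(self) -> str:
        lines = [f"# maf={self.maf!r}\th2={self.h2!r}\tnoise_sd={self.noise_sd!r}"]
        for row in self.f:
            lines.append("\t".join(format(v, ".12g") for v in row))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PenetranceModel":
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        meta = dict(
            item.split("=", 1) for item in lines[0].lstrip("# ").split("\t")
        )
        f = np.array([[float(v) for v in ln.split("\t")] for ln in lines[1:4]])
        return cls(
            f, float(meta["maf"]), float(meta["h2"]), float(meta["noise_sd"])
        )


def simulate_genotypes(n: int, m: int, maf_law=(0.1, 0.5), seed=None) -> np.ndarray:
    """Simulate an (n, m) genotype matrix of independent HWE SNPs.

    ``maf_law`` is either a fixed minor allele frequency or an (lo, hi) pair,
    in which case each SNP's MAF is drawn Uniform(lo, hi).  Each genotype is
    the sum of two independent Bernoulli(p) allele draws, i.e. genotype
    probabilities ((1-p)^2, 2p(1-p), p^2).
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be positive")
    rng = np.random.default_rng(seed)
    if np.isscalar(maf_law):
        maf = np.full(m, float(maf_law))
    else:
        lo, hi = maf_law
        maf = rng.uniform(lo, hi, size=m)
    if (maf <= 0).any() or (maf > 0.5).any():
        raise ValueError("minor allele frequencies must lie in (0, 0.5]")
    return rng.binomial(2, maf, size=(n, m)).astype(np.int8)


def simulate_null_dataset(n: int, m: int, seed=None) -> Dataset:
    """A dataset with no genotype-trait association: HWE SNPs with
    MAF ~ Uniform(0.1, 0.5) and an independent standard normal trait."""
    if n < 20:
        raise ValueError("need n >= 20 for 10-fold CV analyses")
    rng = np.random.default_rng(seed)
    geno = simulate_genotypes(n, m, (0.1, 0.5), rng)
    trait = rng.standard_normal(n)
    names = tuple(f"SNP{i + 1}" for i in range(m))
    return Dataset(geno, trait, names, "quantitative")


def generate_pure_epistasis_model(
    h2: float,
    maf: float,
    noise_sd_rule="match-h2",
    seed=None,
    max_tries: int = 100,
) -> PenetranceModel:
    """Draw a random purely epistatic penetrance table at a target heritability.

    A candidate 3x3 table of standard normal entries is projected onto the
    subspace with zero HWE-weighted row and column effects (alternating
    row/column centering, iterated to convergence), then rescaled so the
    HWE genetic variance matches the target heritability given the noise
    standard deviation.  With ``noise_sd_rule="match-h2"`` the noise SD is 1
    and Var_g = h2 / (1 - h2); a numeric rule fixes the noise SD instead.
    """
    if not 0 < h2 < 1:
        raise ValueError("h2 must lie in (0, 1)")
    if not 0 < maf <= 0.5:
        raise ValueError("maf must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    w = _hwe_weights(maf)
    noise_sd = 1.0 if noise_sd_rule == "match-h2" else float(noise_sd_rule)
    target_vg = h2 / (1 - h2) * noise_sd**2
    best_violation = np.inf
    for _ in range(max_tries):
        g = rng.standard_normal((3, 3))
        for _ in range(200):
            g = g - (g @ w)[:, None]  # remove weighted row means
            g = g - (w @ g)[None, :]  # remove weighted column means
            if max(np.abs(g @ w).max(), np.abs(w @ g).max()) < 1e-13:
                break
        vg = float(np.outer(w, w).ravel() @ (g**2).ravel())
        if vg < 1e-10:  # degenerate draw; resample
            continue
        f = g * np.sqrt(target_vg / vg)
        model = PenetranceModel(f, maf, h2, noise_sd)
        violation = model.marginal_deviation()
        if violation < 1e-6 and abs(model.achieved_h2() - h2) < 0.005:
            return model
        best_violation = min(best_violation, violation)
    raise RuntimeError(
        f"no valid purely epistatic model in {max_tries} tries "
        f"(best marginal deviation {best_violation:.3g})"
    )


def simulate_quantitative_dataset(
    model: PenetranceModel,
    n: int,
    m_noise: int = 18,
    noise_maf_law=(0.1, 0.5),
    seed=None,
):
    """Simulate a dataset with the model's functional SNP pair embedded among
    ``m_noise`` independent noise SNPs.

    The two functional loci are drawn at the model's MAF; the trait of a
    sample with functional genotype (i, j) is Normal(f[i, j], noise_sd^2).
    Functional columns are placed uniformly at random among all columns.

    Returns ``(dataset, functional_indices)`` where ``functional_indices`` is
    the sorted column pair carrying the signal (the ground truth).
    """
    if n < 20:
        raise ValueError("need n >= 20 for 10-fold CV analyses")
    rng = np.random.default_rng(seed)
    func = simulate_genotypes(n, 2, model.maf, rng)
    noise = (
        simulate_genotypes(n, m_noise, noise_maf_law, rng)
        if m_noise > 0
        else np.empty((n, 0), dtype=np.int8)
    )
    m = 2 + m_noise
    cols = rng.permutation(m)
    geno = np.empty((n, m), dtype=np.int8)
    geno[:, cols[:2]] = func
    geno[:, cols[2:]] = noise
    trait = model.f[func[:, 0], func[:, 1]] + model.noise_sd * rng.standard_normal(n)
    names = tuple(f"SNP{i + 1}" for i in range(m))
    truth = tuple(sorted(int(c) for c in cols[:2]))
    return Dataset(geno, trait, names, "quantitative"), truth


def success_rate(best_models, truth_pairs) -> float:
    """Fraction of datasets whose overall best model is exactly the functional
    pair (order 2, both SNPs, nothing else)."""
    best_models = list(best_models)
    truth_pairs = list(truth_pairs)
    if len(best_models) != len(truth_pairs):
        raise ValueError("one truth pair per result required")
    if not best_models:
        raise ValueError("need at least one result")
    hits = 0
    for best, truth in zip(best_models, truth_pairs):
        idx = tuple(best.snp_indices) if hasattr(best, "snp_indices") else tuple(best)
        hits += idx == tuple(sorted(truth))
    return hits / len(best_models)
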