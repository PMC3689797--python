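"""Genotype/trait containers, MDR flat-file I/O, fold partitioning, trait transforms.

The MDR flat-file convention is a tab-delimited text file with a header row:
one column per SNP (genotypes coded 0/1/2, the count of minor alleles) and a
final trait column (conventionally named ``Class``), either binary 0/1 or
real-valued.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "FoldAssignment",
    "read_mdr_file",
    "write_mdr_file",
    "make_folds",
    "median_dichotomize",
]

BINARY = "binary"
QUANTITATIVE = "quantitative"


@dataclass(frozen=True)
class Dataset:
    """An n-sample, m-SNP genotype matrix with a single trait.

    Parameters
    ----------
    genotypes : (n, m) integer array with entries in {0, 1, 2}
        Minor-allele counts.  Any consistent 3-level coding is acceptable;
        the algorithms only use categorical distinctness.
    trait : (n,) array
        Binary 0/1 or real-valued, according to ``trait_kind``.
    snp_names : sequence of m strings
    trait_kind : {"binary", "quantitative"}
    """

    genotypes: np.ndarray
    trait: np.ndarray
    snp_names: tuple[str, ...]
    trait_kind: str
    trait_name: str = field(default="Class")

    def __post_init__(self):
        g = np.asarray(self.genotypes)
        if g.ndim != 2 or g.shape[0] < 1:
            raise ValueError("genotypes must be a non-empty 2-D matrix")
        bad = ~np.isin(g, (0, 1, 2))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"genotype value {g[r, c]!r} at row {r}, column {c} "
                "is not one of 0/1/2 (missing values are not supported)"
            )
        y = np.asarray(self.trait)
        if y.ndim != 1 or y.shape[0] != g.shape[0]:
            raise ValueError("trait length must equal the number of genotype rows")
        if self.trait_kind not in (BINARY, QUANTITATIVE):
            raise ValueError(f"unknown trait_kind {self.trait_kind!r}")
        if self.trait_kind == BINARY:
            if not np.isin(y, (0, 1)).all():
                raise ValueError("binary trait must contain only 0/1 values")
            if len(np.unique(y)) < 2:
                raise ValueError("binary trait must contain both classes")
            y = y.astype(np.int64)
        else:
            y = y.astype(np.float64)
            if not np.isfinite(y).all():
                raise ValueError("quantitative trait must be finite")
        names = tuple(str(s) for s in self.snp_names)
        if len(names) != g.shape[1]:
            raise ValueError("snp_names length must equal the number of SNP columns")
        object.__setattr__(self, "genotypes", g.astype(np.int8))
        object.__setattr__(self, "trait", y)
        object.__setattr__(self, "snp_names", names)

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def with_trait(self, trait: np.ndarray, trait_kind: str | None = None) -> "Dataset":
        """A copy of this dataset with the trait replaced."""
        return Dataset(
            self.genotypes,
            np.asarray(trait),
            self.snp_names,
            self.trait_kind if trait_kind is None else trait_kind,
            self.trait_name,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return (
            np.array_equal(self.genotypes, other.genotypes)
            and np.allclose(self.trait, other.trait, rtol=0, atol=0)
            and self.snp_names == other.snp_names
            and self.trait_kind == other.trait_kind
        )


@dataclass(frozen=True)
class FoldAssignment:
    """A balanced partition of sample indices into F cross-validation folds.

    ``fold_id`` holds values in 1..F; fold sizes differ by at most one.
    """

    fold_id: np.ndarray
    n_folds: int

    def __post_init__(self):
        fid = np.asarray(self.fold_id, dtype=np.int64)
        if fid.ndim != 1:
            raise ValueError("fold_id must be 1-D")
        counts = np.bincount(fid, minlength=self.n_folds + 1)[1:]
        if counts.min() < 1:
            raise ValueError("every fold must be non-empty")
        if counts.max() - counts.min() > 1:
            raise ValueError("fold sizes must differ by at most 1")
        if fid.min() < 1 or fid.max() > self.n_folds:
            raise ValueError("fold labels must lie in 1..n_folds")
        object.__setattr__(self, "fold_id", fid)

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_id == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_id != fold)


def read_mdr_file(path, trait_kind: str = QUANTITATIVE) -> Dataset:
    """Read an MDR flat file (tab-delimited, header row, trait in last column)."""
    try:
        df = pd.read_csv(path, sep="\t", header=0, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # ragged rows and friends
        raise ValueError(f"could not parse {path} as a tab-delimited MDR file: {exc}") from exc
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least one SNP column and a trait column")
    if df.shape[0] < 1:
        raise ValueError(f"{path}: no data rows")
    geno = df.iloc[:, :-1]
    for col in geno.columns:
        vals = pd.to_numeric(geno[col], errors="coerce")
        bad = ~vals.isin((0, 1, 2)) | vals.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: genotype {geno[col].iloc[row]!r} in column {col!r}, "
                f"data row {row} is not 0/1/2"
            )
    trait_col = df.columns[-1]
    if trait_kind == BINARY:
        trait = pd.to_numeric(df[trait_col]).to_numpy(dtype=np.int64)
    else:
        trait = pd.to_numeric(df[trait_col]).to_numpy(dtype=np.float64)
    return Dataset(
        geno.to_numpy(dtype=np.int8),
        trait,
        tuple(str(c) for c in geno.columns),
        trait_kind,
        trait_name=str(trait_col),
    )


def write_mdr_file(dataset: Dataset, path) -> None:
    """Write a Dataset as an MDR flat file readable by :func:`read_mdr_file`.

    Quantitative traits are written with the shortest decimal representation
    that reproduces the float exactly, so read/write round-trips are the
    identity.
    """
    buf = io.StringIO()
    buf.write("\t".join(dataset.snp_names + (dataset.trait_name,)) + "\n")
    quantitative = dataset.trait_kind == QUANTITATIVE
    for row, y in zip(dataset.genotypes, dataset.trait):
        buf.write("\t".join(str(int(v)) for v in row))
        buf.write("\t" + (repr(float(y)) if quantitative else str(int(y))) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def make_folds(n: int, n_folds: int = 10, seed=None, stratify=None) -> FoldAssignment:
    """Assign n samples to ``n_folds`` balanced cross-validation folds.

    Plain seeded random assignment (shuffle, then round-robin fold labels).
    If ``stratify`` is given (a length-n label vector), the round-robin runs
    within each stratum so folds are balanced per stratum; off by default.
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n < n_folds:
        raise ValueError(f"cannot split {n} samples into {n_folds} folds")
    rng = np.random.default_rng(seed)
    fold_id = np.empty(n, dtype=np.int64)
    labels = np.tile(np.arange(1, n_folds + 1), n // n_folds + 1)
    if stratify is None:
        perm = rng.permutation(n)
        fold_id[perm] = labels[:n]
    else:
        stratify = np.asarray(stratify)
        offset = 0
        for s in np.unique(stratify):
            idx = np.flatnonzero(stratify == s)
            rng.shuffle(idx)
            # continue the round-robin across strata to keep global balance
            fold_id[idx] = 1 + (np.arange(offset, offset + idx.size) % n_folds)
            offset += idx.size
    return FoldAssignment(fold_id, n_folds)


def median_dichotomize(trait: np.ndarray) -> np.ndarray:
    """Split a quantitative trait at its median: strictly above -> 1, else 0.

    Ties at the median go to class 0, so the convention is deterministic.
    """
    y = np.asarray(trait, dtype=np.float64)
    if np.ptp(y) == 0:
        raise ValueError("constant trait cannot be dichotomized")
    return (y > np.median(y)).astype(np.int64)
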