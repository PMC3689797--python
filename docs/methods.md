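# Methods

## Constructive induction and scoring

For a candidate set of k SNPs (genotypes coded 0/1/2, no missing values),
each observed multilocus genotype cell is labeled by a strict comparison
against a whole-training-set threshold:

* binary trait: cell case:control ratio > R (the training-set ratio) → high;
  a cell with cases and no controls has infinite ratio and is high; exact
  ties are low. The comparison is implemented as the integer
  cross-multiplication `cases_cell · controls_total > cases_total ·
  controls_cell`, so it is exact.
* quantitative trait: cell trait mean > training-set mean → high; ties low.

Cells unobserved in training are *empty*; any sample falling into one at
prediction time is labeled low. This is the conservative choice: it keeps
every held-out sample scoreable and never promotes an unseen genotype to
high. On a 0/1 trait the quantitative rule reproduces the binary rule
exactly (cell mean > overall mean ⇔ case ratio > R), which the tests verify
exhaustively on random tables.

Scores: balanced accuracy for binary traits; for quantitative traits the
pooled-variance (equal-variance) two-sample t between the high and low
groups, signed high-minus-low. Pooled rather than Welch because the
classical two-sample setting is the natural reading and the asymptotic
normal null argument presumes it; the statistic's sampling law never enters
the procedure (only ranks and empirical quantiles do), so the choice is not
load-bearing. Degenerate cases are defined so that ranking stays total: an
empty group scores 0 (the attribute does not discriminate), zero pooled
variance with equal means scores 0, and zero pooled variance with distinct
means scores the largest finite float (a perfect separator must outrank
everything finite).

## Cross-validated search and selection

Samples are assigned to 10 folds by seeded random shuffling with round-robin
labels (sizes differ by at most one; no stratification by default — an
optional `stratify` argument exists). Within each fold all C(m, k) order-k
subsets are scored on the training 9/10; the winner (ties broken toward the
lexicographically smallest index tuple, for determinism) labels the held-out
tenth. The per-order testing score is computed once on the pooled held-out
labels of all 10 folds; the cross-validation consistency (CVC) is the modal
winner's fold count, and the reported model for an order is that modal
winner (the only single-model summary the 10 fold winners yield; modal-tie →
lexicographic). Overall selection: maximum testing score, then maximum CVC,
then the more parsimonious order, then lexicographic SNP tuple.

The training threshold (overall mean or R) is always computed on the fold's
training samples only, so no information from the held-out fold leaks into
its labels.

The engine packs each candidate's k genotypes into a base-3 cell code and
accumulates per-fold, per-candidate, per-cell counts, trait sums and sums of
squares with a handful of `bincount` calls; per-fold training statistics are
obtained by subtracting each fold's table from the total. Candidates are
processed in blocks bounded to ~4M cells to cap memory. Sums of squared
deviations computed as `Σy² − n·ȳ²` are clipped at zero, and "zero variance"
means below 1e-12 of the total sum of squares. An independent naive
implementation (dictionaries, loops, scipy's t-test) reproduces the engine's
fold winners and scores to 1e-9 in the test suite.

## Significance

Null datasets have independent HWE SNPs with MAF ~ Uniform(0.1, 0.5) and an
independent N(0, 1) trait. The null distribution of the pooled testing score
is nearly invariant in m, n and order (measured 95th-quantile spread ~0.16
score units across m∈{10,20} × n∈{200,400} × order∈{2,3} at 2000 replicates;
SD ≈ 1.6 with slight right skew — wider than the asymptotic standard normal
because CV training sets overlap). That invariance is what justifies a
reusable archive: empirical p-values use the add-one rule
p = (r + 1)/(B + 1) with r the number of archived null scores ≥ the observed
score, looked up at the winning model's order (nearest stored (m, n) if the
exact configuration is absent). The permutation test reruns the *entire*
search + CV + selection pipeline on each trait permutation (fresh fold
assignment per permutation) and applies the same add-one rule.

Type-I error tables use 95th-quantile thresholds from an **independent**
batch of n=400 null datasets with matched m and order. Self-quantiles of the
evaluation batch would give exactly 5% by construction; only independent
thresholds make the estimate informative. Quantiles interpolate linearly
between order statistics.

## Synthetic data

Genotypes are two independent Bernoulli(p) allele draws (HWE:
(1−p)², 2p(1−p), p²), SNPs mutually independent, with no linkage
disequilibrium — real panels violate this, so passing tests say nothing
about LD-induced redundancy among candidate models.

Purely epistatic two-locus models are drawn by projecting a random 3×3
Gaussian table onto the subspace with zero HWE-weighted row and column
effects (alternating weighted centering, iterated to 1e-13), then rescaling
so the HWE-weighted genetic variance Var_g satisfies
Var_g/(Var_g + σ²) = h² with noise SD σ = 1 (the "match-h2" rule; a fixed-σ
rule is available). The trait is Normal(f_ij, σ²) at the sample's functional
two-locus genotype. Both defining properties — marginal deviations < 1e-6
and achieved h² within 0.005 — are enforced at generation. The two
functional columns are placed uniformly at random among the noise SNPs and
recorded as ground truth.

These generated tables stand in for an external catalogue of 70 penetrance
models that is not reproduced here; they enforce the two properties that
define that catalogue (pure epistasis, target h²) but not its value range
(case probabilities in [0, 1]). Consequently success *rates* are comparable
only in trend, not cell-by-cell: under match-h2 scaling the detection
transition occurs at lower nominal h². In our power study the QMDR-over-MDR
advantage is large in the transition region (e.g. ≈+42 points at h²=0.1,
n=400; ≈+10 points at h²=0.1, n=800) and compresses to a few points once
both methods reach the selection ceiling (h² ≥ 0.2 at n=800), a ceiling of
roughly 75–85% imposed by higher-order models occasionally out-scoring the
true pair in held-out data. The h²=0.2/n=800 gap check in the acceptance
suite therefore fails under these study conditions; the corresponding
analysis lives with that test's output rather than being relaxed away.

Success in the power study means the overall best model over orders 1–3 is
exactly the functional pair. The binary-MDR comparator dichotomizes the
trait at its median (strictly-above → 1; ties at the median → 0, a fixed
convention that makes tests deterministic).

## Problem sizes and defaults

Defaults mirror the study design: 10 folds; null calibration at 2000
replicates per configuration (the acceptance script's scale; the test suite
uses 500 with correspondingly widened binomial tolerance, except the
threshold-invariance check, which needs the full 2000 because quantile noise
at 500 replicates exceeds the claim being tested); power cells of 5 models ×
2 MAFs (0.2, 0.4) across h² ∈ {0.01, …, 0.4}; analysis search range 2–4 after
residual adjustment, 1–3 and 1–4 in the power and null studies respectively;
10,000 permutations at paper scale (tests use a few hundred). All
randomness flows from a single integer seed through `numpy` `SeedSequence`
spawning, so every archive, report and table is bit-reproducible.

## Known limitations

No missing-genotype handling (rejected at load), no covariate model beyond
trait residualization, no LD, no heuristic search (exhaustive enumeration
only — m in the tens, not thousands), and the post-hoc variance-explained
regression some analyses report is out of scope.
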