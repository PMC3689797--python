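# qmdr

Cross-validated detection of epistatic SNP–SNP interactions for quantitative
and binary traits, via multifactor dimensionality reduction (MDR) and its
quantitative-trait extension QMDR.

## The problem and the method

Single-locus association scans miss trait architectures in which the outcome
depends on the *joint* genotype at two or more loci with little or no marginal
effect at either locus (epistasis). MDR attacks this by constructive
induction: for a candidate set of k SNPs it builds the (up to) 3^k multilocus
genotype table, labels every cell **high** or **low** by comparing a cell
summary with a whole-sample threshold, and collapses the k SNPs into a single
two-level attribute.

* **Binary trait (MDR).** A cell is high-risk when its case:control ratio
  exceeds the overall ratio R; the attribute is scored by balanced accuracy,
  BA = (sensitivity + specificity) / 2 = (TP/(TP+FN) + TN/(TN+FP)) / 2.
* **Quantitative trait (QMDR).** A cell is high-level when its mean trait
  value exceeds the overall training-set mean; the attribute is scored by the
  pooled two-sample T-statistic between the high and low groups,
  t = (ȳ_high − ȳ_low) / √(s_p² (1/n_high + 1/n_low)).

Model selection uses 10-fold cross-validation: within each fold, every one of
the C(m, k) order-k subsets is scored on the 9/10 training split and the
winner labels the held-out tenth; pooling the held-out labels over all folds
gives one **testing score** per order, and the number of folds won by the
modal subset is the **cross-validation consistency** (CVC). The overall best
model maximizes the testing score, with CVC and then parsimony as
tie-breaks.

Under the null the testing score's distribution is close to invariant in the
SNP count, sample size and interaction order (empirical SD ≈ 1.6, slight
right skew), so a precomputed null-score archive can replace per-dataset
permutation testing: the package ships one (2000 replicates, m=10, n=400,
orders 2–4) and can build others (`qmdr sim-null`). A full permutation test
is also provided for comparison, along with a power/success-rate study that
embeds purely epistatic two-locus penetrance models (no marginal effects
under Hardy–Weinberg weights, target broad-sense heritability h²) among
independent noise SNPs.

## Worked example

```python
from qmdr import QMDR, generate_pure_epistasis_model, simulate_quantitative_dataset

model = generate_pure_epistasis_model(h2=0.2, maf=0.4, seed=0)
ds, truth = simulate_quantitative_dataset(model, n=800, m_noise=18, seed=0)
est = QMDR(min_order=1, max_order=3, random_state=0).fit(ds.genotypes, ds.trait)
print(truth, est.best_snps_, est.best_order_, round(est.best_score_, 2), est.cvc_)
```

prints

```
(0, 12) (0, 12) 2 8.45 10
```

i.e. the planted interacting pair (columns 0 and 12) is recovered as the
overall best model at order 2 with a pooled testing T-score of 8.45, winning
all 10 cross-validation folds. The estimator follows scikit-learn
conventions (`fit`, `transform` to the constructed 0/1 attribute,
`get_params`/`set_params`, trailing-underscore fitted attributes), so it
composes with sklearn pipelines; `MDR` is the binary-trait analogue with
`predict`.

The same analysis from the shell, with significance (the empirical p-value
comes from the shipped null archive, the permutation p-value from re-running
the full search on 199 trait permutations):

```
$ qmdr analyze --input example.txt --min-order 1 --max-order 3 --seed 0 \
      --null-archive packaged --permutations 199

order	best model	testing score	CVC
1	SNP18	2.295	9
2	SNP1 & SNP13	8.571	10
3	SNP1 & SNP13 & SNP18	7.265	5

overall best: SNP1 & SNP13 (order 2, testing score 8.571, CVC 10)
empirical p-value: 0.0004998
permutation p-value: 0.005
```

(Scores differ slightly between the two runs because the CLI draws its own
fold assignment.) `qmdr analyze --screen-main-effects 0.05` additionally
runs a per-SNP one-way ANOVA screen and residualizes significant main
effects out of the trait before the interaction search. `qmdr sim-null` and
`qmdr sim-power` drive the two simulation studies.

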