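# crossnorm

Cross-platform transcriptomic classification with normalization anchored on
non-differentially expressed genes (NDEG).

## The problem

A classifier trained on gene-expression data from one platform (say, RNA-seq
RSEM counts) usually fails on the same genes measured by another platform
(say, microarray intensities): each platform applies its own monotone
distortion to the underlying signal, so feature scales and shapes no longer
match at test time. `crossnorm` implements a strategy for making two
independently measured expression matrices comparable enough for
train-on-one, test-on-the-other evaluation of tumor-subtype classifiers:

1. **Gene selection by one-way ANOVA.** For every gene, the F statistic
   `F = MSB/MSW` compares between-subtype to within-subtype variance, with
   p from the upper tail of F(k−1, N−k). Genes with `p < τ_DEG` are
   differentially expressed (DEG) and become classifier features; genes with
   `p > τ_NDEG` carry no class signal (NDEG) and serve as endogenous
   reference genes — the transcriptome analogue of housekeeping genes.
2. **NDEG-referenced normalization.** Nine schemes, from plain `LOG`, `Z`,
   `NST`, `NPN`, `QN` to the reference-based composites `LOG_RQN`,
   `LOG_RQN_Z`, `LOG_NPN_Z` and `LOG_NICG_Z`. Reference-based quantile
   normalization (RQN) builds its target distribution from the NDEG rows
   only and maps every gene onto it by percentile; NICG subtracts each
   sample's mean over NDEG rows in log space. Each platform is normalized
   independently with its own samples — the shared NDEG anchor is what makes
   the results comparable, and no test-platform statistic leaks into
   training.
3. **Cross-platform evaluation protocol.** Stratified per-class
   `floor(0.75·n_c)` training draws on the training platform; the test set
   is every sample of the other platform whose ID was not drawn; classifier
   tuning by exhaustive grid search over stratified 10-fold CV scored with
   weighted F1 (MLP, XGB, LR, SVM, RF families); the whole pipeline repeated
   with fresh partitions.
4. **Imbalance-aware scoring.** Cohen's kappa `K = (Po − Pe)/(1 − Pe)`,
   balanced accuracy (mean per-class recall), weighted F1/AUC, macro
   recall/specificity, and the composite model-selection score over r
   repeats

   ```
   Evalue = −100 · mean(κ) · mean(BA) · ln(sd(κ) · sd(BA))
   ```

   which rewards models that are both accurate on average and stable under
   re-partitioning.

A synthetic-data module generates paired two-platform matrices with planted
DEG/NDEG ground truth, a monotone platform distortion, severe class
imbalance (default 231:8 ≈ 29:1) and platform-exclusive samples, so every
stage is testable without external data.

## Worked example

```python
from crossnorm import SyntheticDesign, generate, clean_and_match, anova_table, select_genes
from crossnorm.harness import ClassifierGrid, run_cell

platform_a, platform_b, labels, truth = generate(SyntheticDesign())
pair = clean_and_match(platform_a, platform_b, labels)
print(f"cleaned: {pair.matrix_a.n_genes} genes, "
      f"{pair.matrix_a.n_samples}/{pair.matrix_b.n_samples} samples per platform")

table = anova_table(pair.matrix_b, labels.restrict(pair.matrix_b.sample_ids))
sel = select_genes(table, tau_deg=0.05, tau_ndeg=0.95)
print(f"selected {len(sel.deg)} DEG (features), {len(sel.ndeg)} NDEG (references)")

grid = ClassifierGrid("SVM", [{"kernel": ["linear"]}])
for method in ("RAW", "LOG_RQN"):
    cell = run_cell(pair.matrix_b, pair.matrix_a, labels, method,
                    tau_deg=0.05 if method != "RAW" else 1.0, tau_ndeg=0.95,
                    family="SVM", grid=grid, n_repeats=3, base_seed=0)
    m = cell.evaluation.means
    print(f"{method:8s} kappa={m['kappa']:.3f}  BA={m['balanced_accuracy']:.3f}  "
          f"Evalue={cell.evaluation.evalue:.1f}")
```

prints

```
cleaned: 900 genes, 520/522 samples per platform
selected 135 DEG (features), 46 NDEG (references)
RAW      kappa=0.031  BA=0.224  Evalue=4.3
LOG_RQN  kappa=0.978  BA=0.800  Evalue=2162.5
```

Trained on the distorted platform and tested on the other, a linear SVM on
raw values is barely above chance (five imbalanced classes); after
NDEG-referenced quantile normalization the same classifier recovers the
planted subtype structure almost perfectly, and the high Evalue reflects
that the result is also stable across the three re-partitions.

## Command line

```sh
crossnorm simulate --out-dir sim/                 # paired dataset + ground truth
crossnorm select   --matrix sim/platform_b.tsv --labels sim/labels.tsv --out-dir sel/
crossnorm normalize --method LOG_RQN_Z --in sim/platform_a.tsv \
                    --ndeg-file ndeg.txt --out norm_a.tsv
crossnorm run --fast --out-dir results/           # zero-config synthetic experiment
crossnorm report --results results/metrics_aggregate.tsv --out-dir report/
```

Every subcommand writes a JSON manifest (seeds, per-stage counts, file
digests) sufficient to re-run it exactly.

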