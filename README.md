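# bvpredict

Predict **incident bacterial vaginosis (BV)** in women from their male
partner's **baseline penile microbiome**.

BV is defined by a Nugent Gram-stain score of 7–10; *incident* BV is a first
follow-up visit (month 1, 6 or 12) scoring 7–10 in a woman whose baseline
score was 0–6. Couples in which the woman already has BV at baseline, or in
whom no follow-up visit is available, are excluded; a sensitivity variant
additionally drops intermediate baselines (Nugent 4–6). The predictors are
the relative abundances of penile 16S taxa from a single baseline swab
(meatal or glans/coronal sulcus), plus circumcision status.

`bvpredict` is a reusable implementation of that analysis for microbiome
epidemiologists: it takes a taxa count table and couple metadata (or
simulates a cohort with the same statistical structure) and runs the full
classification pipeline with one command.

## Method

1. **Compositional preprocessing.** Taxa contributing < 0.01% of a site's
   total reads are dropped. Zero counts are imputed with independent draws
   from Uniform(0.5, 0.95), then each sample is mapped by the centered
   log-ratio transform, clr(x)ᵢ = ln xᵢ − (1/p) Σⱼ ln xⱼ, and each feature
   is min-max rescaled, x_new = (x − x_min)/(x_max − x_min), so that all
   features lie in [0, 1].
2. **Class rebalancing.** Incident BV is the minority class (~31%).
   SMOTE synthesizes minority points x + u·(x′ − x) between each minority
   sample and one of its k = 5 nearest minority neighbours (u ~ U(0, 1)),
   and the majority class is randomly undersampled.
3. **Classification.** Random forest, RBF-kernel SVM, and k-nearest-
   neighbours are evaluated by 10-fold stratified cross-validation repeated
   many times (1,000 at full scale; 50 by default), with optional
   grid-search tuning by nested inner cross-validation. A **majority vote**
   over the three predicted labels gives the ensemble label; the mean of
   the three scores gives its continuous score. Performance is reported as
   accuracy, sensitivity, specificity, and AUC (Mann–Whitney form), with
   the per-repeat AUC distribution retained.
4. **Variable importance.** Features are ranked per classifier —
   permutation importance (RF), recursive feature elimination by
   cross-validated accuracy (SVM), leave-one-feature-out degradation
   (KNN) — and aggregated into a *voting rank* by averaging the three
   ranks (ties broken by the best single-classifier rank).
5. **Comparison.** Two per-repeat AUC distributions (e.g. two sampling
   sites) are compared with a two-sided permutation test on the Welch t
   statistic, p = (1 + #{|t*| ≥ |t|}) / (1 + B).

## Worked example

Simulate a cohort of 120 couples over 30 taxa in which three taxa
(indices 2, 7, 12 → `taxon_003`, `taxon_008`, `taxon_013`) are shifted by
1.5 natural-log units in incident couples, then run the whole pipeline
(10-fold CV, 10 repeats, leakage-free within-fold rebalancing):

```yaml
# example.yaml
seed: 7
out_dir: example_out
simulate:
  n_couples: 120
  n_taxa: 30
  effect_taxa: {2: 1.5, 7: 1.5, 12: 1.5}
resample:
  mode: within_fold
cv:
  n_folds: 10
  n_repeats: 10
classifiers: desk
```

```sh
bvpredict run-all -c example.yaml
```

prints

```
                rf    svm    knn  voting
accuracy     0.801  0.795  0.557   0.792
specificity  0.878  0.841  0.393   0.807
sensitivity  0.627  0.692  0.924   0.757
auc          0.854  0.858  0.759   0.860
outputs in example_out
```

The three classifiers trade sensitivity against specificity differently
(KNN is sensitive but unspecific here), while the vote balances them and
its AUC (0.860) matches the best individual classifier. The importance
table (`example_out/importance.tsv`) begins

```
feature    rank_knn  rank_rf  rank_svm  mean_rank  voting_rank
taxon_013         6        2         1     3.0000            1
taxon_007         2        6         3     3.6667            2
taxon_019         7        4         5     5.3333            3
```

Two of the three planted taxa are recovered near the top (`taxon_013`
rank 1, `taxon_003` rank 5; `taxon_008` rank 13 of 31); high-ranked
non-planted taxa reflect compositional spillover — shifting one taxon's
concentration perturbs every CLR coordinate.

Other outputs: `performance_summary.tsv`, per-repeat `auc_*.txt` vectors
(inputs to `bvpredict compare`), and `manifest.json` (configuration echo,
derived seeds, stage dimensions, software versions — sufficient to re-run
identically). Every stage is also available as its own subcommand
(`simulate`, `cohort`, `preprocess`, `resample`, `evaluate`, `importance`,
`compare`).

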