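# taxomark

Biomarker discovery from gut-microbiome composition for predicting
postoperative cancer recurrence — differential abundance, leave-one-out
random-forest stability selection, consensus nomination, and
abundance-cutoff survival validation, with a synthetic-cohort generator for
fully reproducible testing.

## The problem

Small surgical cohorts (tens of patients) with 16S-derived genus- or
species-level relative-abundance tables are a common setting for asking
whether any gut taxon predicts a clinical outcome such as tumor recurrence.
Two analysis cultures answer the question differently: classical univariate
testing ranks taxa by a Mann-Whitney *U* p-value, while machine learning
ranks them by the feature importance of a tuned classifier. Both are
unstable at n ≈ 50, and they rarely agree. `taxomark` implements both
tracks, quantifies the instability instead of ignoring it, and treats the
*intersection* of the two rankings as the biomarker shortlist.

For samples *i* = 1..n with group labels *y<sub>i</sub>* ∈ {recurrence,
non-recurrence} and a taxon's percent abundances *x*:

- **Univariate track** — two-sided Mann-Whitney *U* per taxon from
  midranks, *U(x,y) + U(y,x) = n₁n₂*; taxa ranked by raw *p*
  (Benjamini-Hochberg *q* supplied as supplementary output), top 10 kept.
  Taxa with mean abundance ≤ 0.1% are removed first and the survivors
  rescaled to 100% per sample.
- **ML track** — a random forest tuned by seeded random search to maximize
  leave-one-sample-out (LOSO) out-of-fold AUC; with tuned hyperparameters
  fixed, the n LOSO models are refit under 4 seeds and each taxon's
  appearances in a model's importance top 10 are counted. The stability
  total ∈ [0, 4n] (204 at n = 51) is the ranking statistic.
- **Consensus** — taxa in both top-10 lists.
- **Validation** — single-taxon ROC (trapezoid area = tie-adjusted
  concordant-pair counting), a Youden or fixed abundance cutpoint, and
  Kaplan-Meier / log-rank comparison of the strata above vs below the
  cutpoint ("high" = strictly above; product-limit estimator
  S(t) = Π<sub>tᵢ≤t</sub>(1 − dᵢ/nᵢ), unweighted log-rank
  χ² = (O − E)²/V with 1 df).

Survival and rank statistics are implemented from the formulas; lifelines,
scipy and scikit-learn serve as independent cross-checks in the test suite.
See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

A synthetic 18/33 cohort of 200 compositional taxa, one taxon spiked
five-fold in the recurrence group near a 1% baseline:

```python
import numpy as np
from taxomark import (SyntheticSpec, baseline_composition, generate_cohort,
                      filter_and_renormalize, rank_by_pvalue,
                      run_stability_analysis, consensus_taxa,
                      taxon_roc, select_cutpoint, dichotomize_and_compare)

probe = SyntheticSpec(seed=1, n_taxa=200)
base = baseline_composition(probe) * 100
spike = int(np.argmin(np.abs(base - 1.0)))          # a taxon near 1% baseline
spec = SyntheticSpec(seed=1, n_taxa=200, spiked_taxa=[(spike, 5.0)],
                     biomarker_taxon=spike)
table, meta = generate_cohort(spec)
filt = filter_and_renormalize(table)                 # mean > 0.1%, resummed to 100
full, top10 = rank_by_pvalue(filt, meta, k=10)
print(full[["p_value", "mean_recurrence", "mean_non_recurrence"]].head(3).round(4))

ranking, perfs = run_stability_analysis(
    filt, meta, {"n_estimators": 60}, seeds=[11, 12, 13, 14], k=10)
print(ranking[["total", "mean_importance"]].head(3).round(4))
print("mean out-of-fold AUC:", round(np.mean([p.auc for p in perfs]), 3))

cons = consensus_taxa(list(top10.index), list(ranking.head(10).index))
roc = taxon_roc(filt, meta["event"].to_numpy(), taxon=table.taxon_ids[spike])
cut = select_cutpoint(roc, method="youden")
print(f"abundance ROC AUC = {roc.auc:.3f}, Youden cutpoint = {cut:.3f}%")
km_hi, km_lo, lr = dichotomize_and_compare(
    filt, meta, table.taxon_ids[spike],
    float(np.median(table.values.iloc[:, spike])))
print(f"log-rank chi2 = {lr.chi_square:.2f}, p = {lr.p_value:.2e}")
```

Output:

```
             p_value  mean_recurrence  mean_non_recurrence
taxon
g__Taxon141   0.0000           5.6456               0.6798
g__Taxon192   0.0003           0.2962               0.0210
g__Taxon079   0.0032           0.0104               0.2161
             total  mean_importance
taxon
g__Taxon141    204           0.1687
g__Taxon192    201           0.0524
g__Taxon186    186           0.0378
mean out-of-fold AUC: 0.908
abundance ROC AUC = 0.884, Youden cutpoint = 1.029%
log-rank chi2 = 39.33, p = 3.57e-10
```

The spiked taxon (`g__Taxon141`) tops the univariate ranking (its
recurrence-group mean is ~5x the non-recurrence mean, as planted), attains
the maximum stability total of 204 (in the importance top 10 of all 51
models in all 4 repeats), enters the consensus set, and its abundance
dichotomy separates survival decisively — the generator gave the
high-abundance stratum a 4-fold hazard.

## Command line

```sh
taxomark simulate --spec spec.yaml --outdir data/        # synthetic cohort
taxomark run --config pipeline.yaml --profile desk       # full analysis
taxomark version
```

`run` executes ingest → 0.1% filter → univariate (top 10 / effect top 7) →
tuning → 4-repeat LOSO stability (top 10) → consensus → ROC/cutpoint
(default fixed value 0.75%) → survival, writing every stage as TSV plus a
`manifest.json` (config echo, seeds, version, checksums) that suffices to
re-run the identical analysis. The `desk` profile (15 tuning trials, small
forests) finishes in minutes; `paper` (1000 trials) reproduces a full
search.

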