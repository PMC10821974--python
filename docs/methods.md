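# Methods

`taxomark` implements a biomarker-discovery analysis for small labeled
microbiome cohorts: given a percent-composition table of gut taxa and a
binary clinical outcome (postoperative recurrence), it ranks taxa by two
independent routes, nominates the taxa both routes agree on, and validates a
nominated biomarker against overall survival. This note records the models,
the defaults and why they were chosen, and what the synthetic data can and
cannot show.

## Data model

The unit of analysis is a samples x taxa matrix of **relative abundances in
percent**, each sample summing to 100. Percent (0-100), not fractions, is
the canonical unit everywhere, matching how abundance cutoffs such as 0.75%
are quoted in clinical microbiome work. On disk, tables use the common
taxonomy-export dialect (taxa rows, sample columns, first column a
`k__...;g__...;s__...` lineage string); the reader transposes, derives taxon
ids at the requested rank, and labels taxa unresolved at that rank
`unclassified <deepest parent> (<rank>)`. Rows binned to the same id at the
requested rank are summed.

Before any ranking, taxa whose **mean relative abundance is <= 0.1%** are
removed and the remaining taxa are rescaled per sample to sum to 100. A
mean-abundance reading of the filter was chosen over a prevalence reading
(fraction of cases carrying the taxon) because with ~50 subjects a 0.1%
prevalence threshold is below one sample and therefore degenerate; a
prevalence-based switch (`criterion="prevalence"`) is provided for users who
want the alternative. The filter is idempotent and preserves within-sample
abundance ratios of retained taxa.

## Univariate track

Each taxon is compared between groups with a two-sided Mann-Whitney U test.
U is computed from midranks (ties contribute half a favorable pair), so
`U(x,y) + U(y,x) = n1*n2` exactly. Two p-value modes:

- **normal** (default): tie-corrected normal deviate, no continuity
  correction; degenerate (constant) taxa are flagged and given p = 1.
- **exact**: the permutation null of U — full enumeration of the
  `C(n1+n2, n1)` group assignments when that count is within the
  enumeration budget (200,000), otherwise seeded Monte-Carlo permutation
  with an add-one estimator so p stays in (0, 1].

At the cohort's 18/33 group sizes the two modes agree to ~0.005. At small
sizes (8 vs 8) the discreteness of U leaves normal-vs-exact gaps up to
~0.03 in the mid-range of the null distribution even with few ties; in the
tail (p below ~0.2), the regime that decides rankings, agreement is within
0.01. Users testing very small groups should prefer the exact mode.

Rankings report **raw p-values** (the presentation convention this analysis
follows plots raw p against the 0.05 line); a Benjamini-Hochberg q column is
emitted alongside as supplementary output, never used for ranking. Ties in
p break by |z| descending, then taxon id, making every ranking
deterministic. Effect rankings (top-7 per direction) order taxa by the raw
difference of group mean abundances; the recurrence-enriched list is built
first and its members are excluded from the other list, so the two lists
are always disjoint. Zero abundances are legitimate values, not missing
data; no pseudocounts or compositional (CLR) transforms are applied.

## Machine-learning track

The classifier is a random forest (bagged CART trees with per-split feature
subsampling, impurity importances normalized to sum to 1), backed by
scikit-learn; `taxomark.ensemble.ReferenceRandomForest` is a transparent
plain-numpy implementation of the same contract used in contract tests.
Feature columns are put in canonical (lexicographic) order before fitting,
because tree feature sampling is index-keyed; this makes every result
invariant to the column order of the input file.

**Cross-validation** is leave-one-sample-out (LOSO): n folds, each training
on n-1 samples with a per-fold seed derived from `(run seed, fold index)`,
recording the held-out sample's predicted recurrence probability and the
model's importance vector. Out-of-fold accuracy, sensitivity and
specificity are computed at probability threshold 0.5 (recurrence =
positive class); AUC by tie-adjusted pair counting. Folds whose training
labels are single-class (impossible at 18/33, possible in tiny synthetic
runs) are flagged degenerate and predicted at the training-class rate.

**Tuning** is seeded random search maximizing the LOSO out-of-fold AUC of
the full cohort. The search space: tree count (profile dependent, below),
max depth in {unlimited, 2..20}, feature subset in {sqrt, log2, fraction
0.1-1.0}, min leaf size 1-8, class weighting in {none, balanced}. Because
the tuning objective is evaluated on the same cohort later used for
reporting, the tuned out-of-fold AUC carries an optimistic selection bias;
this mirrors a single-cohort tune-once discovery design and is the reason
the stability count, not the AUC, is the track's ranking statistic.

**Stability counting**: with the tuned configuration held fixed, the LOSO
pass is repeated under 4 distinct seeds. In each of the 4 x n models the
taxa are ranked by importance (ties broken by name, so top-10 membership is
a strict set) and each taxon's appearances in the top 10 are counted,
giving totals in [0, 4n] — 204 for a taxon present in every top-10 of a
51-sample cohort. Final ranking is by total descending, then mean
importance, then name.

Two profiles control cost: **desk** (15 tuning trials, 30-100 trees) keeps
a full tuning-plus-repeats run on a 51 x ~100 table around two minutes on
one CPU and is the scale used throughout the test suite; **paper** (1000
trials, 50-1000 trees) reproduces a full overnight search. Problem sizes in
the tests (200-300 simulated taxa, 10-seed recovery runs, 100-seed power
sweeps) were chosen so the whole suite completes at desk scale while
keeping Monte-Carlo tolerances meaningful.

## Consensus and cutpoint

The consensus set is the intersection of the univariate top-10 and the
stability top-10, reported in stability-rank order; an empty intersection
is a legitimate finding. A nominated taxon is characterized by the ROC of
its percent abundance against a binary outcome (for survival validation,
death during follow-up). The ROC treats each unique score as a threshold
("positive" = score >= threshold); the trapezoid area over the step curve
equals tie-adjusted pair counting to 1e-9 by construction. Cutpoints come
either from the Youden index (smallest threshold maximizing tpr - fpr) or
are fixed externally (e.g. an established 0.75% abundance threshold). When
a cutpoint dichotomizes a cohort, "high" means **strictly greater** than
the cutpoint; boundary samples go to the low stratum.

## Survival analysis

Kaplan-Meier curves and the unweighted two-group log-rank test are
implemented directly from the product-limit and hypergeometric formulas
(the installed survival packages serve as independent references in the
test suite, not as the implementation). Conventions: censored subjects
leave the risk set after their time; at tied event/censoring times events
are counted first; no continuity correction; p from chi-square with 1 df.
Event = death (overall survival); recurrence-free survival is out of scope
because recurrence dates are not modeled.

## Synthetic cohorts

The generator emulates the study conditions the analysis assumes: 18
recurrence / 33 non-recurrence subjects, several hundred sparse
compositional taxa, a small set of group-differential taxa, and survival
driven by a biomarker-abundance dichotomy.

- **Baseline composition**: log-normal(mu=0, sigma=2) scales, normalized —
  a heavy-tailed profile with a few dominant and many rare taxa, the shape
  a genus-level 16S table typically has.
- **Group effect**: spiked taxa have their baseline multiplied by a fold in
  the recurrence group, then the baseline is renormalized, so effects are
  compositionally coherent. The expected recurrence-group proportion of a
  spiked taxon is `f*p / (1 + (f-1)*p)` — the renormalized Dirichlet mean
  used as the analytic oracle in tests.
- **Subject noise**: per-subject Dirichlet with concentration `c x
  baseline` (default c = 50, visibly noisy but recoverable at n = 51);
  optional multinomial resampling at a fixed read depth (default 10,000,
  the upper end of a typical rarefaction range; 0 disables count noise).
- **Survival**: exponential hazards, base rate 0.01 events/month, times
  administratively censored at 60 months (a follow-up window consistent
  with a 12-month minimum observation period); the hazard is multiplied by
  `hazard_ratio_high` (default 4) when the designated biomarker taxon
  exceeds its cutoff.
- **Streams**: one integer seed; fixed sub-stream offsets for baseline,
  composition, survival and covariates, so changing hazard parameters never
  perturbs the abundance table and the baseline can be inspected before
  generating. Helpers (`baseline_composition`, `pick_biomarker_cutoff`)
  exist because with a log-normal baseline a hard-coded taxon index could
  land on a taxon too rare to survive the 0.1% filter; tests place spikes
  near a 1% baseline and set survival cutoffs at the realized median.

What the synthetic model does **not** emulate: phylogenetic correlation
between taxa, overdispersion beyond Dirichlet-multinomial, batch or
sequencing-run effects, covariate-outcome confounding, and non-exponential
hazards. Passing tests therefore demonstrate that the pipeline recovers
planted signal under its own assumptions — not that those assumptions hold
for any particular real cohort, whose per-sample abundances this package
never sees.

## Numerical choices and degenerate inputs

- Row-closure tolerance 1e-6 on percent scales; product-limit identities
  asserted to 1e-12.
- All rank statistics use midranks; all rankings have total deterministic
  tie-breaks (statistic, then name).
- Monte-Carlo p-values use an add-one estimator; exact enumeration is used
  up to 200,000 assignments.
- Constant taxa: flagged degenerate, p = 1, never dropped silently.
- Dirichlet concentrations are floored at 1e-9 so a spike fold of 0 (taxon
  absent in one group) remains a proper distribution.
- A log-rank test with no events in either group is an error rather than a
  silent p = 1.

## Known limitations

- The tuning objective shares data with the reported evaluation (see
  above); a nested scheme is the obvious extension but is not the design
  this pipeline reproduces.
- Random search is the only tuning strategy shipped; the search is seeded
  and logged, so any trial can be re-run.
- No confidence intervals on AUC or survival curves; no Cox models or
  covariate adjustment; no BIOM/binary I/O.
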