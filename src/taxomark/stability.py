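"""Machine-learning track: tuned random forests under leave-one-sample-out
cross-validation with top-10 importance stability counting.

The classifier is a random forest (scikit-learn backend; see
:mod:`taxomark.ensemble` for a transparent reference implementation of the
same contract) predicting recurrence from the percent composition. Model
selection maximizes the out-of-fold AUC of a full leave-one-sample-out
(LOSO) pass via seeded random search over the hyperparameter space. With the
tuned configuration fixed, the LOSO pass is repeated under several random
seeds (four by default); in every fitted model the taxa are ranked by
normalized impurity importance and top-10 membership is counted, giving each
taxon a stability total in [0, 4 x n_samples]. The stability total, not raw
importance, is the track's ranking statistic — it damps the run-to-run
randomness of forest importances on a small cohort.

Note the tuning objective is evaluated on the same cohort later used for
reporting, so the tuned out-of-fold AUC carries an optimistic selection
bias; this mirrors a single-cohort discovery design and is documented in the
methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .consensus import pair_auc
from .io import TaxonTable

#: hyperparameter spaces; the desk profile keeps forests small so full
#: LOSO tuning stays interactive on one CPU, the paper profile matches a
#: 1000-trial overnight search
SEARCH_SPACES: dict[str, dict] = {
    "desk": {"n_estimators": (30, 100)},
    "paper": {"n_estimators": (50, 1000)},
}

POSITIVE_GROUP = "recurrence"


def _fold_seed(seed: int, fold_index: int) -> int:
    """Stable per-fold seed keyed to the fold index only."""
    return int(np.random.SeedSequence((int(seed), int(fold_index))).generate_state(1)[0] % (2**31))


def sample_params(rng: np.random.Generator, profile: str = "desk") -> dict:
    """Draw one hyperparameter configuration from the search space.

    Space: tree count (profile-dependent range), max depth in {None, 2..20},
    feature subset in {sqrt, log2, fraction 0.1-1.0}, min leaf size 1-8,
    class weighting in {None, balanced}.
    """
    lo, hi = SEARCH_SPACES[profile]["n_estimators"]
    depth_choices = [None] + list(range(2, 21))
    mf_kind = rng.integers(0, 3)
    if mf_kind == 0:
        max_features = "sqrt"
    elif mf_kind == 1:
        max_features = "log2"
    else:
        max_features = float(np.round(rng.uniform(0.1, 1.0), 3))
    return {
        "n_estimators": int(rng.integers(lo, hi + 1)),
        "max_depth": depth_choices[rng.integers(0, len(depth_choices))],
        "max_features": max_features,
        "min_samples_leaf": int(rng.integers(1, 9)),
        "class_weight": [None, "balanced"][rng.integers(0, 2)],
    }


@dataclass
class TunedConfig:
    """Best configuration found by the search, with its trial log."""

    params: dict
    objective: float  # LOSO out-of-fold AUC of `params`
    n_trials: int
    seed: int
    trials: pd.DataFrame = field(repr=False, default=None)


@dataclass
class FoldModel:
    """One LOSO fold: the held-out prediction and the model's importances."""

    left_out_sample: str
    oof_probability: float
    importance: np.ndarray  # aligned to `taxa`; sums to 1 unless degenerate
    fold_index: int
    taxa: tuple[str, ...]
    degenerate: bool = False
    n_training: int = 0


@dataclass
class CVPerformance:
    """Out-of-fold classification metrics (recurrence = positive class)."""

    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    threshold: float = 0.5


def _design(table: TaxonTable, meta: pd.DataFrame):
    """Feature matrix in canonical (lexicographic) taxon order plus labels.

    Canonical ordering makes every downstream result invariant to the
    column order of the input table: tree feature sampling is index-keyed,
    so without it a mere column permutation would change the fitted models.
    """
    taxa = tuple(sorted(table.taxon_ids))
    X = table.values.loc[:, list(taxa)].to_numpy(dtype=float)
    meta = meta.loc[table.sample_ids]
    y = (meta["group"] == POSITIVE_GROUP).to_numpy(dtype=int)
    return X, y, taxa


def loso_fit(
    table: TaxonTable,
    meta: pd.DataFrame,
    config: TunedConfig | dict,
    seed: int,
    learner_factory: Callable[..., object] | None = None,
) -> list[FoldModel]:
    """Leave-one-sample-out pass: one model and one held-out prediction per sample.

    Fold i trains on all samples but i with the fixed hyperparameters and a
    per-fold seed derived from (seed, fold index), then records sample i's
    predicted recurrence probability and the model's importance vector
    normalized to sum to one. A fold whose training labels are single-class
    is flagged degenerate: its prediction falls back to the training-class
    rate and its importances are all zero.
    """
    params = config.params if isinstance(config, TunedConfig) else dict(config)
    X, y, taxa = _design(table, meta)
    n = len(y)
    if n < 3:
        raise ValueError(f"need >=3 samples for LOSO, got {n}")
    if learner_factory is None:
        learner_factory = lambda **kw: RandomForestClassifier(n_jobs=1, **kw)
    folds: list[FoldModel] = []
    sample_ids = table.sample_ids
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        X_tr, y_tr = X[mask], y[mask]
        fold_seed = _fold_seed(seed, i)
        if len(np.unique(y_tr)) < 2:
            folds.append(
                FoldModel(sample_ids[i], float(y_tr.mean()), np.zeros(len(taxa)),
                          i, taxa, degenerate=True, n_training=len(y_tr))
            )
            continue
        clf = learner_factory(random_state=fold_seed, **params)
        clf.fit(X_tr, y_tr)
        pos_col = int(np.argmax(clf.classes_ == 1))
        prob = float(clf.predict_proba(X[i:i + 1])[0, pos_col])
        imp = np.asarray(clf.feature_importances_, dtype=float)
        s = imp.sum()
        degenerate = s <= 0
        if not degenerate:
            imp = imp / s
        folds.append(
            FoldModel(sample_ids[i], prob, imp, i, taxa, degenerate,
                      n_training=len(y_tr))
        )
    return folds


def cv_performance(
    folds: Sequence[FoldModel], meta: pd.DataFrame, threshold: float = 0.5
) -> CVPerformance:
    """Accuracy/sensitivity/specificity at a probability threshold, plus AUC.

    All metrics come from the out-of-fold probabilities: a sample is called
    recurrent when its held-out probability strictly exceeds the threshold;
    the AUC uses tie-adjusted pair counting.
    """
    ids = [f.left_out_sample for f in folds]
    missing = set(meta.index) - set(ids)
    if missing:
        raise ValueError(f"missing folds for samples: {sorted(missing)}")
    probs = np.array([f.oof_probability for f in folds])
    y = (meta.loc[ids, "group"] == POSITIVE_GROUP).to_numpy(dtype=int)
    pred = (probs > threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return CVPerformance(
        accuracy=(tp + tn) / len(y),
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        auc=pair_auc(probs, y),
        threshold=threshold,
    )


def tune_hyperparameters(
    table: TaxonTable,
    meta: pd.DataFrame,
    n_trials: int,
    seed: int,
    profile: str = "desk",
) -> TunedConfig:
    """Seeded random search maximizing the LOSO out-of-fold AUC.

    Every trial runs a complete LOSO pass at the candidate configuration
    (all folds share the tuning seed policy, so trials are comparable) and
    is scored by the resulting out-of-fold AUC. Ties keep the earlier trial.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng([int(seed), 23])
    rows = []
    best: tuple[float, dict] | None = None
    for t in range(n_trials):
        params = sample_params(rng, profile)
        folds = loso_fit(table, meta, params, seed=seed)
        auc = cv_performance(folds, meta).auc
        rows.append({"trial": t, "objective": auc, **{f"param_{k}": v for k, v in params.items()}})
        if best is None or auc > best[0]:
            best = (auc, params)
    trials = pd.DataFrame(rows)
    return TunedConfig(best[1], best[0], n_trials, seed, trials)


def top_k_taxa(fold: FoldModel, k: int = 10) -> list[str]:
    """The fold model's top-k taxa by importance, ties broken by name."""
    order = sorted(range(len(fold.taxa)), key=lambda j: (-fold.importance[j], fold.taxa[j]))
    return [fold.taxa[j] for j in order[:k]]


def importance_stability(
    repeats: Sequence[Sequence[FoldModel]], k: int = 10
) -> pd.DataFrame:
    """Count top-k importance appearances across all models of all repeats.

    Returns one row per taxon with per-repeat counts (``count_repeat_i``),
    their ``total``, the ``mean_importance`` over all models, and a 1-based
    ``final_rank`` by total descending (ties by mean importance descending,
    then name). Exactly k taxa are counted per model, so each repeat's
    counts sum to k x n_folds.
    """
    taxa = repeats[0][0].taxa
    n_folds = len(repeats[0])
    for rep in repeats:
        if len(rep) != n_folds:
            raise ValueError("all repeats must have the same fold count")
        for fold in rep:
            if fold.taxa != taxa:
                raise ValueError("repeats have mismatched taxon universes")
    k = min(k, len(taxa))
    counts = np.zeros((len(repeats), len(taxa)), dtype=int)
    index = {t: j for j, t in enumerate(taxa)}
    imp_sum = np.zeros(len(taxa))
    for r, rep in enumerate(repeats):
        for fold in rep:
            imp_sum += fold.importance
            for t in top_k_taxa(fold, k):
                counts[r, index[t]] += 1
    out = pd.DataFrame(
        {f"count_repeat_{r + 1}": counts[r] for r in range(len(repeats))},
        index=pd.Index(taxa, name="taxon"),
    )
    out["total"] = counts.sum(axis=0)
    out["mean_importance"] = imp_sum / (len(repeats) * n_folds)
    order = sorted(
        out.index,
        key=lambda t: (-out.at[t, "total"], -out.at[t, "mean_importance"], t),
    )
    out = out.loc[order]
    out["final_rank"] = np.arange(1, len(out) + 1)
    return out


def run_stability_analysis(
    table: TaxonTable,
    meta: pd.DataFrame,
    config: TunedConfig | dict,
    seeds: Sequence[int],
    k: int = 10,
) -> tuple[pd.DataFrame, list[CVPerformance]]:
    """Repeat the LOSO pass once per seed at the tuned configuration.

    Returns the aggregate stability ranking and the per-repeat out-of-fold
    performance. Seeds must be distinct — identical seeds would silently
    count the same models twice.
    """
    if len(set(seeds)) != len(seeds):
        raise ValueError("seeds must be distinct")
    repeats = [loso_fit(table, meta, config, seed=s) for s in seeds]
    performances = [cv_performance(rep, meta) for rep in repeats]
    return importance_stability(repeats, k=k), performances
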