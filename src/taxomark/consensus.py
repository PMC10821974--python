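"""Biomarker nomination: track consensus, single-taxon ROC, and cutpoints.

A candidate biomarker is a taxon appearing both in the univariate top-k
(Mann-Whitney ranking) and in the model-importance stability top-k. A
nominated taxon's discriminative ability is characterized by the ROC of its
percent abundance (or of any supplied score, e.g. out-of-fold model
probabilities) against a binary outcome, with the area computed by the
trapezoid rule over the step curve — identical, by construction, to
tie-adjusted concordant-pair counting. A cutpoint is chosen either by the
Youden index or fixed externally (e.g. the 0.75% abundance threshold);
"high" always means abundance strictly greater than the cutpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import TaxonTable


@dataclass
class ROCCurve:
    """Stepwise ROC: descending thresholds with cumulative (fpr, tpr)."""

    thresholds: np.ndarray  # descending unique score cutoffs
    fpr: np.ndarray         # non-decreasing, starts at 0, ends at 1
    tpr: np.ndarray
    auc: float


def pair_auc(scores, labels) -> float:
    """AUC by tie-adjusted pair counting, via midranks.

    Equals (concordant + 0.5 * tied) / (n_pos * n_neg): the probability that
    a random positive outscores a random negative, ties counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_curve_from_scores(scores, labels) -> ROCCurve:
    """Build the stepwise ROC over the unique score thresholds.

    A sample is called positive when its score exceeds the threshold
    (strictly), so each unique score value produces one step. The curve is
    anchored at (0,0) with a sentinel threshold above the maximal score.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    last = np.r_[np.diff(s) != 0, True]  # last index of each unique score
    thr = s[last]
    tpr = np.r_[0.0, tps[last] / n_pos]
    fpr = np.r_[0.0, fps[last] / n_neg]
    thresholds = np.r_[np.inf, thr]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds, fpr, tpr, auc)


def taxon_roc(
    table: TaxonTable, labels, taxon: str | None = None, scores=None
) -> ROCCurve:
    """ROC of a taxon's percent abundance (or of an explicit score vector).

    ``labels`` is a binary outcome per sample, aligned with the table's
    sample order (e.g. death during follow-up, or recurrence). Exactly one
    of ``taxon`` / ``scores`` must be given.
    """
    if (taxon is None) == (scores is None):
        raise ValueError("supply exactly one of taxon or scores")
    if taxon is not None:
        if taxon not in table.values.columns:
            raise KeyError(f"taxon {taxon!r} not in table")
        scores = table.values[taxon].to_numpy()
    return roc_curve_from_scores(scores, labels)


def select_cutpoint(
    roc: ROCCurve, method: str = "youden", fixed_value: float = 0.75
) -> float:
    """Choose a score cutpoint from a ROC curve.

    ``"youden"`` returns the smallest finite threshold maximizing the Youden
    index J = tpr - fpr; ``"fixed"`` passes ``fixed_value`` through. Samples
    with score exactly equal to the cutpoint belong to the low group ("high"
    requires strictly exceeding it).
    """
    if method == "fixed":
        return float(fixed_value)
    if method != "youden":
        raise ValueError(f"method must be 'youden' or 'fixed', got {method!r}")
    j = roc.tpr - roc.fpr
    best = j.max()
    candidates = roc.thresholds[(j >= best - 1e-12) & np.isfinite(roc.thresholds)]
    return float(candidates.min())


@dataclass
class ConsensusResult:
    """Intersection of the two biomarker tracks at one taxonomic rank."""

    univariate_topk: list[str]
    stability_topk: list[str]
    intersection: list[str] = field(init=False)
    level: str = "genus"

    def __post_init__(self):
        uni = set(self.univariate_topk)
        self.intersection = [t for t in self.stability_topk if t in uni]


def consensus_taxa(
    univariate_topk: list[str], stability_topk: list[str], level: str = "genus"
) -> ConsensusResult:
    """Taxa shared by the univariate and stability top-k lists.

    The intersection is reported in stability-rank order. An empty
    intersection is a valid result.
    """
    if not univariate_topk or not stability_topk:
        raise ValueError("both top-k lists must be nonempty")
    return ConsensusResult(list(univariate_topk), list(stability_topk), level=level)
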