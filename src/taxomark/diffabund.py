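"""Univariate differential abundance: Mann-Whitney U tests and effect ranking.

Each taxon's percent abundance is compared between the recurrence and
non-recurrence groups with a two-sided Mann-Whitney U test. U is computed
from midranks, so ties contribute half a favorable pair. Two p-value modes
are offered: a tie-corrected normal approximation (no continuity
correction), and an exact permutation mode that enumerates the label
assignments when feasible and falls back to seeded Monte-Carlo permutation
above an enumeration budget. Rankings report raw p-values (a
Benjamini-Hochberg q column is emitted as supplementary output).
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .io import TaxonTable


class MWUResult(NamedTuple):
    U: float
    z: float
    p_value: float
    degenerate: bool = False


def _u_and_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Midrank U for x over y, tie-corrected z, and the null variance."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3) - counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    mu = n1 * n2 / 2.0
    z = 0.0 if var <= 0 else (u - mu) / math.sqrt(var)
    return u, z, var


def mann_whitney_u(
    x,
    y,
    mode: str = "normal",
    *,
    max_enumeration: int = 200_000,
    n_permutations: int = 20_000,
    seed: int = 0,
) -> MWUResult:
    """Two-sided Mann-Whitney U test of two independent samples.

    ``U`` counts favorable pairs for ``x`` (ties count one half), so
    ``U(x, y) + U(y, x) = n1 * n2``.

    mode="normal"
        Tie-corrected standard-normal approximation, no continuity
        correction; if the pooled data are constant the test is degenerate
        and ``p = 1`` is returned with the ``degenerate`` flag set.
    mode="exact"
        Permutation null of U: full enumeration of the
        ``C(n1+n2, n1)`` group assignments when that count is within
        ``max_enumeration``, otherwise ``n_permutations`` seeded Monte-Carlo
        permutations. Two-sided p is the null probability of a deviation
        ``|U - n1 n2 / 2|`` at least as large as observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    if mode not in ("normal", "exact"):
        raise ValueError(f"mode must be 'normal' or 'exact', got {mode!r}")
    n1, n2 = len(x), len(y)
    u, z, var = _u_and_z(x, y)
    mu = n1 * n2 / 2.0

    if mode == "normal":
        if var <= 0:
            return MWUResult(u, 0.0, 1.0, degenerate=True)
        p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
        return MWUResult(u, z, p)

    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n = n1 + n2
    obs_dev = abs(u - mu)
    offset = n1 * (n1 + 1) / 2.0
    total = math.comb(n, n1)
    if total <= max_enumeration:
        devs = np.fromiter(
            (abs(sum(ranks[i] for i in idx) - offset - mu)
             for idx in combinations(range(n), n1)),
            dtype=float,
            count=total,
        )
        p = float((devs >= obs_dev - 1e-12).sum()) / total
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            u_perm = ranks[perm[:n1]].sum() - offset
            if abs(u_perm - mu) >= obs_dev - 1e-12:
                hits += 1
        # add-one estimate keeps Monte-Carlo p in (0, 1]
        p = (hits + 1) / (n_permutations + 1)
    return MWUResult(u, z, min(1.0, p), degenerate=var <= 0)


def _group_values(table: TaxonTable, meta: pd.DataFrame):
    meta = meta.loc[table.sample_ids]
    rec = table.values.loc[meta["group"] == "recurrence"]
    non = table.values.loc[meta["group"] == "non_recurrence"]
    return rec, non


def compare_all_taxa(
    table: TaxonTable, meta: pd.DataFrame, mode: str = "normal", seed: int = 0
) -> pd.DataFrame:
    """Run the group comparison for every taxon; unranked results.

    Returns one row per taxon with columns ``U, z, p_value, q_value,
    mean_recurrence, mean_non_recurrence, mean_difference``. ``q_value`` is
    the Benjamini-Hochberg adjusted p, supplementary to the raw ranking.
    """
    rec, non = _group_values(table, meta)
    if len(rec) < 2 or len(non) < 2:
        raise ValueError(
            f"need >=2 samples per group, got {len(rec)} recurrence / "
            f"{len(non)} non-recurrence"
        )
    rows = []
    for taxon in table.taxon_ids:
        x = rec[taxon].to_numpy()
        y = non[taxon].to_numpy()
        res = mann_whitney_u(x, y, mode=mode, seed=seed)
        rows.append(
            {
                "taxon": taxon,
                "U": res.U,
                "z": res.z,
                "p_value": res.p_value,
                "mean_recurrence": float(x.mean()),
                "mean_non_recurrence": float(y.mean()),
                "mean_difference": float(x.mean() - y.mean()),
                "degenerate": res.degenerate,
            }
        )
    out = pd.DataFrame(rows).set_index("taxon")
    out["q_value"] = stats.false_discovery_control(out["p_value"].to_numpy())
    return out


def rank_by_pvalue(
    table: TaxonTable,
    meta: pd.DataFrame,
    k: int = 10,
    mode: str = "normal",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank taxa by ascending raw p-value; return (full ranking, top-k).

    Ties in p are broken by |z| descending, then taxon id lexicographically,
    so the ranking is deterministic. The full frame carries a 1-based
    ``rank`` column; the second element is its head of length <= k.
    """
    res = compare_all_taxa(table, meta, mode=mode, seed=seed)
    order = sorted(
        res.index, key=lambda t: (res.at[t, "p_value"], -abs(res.at[t, "z"]), t)
    )
    ranked = res.loc[order].copy()
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    return ranked, ranked.head(k)


def rank_by_effect(
    table: TaxonTable, meta: pd.DataFrame, k: int = 7
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k taxa enriched in each group by mean abundance difference.

    Returns ``(recurrence_enriched, non_recurrence_enriched)``: the first is
    the k largest mean differences (recurrence minus non-recurrence,
    descending), the second the k smallest among the remaining taxa
    (ascending). The lists are disjoint by construction; ties break
    lexicographically.
    """
    res = compare_all_taxa(table, meta)
    desc = sorted(res.index, key=lambda t: (-res.at[t, "mean_difference"], t))
    rec_top = desc[:k]
    asc = sorted(res.index, key=lambda t: (res.at[t, "mean_difference"], t))
    non_top = [t for t in asc if t not in set(rec_top)][:k]
    cols = ["mean_recurrence", "mean_non_recurrence", "mean_difference"]
    return res.loc[rec_top, cols], res.loc[non_top, cols]
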