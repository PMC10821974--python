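"""Reading, validating and filtering taxon abundance tables and cohort metadata.

The canonical in-memory orientation is samples x taxa (a pandas DataFrame
whose index holds sample ids and whose columns hold taxon ids); on disk the
table uses the common taxonomy-export dialect of taxa rows x sample columns,
with the first column holding the full lineage string. All abundances are
percent composition in [0, 100]; every sample (row) sums to 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROW_SUM_TOL = 1e-6

#: ordered taxonomic ranks with their greengenes-style lineage prefixes
RANKS = [
    ("kingdom", "k__"),
    ("phylum", "p__"),
    ("class", "c__"),
    ("order", "o__"),
    ("family", "f__"),
    ("genus", "g__"),
    ("species", "s__"),
]
RANK_INDEX = {name: i for i, (name, _) in enumerate(RANKS)}


class TableFormatError(ValueError):
    """Raised when an abundance table or metadata file fails validation."""


@dataclass
class TaxonTable:
    """Samples x taxa percent-composition matrix with lineage metadata.

    Parameters
    ----------
    values
        DataFrame of percent abundances, samples as rows, taxon ids as
        columns. Rows must sum to 100 within ``ROW_SUM_TOL`` once
        :meth:`validate` is called with ``require_closure=True``.
    lineages
        Mapping taxon id -> full lineage string (may equal the id for
        synthetic taxa).
    level
        Taxonomic rank of the columns, ``"genus"`` or ``"species"``.
    """

    values: pd.DataFrame
    lineages: dict[str, str] = field(default_factory=dict)
    level: str = "genus"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def validate(self, require_closure: bool = True) -> "TaxonTable":
        idx = pd.Index(self.values.index)
        cols = pd.Index(self.values.columns)
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].tolist()
            raise TableFormatError(f"duplicate sample ids: {dup}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].tolist()
            raise TableFormatError(f"duplicate taxon ids: {dup}")
        vals = self.values.to_numpy(dtype=float)
        if np.isnan(vals).any():
            r, c = np.argwhere(np.isnan(vals))[0]
            raise TableFormatError(
                f"missing value at sample {idx[r]!r}, taxon {cols[c]!r}"
            )
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise TableFormatError(
                f"negative abundance at sample {idx[r]!r}, taxon {cols[c]!r}: "
                f"{vals[r, c]}"
            )
        if require_closure:
            sums = vals.sum(axis=1)
            bad = np.abs(sums - 100.0) > ROW_SUM_TOL
            if bad.any():
                r = int(np.argmax(bad))
                raise TableFormatError(
                    f"sample {idx[r]!r} sums to {sums[r]:.6f}, expected 100"
                )
        return self

    def renormalized(self) -> "TaxonTable":
        """Return a copy with every sample rescaled to sum to 100."""
        sums = self.values.sum(axis=1)
        if (sums <= 0).any():
            bad = sums.index[sums <= 0][0]
            raise TableFormatError(f"sample {bad!r} has zero total abundance")
        vals = self.values.div(sums, axis=0) * 100.0
        return TaxonTable(vals, dict(self.lineages), self.level)


def parse_lineage(lineage: str, level: str) -> str:
    """Extract the taxon id for ``level`` from a ';'-separated lineage string.

    Handles greengenes-style rank prefixes (``k__ ... s__``). A lineage that
    does not resolve at the requested rank is labeled
    ``"unclassified <deepest parent> (<parent rank>)"``, e.g. a genus-level
    query on ``...;f__Rikenellaceae;g__`` gives
    ``"unclassified Rikenellaceae (family)"``.
    """
    if level not in ("genus", "species"):
        raise ValueError(f"level must be 'genus' or 'species', got {level!r}")
    parts = [p.strip() for p in lineage.split(";")]
    names: dict[str, str] = {}
    prefixed = False
    for part in parts:
        for rank, prefix in RANKS:
            if part.startswith(prefix):
                prefixed = True
                names[rank] = part[len(prefix):].strip().strip("[]")
                break
    if not prefixed:
        if len(parts) == 1:
            return parts[0] or "unclassified"
        # bare multi-part lineage: assume ranks in canonical order
        for (rank, _), part in zip(RANKS, parts):
            names[rank] = part.strip()
    target = names.get(level, "")
    if target:
        if level == "species":
            genus = names.get("genus", "")
            if genus and not target.startswith(genus):
                return f"{genus} {target}"
        return target
    # fall back to the deepest classified ancestor
    for rank, _ in reversed(RANKS[: RANK_INDEX[level]]):
        name = names.get(rank, "")
        if name:
            return f"unclassified {name} ({rank})"
    return "unclassified"


def _read_header(path: str, sep: str) -> list[str]:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return [c.strip() for c in line.rstrip("\n").split(sep)]
    raise TableFormatError(f"{path}: no header line found")


def _sep_for(path: str) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def load_taxon_table(path: str, level: str = "genus") -> TaxonTable:
    """Read a taxa-rows x sample-columns TSV/CSV into a :class:`TaxonTable`.

    The first column holds the lineage string; remaining columns are samples
    with percent abundances. Lines starting with ``#`` are ignored. The file
    is transposed into the in-memory samples x taxa orientation and taxon
    ids are derived from the lineages at the requested rank; ids colliding
    at that rank are aggregated by summation (reads binned to the same
    genus/species).
    """
    sep = _sep_for(path)
    header = _read_header(path, sep)
    samples = header[1:]
    dup = pd.Index(samples)
    if dup.has_duplicates:
        raise TableFormatError(
            f"{path}: duplicate sample column(s): {dup[dup.duplicated()].tolist()}"
        )
    try:
        raw = pd.read_csv(path, sep=sep, comment="#", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows and friends
        raise TableFormatError(f"{path}: malformed table: {exc}") from exc
    raw.index = raw.index.astype(str)
    try:
        mat = raw.astype(float)
    except ValueError as exc:
        raise TableFormatError(f"{path}: non-numeric abundance value: {exc}") from exc
    if mat.isna().any().any():
        row = mat.index[mat.isna().any(axis=1)][0]
        col = mat.columns[mat.isna().any(axis=0)][0]
        raise TableFormatError(f"{path}: missing value at taxon {row!r}, sample {col!r}")

    lineage_strings = list(mat.index)
    taxon_ids = [parse_lineage(lin, level) for lin in lineage_strings]
    lineages: dict[str, str] = {}
    for tid, lin in zip(taxon_ids, lineage_strings):
        lineages.setdefault(tid, lin)
    # aggregate duplicate ids at the requested rank, preserve first-seen order
    mat.index = pd.Index(taxon_ids, name="taxon")
    order = list(dict.fromkeys(taxon_ids))
    mat = mat.groupby(level=0, sort=False).sum().loc[order]
    table = TaxonTable(mat.T, lineages, level)
    table.validate(require_closure=False)
    sums = table.values.sum(axis=1)
    if (np.abs(sums - 100.0) > ROW_SUM_TOL).any():
        table = table.renormalized()
    return table.validate()


def write_taxon_table(table: TaxonTable, path: str) -> None:
    """Write the on-disk dialect (taxa rows x sample columns)."""
    sep = _sep_for(path)
    out = table.values.T.copy()
    out.index = pd.Index(
        [table.lineages.get(t, t) for t in out.index], name="taxon"
    )
    out.to_csv(path, sep=sep, float_format="%.10g")


METADATA_COLUMNS = ["group", "survival_months", "event", "age", "sex", "stage"]
GROUPS = ("recurrence", "non_recurrence")


def validate_metadata(meta: pd.DataFrame, table: TaxonTable | None = None) -> pd.DataFrame:
    """Check the per-sample metadata contract; return the frame unchanged."""
    if meta.empty:
        raise TableFormatError("metadata is empty")
    if meta.index.has_duplicates:
        dup = meta.index[meta.index.duplicated()].tolist()
        raise TableFormatError(f"duplicate metadata sample ids: {dup}")
    for col in ("group", "survival_months", "event"):
        if col not in meta.columns:
            raise TableFormatError(f"metadata missing required column {col!r}")
    bad_group = set(meta["group"]) - set(GROUPS)
    if bad_group:
        raise TableFormatError(f"unknown group label(s): {sorted(bad_group)}")
    if (meta["survival_months"].astype(float) < 0).any():
        raise TableFormatError("negative survival_months")
    if not meta["event"].isin([0, 1]).all():
        raise TableFormatError("event must be 0 or 1")
    zero_event = (meta["event"] == 1) & (meta["survival_months"].astype(float) <= 0)
    if zero_event.any():
        raise TableFormatError(
            f"event=1 requires survival_months > 0 (sample {meta.index[zero_event][0]!r})"
        )
    if table is not None:
        missing = set(table.sample_ids) - set(meta.index)
        if missing:
            raise TableFormatError(f"samples without metadata: {sorted(missing)}")
    return meta


def load_metadata(path: str) -> pd.DataFrame:
    sep = _sep_for(path)
    meta = pd.read_csv(path, sep=sep, comment="#", index_col="sample_id")
    meta.index = meta.index.astype(str)
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path: str) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep=_sep_for(path))


def filter_and_renormalize(
    table: TaxonTable, min_pct: float = 0.1, criterion: str = "mean"
) -> TaxonTable:
    """Drop low-abundance taxa and rescale each sample back to 100%.

    ``criterion="mean"`` (default) removes taxa whose mean relative abundance
    across samples is <= ``min_pct`` percent, the reading under which the
    retained taxa are "summed to 100%". ``criterion="prevalence"`` instead
    keeps taxa detected (abundance > 0) in more than ``min_pct`` percent of
    samples. Taxon order is preserved.
    """
    if criterion == "mean":
        keep = table.values.mean(axis=0) > min_pct
    elif criterion == "prevalence":
        keep = (table.values > 0).mean(axis=0) * 100.0 > min_pct
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    if not keep.any():
        raise TableFormatError("empty table after filtering")
    kept = table.values.loc[:, keep]
    lineages = {t: table.lineages.get(t, t) for t in kept.columns}
    return TaxonTable(kept, lineages, table.level).renormalized()


def summarize_cohort(meta: pd.DataFrame) -> pd.DataFrame:
    """Per-group cohort summary: n, sex counts, stage counts with percentages.

    Returns a long-format frame with columns ``group, variable, category, n,
    pct`` where ``pct`` is the percentage of the group total rounded to one
    decimal. A final ``total`` row carries the grand total.
    """
    validate_metadata(meta)
    rows = []
    for group in GROUPS:
        sub = meta[meta["group"] == group]
        n_group = len(sub)
        rows.append((group, "n", "all", n_group, 100.0 if n_group else 0.0))
        for var in ("sex", "stage"):
            if var not in meta.columns:
                continue
            counts = sub[var].dropna().astype(str).value_counts()
            categories = sorted(meta[var].dropna().astype(str).unique())
            for category in categories:
                n = int(counts.get(category, 0))
                pct = round(100.0 * n / n_group, 1) if n_group else 0.0
                rows.append((group, var, category, n, pct))
    total = int((meta["group"].isin(GROUPS)).sum())
    rows.append(("all", "n", "total", total, 100.0))
    return pd.DataFrame(rows, columns=["group", "variable", "category", "n", "pct"])
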