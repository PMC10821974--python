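"""Shared fixtures: tiny hand-built tables and a session-scoped spiked cohort."""

import numpy as np
import pandas as pd
import pytest

from taxomark.io import TaxonTable, filter_and_renormalize
from taxomark.synthetic import SyntheticSpec, baseline_composition, generate_cohort


def make_table(values, sample_ids=None, taxon_ids=None, level="genus"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = sample_ids or [f"S{i}" for i in range(n)]
    taxon_ids = taxon_ids or [f"g__T{j}" for j in range(p)]
    frame = pd.DataFrame(values, index=sample_ids, columns=taxon_ids)
    return TaxonTable(frame, {t: t for t in taxon_ids}, level)


def make_meta(groups, times=None, events=None, **cols):
    n = len(groups)
    times = times if times is not None else [24.0] * n
    events = events if events is not None else [0] * n
    return pd.DataFrame(
        {"group": groups, "survival_months": times, "event": events, **cols},
        index=pd.Index([f"S{i}" for i in range(n)], name="sample_id"),
    )


def table1_metadata():
    """Cohort metadata matching the published patient-background table:
    18 recurrent (16 M / 2 F) and 33 non-recurrent (22 M / 11 F) subjects
    with the printed pTNM stage counts."""
    rec_stages = (
        ["IA"] * 2 + ["IB"] + ["IIA"] + ["IIB"] * 2 + ["IIIA"] * 2
        + ["IIIB"] * 5 + ["IIIC"] * 2 + ["IV"] * 3
    )
    non_stages = (
        ["0"] * 5 + ["IA"] * 11 + ["IB"] * 2 + ["IIA"] * 2 + ["IIB"] * 9
        + ["IIIA"] * 2 + ["IIIB"] * 2
    )
    groups = ["recurrence"] * 18 + ["non_recurrence"] * 33
    sex = ["male"] * 16 + ["female"] * 2 + ["male"] * 22 + ["female"] * 11
    return pd.DataFrame(
        {
            "group": groups,
            "survival_months": [24.0] * 51,
            "event": [0] * 51,
            "sex": sex,
            "stage": rec_stages + non_stages,
        },
        index=pd.Index([f"P{i:02d}" for i in range(51)], name="sample_id"),
    )


def spiked_spec(seed=1, fold=5.0, n_taxa=300, **kw):
    """Cohort spec with one taxon spiked in the recurrence group, the spike
    placed on the taxon whose baseline abundance is nearest 1% so it both
    survives the composition filter and matters to the classifiers."""
    probe = SyntheticSpec(seed=seed, n_taxa=n_taxa)
    base = baseline_composition(probe) * 100.0
    idx = int(np.argmin(np.abs(base - 1.0)))
    return SyntheticSpec(
        seed=seed, n_taxa=n_taxa, spiked_taxa=[(idx, fold)],
        biomarker_taxon=idx, cutoff_pct=float(base[idx]), **kw
    ), idx


@pytest.fixture(scope="session")
def spiked_cohort():
    spec, idx = spiked_spec(seed=1)
    table, meta = generate_cohort(spec)
    return spec, table, meta, table.taxon_ids[idx]


@pytest.fixture(scope="session")
def filtered_spiked(spiked_cohort):
    spec, table, meta, spike = spiked_cohort
    return filter_and_renormalize(table), meta, spike
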