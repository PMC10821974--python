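"""Synthetic compositional cohorts with group-dependent taxa and survival.

Emulates a small surgical cohort (default 18 recurrence / 33 non-recurrence
subjects) whose gut-microbiome profile is a sparse percent-composition table
over several hundred taxa. Baseline taxon proportions are drawn once from a
heavy-tailed law (log-normal scales, normalized) shared by both groups;
designated "spiked" taxa have their baseline multiplied in the recurrence
group before per-subject Dirichlet sampling, so group effects remain
compositionally coherent. Optional multinomial resampling at a fixed read
depth adds count noise. Overall survival follows an exponential hazard that
is multiplied by ``hazard_ratio_high`` whenever a designated biomarker
taxon's abundance exceeds a percent cutoff, with administrative censoring at
``followup_max`` months.

One integer seed drives everything; independent sub-streams are derived by
fixed offsets for the baseline, per-subject composition, survival, and
covariates, so e.g. changing hazard parameters never perturbs the abundance
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import TaxonTable

# fixed sub-stream offsets (arbitrary distinct constants)
_STREAM_BASELINE = 11
_STREAM_COMPOSITION = 13
_STREAM_SURVIVAL = 17
_STREAM_COVARIATES = 19

# stage frequencies used for the synthetic covariates, by group, mirroring a
# typical early-vs-advanced shift between non-recurrent and recurrent disease
_STAGE_LEVELS = ["0", "IA", "IB", "IIA", "IIB", "IIIA", "IIIB", "IIIC", "IV"]
_STAGE_P = {
    "recurrence": [0, 2, 1, 1, 2, 2, 5, 2, 3],
    "non_recurrence": [5, 11, 2, 2, 9, 2, 2, 0, 0],
}


class SyntheticSpecError(ValueError):
    """Invalid generator specification; the message names the field."""


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic cohort generator.

    Defaults follow the study design the analysis targets: 18 recurrence vs
    33 non-recurrence subjects, 300 sparse compositional taxa, a read depth
    in the 5,000-10,000 rarefaction range, a 60-month follow-up window
    (minimum observation 12 months, events on a monthly scale), and an
    abundance cutoff of 0.75% for the survival biomarker.
    """

    n_recurrence: int = 18
    n_non_recurrence: int = 33
    n_taxa: int = 300
    #: (taxon index, multiplicative fold >= 0 applied in the recurrence group)
    spiked_taxa: list[tuple[int, float]] = field(default_factory=list)
    #: Dirichlet concentration scalar; larger = less subject-to-subject noise
    concentration: float = 50.0
    #: multinomial read depth per sample; 0 disables count noise
    depth: int = 10_000
    hazard_base: float = 0.01  # events per month
    hazard_ratio_high: float = 4.0
    biomarker_taxon: int = 0
    cutoff_pct: float = 0.75
    followup_max: float = 60.0
    seed: int = 0

    def validate(self) -> "SyntheticSpec":
        if self.n_recurrence < 1:
            raise SyntheticSpecError("n_recurrence must be >= 1")
        if self.n_non_recurrence < 1:
            raise SyntheticSpecError("n_non_recurrence must be >= 1")
        if self.n_recurrence + self.n_non_recurrence < 2:
            raise SyntheticSpecError("n_recurrence + n_non_recurrence must be >= 2")
        if self.n_taxa < 1:
            raise SyntheticSpecError("n_taxa must be >= 1")
        for idx, fold in self.spiked_taxa:
            if not (0 <= idx < self.n_taxa):
                raise SyntheticSpecError(
                    f"spiked_taxa index {idx} out of range for n_taxa={self.n_taxa}"
                )
            if fold < 0:
                raise SyntheticSpecError(f"spiked_taxa fold must be >= 0, got {fold}")
        if self.concentration <= 0:
            raise SyntheticSpecError("concentration must be > 0")
        if self.depth < 0:
            raise SyntheticSpecError("depth must be >= 0")
        if self.hazard_base <= 0:
            raise SyntheticSpecError("hazard_base must be > 0")
        if self.hazard_ratio_high < 0:
            raise SyntheticSpecError("hazard_ratio_high must be >= 0")
        if not (0 <= self.biomarker_taxon < self.n_taxa):
            raise SyntheticSpecError(
                f"biomarker_taxon {self.biomarker_taxon} out of range"
            )
        if not (0 <= self.cutoff_pct <= 100):
            raise SyntheticSpecError("cutoff_pct must be in [0, 100]")
        if self.followup_max <= 0:
            raise SyntheticSpecError("followup_max must be > 0")
        return self


def _stream(spec: SyntheticSpec, offset: int) -> np.random.Generator:
    return np.random.default_rng([int(spec.seed), offset])


def taxon_names(n_taxa: int) -> list[str]:
    width = len(str(n_taxa - 1))
    return [f"g__Taxon{str(i).zfill(width)}" for i in range(n_taxa)]


def baseline_composition(spec: SyntheticSpec) -> np.ndarray:
    """Shared baseline proportions (sum to 1), before any group spiking.

    Deterministic in ``(seed, n_taxa)`` only, so callers may inspect the
    baseline to choose spike/biomarker indices before generating the cohort.
    """
    spec.validate()
    rng = _stream(spec, _STREAM_BASELINE)
    scales = rng.lognormal(mean=0.0, sigma=2.0, size=spec.n_taxa)
    return scales / scales.sum()


def expected_group_means(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Analytic expected percent abundance per taxon for each group.

    The recurrence-group baseline is the spiked, renormalized baseline; the
    Dirichlet and multinomial stages are mean-preserving, so the expectation
    of each group's composition equals its (re)normalized baseline.
    Returns ``(mean_recurrence, mean_non_recurrence)`` in percent.
    """
    base = baseline_composition(spec)
    spiked = base.copy()
    for idx, fold in spec.spiked_taxa:
        spiked[idx] *= fold
    spiked = spiked / spiked.sum()
    return spiked * 100.0, base * 100.0


def generate_cohort(spec: SyntheticSpec) -> tuple[TaxonTable, pd.DataFrame]:
    """Draw one labeled cohort: percent-composition table plus metadata.

    Samples are named ``R00..`` (recurrence) and ``N00..`` (non-recurrence).
    Identical spec + seed reproduces the output bit for bit.
    """
    spec.validate()
    base = baseline_composition(spec)
    spiked = base.copy()
    for idx, fold in spec.spiked_taxa:
        spiked[idx] *= fold
    spiked = spiked / spiked.sum()

    n_rec, n_non = spec.n_recurrence, spec.n_non_recurrence
    n = n_rec + n_non
    groups = ["recurrence"] * n_rec + ["non_recurrence"] * n_non
    sample_ids = [f"R{i:03d}" for i in range(n_rec)] + [
        f"N{i:03d}" for i in range(n_non)
    ]

    comp_rng = _stream(spec, _STREAM_COMPOSITION)
    props = np.empty((n, spec.n_taxa))
    # tiny alpha floor keeps the Dirichlet proper when a spike fold is 0
    for i, group in enumerate(groups):
        mean = spiked if group == "recurrence" else base
        alpha = np.maximum(spec.concentration * mean, 1e-9)
        props[i] = comp_rng.dirichlet(alpha)
    if spec.depth > 0:
        for i in range(n):
            counts = comp_rng.multinomial(spec.depth, props[i])
            props[i] = counts / spec.depth
    percent = props * 100.0

    surv_rng = _stream(spec, _STREAM_SURVIVAL)
    biomarker_pct = percent[:, spec.biomarker_taxon]
    high = biomarker_pct > spec.cutoff_pct
    rate = spec.hazard_base * np.where(high, spec.hazard_ratio_high, 1.0)
    # one unit-exponential draw per subject, scaled by the subject's rate, so
    # the stream position does not depend on hazard parameters
    unit = surv_rng.exponential(1.0, size=n)
    draws = np.where(rate > 0, unit / np.maximum(rate, 1e-300), np.inf)
    time = np.minimum(draws, spec.followup_max)
    event = (draws <= spec.followup_max).astype(int)

    cov_rng = _stream(spec, _STREAM_COVARIATES)
    age = cov_rng.integers(40, 86, size=n)
    sex = cov_rng.choice(["male", "female"], size=n, p=[0.75, 0.25])
    stage = np.empty(n, dtype=object)
    for group in ("recurrence", "non_recurrence"):
        mask = np.array([g == group for g in groups])
        p = np.asarray(_STAGE_P[group], dtype=float)
        stage[mask] = cov_rng.choice(_STAGE_LEVELS, size=mask.sum(), p=p / p.sum())

    names = taxon_names(spec.n_taxa)
    values = pd.DataFrame(percent, index=sample_ids, columns=names)
    table = TaxonTable(values, {t: t for t in names}, level="genus")
    meta = pd.DataFrame(
        {
            "group": groups,
            "survival_months": np.round(time, 6),
            "event": event,
            "age": age,
            "sex": sex,
            "stage": stage,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return table, meta


def pick_biomarker_cutoff(
    spec: SyntheticSpec, target_pct: float | None = None
) -> tuple[int, float]:
    """Choose a biomarker taxon and an abundance cutoff that splits the cohort.

    Returns the index of the taxon whose baseline percent abundance is
    closest to ``target_pct`` (default: the spec's ``cutoff_pct``, i.e. a
    taxon living near the intended threshold) together with the median of
    that taxon's realized percent abundance across the generated cohort, so
    that both strata of an abundance dichotomy are non-empty. Uses only the
    composition sub-streams; survival parameters are irrelevant here.
    """
    base = baseline_composition(spec) * 100.0
    target = spec.cutoff_pct if target_pct is None else target_pct
    idx = int(np.argmin(np.abs(base - target)))
    table, _ = generate_cohort(spec)
    cutoff = float(np.median(table.values.iloc[:, idx]))
    return idx, cutoff
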