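"""End-to-end orchestration: simulate-or-load through survival validation.

Stage order: ingest (or synthesize) the abundance table and metadata ->
composition filter -> univariate track (Mann-Whitney ranking, effect
ranking) -> machine-learning track (tuning, LOSO stability repeats) ->
consensus -> single-biomarker ROC and cutpoint -> abundance-dichotomized
survival comparison. Every stage writes a plain-text artifact into the
output directory and the run ends with a manifest (config echo, seeds,
package version, SHA-256 checksums) sufficient to reproduce the analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .consensus import consensus_taxa, select_cutpoint, taxon_roc
from .diffabund import rank_by_effect, rank_by_pvalue
from .io import (
    TaxonTable,
    filter_and_renormalize,
    load_metadata,
    load_taxon_table,
    summarize_cohort,
    validate_metadata,
    write_metadata,
    write_taxon_table,
)
from .stability import run_stability_analysis, tune_hyperparameters
from .survival import dichotomize_and_compare
from .synthetic import SyntheticSpec, generate_cohort

log = logging.getLogger("taxomark")

#: resolved tuning effort per profile (trials of full-LOSO random search)
PROFILE_TRIALS = {"desk": 15, "paper": 1000}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Single source of truth for one pipeline run.

    Defaults reproduce the analysis constants: 0.1% composition filter,
    univariate top 10, effect top 7, 1000 tuning trials (paper profile),
    4 stability repeats, top-10 stability counting, and a fixed 0.75%
    abundance cutpoint option.
    """

    outdir: str = "taxomark_out"
    level: str = "genus"
    # exactly one of (table_path & metadata_path) or synthetic
    table_path: str | None = None
    metadata_path: str | None = None
    synthetic: dict | None = None
    min_pct: float = 0.1
    filter_criterion: str = "mean"
    univariate_k: int = 10
    effect_k: int = 7
    profile: str = "paper"
    n_trials: int | None = None  # None -> PROFILE_TRIALS[profile]
    tuning_seed: int = 1
    repeat_seeds: tuple[int, ...] = (101, 102, 103, 104)
    stability_k: int = 10
    cutpoint_method: str = "youden"
    cutpoint_value: float = 0.75
    biomarker_taxon: str | None = None  # None -> consensus/stability leader
    survival_subgroup: str | None = None

    def validate(self) -> "PipelineConfig":
        has_paths = self.table_path is not None or self.metadata_path is not None
        if has_paths and self.synthetic is not None:
            raise ValueError("give either input paths or a synthetic spec, not both")
        if not has_paths and self.synthetic is None:
            raise ValueError("give input paths or a synthetic spec")
        if has_paths and (self.table_path is None or self.metadata_path is None):
            raise ValueError("both table_path and metadata_path are required")
        if self.profile not in PROFILE_TRIALS:
            raise ValueError(f"unknown profile {self.profile!r}")
        if len(set(self.repeat_seeds)) != len(self.repeat_seeds):
            raise ValueError("repeat_seeds must be distinct")
        return self

    @property
    def resolved_trials(self) -> int:
        return self.n_trials if self.n_trials is not None else PROFILE_TRIALS[self.profile]

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "repeat_seeds" in raw:
            raw["repeat_seeds"] = tuple(raw["repeat_seeds"])
        return cls(**raw).validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["repeat_seeds"] = list(self.repeat_seeds)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; return the in-memory report bundle.

    The bundle maps stage names to their results (tables as DataFrames,
    tuned config, curves) plus ``paths`` with every artifact written.
    Stage failures raise :class:`StageError` naming the stage; artifacts
    from earlier stages are left on disk for debugging.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    bundle: dict = {"config": config, "paths": paths}
    t0 = time.time()

    def _stage(name: str):
        log.info("[%7.1fs] stage: %s", time.time() - t0, name)

    def _write(name: str, frame: pd.DataFrame, **kw) -> Path:
        p = outdir / name
        frame.to_csv(p, sep="\t", **kw)
        paths[name] = p
        return p

    try:
        _stage("ingest")
        if config.synthetic is not None:
            spec = SyntheticSpec(**config.synthetic)
            table, meta = generate_cohort(spec)
            write_taxon_table(table, str(outdir / "table.tsv"))
            write_metadata(meta, str(outdir / "metadata.tsv"))
            paths["table.tsv"] = outdir / "table.tsv"
            paths["metadata.tsv"] = outdir / "metadata.tsv"
        else:
            table = load_taxon_table(config.table_path, level=config.level)
            meta = load_metadata(config.metadata_path)
        validate_metadata(meta, table)
        bundle["table"], bundle["metadata"] = table, meta
        _write("cohort_summary.tsv", summarize_cohort(meta), index=False)
    except Exception as exc:
        raise StageError(f"ingest: {exc}") from exc

    try:
        _stage("filter")
        filtered = filter_and_renormalize(table, config.min_pct, config.filter_criterion)
        bundle["filtered"] = filtered
        write_taxon_table(filtered, str(outdir / f"filtered_{config.level}.tsv"))
        paths[f"filtered_{config.level}.tsv"] = outdir / f"filtered_{config.level}.tsv"
    except Exception as exc:
        raise StageError(f"filter: {exc}") from exc

    try:
        _stage("univariate")
        uni_full, uni_top = rank_by_pvalue(filtered, meta, k=config.univariate_k)
        rec_eff, non_eff = rank_by_effect(filtered, meta, k=config.effect_k)
        bundle["univariate"], bundle["univariate_topk"] = uni_full, uni_top
        bundle["effect"] = (rec_eff, non_eff)
        _write(f"univariate_{config.level}.tsv", uni_full)
        _write(f"effect_recurrence_{config.level}.tsv", rec_eff)
        _write(f"effect_non_recurrence_{config.level}.tsv", non_eff)
    except Exception as exc:
        raise StageError(f"univariate: {exc}") from exc

    try:
        _stage("tuning")
        tuned = tune_hyperparameters(
            filtered, meta, config.resolved_trials, config.tuning_seed,
            profile=config.profile,
        )
        bundle["tuned"] = tuned
        _write("tuning_trials.tsv", tuned.trials, index=False)
    except Exception as exc:
        raise StageError(f"tuning: {exc}") from exc

    try:
        _stage("stability")
        ranking, performances = run_stability_analysis(
            filtered, meta, tuned, config.repeat_seeds, k=config.stability_k
        )
        bundle["stability"] = ranking
        bundle["cv_performance"] = performances
        _write(f"stability_{config.level}.tsv", ranking)
        perf = pd.DataFrame(
            [dataclasses.asdict(p) for p in performances],
            index=pd.Index(
                [f"repeat_{i+1}" for i in range(len(performances))], name="repeat"
            ),
        )
        _write("cv_performance.tsv", perf)
    except Exception as exc:
        raise StageError(f"stability: {exc}") from exc

    try:
        _stage("consensus")
        uni_list = list(uni_top.index)
        stab_list = list(ranking.head(config.stability_k).index)
        cons = consensus_taxa(uni_list, stab_list, level=config.level)
        bundle["consensus"] = cons
        _write(
            f"consensus_{config.level}.tsv",
            pd.DataFrame({"taxon": cons.intersection}),
            index=False,
        )
    except Exception as exc:
        raise StageError(f"consensus: {exc}") from exc

    try:
        _stage("roc_cutpoint")
        biomarker = config.biomarker_taxon
        if biomarker is None:
            biomarker = cons.intersection[0] if cons.intersection else stab_list[0]
        bundle["biomarker"] = biomarker
        outcome = meta.loc[filtered.sample_ids, "event"].to_numpy(dtype=int)
        roc = taxon_roc(filtered, outcome, taxon=biomarker)
        cut = select_cutpoint(roc, config.cutpoint_method, config.cutpoint_value)
        bundle["roc"], bundle["cutpoint"] = roc, cut
        safe = biomarker.replace("/", "_").replace(" ", "_")
        _write(
            f"roc_{safe}.tsv",
            pd.DataFrame(
                {"threshold": roc.thresholds, "fpr": roc.fpr, "tpr": roc.tpr}
            ),
            index=False,
        )
        (outdir / "cutpoint.txt").write_text(
            f"taxon\t{biomarker}\nmethod\t{config.cutpoint_method}\n"
            f"cutpoint_pct\t{cut:.6g}\nauc\t{roc.auc:.6g}\n"
        )
        paths["cutpoint.txt"] = outdir / "cutpoint.txt"
    except Exception as exc:
        raise StageError(f"roc_cutpoint: {exc}") from exc

    try:
        _stage("survival")
        km_high, km_low, lr = dichotomize_and_compare(
            filtered, meta, biomarker, cut, subgroup=config.survival_subgroup
        )
        bundle["km_high"], bundle["km_low"], bundle["logrank"] = km_high, km_low, lr
        for name, km in (("high", km_high), ("low", km_low)):
            _write(
                f"km_{name}.tsv",
                pd.DataFrame(
                    {
                        "time_months": km.event_times,
                        "n_at_risk": km.n_at_risk,
                        "n_events": km.n_events,
                        "survival": km.survival,
                    }
                ),
                index=False,
            )
        _write(
            "logrank.tsv",
            pd.DataFrame(
                {
                    "stratum": ["high", "low"],
                    "observed": lr.observed,
                    "expected": lr.expected,
                    "chi_square": [lr.chi_square] * 2,
                    "p_value": [lr.p_value] * 2,
                }
            ),
            index=False,
        )
    except Exception as exc:
        raise StageError(f"survival: {exc}") from exc

    _stage("manifest")
    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "tuned_params": tuned.params,
        "tuned_objective": tuned.objective,
        "biomarker": biomarker,
        "cutpoint_pct": cut,
        "checksums": {name: _sha256(p) for name, p in sorted(paths.items())},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    paths["manifest.json"] = outdir / "manifest.json"
    _stage("done")
    return bundle
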