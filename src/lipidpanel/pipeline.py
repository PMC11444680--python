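"""End-to-end workflow orchestration.

``run_pipeline`` executes the stages in study order — simulate (or load) ->
preprocess -> unsupervised structure check -> holdout segregation ->
consensus feature selection -> validation (with permutation control) ->
classical statistics — from a single :class:`PipelineConfig` with one master
seed from which every stage seed is derived deterministically.

The neuropathy task carries the study's decision rule: when every classifier
family's balanced-accuracy CI on the reduced panel contains chance (0.5),
multivariate selection is not considered validated and selection is re-run
with univariate methods only (effect size, FPR, FWE).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .data import make_labeling, read_dataset
from .errors import ParameterError, PipelineError
from .esom import EsomSpec, extract_clusters, train_esom, umatrix
from .preprocess import filter_missing, log_transform, rf_impute, z_standardize
from .selection import run_moe, univariate_ensemble
from .stats import adjust_p, class_enrichment, kruskal_wallis
from .structure import cluster_class_association, pca_structure
from .synthetic import SyntheticSpec, generate
from .validation import default_specs, split_holdout, validate

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Single source of truth for one pipeline run."""

    task: str = "timepoint"
    master_seed: int = 0
    # data source: either a simulation spec or paths to tables
    simulate: bool = True
    synthetic: dict = field(default_factory=dict)
    values_path: Optional[str] = None
    metadata_path: Optional[str] = None
    annotation_path: Optional[str] = None
    # stage parameters
    missing_threshold: float = 0.2
    #: impute the whole matrix once before holdout segregation (the workflow
    #: order this pipeline reproduces) or each partition separately
    impute_per_partition: bool = False
    holdout_fraction: float = 0.2
    n_splits: int = 5
    n_repeats: int = 20
    run_structure: bool = False  # ESOM is informative but not needed for sets
    esom: dict = field(default_factory=dict)
    correction: str = "bh"
    enrichment_class: str = "sphingolipid"

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        digest = hashlib.sha256(f"{self.master_seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class RunReport:
    config_hash: str
    artifacts: dict[str, str]
    summary: dict


def _load_or_simulate(config: PipelineConfig):
    if config.simulate:
        spec = SyntheticSpec(**{**config.synthetic,
                                "seed": config.stage_seed("simulate")})
        ds, truth = generate(spec)
        return ds, truth
    if not (config.values_path and config.metadata_path):
        raise ParameterError("need values_path and metadata_path when not simulating")
    ds = read_dataset(config.values_path, config.metadata_path,
                      config.annotation_path)
    return ds, None


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunReport:
    """Execute the full workflow; writes JSON/CSV artifacts under ``out_dir``."""
    if not 0 < config.holdout_fraction < 1:
        raise ParameterError("holdout_fraction must be in (0, 1)")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    summary: dict = {"task": config.task, "master_seed": config.master_seed}
    t0 = time.time()

    def _stage(name):
        logger.info("stage %s (seed %d) at +%.1fs", name,
                    config.stage_seed(name), time.time() - t0)

    try:
        _stage("simulate")
        ds, truth = _load_or_simulate(config)
        summary["input_shape"] = list(ds.shape)

        _stage("preprocess")
        ds = log_transform(ds)
        ds, filt_report = filter_missing(ds, config.missing_threshold)
        n_imputed = 0
        if not config.impute_per_partition:
            ds, imp_report = rf_impute(ds, seed=config.stage_seed("impute"))
            n_imputed = len(imp_report.imputed_cells)

        labeling = make_labeling(ds, config.task)

        _stage("holdout")
        train, holdout = split_holdout(
            ds, labeling, fraction=config.holdout_fraction,
            seed=config.stage_seed("holdout"),
        )
        if config.impute_per_partition:
            # strictest leakage control: each partition imputed on its own
            train, rep_t = rf_impute(train, seed=config.stage_seed("impute"))
            holdout, rep_h = rf_impute(
                holdout, seed=config.stage_seed("impute-holdout")
            )
            ds = _recombine(ds, train, holdout)
            n_imputed = len(rep_t.imputed_cells) + len(rep_h.imputed_cells)
        summary["preprocess"] = {
            "dropped_features": filt_report.dropped_features,
            "dropped_samples": filt_report.dropped_samples,
            "n_imputed_cells": n_imputed,
        }
        # scale both partitions with training statistics only: no leakage
        ds_z = z_standardize(ds, fit_on=train.sample_ids)
        train = ds_z.subset_samples(train.sample_ids)
        holdout_z = ds_z.subset_samples(holdout.sample_ids)
        summary["split"] = {
            "n_train": train.n_samples, "n_holdout": holdout.n_samples
        }

        if config.run_structure:
            _stage("structure")
            pca = pca_structure(train)
            model = train_esom(train, EsomSpec(**config.esom),
                               seed=config.stage_seed("esom"))
            um = umatrix(model, train)
            structure_summary = {
                "n_retained_components": pca.n_retained,
                "explained_fraction": pca.explained_fraction,
                "n_important_features": len(pca.important_features),
            }
            try:
                clusters = extract_clusters(um, model, n_clusters=2)
                assoc = cluster_class_association(
                    clusters, labeling.restrict(train.sample_ids)
                )
                structure_summary["cluster_class_p"] = assoc.p
                structure_summary["cluster_class_odds_ratio"] = assoc.statistic
            except Exception as exc:
                structure_summary["clustering"] = f"failed: {exc}"
            summary["structure"] = structure_summary

        _stage("select")
        tally = run_moe(
            train, labeling, n_splits=config.n_splits,
            n_repeats=config.n_repeats, seed=config.stage_seed("select"),
        )
        tally.counts.to_csv(out_dir / "tally.csv")
        artifacts["tally"] = str(out_dir / "tally.csv")
        sets = {"reduced": tally.reduced_set, "sparse": tally.sparse_set}

        _stage("validate")
        specs = default_specs(config.task)
        reports = {}
        for name, feats in sets.items():
            if not feats:
                continue
            for permute in (False, True):
                key = f"{name}_permuted" if permute else name
                reports[key] = validate(
                    train, holdout_z, labeling, feats, specs=specs,
                    n_splits=config.n_splits, n_repeats=config.n_repeats,
                    seed=config.stage_seed(f"validate:{key}"), permute=permute,
                )

        # univariate fallback: multivariate selection counts only when some
        # family separates from chance on the reduced panel
        fallback = False
        if "reduced" in reports:
            rep = reports["reduced"]
            fallback = not any(
                rep.separated_from_chance(f) for f in rep.summary.index
            )
        if fallback:
            _stage("select-univariate")
            tally = run_moe(
                train, labeling, ensemble=univariate_ensemble(),
                n_splits=config.n_splits, n_repeats=config.n_repeats,
                seed=config.stage_seed("select-univariate"),
            )
            sets = {"reduced": tally.reduced_set, "sparse": tally.sparse_set}
        summary["univariate_fallback"] = fallback
        sets_payload = {
            **sets,
            "sum_score": {f: int(v) for f, v in tally.sum_score.items()
                          if v > 0},
        }
        (out_dir / "sets.json").write_text(json.dumps(sets_payload, indent=1))
        artifacts["sets"] = str(out_dir / "sets.json")

        summary["validation"] = {
            key: {
                fam: {
                    "median_balanced_accuracy": rep.median(fam),
                    "ci": list(rep.ci(fam)),
                    "separated_from_chance": rep.separated_from_chance(fam),
                }
                for fam in rep.summary.index
            }
            for key, rep in reports.items()
        }

        _stage("stats")
        stat_rows = []
        lab = labeling.restrict(ds.sample_ids)
        final_set = sets["sparse"] or sets["reduced"]
        for feat in final_set:
            vals = ds.values.loc[lab.included_samples, feat]
            groups = [vals[lab.labels == c].to_numpy()
                      for c in sorted(set(lab.labels))]
            res = kruskal_wallis(groups)
            stat_rows.append({"feature": feat, "H": res.statistic, "p": res.p})
        stats_df = pd.DataFrame(stat_rows)
        if not stats_df.empty:
            stats_df["p_adjusted"] = adjust_p(stats_df["p"], config.correction)
        stats_df.to_csv(out_dir / "stats.csv", index=False)
        artifacts["stats"] = str(out_dir / "stats.csv")

        if ds.feature_class is not None and final_set:
            enr = class_enrichment(final_set, ds.feature_class,
                                   config.enrichment_class)
            summary["enrichment"] = {
                "class": config.enrichment_class,
                "p": enr.p,
                "odds_ratio": enr.statistic,
            }

        if truth is not None:
            recovered = set(sets["reduced"]) & set(truth.time_features)
            summary["ground_truth"] = {
                "n_informative_time": len(truth.time_features),
                "n_recovered_reduced": len(recovered),
            }
    except Exception as exc:
        raise PipelineError(f"pipeline failed during task {config.task!r}: {exc}") \
            from exc

    summary["config_hash"] = config.config_hash()
    summary["seconds"] = round(time.time() - t0, 1)
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    artifacts["summary"] = str(out_dir / "summary.json")
    return RunReport(config.config_hash(), artifacts, summary)


def _recombine(ds, train, holdout):
    """Write partition-imputed values back into the full dataset's rows."""
    from dataclasses import replace

    values = ds.values.copy()
    values.loc[train.sample_ids] = train.values
    values.loc[holdout.sample_ids] = holdout.values
    return replace(ds, values=values)
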