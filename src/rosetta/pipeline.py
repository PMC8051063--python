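"""End-to-end pipeline: simulate (or load) -> translate -> impute ->
train/cross-validate -> report.

A single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence`` spawning, so each stage is independently
reproducible and re-running a stage with the same global seed gives
byte-identical artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import ClassifierConfig, cross_validate, iterative_prune
from .crosswalk import Crosswalk, RosettaMatrix, fusion_summary, overlap_matrix, translate
from .impute import ImputationConfig, coverage_profile, impute
from .simulate import CohortConfig, simulate_cohort, synthetic_crosswalk

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "fan_out_seeds"]

log = logging.getLogger("rosetta")


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


def fan_out_seeds(seed: int, n: int = 4) -> list[int]:
    """Derive n independent per-stage seeds (< 2**31) from one global seed."""
    return [int(s.generate_state(1)[0] % (2**31)) for s in
            np.random.SeedSequence(seed).spawn(n)]


@dataclass
class PipelineConfig:
    """Desk-scale pipeline defaults.

    The sub-config defaults here are sized for a 750-child cohort on one
    CPU: the imputation class-size guard drops to 15 (the smallest class
    holds only 69 children) with 50-tree forests, and cross-validation uses
    5 folds.  The component dataclasses keep the full-scale defaults
    (guard 50, 100 trees, 20 folds) for use on larger cohorts.
    """

    crosswalk: Crosswalk | str | None = None  # None -> synthetic bank
    cohort: CohortConfig = field(default_factory=CohortConfig)
    imputation: ImputationConfig = field(default_factory=lambda: ImputationConfig(
        min_class_samples=15, min_predictions=10, subset_size_range=(3, 6),
        trees_per_forest=30, max_draws_per_feature=300,
    ))
    classifier: ClassifierConfig = field(default_factory=lambda: ClassifierConfig(
        k_folds=5, n_rounds=150, prune=True, prune_patience=3,
    ))
    translate_policy: str = "max"
    outdir: str | Path = "rosetta_run"
    seed: int = 0


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write artifacts under ``config.outdir`` and return
    the summary report (also written as ``summary.json``)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = fan_out_seeds(config.seed, 4)
    log.info("pipeline seed=%d -> stage seeds %s", config.seed, seeds)

    def stage(name):
        def wrap(exc):
            return PipelineError(f"stage {name!r} failed: {exc}")
        return wrap

    # ---- crosswalk --------------------------------------------------------
    try:
        if config.crosswalk is None:
            cw = synthetic_crosswalk(seed=seeds[0])
        elif isinstance(cw_in := config.crosswalk, Crosswalk):
            cw = cw_in
        else:
            cw = Crosswalk.from_json(config.crosswalk)
        problems = cw.validate()
        if problems:
            raise ValueError(f"invalid crosswalk: {problems[:5]}")
    except Exception as exc:
        raise stage("crosswalk")(exc) from exc

    # ---- simulate ---------------------------------------------------------
    try:
        cohort_cfg = replace(config.cohort, seed=seeds[1])
        cohort = simulate_cohort(cw, cohort_cfg)
        cohort.truth.to_csv(outdir / "truth.csv", index=False)
        cohort.responses.to_csv(outdir / "responses.csv", index=False)
        cohort.assignments.to_csv(outdir / "assignments.csv", index=False)
    except Exception as exc:
        raise stage("simulate")(exc) from exc

    # ---- translate --------------------------------------------------------
    try:
        matrix = translate(cw, cohort.responses, policy=config.translate_policy)
        matrix.to_csv(outdir / "matrix.csv", outdir / "code_ranges.json")
    except Exception as exc:
        raise stage("translate")(exc) from exc

    labels = cohort.truth.set_index("child_id")["condition"].reindex(
        matrix.codes.index
    )

    # ---- impute -----------------------------------------------------------
    try:
        imp_cfg = replace(config.imputation, seed=seeds[2])
        imputed = impute(matrix, labels, imp_cfg)
        imputed.to_csv(outdir / "imputed.csv", outdir / "provenance.csv")
    except Exception as exc:
        raise stage("impute")(exc) from exc

    # ---- train / cross-validate ------------------------------------------
    try:
        clf_cfg = replace(config.classifier, seed=seeds[3])
        rows, feats = list(imputed.values.index), list(imputed.values.columns)
        trace = None
        if clf_cfg.prune:
            rows, feats, trace = iterative_prune(imputed, labels, clf_cfg)
            trace.to_csv(outdir / "prune_trace.tsv", sep="\t", index=False)
        cv = cross_validate(imputed.values.loc[rows, feats], labels.loc[rows],
                            clf_cfg)
        cv.per_fold.to_csv(outdir / "cv.tsv", sep="\t", index=False)
    except Exception as exc:
        raise stage("classify")(exc) from exc

    # ---- reports ----------------------------------------------------------
    try:
        fus = fusion_summary(cw)
        fus.to_csv(outdir / "fusion.tsv", sep="\t")
        ov, totals = overlap_matrix(cw)
        ov.assign(total=totals).to_csv(outdir / "overlap.tsv", sep="\t")
        row_cov, feat_cov = coverage_profile(imputed)
    except Exception as exc:
        raise stage("report")(exc) from exc

    summary = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "n_children": int(len(matrix.codes)),
        "n_questions": int(len(matrix.codes.columns)),
        "class_counts": labels.value_counts().sort_index().to_dict(),
        "observed_fraction": round(float(matrix.mask.to_numpy().mean()), 6),
        "n_imputed_cells": imputed.n_imputed,
        "n_failed_cells": imputed.n_failed,
        "mean_row_coverage_after_imputation": round(float(row_cov.mean()), 6),
        "selected_features": feats,
        "n_selected_rows": len(rows),
        "stage1_auc": round(float(cv.stage1_auc), 6),
        "stage2_auc": round(float(cv.stage2_auc), 6),
        "artifacts": sorted(
            ["truth.csv", "responses.csv", "assignments.csv", "matrix.csv",
             "code_ranges.json", "imputed.csv", "provenance.csv", "cv.tsv",
             "fusion.tsv", "overlap.tsv", "summary.json"]
            + (["prune_trace.tsv"] if trace is not None else [])
        ),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
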