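"""Configuration, file formats and the end-to-end pipeline.

Cohorts live on disk as plain CSV (first column = subject ID, header row =
metabolite/food names, empty cell = missing) with a ``loq.csv`` sidecar, and
results as correlation/selection/evaluation CSVs plus a JSON bundle.  The
pipeline executes

    preprocess -> screen -> preselect -> select (RRR-VIP and LASSO)
    -> two-fold split -> evaluate -> report

deterministically for a given global seed; the global seed is expanded into
independent per-stage seeds with ``numpy.random.SeedSequence(seed,
spawn_key=(stage_index,))`` so any stage can be rerun in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, evaluation, preprocessing, selection
from .preprocessing import CovariateSet, IntakeTable, MetaboliteMatrix

logger = logging.getLogger("polypattern")

STAGE_INDEX = {
    "simulate": 0, "preprocess": 1, "screen": 2, "select": 3,
    "split": 4, "evaluate": 5,
}


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed (documented scheme)."""
    ss = np.random.SeedSequence(seed, spawn_key=(STAGE_INDEX[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Paths, thresholds and the global seed for one pipeline run.

    Threshold defaults are the method's canonical values: significance
    alpha 0.05, preselection at >= 5 significant metabolites with max r >=
    0.3, VIP > 0.85, 5-fold LASSO CV, equal two-fold split, exclusion of
    metabolites >= 98% below LOQ, intake log offset 1 g/day.
    """

    cohort_dir: str = "."
    output_dir: str = "results"
    alpha: float = 0.05
    min_significant: int = 5
    min_r: float = 0.3
    vip_threshold: float = 0.85
    lasso_folds: int = 5
    lasso_rule: str = "min"
    cv_test_fraction: float = 0.5
    exclusion_fraction: float = 0.98
    intake_log_offset: float = 1.0
    comparator_scope: str = "train"  # or "full"
    seed: int = 0

    def validate(self) -> None:
        checks = [
            0 < self.alpha < 1,
            self.min_significant >= 1,
            0 <= self.min_r <= 1,
            self.vip_threshold >= 0,
            self.lasso_folds >= 2,
            0 < self.cv_test_fraction < 1,
            0 < self.exclusion_fraction <= 1,
            self.intake_log_offset >= 0,
            self.comparator_scope in ("train", "full"),
            self.lasso_rule in ("min", "1se"),
        ]
        if not all(checks):
            raise ValueError("pipeline configuration outside documented ranges")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            cfg = cls(**(yaml.safe_load(fh) or {}))
        cfg.validate()
        return cfg


@dataclass
class ProcessedCohort:
    """Preprocessing output consumed by screening and evaluation."""

    metabolites: MetaboliteMatrix  # stage=residualized
    intake_24hdr: IntakeTable  # stage=adjusted
    intake_dq: IntakeTable
    covariates: CovariateSet


# ---------------------------------------------------------------------------
# cohort I/O


def write_cohort(cohort, outdir) -> None:
    """Persist a cohort as CSV: metabolites.csv (empty cell = missing),
    loq.csv sidecar, intake tables, covariates (with center/batch), and
    truth.json when ground truth is known."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    m = cohort.metabolites
    m.values.to_csv(outdir / "metabolites.csv")
    m.loq.rename_axis("metabolite").reset_index().to_csv(
        outdir / "loq.csv", index=False
    )
    cohort.intake_24hdr.raw.assign(energy=cohort.intake_24hdr.energy).to_csv(
        outdir / "intake_24hdr.csv"
    )
    cohort.intake_dq.raw.assign(energy=cohort.intake_dq.energy).to_csv(
        outdir / "intake_dq.csv"
    )
    cohort.covariates.frame.assign(center=m.center, batch=m.batch).to_csv(
        outdir / "covariates.csv"
    )
    truth = getattr(cohort, "truth", None)
    if truth:
        t = dict(truth)
        lam = t.get("loading_matrix")
        if isinstance(lam, pd.DataFrame):
            t["loading_matrix"] = {
                "index": list(lam.index),
                "columns": list(lam.columns),
                "values": lam.to_numpy().tolist(),
            }
        with open(outdir / "truth.json", "w") as fh:
            json.dump(t, fh, indent=1)


def read_cohort(indir):
    """Read a cohort written by :func:`write_cohort`.

    The below-LOQ mask is reconstructed as value < LOQ; missingness as empty
    cells.  Returns a :class:`~polypattern.synthetic.SyntheticCohort`-shaped
    object (truth is None when truth.json is absent).
    """
    from .synthetic import SyntheticCohort  # local import to avoid a cycle

    indir = Path(indir)
    values = pd.read_csv(indir / "metabolites.csv", index_col=0)
    loq = pd.read_csv(indir / "loq.csv").set_index("metabolite")["loq"]
    loq = loq.reindex(values.columns)
    covs = pd.read_csv(indir / "covariates.csv", index_col=0)
    below = values.lt(loq, axis=1) & values.notna()
    metabolites = MetaboliteMatrix(
        values=values,
        below_loq=below,
        loq=loq,
        center=covs["center"].astype(str),
        batch=covs["batch"].astype(str),
    )

    def _intake(path, instrument):
        df = pd.read_csv(path, index_col=0)
        energy = df.pop("energy")
        return IntakeTable(raw=df, instrument=instrument, energy=energy)

    covariates = CovariateSet(frame=covs[["sex", "bmi", "age"]])
    truth = None
    if (indir / "truth.json").exists():
        with open(indir / "truth.json") as fh:
            truth = json.load(fh)
    return SyntheticCohort(
        metabolites=metabolites,
        intake_24hdr=_intake(indir / "intake_24hdr.csv", "24-HDR"),
        intake_dq=_intake(indir / "intake_dq.csv", "DQ"),
        covariates=covariates,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# pipeline stages


def preprocess_cohort(cohort, config: PipelineConfig) -> ProcessedCohort:
    met = preprocessing.preprocess_metabolites(
        cohort.metabolites, exclusion_fraction=config.exclusion_fraction
    )
    hdr = preprocessing.preprocess_intakes(
        cohort.intake_24hdr, offset=config.intake_log_offset
    )
    dq = preprocessing.preprocess_intakes(
        cohort.intake_dq, offset=config.intake_log_offset
    )
    return ProcessedCohort(met, hdr, dq, cohort.covariates)


def _corr_on_subset(proc: ProcessedCohort, idx) -> association.CorrelationTable:
    """Correlation table restricted to subject positions ``idx`` (used for
    the training-fold comparator choice)."""
    from dataclasses import replace

    met = replace(
        proc.metabolites,
        values=proc.metabolites.values.iloc[idx],
        below_loq=proc.metabolites.below_loq.iloc[idx],
        center=proc.metabolites.center.iloc[idx],
        batch=proc.metabolites.batch.iloc[idx],
    )
    met.missing = proc.metabolites.missing.iloc[idx]
    intakes = replace(
        proc.intake_24hdr,
        raw=proc.intake_24hdr.raw.iloc[idx],
        values=proc.intake_24hdr.values.iloc[idx],
        energy=proc.intake_24hdr.energy.iloc[idx],
    )
    cov = CovariateSet(frame=proc.covariates.frame.iloc[idx])
    return association.correlation_screen(met, intakes, cov)


def run_on_cohort(cohort, config: PipelineConfig) -> dict:
    """Execute screen -> preselect -> select -> evaluate -> report on an
    in-memory cohort; returns a results bundle (dict)."""
    config.validate()
    proc = preprocess_cohort(cohort, config)
    n = len(proc.metabolites.subjects)

    corr = association.correlation_screen(
        proc.metabolites, proc.intake_24hdr, proc.covariates
    )
    foods = association.preselect_food_groups(
        corr,
        alpha=config.alpha,
        min_significant=config.min_significant,
        min_r=config.min_r,
    )
    logger.info("preselected %d/%d food groups: %s", len(foods), corr.r.shape[0], foods)

    sel_seed = stage_seed(config.seed, "select")
    selections: dict[str, dict[str, selection.SelectionResult]] = {}
    for food in foods:
        selections[food] = selection.select_both(
            proc.metabolites.values,
            proc.intake_24hdr.values[food],
            food=food,
            vip_threshold=config.vip_threshold,
            lasso_folds=config.lasso_folds,
            seed=sel_seed,
        )

    test_size = int(np.floor(n * config.cv_test_fraction))
    split = evaluation.split_two_fold(
        n, seed=stage_seed(config.seed, "split"), test_size=test_size
    )
    if config.comparator_scope == "train":
        comp_corr = _corr_on_subset(proc, split.train_idx)
    else:
        comp_corr = corr

    rows: list[evaluation.EvaluationRow] = []
    for food in foods:
        for instrument in ("24-HDR", "DQ"):
            try:
                comp = evaluation.best_single_biomarker(comp_corr, food)
                single = selection.SelectionResult(
                    food=food, method="single-PP", selected=[comp],
                    statistic=pd.Series([1.0], index=[comp]),
                )
                rows.append(
                    evaluation.evaluate_pattern(
                        proc, food, single, split, instrument,
                        method="single-PP", comparator_name=comp,
                    )
                )
            except evaluation.EvaluationError as exc:
                logger.warning("single-PP skipped for %s (%s): %s", food, instrument, exc)
            for method in ("RRR-VIP", "LASSO"):
                sel = selections[food][method]
                if not sel.selected:
                    logger.warning("%s selected nothing for %s", method, food)
                    continue
                try:
                    rows.append(
                        evaluation.evaluate_pattern(proc, food, sel, split, instrument)
                    )
                except evaluation.EvaluationError as exc:
                    logger.warning(
                        "evaluation skipped for %s/%s (%s): %s",
                        food, method, instrument, exc,
                    )

    report = evaluation.build_report(rows)
    return {
        "config": asdict(config),
        "n_subjects": n,
        "metabolites_retained": proc.metabolites.metabolite_names,
        "correlations": corr,
        "preselected_foods": foods,
        "selections": selections,
        "split": split,
        "rows": rows,
        "report": report,
    }


def write_results(bundle: dict, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle["correlations"].to_csv(
        outdir / "correlations.csv", outdir / "correlation_pvalues.csv"
    )
    flat = [
        sel for per_food in bundle["selections"].values() for sel in per_food.values()
    ]
    selection.selections_to_csv(flat, outdir / "selections.csv")
    bundle["report"].to_csv(outdir / "evaluation.csv", index=False)
    payload = {
        "config": bundle["config"],
        "n_subjects": bundle["n_subjects"],
        "metabolites_retained": bundle["metabolites_retained"],
        "preselected_foods": bundle["preselected_foods"],
        "split": {
            "train_idx": bundle["split"].train_idx.tolist(),
            "test_idx": bundle["split"].test_idx.tolist(),
            "seed": bundle["split"].seed,
        },
        "selections": {
            food: {
                method: {
                    "selected": sel.selected,
                    "statistic": sel.statistic.to_dict(),
                    "settings": sel.settings,
                }
                for method, sel in per_food.items()
            }
            for food, per_food in bundle["selections"].items()
        },
        "evaluation": bundle["report"].to_dict(orient="records"),
    }
    with open(outdir / "results.json", "w") as fh:
        json.dump(payload, fh, indent=1)


def run_pipeline(config: PipelineConfig) -> dict:
    """Read the cohort from ``config.cohort_dir``, run everything, persist
    every stage's output under ``config.output_dir``."""
    cohort = read_cohort(config.cohort_dir)
    bundle = run_on_cohort(cohort, config)
    write_results(bundle, config.output_dir)
    return bundle
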