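"""Pipeline orchestration: simulate -> develop -> score -> triage ->
validate -> report.

Every stage writes a plain-text artifact into the output directory; a
manifest records what was produced, with a provenance block (config hash,
seed, package version) so any printed value can be traced to the exact
configuration that produced it.  Identical configs and seeds produce
byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .exceptions import ChantError
from .items import MeasurandThresholds
from .measurand import ConfusionTable, CostWeights, evaluate_cohort
from .reference import reference_verdicts
from .scorer import score_cohort
from .synthetic import (
    CohortConfig,
    RATER_ITEM_COLUMNS,
    _config_to_dict,
    generate_cohort,
    generate_rater_pair,
    panel_from_counts,
    write_cohort,
)
from .triage import triage_cohort
from .validation import (
    cvr,
    diagnostic_metrics,
    fagan_posttest,
    inter_tester,
    panel_response_from_matrix,
    reliability_report,
)

ARTIFACTS = (
    "cohort.csv",
    "measurand_report.csv",
    "chant_scores.csv",
    "triage.csv",
    "validation.json",
    "summary.md",
)


class StageError(ChantError):
    """A pipeline stage failed; the stage name prefixes the message."""


@dataclass(frozen=True)
class PipelineConfig:
    outdir: str = "chant_output"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    thresholds: MeasurandThresholds = field(default_factory=MeasurandThresholds)
    weights: CostWeights = field(default_factory=CostWeights)
    rule: str = "verbal"
    reference_standard: str = "hiv_pins"  # or "uens"
    rater_seed: int = 1
    n_panelists: int = 5
    panel_essential_counts: tuple[int, ...] = (4, 5, 5, 5)


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(_config_to_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonable(value):
    if isinstance(value, float) and math.isinf(value):
        return "inf"
    if isinstance(value, dict):
        return {k: _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    return value


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the report bundle as a dict of artifact
    paths plus the in-memory validation summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "provenance": {
            "config_hash": _config_hash(config),
            "seed": config.cohort.seed,
            "version": __version__,
        },
        "artifacts": [],
    }

    def _finish_stage(name: str) -> None:
        manifest["artifacts"].append(name)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    stage = "simulate"
    try:
        cohort = generate_cohort(config.cohort)
        write_cohort(cohort, outdir / "cohort.csv")
        _finish_stage("cohort.csv")

        stage = "develop"
        reference = reference_verdicts(cohort, standard="hiv_pins")
        dev_labels = reference["positive"].to_numpy(dtype=bool)
        table1 = evaluate_cohort(cohort, dev_labels, config.weights)
        table1.to_csv(outdir / "measurand_report.csv", index=False)
        _finish_stage("measurand_report.csv")

        stage = "score"
        scores = score_cohort(cohort, config.thresholds, config.rule)
        scores.to_csv(outdir / "chant_scores.csv", index=False)
        _finish_stage("chant_scores.csv")

        stage = "triage"
        triage = triage_cohort(cohort, scores)
        triage.to_csv(outdir / "triage.csv", index=False)
        _finish_stage("triage.csv")

        stage = "validate"
        validation = _validate_stage(cohort, scores, config)
        with open(outdir / "validation.json", "w") as fh:
            json.dump(_jsonable(validation), fh, indent=2, sort_keys=True)
            fh.write("\n")
        _finish_stage("validation.json")

        stage = "report"
        summary = _summary_markdown(config, table1, scores, triage, validation)
        (outdir / "summary.md").write_text(summary)
        _finish_stage("summary.md")
    except Exception as exc:  # noqa: BLE001 - re-raise with the stage name
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    return {
        "outdir": str(outdir),
        "artifacts": list(manifest["artifacts"]),
        "validation": validation,
    }


def _validate_stage(cohort: pd.DataFrame, scores: pd.DataFrame,
                    config: PipelineConfig) -> dict:
    verdicts = reference_verdicts(cohort, standard=config.reference_standard)
    merged = scores.merge(verdicts, on="id", suffixes=("", "_ref"))
    if "asymmetric_excluded" in merged.columns:
        n_excluded = int(merged["asymmetric_excluded"].sum())
        merged = merged[~merged["asymmetric_excluded"]]
    else:
        n_excluded = 0
    ref = merged["positive"].astype(bool).to_numpy()
    test = merged["chant_positive"].astype(bool).to_numpy()
    table = ConfusionTable(
        tp=int((test & ref).sum()), fp=int((test & ~ref).sum()),
        fn=int((~test & ref).sum()), tn=int((~test & ~ref).sum()),
    )
    metrics = diagnostic_metrics(table)
    pretest = (table.tp + table.fn) / table.total
    posttest = (
        fagan_posttest(pretest, metrics.lr_pos)
        if 0 < pretest < 1 and math.isfinite(metrics.lr_pos) else None
    )

    tallies = scores[[c for c in scores.columns if c.endswith("_tally")]]
    item_cols = list(RATER_ITEM_COLUMNS)
    rater1 = cohort[["id"] + item_cols]
    rater2 = generate_rater_pair(cohort, config.cohort.rater2_agreement,
                                 config.rater_seed)
    reliability = reliability_report(tallies, rater2_matrix=None)
    concordance = inter_tester(rater1, rater2)

    panel = panel_response_from_matrix(
        panel_from_counts(config.panel_essential_counts, config.n_panelists)
    )
    cvr_values, cvr_mean = cvr(panel)

    return {
        "reference_standard": config.reference_standard,
        "n_excluded_asymmetric": n_excluded,
        "confusion": {"tp": table.tp, "fp": table.fp,
                      "fn": table.fn, "tn": table.tn},
        "metrics": dataclasses.asdict(metrics),
        "pretest_probability": pretest,
        "posttest_probability": posttest,
        "reliability": {
            "cronbach_alpha": reliability.cronbach_alpha,
            "item_total": reliability.item_total,
            "item_total_mean": reliability.item_total_mean,
            "inter_tester": concordance,
        },
        "content_validity": {"per_item": list(cvr_values), "mean": cvr_mean},
    }


def worked_example(tp: int, fp: int, fn: int, tn: int, pretest: float) -> dict:
    """Accuracy metrics and post-test probability straight from a 2x2 table
    (the CLI's `validate --table` mode)."""
    table = ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)
    metrics = diagnostic_metrics(table)
    posttest = (fagan_posttest(pretest, metrics.lr_pos)
                if math.isfinite(metrics.lr_pos) else 1.0)
    return {
        "confusion": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
        "metrics": dataclasses.asdict(metrics),
        "report": metrics.rounded(),
        "pretest_probability": pretest,
        "posttest_probability": posttest,
        "posttest_pct": int(round(100 * posttest)),
    }


def _summary_markdown(config: PipelineConfig, table1: pd.DataFrame,
                      scores: pd.DataFrame, triage: pd.DataFrame,
                      validation: dict) -> str:
    m = validation["metrics"]
    lines = [
        "# Screening-pipeline summary",
        "",
        f"- config hash: `{_config_hash(config)}`",
        f"- seed: {config.cohort.seed}",
        f"- version: {__version__}",
        "",
        f"Patients: {len(scores)}; screen-positive: "
        f"{int(scores['chant_positive'].sum())} ({config.rule} rule)",
        "",
        "## Validation vs "
        + ("composite 2-of-3 case definition"
           if validation["reference_standard"] == "hiv_pins"
           else "examination-score proxy (symmetric cutoff 8)"),
        "",
        f"- sensitivity: {100 * m['sensitivity']:.1f}%",
        f"- specificity: {100 * m['specificity']:.1f}%",
        f"- PPV: {100 * m['ppv']:.1f}%  NPV: {100 * m['npv']:.1f}%",
        f"- LR+: {m['lr_pos']:.2f}  LR-: {m['lr_neg']:.2f}"
        if math.isfinite(m["lr_pos"])
        else f"- LR+: inf  LR-: {m['lr_neg']:.2f}",
        f"- pre-test probability: {100 * validation['pretest_probability']:.1f}%",
    ]
    if validation["posttest_probability"] is not None:
        lines.append(
            f"- post-test probability: "
            f"{100 * validation['posttest_probability']:.1f}%"
        )
    rel = validation["reliability"]
    lines += [
        "",
        "## Reliability",
        "",
        f"- Cronbach alpha (4 tallies): {rel['cronbach_alpha']:.4f}",
        f"- mean item-total correlation: {rel['item_total_mean']:.4f}",
        "",
        "## Triage",
        "",
    ]
    for category, count in triage["category"].value_counts().sort_index().items():
        lines.append(f"- {category}: {count}")
    lines += ["", "## Measurand development table", "",
              table1.to_string(index=False), ""]
    return "\n".join(lines)
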