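"""End-to-end study replica: cohort → scenarios → predictions → validation.

Stages, in order:

1. generate (or load) a synthetic cohort;
2. build the scenario populations (single-method Population A, mixed-method
   Population B) with CONSORT-style rejection accounting;
3. optionally harmonize Population-B inputs onto the target measurement's
   scale (Population A is single-method, so harmonization cannot touch it);
4. forecast each instance's target with the empirical-Bayes predictor;
5. summarize per scenario: Bland-Altman margin, median/IQR of aPE and rPE,
   mis-prediction tabulation, clinical-acceptance and exactness verdicts,
   the hemolytic-disease subgroup, and observed-vs-predicted bilirubin
   increase rates for the mixed-method scenarios (both harmonization arms).

One global seed drives everything; prediction itself is deterministic, so a
re-run with the same configuration reproduces summary.json byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortConfig, CohortDataset, generate_cohort
from .metrics import (
    AcceptanceThresholds,
    PredictionRecord,
    ValidationSummary,
    harmonize,
    increase_rate,
    summarize,
)
from .model import PopulationModel, default_population_model, predict_bilirubin
from .scenarios import (
    BuildReport,
    ScenarioInstance,
    ScenarioSpec,
    build_population,
    default_scenarios,
)
from .types import DEFAULT_TCB_OFFSET, NeonatalPatient

__all__ = [
    "RunConfig",
    "RunReport",
    "run_study",
    "predict_instances",
    "compare_increase_rates",
    "write_outputs",
]

logger = logging.getLogger("biliforecast")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full study run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    model: PopulationModel = field(default_factory=default_population_model)
    scenarios: tuple[ScenarioSpec, ...] = field(
        default_factory=lambda: tuple(default_scenarios())
    )
    thresholds: AcceptanceThresholds = field(default_factory=AcceptanceThresholds)
    harmonize: bool = True
    seed: int = 0
    tcb_offset: float = DEFAULT_TCB_OFFSET

    def __post_init__(self) -> None:
        ids = [s.scenario_id for s in self.scenarios]
        if len(ids) != len(set(ids)):
            raise ValueError("scenario ids must be unique")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a run configuration from a YAML document.

        Recognised top-level keys: ``seed``, ``harmonize``, ``tcb_offset``,
        ``cohort`` (CohortConfig fields), ``model`` (flat PopulationModel
        document or a path to one), ``thresholds`` (AcceptanceThresholds
        fields). Scenarios always default to the standard five.
        """
        doc = yaml.safe_load(Path(path).read_text()) or {}
        cohort_kwargs = doc.get("cohort", {})
        for tup in ("n_measurements_range", "first_window", "first_window_tcb",
                    "gap_window", "ga_skewnorm", "ga_bounds",
                    "weight_skewnorm", "weight_bounds"):
            if tup in cohort_kwargs:
                cohort_kwargs[tup] = tuple(cohort_kwargs[tup])
        model_doc = doc.get("model")
        if isinstance(model_doc, str):
            model = PopulationModel.load(model_doc)
        elif isinstance(model_doc, dict):
            model = PopulationModel.from_dict(model_doc)
        else:
            model = default_population_model()
        return cls(
            cohort=CohortConfig(**cohort_kwargs),
            model=model,
            thresholds=AcceptanceThresholds(**doc.get("thresholds", {})),
            harmonize=bool(doc.get("harmonize", True)),
            seed=int(doc.get("seed", 0)),
            tcb_offset=float(doc.get("tcb_offset", DEFAULT_TCB_OFFSET)),
        )


@dataclass
class RateSummary:
    """Median (IQR) of observed and predicted increase rates, mg/dl per hour."""

    observed_median: float
    observed_iqr: tuple[float, float]
    predicted_median: float
    predicted_iqr: tuple[float, float]
    n: int

    def to_dict(self) -> dict[str, object]:
        return {
            "observed_median": self.observed_median,
            "observed_iqr": list(self.observed_iqr),
            "predicted_median": self.predicted_median,
            "predicted_iqr": list(self.predicted_iqr),
            "n": self.n,
        }


@dataclass
class RunReport:
    """Everything one study run produces."""

    summaries: dict[int, ValidationSummary | None]
    summaries_unharmonized: dict[int, ValidationSummary | None]
    hemolytic_summaries: dict[int, ValidationSummary | None]
    increase_rates: dict[str, RateSummary]
    records: dict[int, list[PredictionRecord]]
    records_unharmonized: dict[int, list[PredictionRecord]]
    build: BuildReport
    dataset: CohortDataset
    config: RunConfig

    def to_json_dict(self) -> dict[str, object]:
        def summ(d: dict[int, ValidationSummary | None]) -> dict[str, object]:
            return {
                str(sid): (s.to_dict() if s is not None else None)
                for sid, s in sorted(d.items())
            }

        return {
            "n_patients": len(self.dataset.patients),
            "seed": self.config.seed,
            "harmonize": self.config.harmonize,
            "scenario_summaries": summ(self.summaries),
            "scenario_summaries_unharmonized": summ(self.summaries_unharmonized),
            "hemolytic_subgroup_summaries": summ(self.hemolytic_summaries),
            "increase_rates": {k: v.to_dict() for k, v in sorted(self.increase_rates.items())},
            "accounting": self.build.accounting_rows(),
        }


def predict_instances(
    pop: PopulationModel,
    patients_by_id: dict[str, NeonatalPatient],
    instances: Sequence[ScenarioInstance],
    spec: ScenarioSpec,
    *,
    harmonize_inputs: bool,
    tcb_offset: float = DEFAULT_TCB_OFFSET,
) -> list[PredictionRecord]:
    """Forecast every scenario instance and pair it with its observed target.

    With ``harmonize_inputs`` the input measurements (and the last-input
    value carried into the increase-rate analysis) are first mapped onto
    the target measurement's scale; the observed target itself is already
    on that scale and is never adjusted.
    """
    records = []
    for inst in instances:
        patient = patients_by_id[inst.patient_id]
        inputs = list(inst.inputs)
        if harmonize_inputs:
            inputs = harmonize(inputs, inst.target.method, offset=tcb_offset)
        b_pred = predict_bilirubin(
            pop, patient.covariates, inputs, inst.t_target, horizon_limit=spec.horizon
        )
        records.append(
            PredictionRecord(
                patient_id=inst.patient_id,
                scenario_id=inst.scenario_id,
                b_pred=b_pred,
                b_obs=inst.target.value,
                b_last=inputs[-1].value,
                t_last=inst.t_last,
                t_target=inst.t_target,
                target_method=inst.target.method,
                hemolytic=patient.covariates.hemolytic,
            )
        )
    return records


def compare_increase_rates(records: Sequence[PredictionRecord]) -> RateSummary:
    """Observed vs predicted bilirubin increase rates, median (IQR).

    The observed rate uses the measured target, the predicted rate the
    forecast target; both share B_last and the time interval.
    """
    if not records:
        raise ValueError("compare_increase_rates needs at least one record")
    obs = np.array([increase_rate(r.b_obs, r.b_last, r.t_target, r.t_last) for r in records])
    pred = np.array([increase_rate(r.b_pred, r.b_last, r.t_target, r.t_last) for r in records])
    o25, o50, o75 = np.percentile(obs, [25, 50, 75])
    p25, p50, p75 = np.percentile(pred, [25, 50, 75])
    return RateSummary(
        observed_median=float(o50), observed_iqr=(float(o25), float(o75)),
        predicted_median=float(p50), predicted_iqr=(float(p25), float(p75)),
        n=len(records),
    )


def _maybe_summarize(
    records: Sequence[PredictionRecord], thresholds: AcceptanceThresholds
) -> ValidationSummary | None:
    """Summaries need ≥ 2 records; smaller groups are flagged empty (None)."""
    if len(records) < 2:
        return None
    return summarize(records, thresholds)


def run_study(config: RunConfig, dataset: CohortDataset | None = None) -> RunReport:
    """Execute the full study replica.

    A pre-generated ``dataset`` may be supplied (stage re-entrancy);
    otherwise one is generated from ``config.cohort`` with the global seed.
    """
    if dataset is None:
        cohort_cfg = replace(config.cohort, seed=config.seed)
        logger.info("generating synthetic cohort: n=%d seed=%d",
                    cohort_cfg.n_patients, cohort_cfg.seed)
        dataset = generate_cohort(cohort_cfg, config.model)

    logger.info("building scenario populations (%d scenarios)", len(config.scenarios))
    build = build_population(dataset.measurements, config.scenarios)
    for rej in build.rejection_records:
        logger.debug("rejected scenario=%d patient=%s rule=%s %s",
                     rej.scenario_id, rej.patient_id, rej.reason, rej.detail)
    patients_by_id = {p.patient_id: p for p in dataset.patients}

    summaries: dict[int, ValidationSummary | None] = {}
    summaries_raw: dict[int, ValidationSummary | None] = {}
    hemolytic: dict[int, ValidationSummary | None] = {}
    rates: dict[str, RateSummary] = {}
    records_primary: dict[int, list[PredictionRecord]] = {}
    records_raw: dict[int, list[PredictionRecord]] = {}

    for spec in config.scenarios:
        instances = build.instances[spec.scenario_id]
        logger.info("scenario %d: %d instances", spec.scenario_id, len(instances))
        mixed = spec.population == "B"
        use_harmonized = mixed and config.harmonize

        primary = predict_instances(
            config.model, patients_by_id, instances, spec,
            harmonize_inputs=use_harmonized, tcb_offset=config.tcb_offset,
        )
        records_primary[spec.scenario_id] = primary
        summaries[spec.scenario_id] = _maybe_summarize(primary, config.thresholds)

        if mixed:
            if use_harmonized:
                raw = predict_instances(
                    config.model, patients_by_id, instances, spec,
                    harmonize_inputs=False, tcb_offset=config.tcb_offset,
                )
            else:
                raw = primary
            records_raw[spec.scenario_id] = raw
            summaries_raw[spec.scenario_id] = _maybe_summarize(raw, config.thresholds)
            if primary:
                rates[f"scenario{spec.scenario_id}_adjusted"] = compare_increase_rates(primary)
            if raw:
                rates[f"scenario{spec.scenario_id}_unadjusted"] = compare_increase_rates(raw)
        else:
            subgroup = [r for r in primary if r.hemolytic]
            hemolytic[spec.scenario_id] = _maybe_summarize(subgroup, config.thresholds)

    return RunReport(
        summaries=summaries,
        summaries_unharmonized=summaries_raw,
        hemolytic_summaries=hemolytic,
        increase_rates=rates,
        records=records_primary,
        records_unharmonized=records_raw,
        build=build,
        dataset=dataset,
        config=config,
    )


# ---------------------------------------------------------------------------
# file outputs


def instances_frame(build: BuildReport) -> pd.DataFrame:
    rows = []
    for sid in sorted(build.instances):
        for inst in build.instances[sid]:
            rows.append({
                "scenario_id": sid,
                "patient_id": inst.patient_id,
                "input_pnas": ";".join(f"{m.pna!r}" for m in inst.inputs),
                "input_values": ";".join(f"{m.value!r}" for m in inst.inputs),
                "input_methods": ";".join(m.method for m in inst.inputs),
                "target_pna": inst.target.pna,
                "target_value": inst.target.value,
                "target_method": inst.target.method,
                "horizon_used_h": inst.horizon_used,
            })
    return pd.DataFrame(rows, columns=[
        "scenario_id", "patient_id", "input_pnas", "input_values", "input_methods",
        "target_pna", "target_value", "target_method", "horizon_used_h",
    ])


def predictions_frame(records: dict[int, list[PredictionRecord]]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": r.patient_id,
            "scenario_id": sid,
            "b_pred_umol_l": r.b_pred,
            "b_obs_umol_l": r.b_obs,
            "pe": r.pe,
            "ape": r.ape,
            "rpe_pct": r.rpe,
        }
        for sid in sorted(records)
        for r in records[sid]
    ]
    return pd.DataFrame(rows, columns=[
        "patient_id", "scenario_id", "b_pred_umol_l", "b_obs_umol_l",
        "pe", "ape", "rpe_pct",
    ])


def render_markdown(report: RunReport) -> str:
    """Tabular text report mirroring the per-scenario summary layout."""

    def fmt_summary_rows(d: dict[int, ValidationSummary | None], title: str) -> list[str]:
        lines = [f"## {title}", "",
                 "| Scenario | N | Margin of error of 95% CI (µmol/L) | "
                 "Median (IQR) of rPE (%) | PE<−85 | PE>+85 | Clinical | Exactness |",
                 "|---|---|---|---|---|---|---|---|"]
        for sid, s in sorted(d.items()):
            if s is None:
                lines.append(f"| {sid} | — | — | — | — | — | empty | empty |")
                continue
            lines.append(
                f"| {sid} | {s.n} | {s.margin_95ci:.1f} "
                f"| {s.median_rpe:.1f} ({s.iqr_rpe[0]:.1f}, {s.iqr_rpe[1]:.1f}) "
                f"| {s.n_under} ({s.pct_under}%) | {s.n_over} ({s.pct_over}%) "
                f"| {'pass' if s.clinical_acceptance.passed else 'fail'} "
                f"| {'pass' if s.exactness.passed else 'fail'} |"
            )
        lines.append("")
        return lines

    lines = ["# Bilirubin forecast validation report", ""]
    lines += fmt_summary_rows(report.summaries, "Scenario summaries (primary arm)")
    if report.summaries_unharmonized:
        lines += fmt_summary_rows(report.summaries_unharmonized,
                                  "Mixed-method scenarios without harmonization")
    if any(v is not None for v in report.hemolytic_summaries.values()):
        lines += fmt_summary_rows(report.hemolytic_summaries, "Hemolytic-disease subgroup")
    else:
        lines += ["## Hemolytic-disease subgroup", "", "No subgroup large enough to summarize.", ""]
    if report.increase_rates:
        lines += ["## Bilirubin increase rates (mg/dl per hour)", "",
                  "| Arm | N | Observed median (IQR) | Predicted median (IQR) |",
                  "|---|---|---|---|"]
        for key, rs in sorted(report.increase_rates.items()):
            lines.append(
                f"| {key} | {rs.n} "
                f"| {rs.observed_median:.3f} ({rs.observed_iqr[0]:.3f}, {rs.observed_iqr[1]:.3f}) "
                f"| {rs.predicted_median:.3f} ({rs.predicted_iqr[0]:.3f}, {rs.predicted_iqr[1]:.3f}) |"
            )
        lines.append("")
    return "\n".join(lines)


def write_outputs(report: RunReport, outdir: str | Path) -> None:
    """Flush every stage artefact: cohort CSVs, scenario instances,
    predictions, accounting, summary.json and a markdown report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.dataset.write_csv(outdir)
    instances_frame(report.build).to_csv(outdir / "scenario_instances.csv", index=False)
    predictions_frame(report.records).to_csv(outdir / "predictions.csv", index=False)
    pd.DataFrame(report.build.accounting_rows()).to_csv(outdir / "accounting.csv", index=False)
    (outdir / "summary.json").write_text(
        json.dumps(report.to_json_dict(), indent=2, sort_keys=True) + "\n"
    )
    (outdir / "report.md").write_text(render_markdown(report))
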