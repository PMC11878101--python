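"""Rule-based construction of validation scenarios from longitudinal records.

A validation scenario turns one patient's measurement history into a
prediction task: 1–3 chronological input measurements of the required
method(s), plus a later target measurement to predict. The selection rules
mirror the input criteria of bedside bilirubin-prediction tooling:

(i)   the first input must fall between 8 and 72 h of postnatal age;
(ii)  each subsequent input is the first later measurement at least 8 h
      after the previous one and inside the subsequent window
      (24–96 h for the single-method Population-A scenarios,
      extended to 24–120 h for the mixed-method Population-B scenarios);
(iii) the target is the last eligible measurement within the scenario's
      prediction horizon, itself ≥ 8 h after the last input and inside the
      subsequent window;
(iv)  when two measurements share a time point, the transcutaneous (TcB)
      one is chosen — the noisier option, a deliberate stress choice.

Window boundaries are closed intervals. Selection is greedy first-fit and
fully deterministic; every rejection carries a machine-readable rule tag so
population accounting (CONSORT-style) can be reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .types import BilirubinMeasurement

__all__ = [
    "ScenarioSpec",
    "ScenarioInstance",
    "Rejection",
    "BuildReport",
    "default_scenarios",
    "select_inputs",
    "build_population",
    "REJECTION_REASONS",
]

MIN_GAP_H: float = 8.0
FIRST_WINDOW_H: tuple[float, float] = (8.0, 72.0)
SUBSEQUENT_WINDOW_A_H: tuple[float, float] = (24.0, 96.0)
SUBSEQUENT_WINDOW_B_H: tuple[float, float] = (24.0, 120.0)

#: Machine-readable rejection reasons, by failing rule.
REJECTION_REASONS: tuple[str, ...] = (
    "no_first_measurement",   # no measurement of the required method at all
    "first_window",           # required-method measurements exist, none in 8–72 h
    "window",                 # a subsequent input slot found no candidate inside its window
    "gap",                    # candidates existed inside the window but all closer than 8 h
    "no_target",              # no eligible target measurement after the inputs
    "horizon",                # eligible targets existed but all beyond the horizon
)


@dataclass(frozen=True)
class ScenarioSpec:
    """Static definition of one validation scenario."""

    scenario_id: int
    n_inputs: int
    input_methods: frozenset[str]
    target_methods: frozenset[str]
    horizon: float
    first_window: tuple[float, float] = FIRST_WINDOW_H
    subsequent_window: tuple[float, float] = SUBSEQUENT_WINDOW_A_H
    min_gap: float = MIN_GAP_H
    tie_prefer_tcb: bool = True
    population: str = "A"

    def __post_init__(self) -> None:
        if self.n_inputs not in (1, 2, 3):
            raise ValueError("n_inputs must be 1, 2 or 3")
        if self.horizon not in (30.0, 48.0, 60.0):
            raise ValueError("horizon must be 30, 48 or 60 h")
        if not self.input_methods or not self.input_methods <= {"TSB", "TcB"}:
            raise ValueError("input_methods must be a non-empty subset of {TSB, TcB}")
        if not self.target_methods or not self.target_methods <= {"TSB", "TcB"}:
            raise ValueError("target_methods must be a non-empty subset of {TSB, TcB}")
        if self.min_gap != MIN_GAP_H:
            raise ValueError("the inter-measurement gap rule is fixed at 8 h")


def default_scenarios() -> list[ScenarioSpec]:
    """The five standard scenarios.

    Population A (single-method): 1 TSB / 30 h, 2 TSB / 60 h, 3 TcB / 48 h,
    with subsequent windows of 24–96 h. Population B (any mix of methods):
    2 or 3 measurements / 48 h with subsequent windows extended to 24–120 h.
    """
    tsb, tcb, both = frozenset({"TSB"}), frozenset({"TcB"}), frozenset({"TSB", "TcB"})
    return [
        ScenarioSpec(1, 1, tsb, tsb, 30.0, population="A"),
        ScenarioSpec(2, 2, tsb, tsb, 60.0, population="A"),
        ScenarioSpec(3, 3, tcb, tcb, 48.0, population="A"),
        ScenarioSpec(4, 2, both, both, 48.0,
                     subsequent_window=SUBSEQUENT_WINDOW_B_H, population="B"),
        ScenarioSpec(5, 3, both, both, 48.0,
                     subsequent_window=SUBSEQUENT_WINDOW_B_H, population="B"),
    ]


@dataclass(frozen=True)
class ScenarioInstance:
    """One constructed prediction task."""

    patient_id: str
    scenario_id: int
    inputs: tuple[BilirubinMeasurement, ...]
    target: BilirubinMeasurement
    t_last: float
    t_target: float
    horizon_used: float

    def __post_init__(self) -> None:
        times = [m.pna for m in self.inputs]
        if any(b - a < MIN_GAP_H for a, b in zip(times, times[1:])):
            raise ValueError("inputs must be chronological with ≥ 8 h gaps")
        if self.t_last != times[-1]:
            raise ValueError("t_last must equal the last input time")
        if self.t_target != self.target.pna or self.t_target <= self.t_last:
            raise ValueError("target must lie strictly after the last input")
        if abs(self.horizon_used - (self.t_target - self.t_last)) > 1e-9:
            raise ValueError("horizon_used must equal t_target − t_last")


@dataclass(frozen=True)
class Rejection:
    """A patient that could not fill the scenario's slots, with the rule tag."""

    patient_id: str
    scenario_id: int
    reason: str
    detail: str = ""

    def __post_init__(self) -> None:
        if self.reason not in REJECTION_REASONS:
            raise ValueError(f"unknown rejection reason {self.reason!r}")


def _pick_at_time(
    candidates: list[BilirubinMeasurement], spec: ScenarioSpec
) -> BilirubinMeasurement:
    """Among eligible measurements sharing the same time, prefer TcB."""
    if spec.tie_prefer_tcb:
        for m in candidates:
            if m.method == "TcB":
                return m
    return candidates[0]


def select_inputs(
    measurements: Sequence[BilirubinMeasurement],
    spec: ScenarioSpec,
    patient_id: str = "",
) -> ScenarioInstance | Rejection:
    """Apply the scenario's input rules to one patient's sorted history.

    Greedy first-fit: the first input is the first required-method
    measurement inside the 8–72 h window; each subsequent input is the
    first later required-method measurement ≥ 8 h after the previous one
    and inside the subsequent window; the target is the **last** eligible
    measurement whose distance from the last input does not exceed the
    horizon. Returns a :class:`Rejection` with a rule tag when a slot
    cannot be filled.
    """
    times = [m.pna for m in measurements]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("measurements must be sorted by pna")

    def reject(reason: str, detail: str = "") -> Rejection:
        return Rejection(patient_id=patient_id, scenario_id=spec.scenario_id,
                         reason=reason, detail=detail)

    # --- first input -----------------------------------------------------
    lo, hi = spec.first_window
    method_ok = [m for m in measurements if m.method in spec.input_methods]
    if not method_ok:
        return reject("no_first_measurement")
    eligible_first = [m for m in method_ok if lo <= m.pna <= hi]
    if not eligible_first:
        return reject("first_window",
                      f"no {'/'.join(sorted(spec.input_methods))} in [{lo}, {hi}] h")
    t_first = eligible_first[0].pna
    inputs = [_pick_at_time([m for m in eligible_first if m.pna == t_first], spec)]

    # --- subsequent inputs ------------------------------------------------
    slo, shi = spec.subsequent_window
    for slot in range(1, spec.n_inputs):
        prev = inputs[-1]
        later = [m for m in method_ok if m.pna > prev.pna]
        eligible = [m for m in later
                    if slo <= m.pna <= shi and m.pna - prev.pna >= spec.min_gap]
        if not eligible:
            in_window = [m for m in later if slo <= m.pna <= shi]
            reason = "gap" if in_window else "window"
            return reject(reason, f"input slot {slot + 1}")
        t_next = eligible[0].pna
        inputs.append(_pick_at_time([m for m in eligible if m.pna == t_next], spec))

    # --- target -----------------------------------------------------------
    last = inputs[-1]
    candidates = [
        m for m in measurements
        if m.method in spec.target_methods
        and m.pna > last.pna
        and slo <= m.pna <= shi
        and m.pna - last.pna >= spec.min_gap
    ]
    if not candidates:
        return reject("no_target")
    within = [m for m in candidates if m.pna - last.pna <= spec.horizon]
    if not within:
        return reject("horizon",
                      f"nearest eligible target {min(m.pna for m in candidates) - last.pna:.1f} h ahead")
    t_tgt = max(m.pna for m in within)
    target = _pick_at_time([m for m in within if m.pna == t_tgt], spec)

    return ScenarioInstance(
        patient_id=patient_id,
        scenario_id=spec.scenario_id,
        inputs=tuple(inputs),
        target=target,
        t_last=last.pna,
        t_target=target.pna,
        horizon_used=target.pna - last.pna,
    )


@dataclass
class BuildReport:
    """Scenario populations plus CONSORT-style accounting.

    ``rejections[scenario_id][reason]`` counts patients rejected per rule;
    ``rejection_records`` retains every individual rejection for audit
    logging. A patient may appear in several scenario populations.
    """

    instances: dict[int, list[ScenarioInstance]] = field(default_factory=dict)
    rejections: dict[int, dict[str, int]] = field(default_factory=dict)
    rejection_records: list[Rejection] = field(default_factory=list)

    def n_instances(self, scenario_id: int) -> int:
        return len(self.instances.get(scenario_id, []))

    def accounting_rows(self) -> list[dict[str, object]]:
        rows: list[dict[str, object]] = []
        for sid in sorted(self.instances):
            row: dict[str, object] = {"scenario_id": sid, "n_instances": self.n_instances(sid)}
            for reason in REJECTION_REASONS:
                row[f"rejected_{reason}"] = self.rejections.get(sid, {}).get(reason, 0)
            rows.append(row)
        return rows


def build_population(
    measurements_by_patient: dict[str, Sequence[BilirubinMeasurement]],
    specs: Sequence[ScenarioSpec],
) -> BuildReport:
    """Run every patient through every scenario spec and tally the outcome."""
    report = BuildReport(
        instances={s.scenario_id: [] for s in specs},
        rejections={s.scenario_id: {r: 0 for r in REJECTION_REASONS} for s in specs},
    )
    for pid in sorted(measurements_by_patient):
        ms = sorted(measurements_by_patient[pid], key=lambda m: (m.pna, m.method))
        for spec in specs:
            result = select_inputs(ms, spec, patient_id=pid)
            if isinstance(result, ScenarioInstance):
                report.instances[spec.scenario_id].append(result)
            else:
                report.rejections[spec.scenario_id][result.reason] += 1
                report.rejection_records.append(result)
    return report
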