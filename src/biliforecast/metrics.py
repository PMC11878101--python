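"""Validation metrics and acceptance criteria for bilirubin forecasts.

Definitions
-----------
For a predicted value B_pred and the observed target B_obs:

    PE   = B_pred − B_obs                  (µmol/L; negative = under-prediction,
                                            the clinically dangerous direction)
    aPE  = |B_pred − B_obs|                (µmol/L)
    rPE  = 100 · |B_pred − B_obs| / B_obs  (% of observed)

The agreement criterion works on the Bland-Altman limits of the prediction
errors, mean(PE) ± 1.96·SD(PE) (sample SD); the *margin of error* is the
larger absolute limit. The clinical margin of 85 µmol/L is the printed gap
between gestational-age-specific phototherapy and exchange-transfusion
thresholds; 70 µmol/L is the stricter "exactness" margin.

Verdicts
--------
clinical acceptance: margin ≤ 85 µmol/L  AND  ≥ 95% of aPE ≤ 85 µmol/L
exactness:           margin ≤ 70 µmol/L  AND  no aPE > 85 µmol/L

Mis-prediction tails are counted with strict inequalities (PE < −85,
PE > +85) and reported as percentages rounded half-away-from-zero to one
decimal. Medians/IQRs use the linear-interpolation quantile convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np

from .types import DEFAULT_TCB_OFFSET, UMOL_PER_MGDL, BilirubinMeasurement, Method

__all__ = [
    "PredictionRecord",
    "AcceptanceThresholds",
    "CriterionVerdict",
    "ValidationSummary",
    "prediction_error",
    "absolute_prediction_error",
    "relative_prediction_error",
    "bland_altman_margin",
    "misprediction_counts",
    "clinical_acceptance",
    "exactness",
    "harmonize",
    "unharmonize",
    "increase_rate",
    "summarize",
    "round_pct",
]


@dataclass(frozen=True)
class PredictionRecord:
    """One prediction paired with its observed target."""

    patient_id: str
    scenario_id: int
    b_pred: float
    b_obs: float
    b_last: float
    t_last: float
    t_target: float
    target_method: Method
    hemolytic: bool = False

    def __post_init__(self) -> None:
        for name in ("b_pred", "b_obs", "b_last", "t_last", "t_target"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.t_target <= self.t_last:
            raise ValueError("t_target must lie strictly after t_last")

    @property
    def pe(self) -> float:
        return prediction_error(self.b_pred, self.b_obs)

    @property
    def ape(self) -> float:
        return absolute_prediction_error(self.b_pred, self.b_obs)

    @property
    def rpe(self) -> float:
        return relative_prediction_error(self.b_pred, self.b_obs)


@dataclass(frozen=True)
class AcceptanceThresholds:
    """The fixed clinical constants of the acceptance criteria (µmol/L)."""

    clinical_margin: float = 85.0
    clinical_miss_fraction: float = 0.95
    exact_margin: float = 70.0
    miss_threshold: float = 85.0

    def __post_init__(self) -> None:
        if not self.exact_margin < self.clinical_margin:
            raise ValueError("exact_margin must be below clinical_margin")
        if not 0 < self.clinical_miss_fraction <= 1:
            raise ValueError("clinical_miss_fraction must be in (0, 1]")


def prediction_error(b_pred: float, b_obs: float) -> float:
    """Signed prediction error PE = B_pred − B_obs (µmol/L)."""
    if not (math.isfinite(b_pred) and math.isfinite(b_obs)):
        raise ValueError("prediction_error requires finite inputs")
    return b_pred - b_obs


def absolute_prediction_error(b_pred: float, b_obs: float) -> float:
    """aPE = |B_pred − B_obs| (µmol/L)."""
    return abs(prediction_error(b_pred, b_obs))


def relative_prediction_error(b_pred: float, b_obs: float) -> float:
    """rPE = 100 · |B_pred − B_obs| / B_obs (percent); requires B_obs > 0."""
    if not (math.isfinite(b_pred) and math.isfinite(b_obs)):
        raise ValueError("relative_prediction_error requires finite inputs")
    if b_obs <= 0:
        raise ValueError("rPE is undefined for non-positive observed values")
    return 100.0 * abs(b_pred - b_obs) / b_obs


def bland_altman_margin(
    pe_values: Sequence[float], *, use_se_of_mean: bool = False
) -> float:
    """Margin of error of the 95% agreement interval of prediction errors.

    Default: Bland-Altman limits of agreement, mean(PE) ± 1.96·SD(PE) with
    the sample SD (n−1); the margin is max(|lower|, |upper|). Setting
    ``use_se_of_mean`` replaces SD with SD/√n (the narrower CI-of-the-mean
    reading, available for sensitivity analyses).
    """
    pe = np.asarray(pe_values, dtype=float)
    if pe.size < 2:
        raise ValueError("bland_altman_margin needs at least 2 prediction errors")
    if not np.all(np.isfinite(pe)):
        raise ValueError("prediction errors must be finite")
    mean = float(pe.mean())
    spread = float(pe.std(ddof=1))
    if use_se_of_mean:
        spread /= math.sqrt(pe.size)
    lower, upper = mean - 1.96 * spread, mean + 1.96 * spread
    return max(abs(lower), abs(upper))


def round_pct(count: int, n: int) -> float:
    """Percentage 100·count/n rounded half-away-from-zero to one decimal.

    (Reproduces printed table cells such as 1/109 → 0.9 and 4/76 → 5.3.)
    """
    if n <= 0:
        raise ValueError("n must be positive")
    pct = Decimal(100 * count) / Decimal(n)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _pe_array(records: Sequence[PredictionRecord]) -> np.ndarray:
    return np.array([r.pe for r in records], dtype=float)


def misprediction_counts(
    records: Sequence[PredictionRecord],
    thresholds: AcceptanceThresholds = AcceptanceThresholds(),
) -> tuple[int, float, int, float]:
    """Counts and percentages of clinically relevant mis-predictions.

    Under-predictions are PE < −85 µmol/L (strict), over-predictions
    PE > +85 µmol/L (strict); a PE of exactly ±85 sits in neither tail.
    """
    if not records:
        raise ValueError("misprediction_counts needs at least one record")
    pe = _pe_array(records)
    thr = thresholds.miss_threshold
    n_under = int(np.sum(pe < -thr))
    n_over = int(np.sum(pe > thr))
    n = len(records)
    return n_under, round_pct(n_under, n), n_over, round_pct(n_over, n)


@dataclass(frozen=True)
class CriterionVerdict:
    """Pass/fail verdict with its two sub-conditions reported separately."""

    passed: bool
    margin_ok: bool
    miss_ok: bool
    margin: float
    miss_statistic: float
    boundary_case: bool = False

    def __post_init__(self) -> None:
        if self.passed != (self.margin_ok and self.miss_ok):
            raise ValueError("passed must equal margin_ok AND miss_ok")


def clinical_acceptance(
    records: Sequence[PredictionRecord],
    thresholds: AcceptanceThresholds = AcceptanceThresholds(),
) -> CriterionVerdict:
    """Clinical acceptance: margin ≤ 85 µmol/L and ≥ 95% of aPE ≤ 85 µmol/L.

    The boundary reading of "95% of errors do not exceed 85" is taken as
    ≥ 0.95; an exact-boundary fraction is flagged via ``boundary_case``.
    """
    if len(records) < 2:
        raise ValueError("clinical_acceptance needs at least 2 records")
    margin = bland_altman_margin(_pe_array(records))
    ape = np.abs(_pe_array(records))
    frac_within = float(np.mean(ape <= thresholds.miss_threshold))
    margin_ok = margin <= thresholds.clinical_margin
    miss_ok = frac_within >= thresholds.clinical_miss_fraction
    return CriterionVerdict(
        passed=margin_ok and miss_ok,
        margin_ok=margin_ok,
        miss_ok=miss_ok,
        margin=margin,
        miss_statistic=frac_within,
        boundary_case=math.isclose(frac_within, thresholds.clinical_miss_fraction),
    )


def exactness(
    records: Sequence[PredictionRecord],
    thresholds: AcceptanceThresholds = AcceptanceThresholds(),
) -> CriterionVerdict:
    """Exactness (stress) criterion: margin ≤ 70 µmol/L and max aPE ≤ 85."""
    if len(records) < 2:
        raise ValueError("exactness needs at least 2 records")
    margin = bland_altman_margin(_pe_array(records))
    max_ape = float(np.max(np.abs(_pe_array(records))))
    margin_ok = margin <= thresholds.exact_margin
    miss_ok = max_ape <= thresholds.miss_threshold
    return CriterionVerdict(
        passed=margin_ok and miss_ok,
        margin_ok=margin_ok,
        miss_ok=miss_ok,
        margin=margin,
        miss_statistic=max_ape,
    )


def harmonize(
    measurements: Iterable[BilirubinMeasurement],
    target_method: Method,
    offset: float = DEFAULT_TCB_OFFSET,
) -> list[BilirubinMeasurement]:
    """Map all measurement values onto the target measurement's scale.

    With the default sign convention TcB reads ``offset`` µmol/L above TSB,
    so TcB values are lowered by the offset when the target is TSB and TSB
    values raised when the target is TcB. Each measurement's ``scale``
    records the scale its value currently lives on, which makes the
    operation idempotent; :func:`unharmonize` restores native scales.
    """
    if target_method not in ("TSB", "TcB"):
        raise ValueError(f"unknown target method {target_method!r}")
    level = {"TSB": 0.0, "TcB": offset}
    out = []
    for m in measurements:
        if m.scale == target_method:
            out.append(m)
        else:
            shifted = m.value - level[m.scale] + level[target_method]
            out.append(m.with_value(shifted, target_method))
    return out


def unharmonize(
    measurements: Iterable[BilirubinMeasurement],
    offset: float = DEFAULT_TCB_OFFSET,
) -> list[BilirubinMeasurement]:
    """Undo :func:`harmonize`: return every value to its native method scale."""
    level = {"TSB": 0.0, "TcB": offset}
    out = []
    for m in measurements:
        if m.scale == m.method:
            out.append(m)
        else:
            restored = m.value - level[m.scale] + level[m.method]
            out.append(m.with_value(restored, m.method))
    return out


def increase_rate(
    b_target: float, b_last: float, t_target: float, t_last: float
) -> float:
    """Bilirubin rate of increase in mg/dl per hour.

    incrRate = (B_target − B_last) / (t_target − t_last), with the
    concentration difference converted from µmol/L to mg/dl (17.1 µmol/L
    per mg/dl) so the rate is on the scale used by risk-assessment
    guidance.
    """
    if not all(math.isfinite(v) for v in (b_target, b_last, t_target, t_last)):
        raise ValueError("increase_rate requires finite inputs")
    if t_target <= t_last:
        raise ValueError("t_target must lie strictly after t_last")
    return ((b_target - b_last) / UMOL_PER_MGDL) / (t_target - t_last)


def _median_iqr(values: np.ndarray) -> tuple[float, float, float]:
    q25, q50, q75 = np.percentile(values, [25.0, 50.0, 75.0])  # linear interpolation
    return float(q50), float(q25), float(q75)


@dataclass(frozen=True)
class ValidationSummary:
    """Per-scenario aggregate of all validation metrics."""

    n: int
    margin_95ci: float
    median_ape: float
    iqr_ape: tuple[float, float]
    median_rpe: float
    iqr_rpe: tuple[float, float]
    n_under: int
    pct_under: float
    n_over: int
    pct_over: float
    clinical_acceptance: CriterionVerdict
    exactness: CriterionVerdict

    def to_dict(self) -> dict[str, object]:
        def verdict(v: CriterionVerdict) -> dict[str, object]:
            return {
                "passed": v.passed,
                "margin_ok": v.margin_ok,
                "miss_ok": v.miss_ok,
                "margin": v.margin,
                "miss_statistic": v.miss_statistic,
                "boundary_case": v.boundary_case,
            }

        return {
            "n": self.n,
            "margin_95ci": self.margin_95ci,
            "median_ape": self.median_ape,
            "iqr_ape": list(self.iqr_ape),
            "median_rpe": self.median_rpe,
            "iqr_rpe": list(self.iqr_rpe),
            "n_under": self.n_under,
            "pct_under": self.pct_under,
            "n_over": self.n_over,
            "pct_over": self.pct_over,
            "clinical_acceptance": verdict(self.clinical_acceptance),
            "exactness": verdict(self.exactness),
        }


def summarize(
    records: Sequence[PredictionRecord],
    thresholds: AcceptanceThresholds = AcceptanceThresholds(),
) -> ValidationSummary:
    """Assemble the full per-scenario validation summary.

    Deterministic and invariant to the order of ``records``.
    """
    if len(records) < 2:
        raise ValueError("summarize needs at least 2 records")
    pe = _pe_array(records)
    ape = np.abs(pe)
    rpe = np.array([r.rpe for r in records], dtype=float)
    med_ape, q25_ape, q75_ape = _median_iqr(ape)
    med_rpe, q25_rpe, q75_rpe = _median_iqr(rpe)
    n_under, pct_under, n_over, pct_over = misprediction_counts(records, thresholds)
    return ValidationSummary(
        n=len(records),
        margin_95ci=bland_altman_margin(pe),
        median_ape=med_ape,
        iqr_ape=(q25_ape, q75_ape),
        median_rpe=med_rpe,
        iqr_rpe=(q25_rpe, q75_rpe),
        n_under=n_under,
        pct_under=pct_under,
        n_over=n_over,
        pct_over=pct_over,
        clinical_acceptance=clinical_acceptance(records, thresholds),
        exactness=exactness(records, thresholds),
    )
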