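"""Core domain records: neonates, covariates, and bilirubin measurements.

All concentrations are total bilirubin in µmol/L; the time axis is postnatal
age (PNA) in hours, continuous, with t = 0 at birth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

Sex = Literal["female", "male"]
DeliveryMode = Literal["vaginal", "cesarean"]
Method = Literal["TSB", "TcB"]

#: Molar conversion constant for bilirubin: 1 mg/dl = 17.1 µmol/L.
UMOL_PER_MGDL: float = 17.1

#: Mean TcB − TSB difference (µmol/L) reported in device-comparison studies;
#: used both by the measurement simulator and by harmonization.
DEFAULT_TCB_OFFSET: float = 14.3

#: Minimum gestational age (completed weeks) for inclusion.
MIN_GESTATIONAL_AGE_WEEKS: float = 34.0
#: Minimum birth weight (g) for inclusion.
MIN_BIRTH_WEIGHT_G: float = 1500.0


@dataclass(frozen=True)
class Covariates:
    """Clinical covariates of one neonate used by the kinetic model.

    Parameters
    ----------
    gestational_age
        Gestational age at birth in (decimal) weeks; must be ≥ 34, the
        eligibility floor of late-preterm/term cohorts.
    birth_weight
        Birth weight in grams; must be ≥ 1500 g (very-low-birth-weight
        neonates are out of the model's training domain).
    sex
        ``"female"`` or ``"male"``. Recorded for cohort description; the
        default covariate model does not condition on it.
    delivery_mode
        ``"vaginal"`` or ``"cesarean"``.
    hemolytic
        True if the neonate has hemolytic disease (including blood-group
        incompatibility); modelled as increased bilirubin production.
    """

    gestational_age: float
    birth_weight: float
    sex: Sex = "female"
    delivery_mode: DeliveryMode = "vaginal"
    hemolytic: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.gestational_age) or self.gestational_age < MIN_GESTATIONAL_AGE_WEEKS:
            raise ValueError(
                f"gestational_age must be ≥ {MIN_GESTATIONAL_AGE_WEEKS} weeks, "
                f"got {self.gestational_age}"
            )
        if not math.isfinite(self.birth_weight) or self.birth_weight < MIN_BIRTH_WEIGHT_G:
            raise ValueError(
                f"birth_weight must be ≥ {MIN_BIRTH_WEIGHT_G} g, got {self.birth_weight}"
            )
        if self.sex not in ("female", "male"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.delivery_mode not in ("vaginal", "cesarean"):
            raise ValueError(f"unknown delivery_mode {self.delivery_mode!r}")


#: Reference covariates at which all covariate multipliers equal one
#: (term neonate near the cohort medians).
REFERENCE_GA_WEEKS: float = 38.7
REFERENCE_WEIGHT_G: float = 3500.0


@dataclass(frozen=True)
class BilirubinMeasurement:
    """One timestamped bilirubin observation.

    ``method`` is the physical measurement method (TSB: serum photometry,
    the gold standard; TcB: transcutaneous optics, noisier and offset high).
    ``scale`` is the reporting scale the numeric value currently lives on;
    it equals ``method`` for raw data and is changed by harmonization,
    which maps values onto the target measurement's scale.
    """

    pna: float
    value: float
    method: Method
    scale: Method | None = field(default=None)

    def __post_init__(self) -> None:
        if not math.isfinite(self.pna) or self.pna < 0:
            raise ValueError(f"pna must be a finite nonnegative hour count, got {self.pna}")
        if not math.isfinite(self.value) or self.value < 0:
            raise ValueError(f"value must be finite and nonnegative µmol/L, got {self.value}")
        if self.method not in ("TSB", "TcB"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.scale is None:
            object.__setattr__(self, "scale", self.method)
        elif self.scale not in ("TSB", "TcB"):
            raise ValueError(f"unknown scale {self.scale!r}")

    def with_value(self, value: float, scale: Method) -> "BilirubinMeasurement":
        return replace(self, value=value, scale=scale)


@dataclass(frozen=True)
class NeonatalPatient:
    """One synthetic neonate: identity, covariates and the simulation-truth
    random effects (``true_eta``), which prediction code never sees."""

    patient_id: str
    covariates: Covariates
    true_eta: tuple[float, ...] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if not all(math.isfinite(e) for e in self.true_eta):
            raise ValueError("true_eta must be finite")
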