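"""Domain model for hematologic organ-dysfunction detection.

The types mirror the clinical payload of a PICU stay: LOINC-coded
laboratory observations (platelet count, INR), ICD-10-GM diagnoses,
procedure episodes (ECMO), and the intervals the rule engine and the
evaluation derive from them.

Units are canonical throughout: platelet counts in /mm**3 (equivalently
/uL; multiply x10^9/L values by 1,000), INR dimensionless. Timestamps are
timezone-naive datetimes at minute resolution.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from enum import Enum
from typing import Optional, Sequence


class Analyte(str, Enum):
    PLT = "PLT"
    INR = "INR"


#: LOINC codes accepted by the readers, keyed by analyte.
LOINC_CODES = {Analyte.PLT: "777-3", Analyte.INR: "6301-6"}
ANALYTE_BY_LOINC = {v: k for k, v in LOINC_CODES.items()}


class AlarmCategory(str, Enum):
    TOO_LOW = "TOO_LOW"
    TOO_HIGH = "TOO_HIGH"
    NORMAL = "NORMAL"


class AlarmCriterion(str, Enum):
    ABSOLUTE = "ABSOLUTE"
    RELATIVE_DECLINE = "RELATIVE_DECLINE"


class ODCause(str, Enum):
    PLATELETS = "PLATELETS"
    INR = "INR"
    BOTH = "BOTH"


class BlockLabel(str, Enum):
    TP = "TP"
    FP = "FP"
    FN = "FN"
    TN = "TN"


_ICD10_RE = re.compile(r"[A-Z][0-9A-Z]{1,3}(?:\.[0-9A-Z]{1,4})?")


@dataclass(frozen=True)
class LabObservation:
    """One timestamped analyte measurement.

    ``value`` is in /mm**3 for platelets and dimensionless for INR;
    ``code`` is the LOINC code and must be consistent with ``analyte``.
    """

    patient_id: str
    analyte: Analyte
    value: float
    timestamp: datetime
    code: str = ""

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"observation value must be > 0, got {self.value}")
        expected = LOINC_CODES[self.analyte]
        if not self.code:
            object.__setattr__(self, "code", expected)
        elif self.code != expected:
            raise ValueError(
                f"LOINC code {self.code!r} inconsistent with analyte "
                f"{self.analyte.value} (expected {expected!r})"
            )


@dataclass(frozen=True)
class DiagnosisRecord:
    """A stay-level ICD-10-GM coded diagnosis (no temporal gating)."""

    patient_id: str
    icd10gm_code: str

    def __post_init__(self) -> None:
        if not _ICD10_RE.fullmatch(self.icd10gm_code):
            raise ValueError(f"not an ICD-10-GM code: {self.icd10gm_code!r}")


@dataclass(frozen=True)
class ProcedureEpisode:
    """A procedure interval; only ECMO is relevant to the rules."""

    patient_id: str
    start: datetime
    end: datetime
    procedure: str = "ECMO"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("procedure episode start must be <= end")


@dataclass(frozen=True)
class PatientRecord:
    """One PICU stay: admission window plus observations, diagnoses, procedures.

    Stays shorter than 12 hours are outside the study population and are
    rejected, as are observations outside [admission, discharge].
    """

    patient_id: str
    age_years: float
    admission: datetime
    discharge: datetime
    observations: tuple[LabObservation, ...] = ()
    diagnoses: tuple[DiagnosisRecord, ...] = ()
    procedures: tuple[ProcedureEpisode, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.age_years <= 18:
            raise ValueError(f"age {self.age_years} outside the pediatric range [0, 18]")
        if self.discharge - self.admission < timedelta(hours=12):
            raise ValueError("stay shorter than 12 hours (study inclusion criterion)")
        object.__setattr__(self, "observations", tuple(self.observations))
        object.__setattr__(self, "diagnoses", tuple(self.diagnoses))
        object.__setattr__(self, "procedures", tuple(self.procedures))
        for obs in self.observations:
            if not self.admission <= obs.timestamp <= self.discharge:
                raise ValueError(
                    f"observation at {obs.timestamp} outside stay "
                    f"[{self.admission}, {self.discharge}]"
                )


@dataclass(frozen=True)
class NormRange:
    """Normal range for one analyte; values strictly outside it alarm."""

    analyte: Analyte
    minimum: float
    maximum: float

    def __post_init__(self) -> None:
        if not self.minimum < self.maximum:
            raise ValueError("norm range minimum must be < maximum")


@dataclass(frozen=True)
class AlarmEvent:
    """An interval over which one analyte is persistently abnormal."""

    patient_id: str
    analyte: Analyte
    category: AlarmCategory
    criterion: AlarmCriterion
    start: datetime
    end: datetime

    def __post_init__(self) -> None:
        if self.category is AlarmCategory.NORMAL:
            raise ValueError("alarm events carry only abnormal categories")
        if not self.start < self.end:
            raise ValueError("alarm event start must be < end")


@dataclass(frozen=True)
class ODEpisode:
    """A hematologic organ-dysfunction episode with cause attribution."""

    patient_id: str
    start: datetime
    end: datetime
    cause: ODCause

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("episode start must be < end")


@dataclass(frozen=True)
class ReferenceEpisode:
    """A clinician-adjudicated dysfunction episode (reference standard)."""

    patient_id: str
    start: datetime
    end: datetime

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("reference episode start must be < end")


@dataclass(frozen=True)
class EvaluationBlock:
    """A maximal sub-interval of a stay with constant diagnostic status pair."""

    patient_id: str
    start: datetime
    end: datetime
    label: BlockLabel

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("block start must be < end")

    @property
    def duration(self) -> timedelta:
        return self.end - self.start


# Placeholder diagnosis lists (the site-specific lists are configurable):
# chronic hematology/oncology conditions associated with thrombocytopenia
# (ICD-10 chapter II hematologic malignancies), and hereditary
# coagulation-factor deficiencies that raise INR independently of sepsis.
DEFAULT_CHRONIC_HEMONC_CODES = tuple(f"C{n}" for n in range(81, 97))
DEFAULT_INR_EXCLUSION_CODES = ("D66", "D67", "D68")


@dataclass(frozen=True)
class RuleConfig:
    """Thresholds and windows of the hematologic dysfunction rules.

    ``plt_min`` (/mm**3) and ``inr_max`` are the diagnostic thresholds; the
    respective other boundary of each norm range is a clinical plausibility
    bound. ``decline_fraction`` is the relative platelet decline (vs the
    first value after admission) that triggers the chronic-patient rule.
    ECMO episodes are extended by ``ecmo_pre_hours``/``ecmo_post_hours``
    and suppress platelet alarms inside the extended window.
    """

    plt_min: float = 80_000.0
    plt_max_plausible: float = 1_000_000.0
    inr_max: float = 2.0
    inr_min_plausible: float = 0.5
    decline_fraction: float = 0.5
    chronic_hemonc_codes: tuple[str, ...] = DEFAULT_CHRONIC_HEMONC_CODES
    inr_exclusion_codes: tuple[str, ...] = DEFAULT_INR_EXCLUSION_CODES
    code_prefix_match: bool = True
    ecmo_pre_hours: float = 2.0
    ecmo_post_hours: float = 12.0

    def __post_init__(self) -> None:
        if not self.plt_min < self.plt_max_plausible:
            raise ValueError("plt_min must be < plt_max_plausible")
        if not self.inr_min_plausible < self.inr_max:
            raise ValueError("inr_min_plausible must be < inr_max")
        if not 0 < self.decline_fraction < 1:
            raise ValueError("decline_fraction must be in (0, 1)")
        if self.ecmo_pre_hours < 0 or self.ecmo_post_hours < 0:
            raise ValueError("ECMO window extensions must be >= 0")
        object.__setattr__(self, "chronic_hemonc_codes", tuple(self.chronic_hemonc_codes))
        object.__setattr__(self, "inr_exclusion_codes", tuple(self.inr_exclusion_codes))


__all__ = [
    "Analyte",
    "AlarmCategory",
    "AlarmCriterion",
    "ODCause",
    "BlockLabel",
    "LOINC_CODES",
    "ANALYTE_BY_LOINC",
    "LabObservation",
    "DiagnosisRecord",
    "ProcedureEpisode",
    "PatientRecord",
    "NormRange",
    "AlarmEvent",
    "ODEpisode",
    "ReferenceEpisode",
    "EvaluationBlock",
    "RuleConfig",
    "DEFAULT_CHRONIC_HEMONC_CODES",
    "DEFAULT_INR_EXCLUSION_CODES",
    "replace",
]
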