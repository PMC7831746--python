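"""Sarcopenia phenotyping: BIA-derived skeletal muscle mass and EWGSOP status.

Skeletal muscle mass (SMM, kg) follows the Janssen bioimpedance equation

    SMM = (height_cm^2 / resistance_ohm) * 0.401 + sex * 3.825
          + age * (-0.071) + 5.102

with sex coded 1 for men and 0 for women, height in centimetres inside the
impedance index and resistance in ohms.  The skeletal muscle index (SMI,
kg/m^2) divides SMM by height squared in metres.

Classification uses EWGSOP2-style cutoffs: sarcopenia is confirmed when both
muscle strength (grip) and muscle quantity (SMI) are below the sex-specific
cutoff; low gait speed (<0.8 m/s) marks severe sarcopenia rather than being
required for case status.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort_io import CohortRecord

__all__ = ["CutoffSet", "MuscleMetrics", "janssen_smm", "classify", "DEFAULT_CUTOFFS"]

JANSSEN_IMPEDANCE_COEF = 0.401
JANSSEN_SEX_COEF = 3.825
JANSSEN_AGE_COEF = -0.071
JANSSEN_INTERCEPT = 5.102


@dataclass(frozen=True)
class CutoffSet:
    """Sex-specific EWGSOP cutoffs (kg, kg/m^2, m/s)."""

    grip_low_male: float = 27.0
    grip_low_female: float = 16.0
    smi_low_male: float = 8.87
    smi_low_female: float = 6.42
    gait_low: float = 0.8

    def __post_init__(self) -> None:
        for name in ("grip_low_male", "grip_low_female", "smi_low_male",
                     "smi_low_female", "gait_low"):
            if not getattr(self, name) > 0:
                raise ValueError(f"cutoff {name} must be positive")

    def grip_low(self, sex: str) -> float:
        return self.grip_low_male if sex == "male" else self.grip_low_female

    def smi_low(self, sex: str) -> float:
        return self.smi_low_male if sex == "male" else self.smi_low_female


DEFAULT_CUTOFFS = CutoffSet()


@dataclass(frozen=True)
class MuscleMetrics:
    smm: float
    smi: float
    low_mass: bool
    low_strength: bool
    low_performance: bool
    implausible: bool = False


def janssen_smm(
    height_cm: float, resistance_ohm: float, sex_code: int, age_years: float
) -> float:
    """Skeletal muscle mass (kg) from the Janssen BIA equation.

    ``sex_code`` is 1 for men, 0 for women.  Raises on non-positive
    resistance or height; a negative result is returned as-is (callers flag
    it as implausible).
    """
    if resistance_ohm <= 0:
        raise ValueError("BIA resistance must be positive")
    if height_cm <= 0:
        raise ValueError("height must be positive")
    if sex_code not in (0, 1):
        raise ValueError("sex_code must be 1 (male) or 0 (female)")
    return (
        height_cm**2 / resistance_ohm * JANSSEN_IMPEDANCE_COEF
        + sex_code * JANSSEN_SEX_COEF
        + age_years * JANSSEN_AGE_COEF
        + JANSSEN_INTERCEPT
    )


def classify(
    record: CohortRecord, cutoffs: CutoffSet = DEFAULT_CUTOFFS
) -> tuple[str, MuscleMetrics | None]:
    """EWGSOP classification of one participant.

    Returns ``(status, metrics)`` where status is ``sarcopenic`` (low
    strength AND low mass), ``severe_sarcopenic`` when gait speed is also
    low, ``non_sarcopenic`` otherwise, or ``unclassified`` (metrics None)
    when a required measurement is missing.
    """
    required = (record.grip_kg, record.gait_m_s, record.height_cm,
                record.resistance_ohm)
    if any(v is None for v in required):
        return "unclassified", None

    sex_code = 1 if record.sex == "male" else 0
    smm = janssen_smm(record.height_cm, record.resistance_ohm, sex_code, record.age)
    smi = smm / (record.height_cm / 100.0) ** 2
    metrics = MuscleMetrics(
        smm=smm,
        smi=smi,
        low_mass=smi < cutoffs.smi_low(record.sex),
        low_strength=record.grip_kg < cutoffs.grip_low(record.sex),
        low_performance=record.gait_m_s < cutoffs.gait_low,
        implausible=smm <= 0,
    )
    if metrics.low_strength and metrics.low_mass:
        status = "severe_sarcopenic" if metrics.low_performance else "sarcopenic"
    else:
        status = "non_sarcopenic"
    return status, metrics


def classify_cohort(
    records: list[CohortRecord],
    cutoffs: CutoffSet = DEFAULT_CUTOFFS,
    *,
    overwrite: bool = False,
) -> list[CohortRecord]:
    """Classify every record whose status is unclassified (or all of them).

    Severity collapses onto ``sarcopenic`` for the binary case label carried
    by the cohort table.
    """
    out = []
    for record in records:
        if record.status == "unclassified" or overwrite:
            status, _ = classify(record, cutoffs)
            if status == "severe_sarcopenic":
                status = "sarcopenic"
            record = type(record)(**{**record.__dict__, "status": status})
        out.append(record)
    return out
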