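"""Age-dependent-exponent (ADE) allometric clearance model.

Pediatric clearance is extrapolated from the mean adult clearance by a
body-weight power law,

    CL_child = CL_adult * (W_child / W_ref) ** b,

where the exponent ``b`` is not fixed at the classical 0.75 but varies
with age: rapid, nonlinear physiological change in the first years of
life pushes the effective exponent above 1 in neonates and toward the
adult value only after about five years.  The canonical schedule is

    preterm neonate (0, 0.25] y   b = 1.2
    term neonate    (0, 0.25] y   b = 1.1
    infant/toddler  (0.25, 2] y   b = 1.0
    preschool       (2, 5] y      b = 0.9
    older child     (5, 18) y     b = 0.75

Everything here is pure computation; clearance units are carried through
opaquely (the weight-ratio scaling factor is dimensionless) and are never
converted.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "MaturityStatus",
    "AgeBand",
    "ExponentSchedule",
    "AdultReference",
    "PediatricSubject",
    "ClearancePrediction",
    "DoseProjection",
    "CANONICAL_SCHEDULE",
    "DEFAULT_REFERENCE_WEIGHT_KG",
    "exponent_for_age",
    "predict_clearance",
    "project_dose",
    "fixed_exponent_ratio",
]

#: Adult reference body weight, kg.  The adult clearance entering the
#: power law is standardized to a 70 kg adult.
DEFAULT_REFERENCE_WEIGHT_KG = 70.0

#: Pediatric age domain, years (exclusive at both ends).
AGE_MIN_YEARS = 0.0
AGE_MAX_YEARS = 18.0

#: Upper age bound of the neonatal window, years (3 months).
NEONATAL_AGE_YEARS = 0.25


class DomainError(ValueError):
    """An input lies outside the model's stated domain."""


class MissingMaturityError(DomainError):
    """Neonatal age supplied without a preterm/term designation."""


class MaturityStatus(enum.Enum):
    """Gestational maturity at birth.

    Only meaningful for neonates (age <= 0.25 y), where preterm and term
    infants take different allometric exponents.  ``preterm`` means born
    before 37 completed weeks of gestation by convention; the flag is
    caller-supplied, never inferred.
    """

    PRETERM = "preterm"
    TERM = "term"
    NOT_APPLICABLE = "not_applicable"

    @classmethod
    def from_string(cls, text: str) -> "MaturityStatus":
        try:
            return cls(text.strip().lower())
        except ValueError:
            raise DomainError(f"unknown maturity status: {text!r}") from None


@dataclass(frozen=True)
class AgeBand:
    """One age stratum of the exponent schedule.

    ``lower_open``/``upper_open`` declare the boundary convention; the
    canonical schedule uses half-open bands (lower open, upper closed),
    so age 2.0 falls in the infant/toddler band and 5.0 in preschool.
    """

    label: str
    lower_age: float
    upper_age: float
    exponent: float
    lower_open: bool = True
    upper_open: bool = False

    def __post_init__(self) -> None:
        if not self.lower_age < self.upper_age:
            raise DomainError(
                f"band {self.label!r}: lower_age {self.lower_age} must be "
                f"< upper_age {self.upper_age}"
            )

    def contains(self, age: float) -> bool:
        lo = age > self.lower_age if self.lower_open else age >= self.lower_age
        hi = age < self.upper_age if self.upper_open else age <= self.upper_age
        return lo and hi


@dataclass(frozen=True)
class ExponentSchedule:
    """Ordered, non-overlapping age bands covering (0, 18) years.

    The neonatal band carries two exponents, selected by maturity; all
    later bands ignore maturity.
    """

    bands: tuple[AgeBand, ...]
    neonatal_preterm_exponent: float = 1.2
    neonatal_term_exponent: float = 1.1

    def __post_init__(self) -> None:
        ordered = sorted(self.bands, key=lambda b: b.lower_age)
        if tuple(ordered) != self.bands:
            object.__setattr__(self, "bands", tuple(ordered))
        prev = None
        for band in self.bands:
            if prev is not None and band.lower_age < prev.upper_age:
                raise DomainError(
                    f"bands {prev.label!r} and {band.label!r} overlap"
                )
            prev = band

    @property
    def neonatal_band(self) -> AgeBand:
        return self.bands[0]

    def lookup(self, age: float, maturity: MaturityStatus) -> float:
        return exponent_for_age(age, maturity, self)


def _canonical_bands() -> tuple[AgeBand, ...]:
    return (
        AgeBand("neonate", 0.0, NEONATAL_AGE_YEARS, 1.1),
        AgeBand("infant_toddler", NEONATAL_AGE_YEARS, 2.0, 1.0),
        AgeBand("preschool", 2.0, 5.0, 0.9),
        AgeBand("older_child", 5.0, AGE_MAX_YEARS, 0.75, upper_open=True),
    )


#: The canonical ADE schedule: 1.2 preterm / 1.1 term neonates,
#: 1.0 for >0.25-2 y, 0.9 for >2-5 y, 0.75 above five years.
CANONICAL_SCHEDULE = ExponentSchedule(bands=_canonical_bands())


@dataclass(frozen=True)
class AdultReference:
    """A drug's adult pharmacokinetic anchor for pediatric scaling.

    ``clearance_units`` is preserved verbatim (mL/h, mL/day, L/h,
    mL/min ...) and echoed on every prediction; no conversion happens
    anywhere because the scaling factor is dimensionless.
    """

    drug_name: str
    adult_clearance: float
    clearance_units: str
    drug_class: str = "monoclonal"
    route: str = "IV"
    indication: str = ""
    reference_weight: float = DEFAULT_REFERENCE_WEIGHT_KG

    def __post_init__(self) -> None:
        if not self.adult_clearance > 0:
            raise DomainError(
                f"{self.drug_name}: adult clearance must be positive, "
                f"got {self.adult_clearance}"
            )
        if not self.reference_weight > 0:
            raise DomainError("reference weight must be positive")


@dataclass(frozen=True)
class PediatricSubject:
    """A child to predict for: age in years, maturity flag, optional weight."""

    age: float
    maturity: MaturityStatus = MaturityStatus.NOT_APPLICABLE
    weight: Optional[float] = None

    def __post_init__(self) -> None:
        if not AGE_MIN_YEARS < self.age < AGE_MAX_YEARS:
            raise DomainError(
                f"age must lie in ({AGE_MIN_YEARS}, {AGE_MAX_YEARS}) years, "
                f"got {self.age}"
            )
        if self.weight is not None and not self.weight > 0:
            raise DomainError(f"weight must be positive, got {self.weight}")


@dataclass(frozen=True)
class ClearancePrediction:
    drug_name: str
    weight_used: float
    weight_source: str  # "supplied" | "imputed"
    exponent_used: float
    predicted_clearance: float
    clearance_units: str
    subject: Optional[PediatricSubject] = None


@dataclass(frozen=True)
class DoseProjection:
    """Dose = CL x target AUC; units are the caller's responsibility."""

    target_auc: float
    projected_dose: float
    clearance_used: ClearancePrediction


def exponent_for_age(
    age: float,
    maturity: MaturityStatus = MaturityStatus.NOT_APPLICABLE,
    schedule: ExponentSchedule = CANONICAL_SCHEDULE,
) -> float:
    """Return the allometric exponent for a given age and maturity.

    Total and deterministic over (0, 18) years; boundary ages resolve by
    each band's open/closed flags (canonically upper-inclusive, so 2.0 y
    -> 1.0 and 5.0 y -> 0.9).  Ages at or below 0.25 y require an
    explicit preterm/term designation.
    """
    if not AGE_MIN_YEARS < age < AGE_MAX_YEARS:
        raise DomainError(
            f"age must lie in ({AGE_MIN_YEARS}, {AGE_MAX_YEARS}) years, got {age}"
        )
    for band in schedule.bands:
        if band.contains(age):
            if band is schedule.neonatal_band:
                if maturity is MaturityStatus.PRETERM:
                    return schedule.neonatal_preterm_exponent
                if maturity is MaturityStatus.TERM:
                    return schedule.neonatal_term_exponent
                raise MissingMaturityError(
                    f"age {age} y is neonatal (<= {schedule.neonatal_band.upper_age} y); "
                    "maturity must be 'preterm' or 'term'"
                )
            return band.exponent
    raise DomainError(f"no band covers age {age} y")  # pragma: no cover


def predict_clearance(
    reference: AdultReference,
    weight: float,
    exponent: float,
    *,
    weight_source: str = "supplied",
    subject: Optional[PediatricSubject] = None,
) -> ClearancePrediction:
    """Scale the adult clearance to a child's weight with exponent ``b``.

    CL = CL_adult * (W / W_ref) ** b, at full precision.  Rounding for
    display (one decimal) is a formatting concern, not done here.
    """
    if not weight > 0:
        raise DomainError(f"weight must be positive, got {weight}")
    if not exponent > 0:
        raise DomainError(f"exponent must be positive, got {exponent}")
    cl = reference.adult_clearance * (weight / reference.reference_weight) ** exponent
    return ClearancePrediction(
        drug_name=reference.drug_name,
        weight_used=weight,
        weight_source=weight_source,
        exponent_used=exponent,
        predicted_clearance=cl,
        clearance_units=reference.clearance_units,
        subject=subject,
    )


def project_dose(prediction: ClearancePrediction, target_auc: float) -> DoseProjection:
    """Project a dose achieving a target exposure: Dose = CL x AUC."""
    if not target_auc > 0:
        raise DomainError(f"target AUC must be positive, got {target_auc}")
    return DoseProjection(
        target_auc=target_auc,
        projected_dose=prediction.predicted_clearance * target_auc,
        clearance_used=prediction,
    )


def fixed_exponent_ratio(
    weight: float,
    ade_exponent: float,
    fixed_exponent: float = 0.75,
    reference_weight: float = DEFAULT_REFERENCE_WEIGHT_KG,
) -> float:
    """Over-prediction factor of a fixed-exponent model relative to ADE.

    Returns (W / W_ref) ** (b_fixed - b_ade).  Below the reference weight
    this exceeds 1 whenever the ADE exponent is larger than the fixed
    one, i.e. the classical 0.75 exponent over-predicts neonatal and
    infant clearance, increasingly so the smaller the child.
    """
    if not weight > 0:
        raise DomainError(f"weight must be positive, got {weight}")
    return (weight / reference_weight) ** (fixed_exponent - ade_exponent)


def round_half_away(value: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention printed tables use)."""
    import math

    factor = 10.0 ** decimals
    scaled = value * factor
    return math.copysign(math.floor(abs(scaled) + 0.5), scaled) / factor
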