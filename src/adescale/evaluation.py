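"""Prediction-error statistics and accuracy binning.

The accuracy statistic is the signed percent prediction error,

    %error = (predicted - observed) * 100 / observed,

binned symmetrically on its absolute value at 30% and 50%: |%error| <= 30
is a good prediction, <= 50 acceptable, > 50 unacceptable.  Both
thresholds are inclusive (a -50% row counts as acceptable), so the <= 50
and > 50 bins partition the observations.

Summaries can be computed on two bases:

* ``printed_predictions`` — errors recomputed from the dataset's
  observed/predicted clearance columns (reproducing a published
  evaluation from its printed cells);
* ``model_predictions`` — predictions regenerated from each row's adult
  clearance through the age-dependent-exponent model, with body weight
  imputed from the growth reference unless the row supplies one.

Because published tables round clearances, errors recomputed from
printed cells can differ from the printed error column by a point or
two; rows sitting at a bin boundary may therefore flip bins relative to
the published count.  ``discrepancy_report`` lists such rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

from .core import (
    CANONICAL_SCHEDULE,
    AdultReference,
    ClearancePrediction,
    DomainError,
    ExponentSchedule,
    MaturityStatus,
    exponent_for_age,
    predict_clearance,
    round_half_away,
)
from .dataset import ObservationRecord
from .growth import GrowthReference, load_growth_reference, parse_age_label

__all__ = [
    "ErrorRecord",
    "EvaluationSummary",
    "percent_error",
    "bin_errors",
    "predict_for_record",
    "errors_for_records",
    "summarize",
    "discrepancy_report",
    "format_summary_table",
]

GOOD_THRESHOLD_PCT = 30.0
ACCEPTABLE_THRESHOLD_PCT = 50.0

Basis = Literal["printed_predictions", "model_predictions"]


@dataclass(frozen=True)
class ErrorRecord:
    observation: ObservationRecord
    model_predicted_clearance: float
    percent_error: float


@dataclass(frozen=True)
class EvaluationSummary:
    """Bin counts and error range for one drug class (or overall)."""

    class_or_overall: str
    n_observations: int
    n_within_30: int
    n_within_50: int
    n_over_50: int
    min_abs_error: float
    max_abs_error: float

    def __post_init__(self) -> None:
        if self.n_within_50 + self.n_over_50 != self.n_observations:
            raise DomainError("within-50 and over-50 bins must partition")
        if self.n_within_30 > self.n_within_50:
            raise DomainError("within-30 bin cannot exceed within-50")

    @property
    def pct_within_30(self) -> float:
        return 100.0 * self.n_within_30 / self.n_observations

    @property
    def pct_within_50(self) -> float:
        return 100.0 * self.n_within_50 / self.n_observations

    @property
    def pct_over_50(self) -> float:
        return 100.0 * self.n_over_50 / self.n_observations


def percent_error(predicted: float, observed: float) -> float:
    """Signed percent prediction error, (predicted - observed)*100/observed."""
    if not observed > 0:
        raise DomainError(f"observed clearance must be positive, got {observed}")
    return (predicted - observed) * 100.0 / observed


def bin_errors(
    errors: Sequence[ErrorRecord | float],
    label: str = "overall",
    *,
    rounded: bool = False,
) -> EvaluationSummary:
    """Bin percent errors at the 30%/50% thresholds (absolute, inclusive).

    With ``rounded=True`` the errors are rounded to whole percent (half
    away from zero) before binning, mimicking binning on printed integer
    error columns; the default bins the unrounded values.
    """
    if len(errors) == 0:
        raise DomainError("cannot bin an empty error list")
    values = [
        e.percent_error if isinstance(e, ErrorRecord) else float(e) for e in errors
    ]
    if rounded:
        values = [round_half_away(v) for v in values]
    abs_values = [abs(v) for v in values]
    n30 = sum(v <= GOOD_THRESHOLD_PCT for v in abs_values)
    n50 = sum(v <= ACCEPTABLE_THRESHOLD_PCT for v in abs_values)
    return EvaluationSummary(
        class_or_overall=label,
        n_observations=len(values),
        n_within_30=n30,
        n_within_50=n50,
        n_over_50=len(values) - n50,
        min_abs_error=min(abs_values),
        max_abs_error=max(abs_values),
    )


def predict_for_record(
    record: ObservationRecord,
    schedule: ExponentSchedule = CANONICAL_SCHEDULE,
    growth: Optional[GrowthReference] = None,
) -> ClearancePrediction:
    """Regenerate a row's prediction through the ADE model.

    The exponent comes from the row's ``exponent_override`` when present
    (rows whose age group is unknown carry one), otherwise from the
    schedule at the age label's midpoint age.  The weight comes from the
    row's ``weight_kg`` when present, otherwise from the growth
    reference at that midpoint age.
    """
    if growth is None:
        growth = load_growth_reference()
    reference = AdultReference(
        drug_name=record.drug_name,
        adult_clearance=record.adult_clearance,
        clearance_units=record.clearance_units,
        drug_class=record.drug_class,
        route=record.route,
        indication=record.indication,
    )
    age: Optional[float] = None
    if record.exponent_override is not None:
        exponent = record.exponent_override
    else:
        age = parse_age_label(record.age_label).representative_age
        exponent = exponent_for_age(age, record.maturity, schedule)
    if record.weight_kg is not None:
        weight, source = record.weight_kg, "supplied"
    else:
        if age is None:
            age = parse_age_label(record.age_label).representative_age
        weight, source = growth.median_weight(age, record.maturity), "imputed"
    return predict_clearance(reference, weight, exponent, weight_source=source)


def errors_for_records(
    records: Sequence[ObservationRecord],
    basis: Basis = "printed_predictions",
    schedule: ExponentSchedule = CANONICAL_SCHEDULE,
    growth: Optional[GrowthReference] = None,
) -> list[ErrorRecord]:
    if basis == "printed_predictions":
        return [
            ErrorRecord(
                observation=r,
                model_predicted_clearance=r.paper_predicted_clearance,
                percent_error=percent_error(
                    r.paper_predicted_clearance, r.observed_clearance
                ),
            )
            for r in records
        ]
    if basis == "model_predictions":
        if growth is None:
            growth = load_growth_reference()
        out = []
        for r in records:
            pred = predict_for_record(r, schedule=schedule, growth=growth)
            out.append(
                ErrorRecord(
                    observation=r,
                    model_predicted_clearance=pred.predicted_clearance,
                    percent_error=percent_error(
                        pred.predicted_clearance, r.observed_clearance
                    ),
                )
            )
        return out
    raise DomainError(f"unknown basis {basis!r}")


def summarize(
    records: Sequence[ObservationRecord],
    basis: Basis = "printed_predictions",
    *,
    rounded: bool = False,
    schedule: ExponentSchedule = CANONICAL_SCHEDULE,
    growth: Optional[GrowthReference] = None,
) -> list[EvaluationSummary]:
    """Per-class and overall bin-count summaries (the headline table)."""
    if not records:
        raise DomainError("cannot summarize an empty record list")
    errors = errors_for_records(records, basis, schedule=schedule, growth=growth)
    classes = []
    for e in errors:
        c = e.observation.drug_class
        if c not in classes:
            classes.append(c)
    summaries = [
        bin_errors(
            [e for e in errors if e.observation.drug_class == c], c, rounded=rounded
        )
        for c in classes
    ]
    summaries.append(bin_errors(errors, "overall", rounded=rounded))
    return summaries


def discrepancy_report(
    records: Sequence[ObservationRecord], threshold_pct: float = 2.0
) -> list[dict]:
    """Rows whose recomputed error differs from the stored error column.

    Differences arise purely from rounding of the printed clearance
    cells; rows beyond ``threshold_pct`` points are listed.
    """
    rows = []
    for r in records:
        recomputed = percent_error(r.paper_predicted_clearance, r.observed_clearance)
        diff = recomputed - r.paper_percent_error
        if abs(diff) > threshold_pct:
            rows.append(
                {
                    "drug_name": r.drug_name,
                    "age_label": r.age_label,
                    "stored_percent_error": r.paper_percent_error,
                    "recomputed_percent_error": recomputed,
                    "difference": diff,
                }
            )
    return rows


def format_summary_table(summaries: Sequence[EvaluationSummary]) -> str:
    """Aligned text table of bin counts, one column per class."""
    header = f"{'Description':<22}" + "".join(
        f"{s.class_or_overall:>16}" for s in summaries
    )
    lines = [header]
    lines.append(
        f"{'# of observations':<22}"
        + "".join(f"{s.n_observations:>16d}" for s in summaries)
    )
    for attr, label in [
        ("n_within_30", "<=30% PE"),
        ("n_within_50", "<=50% PE"),
        ("n_over_50", ">50% PE"),
    ]:
        row = f"{label:<22}"
        for s in summaries:
            n = getattr(s, attr)
            pct = 100.0 * n / s.n_observations
            row += f"{n:>9d} ({pct:3.0f}%)"
        lines.append(row)
    lines.append(
        f"{'abs error range (%)':<22}"
        + "".join(
            f"{s.min_abs_error:>7.0f}–{s.max_abs_error:<7.0f}" for s in summaries
        )
    )
    return "\n".join(lines)
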