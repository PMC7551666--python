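"""Weight-for-age reference and age-label parsing.

Published pediatric clearance tables report age groups, not individual
body weights, so predicting from a table row needs two plumbing steps:

* turn an age-group label ("6-12 y", "12.3 months", "<2", "31 days <2",
  "preterm") into a representative age — the arithmetic midpoint of the
  labelled range;
* impute a representative body weight at that age from a packaged
  sex-averaged median weight-for-age table (piecewise-linear
  interpolation, never extrapolated), unless the caller supplies the
  actual weight.

The packaged growth reference has a term stratum (3.4 kg at birth to
70 kg at 18 y) used for all non-neonatal ages, and a short preterm
stratum (1.2-3.0 kg over the first three months).  Callers should supply
real weights whenever they are known; the medians are a stand-in for the
study-specific weights behind published predictions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .core import (
    AGE_MAX_YEARS,
    NEONATAL_AGE_YEARS,
    DomainError,
    MaturityStatus,
)

__all__ = [
    "GrowthReference",
    "AgeLabel",
    "AgeLabelError",
    "ExtrapolationError",
    "load_growth_reference",
    "impute_weight",
    "parse_age_label",
    "format_age_label",
]

MONTHS_PER_YEAR = 12.0
DAYS_PER_YEAR = 365.25


class AgeLabelError(ValueError):
    """An age-group label does not match any documented grammar."""


class ExtrapolationError(ValueError):
    """Requested age lies outside the growth-reference span."""


@dataclass(frozen=True)
class AgeLabel:
    """A parsed age-group label with its representative (midpoint) age."""

    raw_text: str
    lower_age: float
    upper_age: float
    representative_age: float

    def __post_init__(self) -> None:
        if not self.lower_age <= self.representative_age <= self.upper_age:
            raise AgeLabelError(
                f"{self.raw_text!r}: representative age "
                f"{self.representative_age} outside "
                f"[{self.lower_age}, {self.upper_age}]"
            )


class GrowthReference:
    """Median body weight vs age, stratified by gestational maturity."""

    def __init__(self, table: pd.DataFrame):
        required = {"maturity", "age_years", "median_weight_kg"}
        missing = required - set(table.columns)
        if missing:
            raise DomainError(f"growth reference missing columns: {sorted(missing)}")
        self._strata: dict[str, pd.DataFrame] = {}
        self._arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for maturity, group in table.groupby("maturity"):
            group = group.sort_values("age_years").reset_index(drop=True)
            ages = group["age_years"].to_numpy(float)
            weights = group["median_weight_kg"].to_numpy(float)
            if np.any(np.diff(ages) <= 0):
                raise DomainError(f"{maturity}: ages must be strictly increasing")
            if np.any(weights <= 0) or np.any(np.diff(weights) < 0):
                raise DomainError(
                    f"{maturity}: weights must be positive and non-decreasing"
                )
            self._strata[str(maturity)] = group
            self._arrays[str(maturity)] = (ages, weights)

    @staticmethod
    def _key(maturity: MaturityStatus) -> str:
        # everyone past the neonatal window follows the term growth curve
        return "preterm" if maturity is MaturityStatus.PRETERM else "term"

    def stratum(self, maturity: MaturityStatus) -> pd.DataFrame:
        return self._strata[self._key(maturity)]

    def median_weight(self, age: float, maturity: MaturityStatus) -> float:
        ages, weights = self._arrays[self._key(maturity)]
        if not ages[0] <= age <= ages[-1]:
            raise ExtrapolationError(
                f"age {age} y outside the growth-reference span "
                f"[{ages[0]}, {ages[-1]}] for the "
                f"{'preterm' if maturity is MaturityStatus.PRETERM else 'term'} stratum"
            )
        return float(np.interp(age, ages, weights))


def load_growth_reference(path=None) -> GrowthReference:
    """Load the packaged (or a user-supplied) weight-for-age CSV."""
    if path is None:
        source = resources.files("adescale.data") / "growth_reference.csv"
        with resources.as_file(source) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    return GrowthReference(table)


def impute_weight(
    age: float,
    maturity: MaturityStatus = MaturityStatus.NOT_APPLICABLE,
    reference: GrowthReference | None = None,
) -> float:
    """Representative body weight (kg) at an age, by linear interpolation."""
    if reference is None:
        reference = load_growth_reference()
    return reference.median_weight(age, maturity)


# ---------------------------------------------------------------------------
# Age-label grammar
# ---------------------------------------------------------------------------

_NUM = r"(\d+(?:\.\d+)?)"
# en dash, em dash, hyphen, "to"
_SEP = r"\s*(?:[–—-]|to)\s*"
_UNIT = r"\s*(y|yr|yrs|year|years|months?|mo|days?|d)?\s*$"

_RANGE_RE = re.compile(rf"^\s*>?\s*{_NUM}{_SEP}<?\s*{_NUM}{_UNIT}", re.I)
_SINGLE_RE = re.compile(rf"^\s*{_NUM}{_UNIT}", re.I)
_LT_RE = re.compile(rf"^\s*<\s*{_NUM}{_UNIT}", re.I)
_GT_RE = re.compile(rf"^\s*>\s*{_NUM}{_UNIT}", re.I)
_DAYS_RANGE_RE = re.compile(
    rf"^\s*{_NUM}\s*days?\s*<\s*{_NUM}\s*$", re.I
)  # "31 days <2"


def _to_years(value: float, unit: str | None) -> float:
    unit = (unit or "y").lower()
    if unit.startswith(("y",)):
        return value
    if unit.startswith("mo") or unit == "months" or unit.startswith("month"):
        return value / MONTHS_PER_YEAR
    if unit.startswith("d"):
        return value / DAYS_PER_YEAR
    raise AgeLabelError(f"unknown age unit {unit!r}")


def parse_age_label(raw_text: str) -> AgeLabel:
    """Parse an age-group label into bounds and a midpoint age (years).

    Grammars: a single age ("2.9", "7 years", "12.3 months"), a range
    with optional open bounds (">5-<12 year", "2-<5", "11-31 months"),
    an upper bound ("<2", "<30 days": lower bound 0), a lower bound
    (">12": upper bound 18), "31 days <2", and neonatal maturity labels
    containing "preterm" or "term" (mapped to the 0-0.25 y window).
    """
    text = raw_text.strip()
    if not text:
        raise AgeLabelError("empty age label")

    lowered = text.lower()
    if "preterm" in lowered or "term" in lowered:
        lo, hi = 0.0, NEONATAL_AGE_YEARS
        return AgeLabel(raw_text, lo, hi, (lo + hi) / 2.0)

    m = _DAYS_RANGE_RE.match(text)
    if m:
        lo = float(m.group(1)) / DAYS_PER_YEAR
        hi = float(m.group(2))
        return AgeLabel(raw_text, lo, hi, (lo + hi) / 2.0)

    m = _RANGE_RE.match(text)
    if m:
        lo = _to_years(float(m.group(1)), m.group(3))
        hi = _to_years(float(m.group(2)), m.group(3))
        if not lo < hi:
            raise AgeLabelError(f"{raw_text!r}: bounds not increasing")
        return AgeLabel(raw_text, lo, hi, (lo + hi) / 2.0)

    m = _LT_RE.match(text)
    if m:
        hi = _to_years(float(m.group(1)), m.group(2))
        return AgeLabel(raw_text, 0.0, hi, hi / 2.0)

    m = _GT_RE.match(text)
    if m:
        lo = _to_years(float(m.group(1)), m.group(2))
        hi = AGE_MAX_YEARS
        return AgeLabel(raw_text, lo, hi, (lo + hi) / 2.0)

    m = _SINGLE_RE.match(text)
    if m:
        age = _to_years(float(m.group(1)), m.group(2))
        return AgeLabel(raw_text, age, age, age)

    raise AgeLabelError(f"unparseable age label: {raw_text!r}")


def format_age_label(label: AgeLabel) -> str:
    """Canonical text for a parsed label; re-parsing preserves the bounds."""
    if label.lower_age == label.upper_age:
        return f"{label.lower_age:.12g} y"
    return f"{label.lower_age:.12g}–{label.upper_age:.12g} y"
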