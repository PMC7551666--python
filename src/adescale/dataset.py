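"""Packaged clearance-observation dataset and CSV readers/writers.

Ships 75 published pediatric clearance observations across 29
therapeutic proteins — 13 monoclonal antibodies (33 observations),
7 polyclonal antibody preparations (21), and 9 non-antibody proteins
(21) — each carrying the drug's mean adult clearance, the pediatric age
group, the observed pediatric clearance, the prediction published
alongside it, and the published percent error.  Clearance units differ
by drug (mL/h, mL/day, L/h, mL/min) and are preserved verbatim.

User datasets in the same CSV schema round-trip through
:func:`read_dataset` / :func:`write_dataset`; unknown columns survive.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Iterable, Optional

import pandas as pd

from .core import DomainError, MaturityStatus

__all__ = [
    "ObservationRecord",
    "FixtureManifest",
    "FixtureError",
    "SchemaError",
    "DRUG_CLASSES",
    "REQUIRED_COLUMNS",
    "load_paper_fixtures",
    "load_manifest",
    "validate_fixtures",
    "read_dataset",
    "write_dataset",
    "records_to_frame",
]

DRUG_CLASSES = ("monoclonal", "polyclonal", "non_antibody")

REQUIRED_COLUMNS = (
    "drug_name",
    "drug_class",
    "adult_clearance",
    "clearance_units",
    "age_label",
    "maturity",
    "observed_clearance",
    "paper_predicted_clearance",
    "paper_percent_error",
)

OPTIONAL_COLUMNS = ("series", "indication", "route", "weight_kg", "exponent_override")

#: Recomputing the percent error from printed observed/predicted cells may
#: differ from the printed error column because published tables round the
#: clearances; this is the slack allowed before a row is flagged corrupt.
PRINTED_ERROR_TOLERANCE_PCT = 5.0


class FixtureError(RuntimeError):
    """Packaged fixtures fail their manifest or integrity checks."""


class SchemaError(ValueError):
    """A dataset file lacks required columns or contains invalid values."""


@dataclass(frozen=True)
class ObservationRecord:
    """One published observation: a drug, an age group, and clearances."""

    drug_name: str
    drug_class: str
    adult_clearance: float
    clearance_units: str
    age_label: str
    maturity: MaturityStatus
    observed_clearance: float
    paper_predicted_clearance: float
    paper_percent_error: float
    series: str = ""
    indication: str = ""
    route: str = "IV"
    weight_kg: Optional[float] = None
    exponent_override: Optional[float] = None
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.drug_class not in DRUG_CLASSES:
            raise SchemaError(
                f"{self.drug_name}: unknown drug class {self.drug_class!r}"
            )


@dataclass(frozen=True)
class FixtureManifest:
    total_records: int
    records_per_class: dict
    drugs_per_class: dict

    def __post_init__(self) -> None:
        if self.total_records != sum(self.records_per_class.values()):
            raise FixtureError("manifest totals do not sum")


def _maturity(value) -> MaturityStatus:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return MaturityStatus.NOT_APPLICABLE
    return MaturityStatus.from_string(str(value))


def _optional_float(value) -> Optional[float]:
    if value is None or value == "" or (isinstance(value, float) and pd.isna(value)):
        return None
    return float(value)


def _frame_to_records(frame: pd.DataFrame) -> list[ObservationRecord]:
    missing = set(REQUIRED_COLUMNS) - set(frame.columns)
    if missing:
        raise SchemaError(f"dataset missing required columns: {sorted(missing)}")
    known = set(REQUIRED_COLUMNS) | set(OPTIONAL_COLUMNS)
    extra_cols = [c for c in frame.columns if c not in known]
    records = []
    for _, row in frame.iterrows():
        records.append(
            ObservationRecord(
                drug_name=str(row["drug_name"]),
                drug_class=str(row["drug_class"]),
                adult_clearance=float(row["adult_clearance"]),
                clearance_units=str(row["clearance_units"]),
                # published tables use the Unicode minus; normalize to ASCII
                age_label=str(row["age_label"]).replace("−", "-"),
                maturity=_maturity(row.get("maturity")),
                observed_clearance=float(row["observed_clearance"]),
                paper_predicted_clearance=float(row["paper_predicted_clearance"]),
                paper_percent_error=float(
                    str(row["paper_percent_error"]).replace("−", "-")
                ),
                series="" if pd.isna(row.get("series", "")) else str(row.get("series", "")),
                indication="" if pd.isna(row.get("indication", "")) else str(row.get("indication", "")),
                route="IV" if pd.isna(row.get("route", "IV")) else str(row.get("route", "IV")),
                weight_kg=_optional_float(row.get("weight_kg")),
                exponent_override=_optional_float(row.get("exponent_override")),
                extra={c: row[c] for c in extra_cols},
            )
        )
    return records


def records_to_frame(records: Iterable[ObservationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = asdict(r)
        extra = d.pop("extra")
        d["maturity"] = r.maturity.value
        d.update(extra)
        rows.append(d)
    return pd.DataFrame(rows)


def load_manifest() -> dict:
    source = resources.files("adescale.data") / "manifest.json"
    return json.loads(source.read_text(encoding="utf-8"))


def load_paper_fixtures(verify: bool = True) -> list[ObservationRecord]:
    """Load the packaged 75-observation dataset, validated against its manifest.

    Raises :class:`FixtureError` if the packaged CSV's checksum or counts
    disagree with the manifest (a corrupted installation).
    """
    source = resources.files("adescale.data") / "observations.csv"
    raw = source.read_bytes()
    manifest = load_manifest()
    if verify:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != manifest["sha256"]:
            raise FixtureError(
                "packaged observations.csv checksum mismatch: "
                f"{digest} != {manifest['sha256']}"
            )
    import io

    frame = pd.read_csv(io.BytesIO(raw))
    records = _frame_to_records(frame)
    if verify:
        validate_fixtures(records, expected=manifest)
    return records


def validate_fixtures(
    records: list[ObservationRecord], expected: Optional[dict] = None
) -> FixtureManifest:
    """Check counts, positivity and internal consistency of a record list.

    Besides class counts, each row's percent error is recomputed from its
    observed/predicted clearances and compared with the stored error
    column within ±5 percentage points (printed clearances are rounded,
    so exact agreement is not expected).
    """
    if not records:
        raise FixtureError("empty record list")
    per_class = {c: 0 for c in DRUG_CLASSES}
    drugs: dict[str, set] = {c: set() for c in DRUG_CLASSES}
    for i, r in enumerate(records):
        label = f"row {i} ({r.drug_name}, {r.age_label!r})"
        if not r.observed_clearance > 0:
            raise FixtureError(f"{label}: observed clearance must be positive")
        if not r.paper_predicted_clearance > 0:
            raise FixtureError(f"{label}: predicted clearance must be positive")
        if not r.adult_clearance > 0:
            raise FixtureError(f"{label}: adult clearance must be positive")
        recomputed = (
            (r.paper_predicted_clearance - r.observed_clearance)
            * 100.0
            / r.observed_clearance
        )
        if abs(recomputed - r.paper_percent_error) > PRINTED_ERROR_TOLERANCE_PCT:
            raise FixtureError(
                f"{label}: recomputed percent error {recomputed:.1f} differs "
                f"from stored {r.paper_percent_error:.1f} by more than "
                f"{PRINTED_ERROR_TOLERANCE_PCT} points"
            )
        per_class[r.drug_class] += 1
        drugs[r.drug_class].add(r.drug_name)
    manifest = FixtureManifest(
        total_records=len(records),
        records_per_class=per_class,
        drugs_per_class={c: len(drugs[c]) for c in DRUG_CLASSES},
    )
    if expected is not None:
        if manifest.total_records != expected["total_records"]:
            raise FixtureError(
                f"expected {expected['total_records']} records, "
                f"got {manifest.total_records}"
            )
        if manifest.records_per_class != expected["records_per_class"]:
            raise FixtureError(
                f"per-class record counts {manifest.records_per_class} != "
                f"manifest {expected['records_per_class']}"
            )
        if manifest.drugs_per_class != expected["drugs_per_class"]:
            raise FixtureError(
                f"per-class drug counts {manifest.drugs_per_class} != "
                f"manifest {expected['drugs_per_class']}"
            )
    return manifest


def read_dataset(path) -> list[ObservationRecord]:
    """Read a dataset CSV in the observation schema (extra columns kept)."""
    return _frame_to_records(pd.read_csv(path))


def write_dataset(records: Iterable[ObservationRecord], path) -> None:
    """Write records as CSV; reading the file back restores equal records."""
    records_to_frame(records).to_csv(path, index=False)
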