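"""Relational registry tables and their on-disk representation.

The package works with four relational tables mirroring the common core of
longitudinal MS registries (EDMUS/MSBase-style extracts):

``patients``
    one row per patient: ``patient_id, sex, birth_year, onset_date, country,
    source``.
``visits``
    one row per EDSS assessment: ``patient_id, date, edss``.
``relapses``
    one row per relapse onset: ``patient_id, date``.
``treatments``
    one row per disease-modifying-therapy episode: ``patient_id, drug,
    start_date, end_date`` (``end_date`` empty while ongoing).

Internally every date is an integer day offset from a nominal origin — the
day the more recently licensed study drug became available (2011-01-01 for
the fingolimod/natalizumab pair), so that day arithmetic is exact and
deterministic.  Calendar formatting (ISO-8601) happens only at I/O.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

#: Calendar date corresponding to internal day 0 (control-drug availability).
ORIGIN = _dt.date(2011, 1, 1)

#: Decimal year of the origin, used when converting day offsets to ages.
ORIGIN_YEAR = ORIGIN.year

TREATED_DRUG = "natalizumab"
CONTROL_DRUG = "fingolimod"
STUDY_DRUGS = (TREATED_DRUG, CONTROL_DRUG)

#: Therapies with an extended duration of effect (or off-label use) whose
#: prior exposure disqualifies a patient.
EXCLUDED_DRUGS = frozenset(
    {
        "mitoxantrone",
        "alemtuzumab",
        "cladribine",
        "daclizumab",
        "rituximab",
        "ocrelizumab",
        "cyclophosphamide",
    }
)

_TABLE_COLUMNS = {
    "patients": ["patient_id", "sex", "birth_year", "onset_date", "country", "source"],
    "visits": ["patient_id", "date", "edss"],
    "relapses": ["patient_id", "date"],
    "treatments": ["patient_id", "drug", "start_date", "end_date"],
}

_DATE_COLUMNS = {
    "patients": ["onset_date"],
    "visits": ["date"],
    "relapses": ["date"],
    "treatments": ["start_date", "end_date"],
}


def day_to_date(day: float) -> _dt.date:
    return ORIGIN + _dt.timedelta(days=int(day))


def date_to_day(date: _dt.date | str) -> int:
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    return (date - ORIGIN).days


@dataclass
class RegistryTables:
    """The four relational tables plus provenance metadata.

    Dates in the in-memory frames are integer day offsets from :data:`ORIGIN`
    (``end_date`` may be NaN for ongoing episodes).
    """

    patients: pd.DataFrame
    visits: pd.DataFrame
    relapses: pd.DataFrame
    treatments: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        """Check column contracts and referential integrity."""
        for name, cols in _TABLE_COLUMNS.items():
            frame = getattr(self, name)
            missing = set(cols) - set(frame.columns)
            if missing:
                raise ValueError(f"table {name!r} is missing columns {sorted(missing)}")
        ids = set(self.patients["patient_id"])
        if len(ids) != len(self.patients):
            raise ValueError("duplicate patient_id in patients table")
        for name in ("visits", "relapses", "treatments"):
            frame = getattr(self, name)
            orphans = set(frame["patient_id"]) - ids
            if orphans:
                raise ValueError(
                    f"table {name!r} references unknown patients: {sorted(orphans)[:5]}"
                )

    def write(self, out_dir: str | Path) -> None:
        """Write the four tables as CSV with ISO-8601 dates."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in _TABLE_COLUMNS:
            frame = getattr(self, name).copy()
            for col in _DATE_COLUMNS[name]:
                frame[col] = [
                    "" if pd.isna(v) else day_to_date(v).isoformat() for v in frame[col]
                ]
            frame.to_csv(out / f"{name}.csv", index=False)

    @classmethod
    def read(cls, in_dir: str | Path) -> "RegistryTables":
        """Read the four CSV tables, converting ISO dates to day offsets."""
        src = Path(in_dir)
        frames = {}
        for name in _TABLE_COLUMNS:
            frame = pd.read_csv(src / f"{name}.csv")
            for col in _DATE_COLUMNS[name]:
                frame[col] = [
                    float("nan") if (pd.isna(v) or v == "") else float(date_to_day(str(v)))
                    for v in frame[col]
                ]
            frames[name] = frame
        tables = cls(**frames)
        tables.validate()
        return tables

    def last_record_day(self) -> pd.Series:
        """Per-patient day of the last data entry across all tables."""
        pieces = [
            self.visits.groupby("patient_id")["date"].max(),
            self.relapses.groupby("patient_id")["date"].max(),
            self.treatments.groupby("patient_id")["start_date"].max(),
            self.treatments.groupby("patient_id")["end_date"].max(),
        ]
        out = pd.concat(pieces, axis=1).max(axis=1)
        out.name = "last_record"
        return out
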