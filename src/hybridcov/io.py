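"""CSV readers and writers for districts, survey responses and estimates.

Conventions: comma-separated UTF-8 with a header row; empty string means
missing; numbers are serialized at full double precision (shortest
round-trip repr) so read/write round trips are lossless.  Tally columns
are named ``tally_<indicator>``.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .types import (
    DistrictRecord,
    EstimateRow,
    SchemaError,
    SurveyResponse,
    ValidationError,
)

logger = logging.getLogger("hybridcov")

DISTRICT_REQUIRED = ("district_id", "census_population", "prior_tally", "surveyed")
SURVEY_COLUMNS = ("district_id", "sa_id", "indicator", "response")
ESTIMATE_COLUMNS = (
    "district_id",
    "indicator",
    "method",
    "point",
    "variance",
    "low95",
    "high95",
    "capped",
    "denominator",
    "denominator_variance",
    "denominator_source",
)

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def _parse_bool(value, row: int) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ValidationError(f"row {row}: cannot parse surveyed flag {value!r}")


def _opt_count(value, column: str, row: int) -> Optional[int]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    number = float(value)
    if number < 0:
        raise ValidationError(f"row {row}: {column} is negative ({value})")
    return int(round(number))


def read_districts(
    path: str | Path, indicators: Optional[Sequence[str]] = None
) -> list[DistrictRecord]:
    """Read the district-level administrative table.

    Required columns: ``district_id``, ``census_population``,
    ``prior_tally``, ``surveyed`` and one ``tally_<indicator>`` column per
    indicator.  Unknown columns are preserved in ``DistrictRecord.extra``
    and are available as extra regression covariates.
    """
    df = pd.read_csv(path, dtype={"district_id": str}, keep_default_na=True)
    for column in DISTRICT_REQUIRED:
        if column not in df.columns:
            raise SchemaError(f"districts file {path}: missing required column {column!r}")
    tally_columns = [c for c in df.columns if c.startswith("tally_")]
    if indicators is not None:
        missing = [i for i in indicators if f"tally_{i}" not in df.columns]
        if missing:
            raise SchemaError(
                f"districts file {path}: missing tally columns for indicators {missing}"
            )
        tally_columns = [f"tally_{i}" for i in indicators]
    extra_columns = [
        c
        for c in df.columns
        if c not in DISTRICT_REQUIRED and c not in tally_columns and c != "department"
    ]

    records: list[DistrictRecord] = []
    seen: set[str] = set()
    for position, row in enumerate(df.itertuples(index=False), start=2):
        data = row._asdict()
        district_id = str(data["district_id"])
        if district_id in seen:
            raise ValidationError(f"row {position}: duplicate district_id {district_id!r}")
        seen.add(district_id)
        tallies = {}
        for column in tally_columns:
            value = _opt_count(data[column], column, position)
            if value is None:
                raise ValidationError(f"row {position}: missing tally in column {column!r}")
            tallies[column[len("tally_"):]] = value
        department = data.get("department")
        if department is not None and (isinstance(department, float) and math.isnan(department)):
            department = None
        records.append(
            DistrictRecord(
                district_id=district_id,
                census_population=_opt_count(data["census_population"], "census_population", position),
                prior_tally=_opt_count(data["prior_tally"], "prior_tally", position),
                tallies=tallies,
                surveyed=_parse_bool(data["surveyed"], position),
                department=None if department is None else str(department),
                extra={
                    c: float(data[c])
                    for c in extra_columns
                    if data[c] is not None and not (isinstance(data[c], float) and math.isnan(data[c]))
                },
            )
        )
    logger.info("read %d districts from %s (%d surveyed)", len(records), path,
                sum(r.surveyed for r in records))
    return records


def write_districts(records: Iterable[DistrictRecord], path: str | Path) -> None:
    records = list(records)
    indicator_names: list[str] = []
    for record in records:
        for name in record.tallies:
            if name not in indicator_names:
                indicator_names.append(name)
    extra_names: list[str] = []
    for record in records:
        for name in record.extra:
            if name not in extra_names:
                extra_names.append(name)
    rows = []
    for record in records:
        row = {
            "district_id": record.district_id,
            "department": record.department,
            "census_population": record.census_population,
            "prior_tally": record.prior_tally,
        }
        for name in indicator_names:
            row[f"tally_{name}"] = record.tallies.get(name)
        row["surveyed"] = record.surveyed
        for name in extra_names:
            row[name] = record.extra.get(name)
        rows.append(row)
    columns = (
        ["district_id", "department", "census_population", "prior_tally"]
        + [f"tally_{n}" for n in indicator_names]
        + ["surveyed"]
        + extra_names
    )
    frame = pd.DataFrame(rows, columns=columns)
    # Integer columns with missing values would otherwise serialize as floats.
    for column in ("census_population", "prior_tally"):
        frame[column] = frame[column].astype("Int64")
    frame.to_csv(path, index=False)


def read_survey(path: str | Path) -> list[SurveyResponse]:
    """Read the child-level survey table."""
    df = pd.read_csv(path, dtype={"district_id": str, "sa_id": str, "indicator": str})
    for column in SURVEY_COLUMNS:
        if column not in df.columns:
            raise SchemaError(f"survey file {path}: missing required column {column!r}")
    responses = []
    for position, row in enumerate(df.itertuples(index=False), start=2):
        value = row.response
        if value not in (0, 1):
            raise ValidationError(f"row {position}: response must be 0 or 1, got {value!r}")
        responses.append(
            SurveyResponse(
                district_id=str(row.district_id),
                sa_id=str(row.sa_id),
                indicator=str(row.indicator),
                response=int(value),
            )
        )
    logger.info("read %d survey responses from %s", len(responses), path)
    return responses


def write_survey(responses: Iterable[SurveyResponse], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "district_id": r.district_id,
                "sa_id": r.sa_id,
                "indicator": r.indicator,
                "response": r.response,
            }
            for r in responses
        ],
        columns=list(SURVEY_COLUMNS),
    )
    frame.to_csv(path, index=False)


def write_estimates(rows: Iterable[EstimateRow], path: str | Path) -> None:
    """Write per-district estimate rows (one per district x indicator x method)."""
    frame = pd.DataFrame(
        [
            {
                "district_id": r.district_id,
                "indicator": r.indicator,
                "method": r.method,
                "point": r.point,
                "variance": r.variance,
                "low95": r.low95,
                "high95": r.high95,
                "capped": r.capped,
                "denominator": r.denominator,
                "denominator_variance": r.denominator_variance,
                "denominator_source": r.denominator_source,
            }
            for r in rows
        ],
        columns=list(ESTIMATE_COLUMNS),
    )
    frame.to_csv(path, index=False)
    logger.info("wrote %d estimate rows to %s", len(frame), path)


def read_estimates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"district_id": str, "indicator": str, "method": str})
    for column in ESTIMATE_COLUMNS:
        if column not in df.columns:
            raise SchemaError(f"estimates file {path}: missing required column {column!r}")
    return df
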