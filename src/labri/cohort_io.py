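"""Read, validate, filter, segment and join long-format laboratory result tables.

A *result table* is a :class:`pandas.DataFrame` in long format with one row per
lab result and the canonical columns ``person_id``, ``gender``, ``age``,
``analyte``, ``value``, ``date`` (plus an optional ``unit`` column, which is
carried through untouched).  Analytes are identified by their LOINC code;
serum creatinine is ``2160-0`` and blood urea nitrogen ``3094-0``.  Values
are concentrations in mg/dl.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: LOINC code for serum creatinine.
LOINC_CREATININE = "2160-0"
#: LOINC code for blood urea nitrogen (urea).
LOINC_UREA = "3094-0"

#: Upper plausibility thresholds in mg/dl.  Readings above these almost
#: certainly reflect unit or data-entry errors rather than physiology.
DEFAULT_THRESHOLDS: dict[str, float] = {LOINC_CREATININE: 25.0, LOINC_UREA: 150.0}

#: Canonical column names of a result table.
RESULT_COLUMNS = ("person_id", "gender", "age", "analyte", "value", "date")

#: Minimum segment size for a reliable estimate; mirrors the sample-size
#: convention for directly established reference intervals (>= 120 persons).
DEFAULT_MIN_N = 120

_GENDER_ALIASES = {"male": "male", "m": "male", "female": "female", "f": "female"}


@dataclass
class ReadReport:
    """Bookkeeping for rows dropped during reading/validation."""

    n_read: int = 0
    n_kept: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["n_dropped"] = self.n_dropped
        return json.dumps(payload, indent=2)

    def _drop(self, reason: str, count: int) -> None:
        if count:
            self.dropped[reason] = self.dropped.get(reason, 0) + int(count)


class SegmentKey(NamedTuple):
    """Identifier of a gender/age population segment (age is the bin label)."""

    gender: str
    age: int


@dataclass
class Segmentation:
    """Partition of a single-analyte table into gender/age segments.

    ``segments`` maps every observed :class:`SegmentKey` to its value array;
    keys listed in ``unreliable`` hold fewer than ``min_n`` values and should
    be excluded from estimation (they stay in the map for reporting).
    """

    segments: dict[SegmentKey, np.ndarray]
    unreliable: list[SegmentKey]
    bin_width: int
    min_n: int

    def reliable_items(self):
        bad = set(self.unreliable)
        return ((k, v) for k, v in self.segments.items() if k not in bad)

    @property
    def n_total(self) -> int:
        return int(sum(v.size for v in self.segments.values()))


def read_results(
    path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, ReadReport]:
    """Read a CSV of lab results into a validated result table.

    Parameters
    ----------
    path
        CSV file with a header row; dates ISO-8601.
    column_map
        Maps canonical names (``person_id`` ...) to the file's column names.
        Identity by default.

    Returns
    -------
    (table, report)
        Validated table with canonical columns, and a :class:`ReadReport`
        counting rows dropped per reason.  Rows with missing or unparseable
        fields and unknown gender codes are dropped, never guessed.
    """
    colmap = {c: c for c in RESULT_COLUMNS}
    if column_map:
        colmap.update(column_map)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [v for v in colmap.values() if v not in raw.columns]
    if missing:
        raise ValueError(f"missing required columns in {path!r}: {missing}")

    df = pd.DataFrame({canon: raw[src] for canon, src in colmap.items()})
    if "unit" in raw.columns and "unit" not in df.columns:
        df["unit"] = raw["unit"]
    report = ReadReport(n_read=len(df))

    gender = df["gender"].str.strip().str.lower().map(_GENDER_ALIASES)
    bad_gender = gender.isna()
    if bad_gender.any():
        logger.warning("dropping %d rows with unknown gender codes", bad_gender.sum())
    report._drop("unknown_gender", bad_gender.sum())

    age = pd.to_numeric(df["age"], errors="coerce")
    bad_age = age.isna() | (age < 0) | (age != age.round())
    report._drop("invalid_age", (bad_age & ~bad_gender).sum())

    value = pd.to_numeric(df["value"], errors="coerce")
    bad_value = ~np.isfinite(value)
    report._drop("invalid_value", (bad_value & ~bad_gender & ~bad_age).sum())

    date = pd.to_datetime(df["date"], errors="coerce", format="ISO8601")
    bad_date = date.isna()
    report._drop("invalid_date", (bad_date & ~bad_gender & ~bad_age & ~bad_value).sum())

    bad_key = (df["person_id"].str.len() == 0) | (df["analyte"].str.len() == 0)
    report._drop(
        "missing_id_or_analyte",
        (bad_key & ~bad_gender & ~bad_age & ~bad_value & ~bad_date).sum(),
    )

    keep = ~(bad_gender | bad_age | bad_value | bad_date | bad_key)
    out = df.loc[keep].copy()
    out["gender"] = gender[keep]
    out["age"] = age[keep].astype(int)
    out["value"] = value[keep]
    out["date"] = date[keep].dt.date.astype(str)
    out = out.reset_index(drop=True)
    report.n_kept = len(out)
    return out, report


def write_results(table: pd.DataFrame, path) -> None:
    """Write a result table as CSV, values to 6 significant digits."""
    table.to_csv(path, index=False, float_format="%.6g")


def filter_plausible(
    table: pd.DataFrame,
    thresholds: Mapping[str, float] | None = None,
    on_missing: str = "retain",
) -> tuple[pd.DataFrame, int]:
    """Remove physically implausible readings.

    A reading is retained when ``0 < value <= threshold(analyte)``; the upper
    boundary is inclusive.  Non-positive values are always removed —
    concentrations are physically positive.  Analytes without a configured
    threshold are retained (``on_missing="retain"``, with a warning) or
    dropped (``on_missing="drop"``).

    Returns the filtered table and the number of rows removed.
    """
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS
    if on_missing not in ("retain", "drop"):
        raise ValueError("on_missing must be 'retain' or 'drop'")
    if any(t <= 0 for t in thresholds.values()):
        raise ValueError("thresholds must be positive")
    if table.empty:
        return table.copy(), 0

    value = table["value"].to_numpy(float)
    keep = value > 0
    limit = table["analyte"].map(thresholds)
    known = limit.notna().to_numpy()
    if not known.all():
        unknown = sorted(table.loc[~known, "analyte"].unique())
        if on_missing == "retain":
            logger.warning("no plausibility threshold for analytes %s; retaining", unknown)
        else:
            keep &= known
    keep[known] &= value[known] <= limit.to_numpy(float)[known]
    out = table.loc[keep].reset_index(drop=True)
    return out, int(len(table) - len(out))


def segment_by_gender_age(
    table: pd.DataFrame,
    bin_width: int = 1,
    min_n: int = DEFAULT_MIN_N,
) -> Segmentation:
    """Partition a single-analyte table into gender/age-bin value arrays.

    Every retained value lands in exactly one segment.  With the default
    1-year bins the segment label is the integer age itself; wider bins are
    labelled by their lower edge.  Segments with fewer than ``min_n`` values
    are flagged unreliable but kept for reporting.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    if "analyte" in table.columns and table["analyte"].nunique() > 1:
        raise ValueError(
            "segment_by_gender_age expects a single-analyte table; "
            "split by analyte first"
        )
    segments: dict[SegmentKey, np.ndarray] = {}
    unreliable: list[SegmentKey] = []
    if not table.empty:
        bins = (table["age"].to_numpy(int) // bin_width) * bin_width
        for (gender, age_bin), grp in table.groupby([table["gender"], bins], sort=True):
            key = SegmentKey(str(gender), int(age_bin))
            values = grp["value"].to_numpy(float)
            segments[key] = values
            if values.size < min_n:
                unreliable.append(key)
    return Segmentation(segments=segments, unreliable=unreliable, bin_width=bin_width, min_n=min_n)


def join_analytes(
    a: pd.DataFrame,
    b: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Join two single-analyte tables on (person_id, date) into joint records.

    Returns a wide table with one row per (person, date) present in *both*
    inputs, carrying one value column per LOINC code, plus a report with the
    counts of unmatched and duplicate rows.  Duplicate (person, date) rows
    within one input keep the first occurrence by file order.
    """
    report: dict[str, int] = {}
    frames = []
    codes = []
    for name, t in (("a", a), ("b", b)):
        analytes = t["analyte"].unique()
        if len(analytes) != 1:
            raise ValueError(f"table {name} must carry exactly one analyte, got {list(analytes)}")
        code = str(analytes[0])
        codes.append(code)
        dup = t.duplicated(subset=["person_id", "date"])
        report[f"duplicates_{code}"] = int(dup.sum())
        if dup.any():
            logger.info("join: dropping %d duplicate same-day rows for %s", dup.sum(), code)
        frames.append(t.loc[~dup, ["person_id", "gender", "age", "date", "value"]])
    if codes[0] == codes[1]:
        raise ValueError("tables must carry distinct analytes")

    left, right = frames
    joint = left.merge(
        right[["person_id", "date", "value"]],
        on=["person_id", "date"],
        how="inner",
        suffixes=("_a", "_b"),
    )
    joint = joint.rename(columns={"value_a": codes[0], "value_b": codes[1]})
    report[f"unmatched_{codes[0]}"] = int(len(left) - len(joint))
    report[f"unmatched_{codes[1]}"] = int(len(right) - len(joint))
    joint = joint[["person_id", "gender", "age", "date", codes[0], codes[1]]]
    return joint.reset_index(drop=True), report


def split_by_analyte(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split a long-format table into per-analyte tables (file order kept)."""
    return {
        str(code): grp.reset_index(drop=True)
        for code, grp in table.groupby("analyte", sort=True)
    }
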