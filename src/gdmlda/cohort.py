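"""Cohort data model, CSV I/O and validation.

The canonical representation is a *long-format* table with one row per
subject x prenatal visit: visit 1 is the first trimester (gestational age
<= 12 weeks), visit 2 the early second trimester (weeks 16-20).  Each row
carries the four repeated CBC biomarkers -- hemoglobin (``hb``, g/dL),
hematocrit (``hct``, %), fasting blood sugar (``fbs``, mg/dL) and red blood
cell count (``rbc``, x10^12/L) -- plus the clinical covariates used in the
longitudinal model (age, visit-specific BMI/SBP/DBP) and two descriptive
categoricals (parity, education).

Group coding follows the convention of the screening literature this
package targets: ``group = 1`` is non-GDM (population 1), ``group = 2`` is
GDM (population 2).  The discriminant allocation rule indexes populations
by this coding, so it is fixed here rather than configurable; arbitrary
labels in input files are mapped through a column/value map at read time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: the four repeated biomarkers, in canonical order (fixes stacking order
#: everywhere downstream: visits nested within biomarker, biomarkers in
#: this sequence).
BIOMARKERS: tuple[str, ...] = ("hb", "hct", "fbs", "rbc")

#: units, for reports
BIOMARKER_UNITS: dict[str, str] = {
    "hb": "g/dL",
    "hct": "%",
    "fbs": "mg/dL",
    "rbc": "x10^12/L",
}

VISITS: tuple[int, int] = (1, 2)

NON_GDM: int = 1
GDM: int = 2

#: continuous covariates (age is time-stationary; bmi/sbp/dbp vary by visit
#: and are stored per row)
COVARIATES: tuple[str, ...] = ("age", "bmi", "sbp", "dbp")
CATEGORICALS: tuple[str, ...] = ("parity", "education")

EDUCATION_LEVELS: tuple[str, str] = ("non-academic", "academic")

#: fixed on-disk column order (documented contract of :func:`write_cohort`)
COLUMNS: tuple[str, ...] = (
    "subject_id",
    "visit",
    "group",
    *BIOMARKERS,
    *COVARIATES,
    *CATEGORICALS,
)

_NUMERIC_COLUMNS = ("visit", "group", *BIOMARKERS, *COVARIATES, "parity")


class SchemaError(ValueError):
    """A required column is missing or unparseable."""


class CohortValidationError(ValueError):
    """The table violates a cohort invariant; ``.report`` lists all issues."""

    def __init__(self, report: list[str]):
        self.report = report
        super().__init__(
            "invalid cohort table:\n" + "\n".join(f"  - {r}" for r in report)
        )


@dataclass
class CohortTable:
    """Validated long-format cohort: one row per subject x visit.

    Construct through :meth:`from_dataframe` or :func:`read_cohort`; the
    raw constructor performs no checks.
    """

    data: pd.DataFrame

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        column_map: Mapping[str, str] | None = None,
        *,
        validate: bool = True,
        drop_incomplete: bool = False,
    ) -> "CohortTable":
        """Build a cohort from an arbitrary long-format frame.

        Parameters
        ----------
        df : DataFrame
            Long-format data, one row per subject x visit.
        column_map : mapping, optional
            Map from the frame's column names to the canonical names in
            :data:`COLUMNS` (e.g. ``{"id": "subject_id"}``).
        validate : bool
            Raise :class:`CohortValidationError` when invariants fail.
        drop_incomplete : bool
            Drop subjects without both visits (complete-case policy); the
            number of dropped subjects is logged.
        """
        df = df.copy()
        if column_map:
            df = df.rename(columns=dict(column_map))
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        df = df.loc[:, list(COLUMNS)]
        for col in _NUMERIC_COLUMNS:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                idx = df.index[bad][0]
                raise SchemaError(
                    f"non-numeric value in column '{col}' at row index {idx!r}: "
                    f"{df.loc[idx, col]!r}"
                )
            df[col] = coerced
        df["education"] = df["education"].astype(str)
        df = df.sort_values(["subject_id", "visit"], kind="mergesort")
        df = df.reset_index(drop=True)
        if drop_incomplete:
            counts = df.groupby("subject_id")["visit"].agg(
                lambda v: set(v) == set(VISITS)
            )
            keep = counts[counts].index
            n_dropped = counts.size - keep.size
            if n_dropped:
                logger.warning(
                    "dropped %d subject(s) without both visits (complete-case)",
                    n_dropped,
                )
            df = df[df["subject_id"].isin(keep)].reset_index(drop=True)
        table = cls(df)
        if validate:
            report = validate_cohort(table)
            if report:
                raise CohortValidationError(report)
        return table

    # -- convenience accessors -------------------------------------------

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    @property
    def subject_ids(self) -> np.ndarray:
        """Subject ids in canonical (sorted) order."""
        return self.data["subject_id"].unique()

    def subject_groups(self) -> pd.Series:
        """Group label per subject (index = subject_id)."""
        return self.data.groupby("subject_id", sort=True)["group"].first()

    def group_counts(self) -> dict[int, int]:
        g = self.subject_groups()
        return {int(k): int(v) for k, v in g.value_counts().items()}

    def subset(self, subject_ids: Iterable) -> "CohortTable":
        ids = set(subject_ids)
        df = self.data[self.data["subject_id"].isin(ids)].reset_index(drop=True)
        return CohortTable(df)

    def __eq__(self, other) -> bool:  # value semantics, used by round-trip tests
        if not isinstance(other, CohortTable):
            return NotImplemented
        return self.data.equals(other.data)


def validate_cohort(table: CohortTable) -> list[str]:
    """Check all cohort invariants; return a report (empty = valid).

    Total: never raises on arbitrary well-typed input -- every problem
    becomes a report entry.
    """
    report: list[str] = []
    df = table.data
    if df.empty:
        return report

    bad_visit = df.loc[~df["visit"].isin(VISITS), "subject_id"].unique()
    if bad_visit.size:
        report.append(f"visit outside {{1,2}} for subject(s): {list(bad_visit)}")

    bad_group = df.loc[~df["group"].isin((NON_GDM, GDM)), "subject_id"].unique()
    if bad_group.size:
        report.append(f"group outside {{1,2}} for subject(s): {list(bad_group)}")

    visit_sets = df.groupby("subject_id")["visit"].apply(lambda v: sorted(v))
    incomplete = [sid for sid, v in visit_sets.items() if v != [1, 2]]
    if incomplete:
        report.append(
            f"subject(s) without exactly one row per visit 1 and 2: {incomplete}"
        )

    n_groups = df.groupby("subject_id")["group"].nunique()
    varying = list(n_groups[n_groups > 1].index)
    if varying:
        report.append(f"group not constant within subject(s): {varying}")

    for marker in BIOMARKERS:
        vals = pd.to_numeric(df[marker], errors="coerce")
        bad = df.loc[vals.isna() | (vals <= 0), "subject_id"].unique()
        if bad.size:
            report.append(
                f"non-positive or missing biomarker '{marker}' for subject(s): "
                f"{list(bad)}"
            )

    parity = pd.to_numeric(df["parity"], errors="coerce")
    bad = df.loc[parity.isna() | ~parity.isin(range(4)), "subject_id"].unique()
    if bad.size:
        report.append(f"parity outside 0-3 for subject(s): {list(bad)}")

    bad = df.loc[~df["education"].isin(EDUCATION_LEVELS), "subject_id"].unique()
    if bad.size:
        report.append(
            f"education not in {EDUCATION_LEVELS} for subject(s): {list(bad)}"
        )
    return report


def read_cohort(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    *,
    drop_incomplete: bool = False,
) -> CohortTable:
    """Read a cohort CSV (RFC-4180, UTF-8, '.' decimal) and validate it.

    ``dialect`` maps the file's column names onto the canonical ones.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    return CohortTable.from_dataframe(
        df, column_map=dialect, validate=True, drop_incomplete=drop_incomplete
    )


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write the cohort as CSV in the fixed :data:`COLUMNS` order.

    Floats are written at full ``repr`` precision, so a write/read
    round-trip reproduces every value bit-exactly.
    """
    df = table.data.loc[:, list(COLUMNS)].copy()
    # int-valued columns stay integers on disk
    for col in ("visit", "group", "parity"):
        df[col] = df[col].astype(int)
    df.to_csv(path, index=False)
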