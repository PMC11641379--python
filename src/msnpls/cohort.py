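"""Cohort covariates and CSF biomarker group assignment.

Subjects are classified from cerebrospinal-fluid amyloid-beta and tau
concentrations (pg/mL): biomarker-negative (``NEG_NEG``) when amyloid is at
or above 980 pg/mL *and* tau at or below 24 pg/mL, biomarker-positive
(``POS_POS``) on the strict complement of both cuts, and ``EXCLUDED`` for
the mixed profiles (one marker positive, the other negative), which are
dropped from all downstream group analyses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: CSF amyloid-beta cut-point in pg/mL.
ABETA_THRESHOLD = 980.0
#: CSF tau cut-point in pg/mL.
TAU_THRESHOLD = 24.0

#: Numeric encoding used in regression design matrices.
GENDER_CODES = {"M": 1.0, "F": 0.0}


class Group(str, Enum):
    """Biomarker status group."""

    NEG_NEG = "NEG_NEG"  # amyloid-negative / tau-negative
    POS_POS = "POS_POS"  # amyloid-positive / tau-positive
    EXCLUDED = "EXCLUDED"  # mixed profile, not analysed


@dataclass(frozen=True)
class CsfMeasurement:
    """CSF amyloid-beta and tau concentrations, both in pg/mL."""

    abeta: float
    tau: float

    def __post_init__(self) -> None:
        for name, value in (("abeta", self.abeta), ("tau", self.tau)):
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ValueError(f"{name} must be numeric, got {value!r}")
            if not math.isfinite(value) or value <= 0:
                raise ValueError(
                    f"{name} must be finite and > 0 pg/mL, got {value!r}"
                )


def classify_csf_status(
    csf: CsfMeasurement,
    abeta_threshold: float = ABETA_THRESHOLD,
    tau_threshold: float = TAU_THRESHOLD,
) -> Group:
    """Assign the biomarker group from a CSF measurement.

    ``NEG_NEG`` uses inclusive comparisons (abeta >= threshold and
    tau <= threshold); ``POS_POS`` is the strict complement of both, so the
    three groups partition the (abeta, tau) plane.
    """
    if not isinstance(csf, CsfMeasurement):
        csf = CsfMeasurement(*csf)
    if csf.abeta >= abeta_threshold and csf.tau <= tau_threshold:
        return Group.NEG_NEG
    if csf.abeta < abeta_threshold and csf.tau > tau_threshold:
        return Group.POS_POS
    return Group.EXCLUDED


@dataclass
class SubjectRecord:
    """One subject's covariates, biomarker group and (optionally) CSF values."""

    subject_id: str
    group: Group
    age: float
    gender: str  # "M" or "F"
    education: float  # years
    mmse: int  # 0-30
    csf: CsfMeasurement | None = None

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        if self.gender not in GENDER_CODES:
            raise ValueError(
                f"gender must be 'M' or 'F', got {self.gender!r} "
                f"(subject {self.subject_id})"
            )
        if not (0 <= self.mmse <= 30):
            raise ValueError(
                f"MMSE must lie in [0, 30], got {self.mmse} "
                f"(subject {self.subject_id})"
            )
        for name, value in (("age", self.age), ("education", self.education)):
            if not math.isfinite(float(value)):
                raise ValueError(f"{name} must be finite (subject {self.subject_id})")
        if self.csf is not None:
            derived = classify_csf_status(self.csf)
            if derived is not self.group:
                raise ValueError(
                    f"group {self.group.value} inconsistent with CSF values "
                    f"(abeta={self.csf.abeta}, tau={self.csf.tau} implies "
                    f"{derived.value}) for subject {self.subject_id}"
                )


_REQUIRED_COLUMNS = ("subject_id", "age", "gender", "education", "mmse")


def load_covariate_table(path) -> list[SubjectRecord]:
    """Read a tab-separated covariate table into subject records.

    The table must provide ``subject_id, age, gender, education, mmse`` plus
    either a ``group`` column or both ``abeta`` and ``tau`` columns (in which
    case the group is derived through :func:`classify_csf_status`).
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"covariate table missing column(s): {missing}")
    has_csf = {"abeta", "tau"} <= set(df.columns)
    if "group" not in df.columns and not has_csf:
        raise ValueError(
            "covariate table must provide either a 'group' column or both "
            "'abeta' and 'tau'"
        )
    dup = df["subject_id"][df["subject_id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate subject_id(s): {sorted(set(dup))}")

    records: list[SubjectRecord] = []
    for row in df.itertuples(index=False):
        for col in ("age", "education", "mmse"):
            value = getattr(row, col)
            if pd.isna(value):
                raise ValueError(
                    f"missing {col} for subject {row.subject_id}"
                )
        csf = None
        if has_csf and not (pd.isna(row.abeta) or pd.isna(row.tau)):
            csf = CsfMeasurement(float(row.abeta), float(row.tau))
        if "group" in df.columns and not pd.isna(row.group):
            group = Group(str(row.group))
        elif csf is not None:
            group = classify_csf_status(csf)
        else:
            raise ValueError(
                f"subject {row.subject_id} has neither group nor CSF values"
            )
        records.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                group=group,
                age=float(row.age),
                gender=str(row.gender),
                education=float(row.education),
                mmse=int(row.mmse),
                csf=csf,
            )
        )
    return records


def write_covariate_table(records: Iterable[SubjectRecord], path) -> None:
    """Write subject records back to the tab-separated covariate format."""
    rows = []
    for rec in records:
        row = {
            "subject_id": rec.subject_id,
            "age": rec.age,
            "gender": rec.gender,
            "education": rec.education,
            "mmse": rec.mmse,
            "group": rec.group.value,
        }
        if rec.csf is not None:
            row["abeta"] = rec.csf.abeta
            row["tau"] = rec.csf.tau
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def analysed_subjects(records: Sequence[SubjectRecord]) -> list[SubjectRecord]:
    """Drop EXCLUDED (mixed-profile) subjects, logging how many were removed."""
    kept = [r for r in records if r.group is not Group.EXCLUDED]
    n_dropped = len(records) - len(kept)
    if n_dropped:
        logger.info("dropped %d subject(s) with mixed CSF profiles", n_dropped)
    return kept
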