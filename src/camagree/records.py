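"""Assessment data model and long-format table IO.

The canonical representation is a long-format :class:`pandas.DataFrame` with
one row per instrument administration: a patient is visited on an occasion by
two raters, one scoring the long-form CAM and one the 3D-CAM, and each rater
records a binary overall delirium outcome plus the four binary cardinal
features (acute change and fluctuating course, inattention, disorganized
thinking, altered level of consciousness).  Pairing the two concurrent
administrations of an occasion is a derived view, not the stored format, so
occasions where one instrument was aborted are representable and reported.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DuplicateRecordError,
    SchemaError,
    ValidationError,
)

INSTRUMENTS = ("CAM", "3DCAM")
FEATURES = ("acute_change", "inattention", "disorganized_thinking", "aloc")
RESPONSES = ("delirium",) + FEATURES

ID_COLUMNS = ["patient_id", "occasion_id", "instrument", "rater_id"]
REQUIRED_COLUMNS = ID_COLUMNS + list(RESPONSES)
OPTIONAL_COLUMNS = ["duration_minutes"]


@dataclass(frozen=True)
class AssessmentRecord:
    """One instrument administration.

    ``delirium`` is always 0/1; the four feature outcomes may be missing
    (``None``) — such rows are kept for the overall analysis and dropped,
    with a logged count, from that feature's analysis.
    """

    patient_id: str
    occasion_id: str
    instrument: str
    rater_id: str
    delirium: int
    acute_change: int | None
    inattention: int | None
    disorganized_thinking: int | None
    aloc: int | None
    duration_minutes: float | None = None


@dataclass(frozen=True)
class PairedAssessment:
    """Concurrent CAM and 3D-CAM administrations of one occasion."""

    patient_id: str
    occasion_id: str
    cam: AssessmentRecord
    d3cam: AssessmentRecord


@dataclass
class CohortSummary:
    n_patients: int
    n_pairs: int
    n_raters: int
    delirium_positive_per_instrument: dict = field(default_factory=dict)
    median_duration_per_instrument: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def _check_binary(df: pd.DataFrame, column: str, allow_missing: bool,
                  row_offset: int) -> pd.Series:
    raw = df[column]
    values = pd.to_numeric(raw, errors="coerce")
    missing = values.isna()
    if missing.any() and not allow_missing:
        pos = int(np.flatnonzero(missing.to_numpy())[0])
        raise ValidationError(
            f"column {column!r} has a missing or non-numeric value "
            f"{raw.iloc[pos]!r}", row=pos + row_offset)
    bad = ~missing & ~values.isin([0, 1])
    if bad.any():
        pos = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"column {column!r} must be 0 or 1, got {raw.iloc[pos]!r}",
            row=pos + row_offset)
    return values.astype("Int64")


def validate_table(df: pd.DataFrame, row_offset: int = 0) -> pd.DataFrame:
    """Validate and normalize a long-format assessment table.

    Returns a copy with binary outcomes as nullable integers.  ``row_offset``
    shifts reported row numbers (2 when the frame came from a delimited file
    with a header line, so errors cite file line numbers).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    out = df.copy().reset_index(drop=True)
    for c in ID_COLUMNS:
        out[c] = out[c].astype(str)
    bad_inst = ~out["instrument"].isin(INSTRUMENTS)
    if bad_inst.any():
        pos = int(np.flatnonzero(bad_inst.to_numpy())[0])
        raise ValidationError(
            f"instrument must be one of {INSTRUMENTS}, got "
            f"{out['instrument'].iloc[pos]!r}", row=pos + row_offset)
    out["delirium"] = _check_binary(out, "delirium", False, row_offset)
    for feat in FEATURES:
        out[feat] = _check_binary(out, feat, True, row_offset)
    if "duration_minutes" in out.columns:
        dur = pd.to_numeric(out["duration_minutes"], errors="coerce")
        if (dur.dropna() < 0).any():
            pos = int(np.flatnonzero((dur < 0).to_numpy())[0])
            raise ValidationError("duration_minutes must be nonnegative",
                                  row=pos + row_offset)
        out["duration_minutes"] = dur
    dup = out.duplicated(subset=["patient_id", "occasion_id", "instrument"])
    if dup.any():
        pos = int(np.flatnonzero(dup.to_numpy())[0])
        key = tuple(out.loc[pos, ["patient_id", "occasion_id", "instrument"]])
        raise DuplicateRecordError(
            f"duplicate (patient, occasion, instrument) = {key}")
    return out


def read_assessments(path, sep: str | None = None) -> pd.DataFrame:
    """Read and validate a delimited assessment table (header required).

    ``sep=None`` sniffs comma vs tab.  Row numbers in validation errors are
    file line numbers (the header is line 1).
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                     dtype=str)
    return validate_table(df, row_offset=2)


def write_assessments(table: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a validated table in the standard delimited format."""
    cols = REQUIRED_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in table.columns]
    table.to_csv(path, sep=sep, index=False, columns=cols)


def _record(row: pd.Series) -> AssessmentRecord:
    def _opt(v):
        return None if pd.isna(v) else int(v)

    dur = row.get("duration_minutes", np.nan)
    return AssessmentRecord(
        patient_id=row["patient_id"], occasion_id=row["occasion_id"],
        instrument=row["instrument"], rater_id=row["rater_id"],
        delirium=int(row["delirium"]),
        acute_change=_opt(row["acute_change"]),
        inattention=_opt(row["inattention"]),
        disorganized_thinking=_opt(row["disorganized_thinking"]),
        aloc=_opt(row["aloc"]),
        duration_minutes=None if pd.isna(dur) else float(dur),
    )


@dataclass
class PairingResult:
    pairs: list
    orphans: list  # (patient_id, occasion_id, instrument_present)


def pair_assessments(table: pd.DataFrame,
                     same_rater: str = "warn") -> PairingResult:
    """Pair concurrent CAM/3D-CAM administrations by (patient, occasion).

    Occasions with only one instrument are reported as orphans, never
    silently dropped.  A pair scored by the same rater on both instruments
    violates the two-assessor design; ``same_rater`` is ``"warn"`` (default)
    or ``"error"``.
    """
    pairs, orphans = [], []
    for (pid, oid), grp in table.groupby(["patient_id", "occasion_id"],
                                         sort=True):
        by_inst = {r["instrument"]: _record(r) for _, r in grp.iterrows()}
        if len(by_inst) == 2:
            cam, d3 = by_inst["CAM"], by_inst["3DCAM"]
            if cam.rater_id == d3.rater_id:
                msg = (f"patient {pid} occasion {oid}: same rater "
                       f"{cam.rater_id!r} on both instruments")
                if same_rater == "error":
                    from .errors import PairingError
                    raise PairingError(msg)
                warnings.warn(msg)
            pairs.append(PairedAssessment(pid, oid, cam=cam, d3cam=d3))
        else:
            orphans.append((pid, oid, next(iter(by_inst))))
    return PairingResult(pairs=pairs, orphans=orphans)


def summarize_cohort(table: pd.DataFrame) -> CohortSummary:
    """Counts over distinct identifiers; medians over non-missing durations."""
    if len(table) == 0:
        raise ValidationError("cannot summarize an empty table")
    complete = (table.groupby(["patient_id", "occasion_id"])["instrument"]
                .nunique() == 2)
    positives = {
        inst: int(table.loc[table["instrument"] == inst, "delirium"].sum())
        for inst in INSTRUMENTS
    }
    medians = {}
    if "duration_minutes" in table.columns:
        for inst in INSTRUMENTS:
            d = table.loc[table["instrument"] == inst, "duration_minutes"]
            d = d.dropna()
            medians[inst] = float(d.median()) if len(d) else None
    return CohortSummary(
        n_patients=int(table["patient_id"].nunique()),
        n_pairs=int(complete.sum()),
        n_raters=int(table["rater_id"].nunique()),
        delirium_positive_per_instrument=positives,
        median_duration_per_instrument=medians,
    )
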