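"""Subject-level and aggregated trial data: containers, CSV schemas, validation.

Subject-level data follow a time-to-first-event layout: one row per subject,
with the time from randomization to the first of (adverse event of interest,
competing event, censoring) and an event code 0/1/2.  Aggregated summaries
carry only arm-level results, so they can leave a sponsor organization without
any subject-level information — the privacy contract is enforced at write
time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: event codes
CENSORED = 0
ADVERSE_EVENT = 1
COMPETING_EVENT = 2
EVENT_CODES = (CENSORED, ADVERSE_EVENT, COMPETING_EVENT)

EXPERIMENTAL = "experimental"
CONTROL = "control"
ARMS = (EXPERIMENTAL, CONTROL)

SUBJECT_COLUMNS = ("subject_id", "arm", "time", "event_code")
CE_SUBTYPE_COLUMN = "ce_subtype"

AGGREGATE_SCHEMA_TAG = "# aerisk-aggregate-v1"
AGGREGATE_COLUMNS = (
    "trial_id", "ae_id", "arm", "estimator", "tau", "estimate",
    "variance", "n", "d_ae", "d_ce", "n_cens", "person_time",
)
#: columns that must never appear in an aggregated file
SUBJECT_LEVEL_FIELDS = frozenset({"subject_id", "time", "event_code", CE_SUBTYPE_COLUMN})


class SchemaError(ValueError):
    """A file or table does not match the expected column layout."""


class ValidationError(ValueError):
    """Rows violate subject-level invariants; the message lists offenders."""


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's first-event observation.

    ``time`` is the strictly positive time from randomization to the first of
    AE / competing event / censoring, in whatever unit the dataset uses (days
    by convention, years in the simulator).
    """

    subject_id: str
    arm: str
    time: float
    event_code: int


def _row_problems(df: pd.DataFrame, *, line_offset: int | None = None) -> list[str]:
    """Collect human-readable invariant violations, one string per bad row."""
    problems: list[str] = []

    def where(i: int) -> str:
        if line_offset is not None:
            return f"line {i + line_offset}"
        return f"row {i}"

    times = pd.to_numeric(df["time"], errors="coerce")
    codes = pd.to_numeric(df["event_code"], errors="coerce")
    for i in range(len(df)):
        sid = df["subject_id"].iloc[i]
        t = times.iloc[i]
        c = codes.iloc[i]
        arm = df["arm"].iloc[i]
        if pd.isna(t) or not np.isfinite(t):
            problems.append(f"{where(i)} (subject {sid}): time is missing or not finite")
        elif t <= 0:
            problems.append(f"{where(i)} (subject {sid}): time must be > 0, got {t}")
        if pd.isna(c) or float(c) != int(c) or int(c) not in EVENT_CODES:
            problems.append(
                f"{where(i)} (subject {sid}): event_code must be one of "
                f"{EVENT_CODES} (0=censored, 1=AE, 2=competing event), got {df['event_code'].iloc[i]!r}"
            )
        if arm not in ARMS:
            problems.append(f"{where(i)} (subject {sid}): arm must be one of {ARMS}, got {arm!r}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    for sid in dup.unique():
        problems.append(f"subject_id {sid!r} is not unique within the dataset")
    return problems


@dataclass
class TrialDataset:
    """Subject-level first-event data for one trial and one AE type.

    The canonical container consumed by every estimator.  The table is
    validated on construction and kept sorted by time.
    """

    table: pd.DataFrame
    trial_id: str = ""
    ae_id: str = ""

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table).copy()
        missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        if df.empty:
            raise ValidationError("dataset is empty")
        problems = _row_problems(df)
        if problems:
            raise ValidationError("invalid subject rows:\n  " + "\n  ".join(problems))
        keep = list(SUBJECT_COLUMNS)
        if CE_SUBTYPE_COLUMN in df.columns:
            keep.append(CE_SUBTYPE_COLUMN)
        df = df[keep]
        df["subject_id"] = df["subject_id"].astype(str)
        df["time"] = df["time"].astype(float)
        df["event_code"] = df["event_code"].astype(int)
        # stable sort so equal times keep input order (tie conventions are
        # handled downstream by processing distinct times, not row order)
        df = df.sort_values("time", kind="mergesort").reset_index(drop=True)
        self.table = df

    # -- constructors --------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        arms: Mapping[str, tuple[Sequence[float], Sequence[int]]],
        *,
        trial_id: str = "",
        ae_id: str = "",
    ) -> "TrialDataset":
        """Build a dataset from per-arm ``(times, event_codes)`` arrays."""
        frames = []
        for label, (times, events) in arms.items():
            times = np.asarray(times, dtype=float)
            events = np.asarray(events, dtype=int)
            prefix = label[:1].upper()
            frames.append(pd.DataFrame({
                "subject_id": [f"{prefix}{i + 1:05d}" for i in range(len(times))],
                "arm": label,
                "time": times,
                "event_code": events,
            }))
        return cls(pd.concat(frames, ignore_index=True), trial_id=trial_id, ae_id=ae_id)

    # -- accessors -----------------------------------------------------
    @property
    def arms(self) -> tuple[str, ...]:
        present = set(self.table["arm"])
        return tuple(a for a in ARMS if a in present)

    def arm_table(self, arm: str) -> pd.DataFrame:
        return self.table[self.table["arm"] == arm]

    def arm_arrays(self, arm: str) -> tuple[np.ndarray, np.ndarray]:
        """Times and event codes for one arm, sorted by time."""
        sub = self.arm_table(arm)
        return sub["time"].to_numpy(), sub["event_code"].to_numpy()

    def n(self, arm: str | None = None) -> int:
        if arm is None:
            return len(self.table)
        return int((self.table["arm"] == arm).sum())

    def require_two_arms(self) -> None:
        for arm in ARMS:
            if self.n(arm) == 0:
                raise ValidationError(f"comparative analysis requires a nonempty {arm!r} arm")

    def records(self) -> Iterator[SubjectRecord]:
        for row in self.table.itertuples(index=False):
            yield SubjectRecord(row.subject_id, row.arm, float(row.time), int(row.event_code))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialDataset):
            return NotImplemented
        return (
            self.trial_id == other.trial_id
            and self.ae_id == other.ae_id
            and self.table[list(SUBJECT_COLUMNS)].equals(other.table[list(SUBJECT_COLUMNS)])
        )


def max_eval_time(data: TrialDataset, arm: str | None = None) -> float:
    """Latest time with an observation (event or censored).

    Pooled over both arms by default — this is the default evaluation time
    tau for reading off absolute-risk estimates.  Pass ``arm`` for an
    arm-wise variant.
    """
    table = data.table if arm is None else data.arm_table(arm)
    if table.empty:
        raise ValidationError("cannot compute the maximal evaluation time of an empty dataset")
    return float(table["time"].max())


def read_trial(
    path: str | Path,
    *,
    trial_id: str | None = None,
    ae_id: str = "",
    death_only: bool = False,
    death_label: str = "death",
) -> TrialDataset:
    """Read a subject-level CSV (subject_id, arm, time, event_code[, ce_subtype]).

    ``death_only=True`` applies the sensitivity recoding in which only death
    counts as a competing event: rows with ``event_code == 2`` whose
    ``ce_subtype`` differs from ``death_label`` are recoded to censored.
    Invalid rows are reported with their file line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "arm": str})
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {', '.join(missing)}")
    problems = _row_problems(df, line_offset=2)  # header is line 1
    if problems:
        raise ValidationError(f"{path.name}: invalid subject rows:\n  " + "\n  ".join(problems))
    if death_only:
        if CE_SUBTYPE_COLUMN not in df.columns:
            raise SchemaError(
                f"{path.name}: death-only recoding requires a {CE_SUBTYPE_COLUMN!r} column"
            )
        recode = (df["event_code"].astype(int) == COMPETING_EVENT) & (
            df[CE_SUBTYPE_COLUMN].astype(str).str.lower() != death_label
        )
        df.loc[recode, "event_code"] = CENSORED
    return TrialDataset(df, trial_id=trial_id if trial_id is not None else path.stem, ae_id=ae_id)


def write_trial(path: str | Path, data: TrialDataset) -> None:
    """Write a subject-level CSV that :func:`read_trial` round-trips."""
    data.table.to_csv(path, index=False)


@dataclass
class AggregateSummary:
    """Arm-level estimator results keyed by (trial, AE, arm, estimator).

    Contains no subject-level fields by construction; this is the only schema
    intended to leave an organization.
    """

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=list(AGGREGATE_COLUMNS)))

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table).copy()
        forbidden = SUBJECT_LEVEL_FIELDS.intersection(df.columns)
        if forbidden:
            raise SchemaError(
                f"aggregated summaries must not contain subject-level field(s): {sorted(forbidden)}"
            )
        missing = [c for c in AGGREGATE_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing aggregate column(s): {', '.join(missing)}")
        df = df[list(AGGREGATE_COLUMNS)]
        if len(df):
            est = df["estimate"].astype(float)
            var = df["variance"].astype(float)
            if ((est < 0) | (est > 1)).any():
                raise ValidationError("aggregate estimates must lie in [0, 1]")
            if (var < 0).any():
                raise ValidationError("aggregate variances must be >= 0")
        self.table = df.reset_index(drop=True)

    @classmethod
    def from_estimates(
        cls, trial_id: str, ae_id: str, arm: str, estimates: Iterable
    ) -> "AggregateSummary":
        """Build rows from :class:`~aerisk.absolute.RiskEstimate` objects."""
        rows = [
            {
                "trial_id": trial_id, "ae_id": ae_id, "arm": arm,
                "estimator": e.estimator, "tau": e.tau, "estimate": e.point,
                "variance": e.variance, "n": e.n, "d_ae": e.d_ae,
                "d_ce": e.d_ce, "n_cens": e.n_cens, "person_time": e.person_time,
            }
            for e in estimates
        ]
        return cls(pd.DataFrame(rows, columns=list(AGGREGATE_COLUMNS)))

    def equals(self, other: "AggregateSummary") -> bool:
        a, b = self.table, other.table
        if a.shape != b.shape:
            return False
        for col in AGGREGATE_COLUMNS:
            x, y = a[col], b[col]
            if col in ("tau", "estimate", "variance", "person_time"):
                if not np.allclose(x.astype(float), y.astype(float), rtol=0, atol=0, equal_nan=True):
                    return False
            elif not (x.astype(str) == y.astype(str)).all():
                return False
        return True


def write_aggregate(path: str | Path, summary: AggregateSummary) -> None:
    """Write an aggregated CSV with a schema-version header line.

    Refuses anything that is not an :class:`AggregateSummary` — in particular
    subject-level data cannot be serialized through this path.
    """
    if isinstance(summary, TrialDataset):
        raise SchemaError("refusing to write subject-level data through the aggregate schema")
    if not isinstance(summary, AggregateSummary):
        summary = AggregateSummary(summary)  # re-validates, rejects subject-level fields
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(AGGREGATE_SCHEMA_TAG + "\n")
        summary.table.to_csv(fh, index=False)


def read_aggregate(path: str | Path) -> AggregateSummary:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        tag = fh.readline().strip()
        if tag != AGGREGATE_SCHEMA_TAG:
            raise SchemaError(
                f"{path.name}: not an aggregate file (expected first line {AGGREGATE_SCHEMA_TAG!r})"
            )
        df = pd.read_csv(fh, dtype={"trial_id": str, "ae_id": str, "arm": str, "estimator": str})
    return AggregateSummary(df)
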