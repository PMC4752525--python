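"""Data model and I/O for recurrent gap-time datasets.

The analysis works on *gap times*: the at-risk intervals between a hospital
discharge and the next readmission (the first gap runs from disease onset to
the first admission).  Time spent in hospital is excluded from the time scale.
Each subject contributes an ordered sequence of gaps, the last of which may be
right-censored at the end of follow-up.  Covariates are fixed at baseline.

Long-format layout (one row per gap)::

    subject_id, rank, gap_weeks, event, age_onset, gender, marital,
    mode_onset, head_injury, family_history

Indicator codings (1 = first-named level): gender 1=male (reference female),
marital 1=single (reference married), mode_onset 1=gradual (reference sudden),
head_injury 1=yes, family_history 1=yes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("relapse_frailty")

#: canonical column order of the long gap-time CSV dialect
COLUMNS = (
    "subject_id",
    "rank",
    "gap_weeks",
    "event",
    "age_onset",
    "gender",
    "marital",
    "mode_onset",
    "head_injury",
    "family_history",
)

#: the six covariate columns, in reporting order
COVARIATE_NAMES = (
    "age_onset",
    "gender",
    "marital",
    "mode_onset",
    "head_injury",
    "family_history",
)

#: human-readable labels for the indicator levels (first-named level coded 1)
INDICATOR_LABELS = {
    "gender": {1: "Male", 0: "Female"},
    "marital": {1: "Single", 0: "Married"},
    "mode_onset": {1: "Gradual", 0: "Sudden"},
    "head_injury": {1: "Yes", 0: "No"},
    "family_history": {1: "Yes", 0: "No"},
}


class DataFormatError(ValueError):
    """Raised when an input file does not match the expected dialect."""


class ValidationError(ValueError):
    """Raised when a dataset violates a structural invariant.

    Attributes
    ----------
    violations : list of (subject_id, rule, message)
    """

    def __init__(self, violations):
        self.violations = list(violations)
        lines = [f"{s!r}: [{rule}] {msg}" for s, rule, msg in self.violations]
        super().__init__("dataset validation failed:\n" + "\n".join(lines))


@dataclass(frozen=True)
class CovariateVector:
    """One subject's six baseline covariates (age in years + five indicators)."""

    age_onset: float
    gender: int
    marital: int
    mode_onset: int
    head_injury: int
    family_history: int

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.age_onset,
                self.gender,
                self.marital,
                self.mode_onset,
                self.head_injury,
                self.family_history,
            ],
            dtype=float,
        )

    def violations(self):
        out = []
        if not (np.isfinite(self.age_onset) and self.age_onset > 0):
            out.append(("nonpositive-age", f"age_onset={self.age_onset}"))
        for name in COVARIATE_NAMES[1:]:
            v = getattr(self, name)
            if v not in (0, 1):
                out.append(("bad-indicator", f"{name}={v} not in {{0,1}}"))
        return out


@dataclass(frozen=True)
class GapRecord:
    """One at-risk interval: subject, event rank k, gap time (weeks), event flag."""

    subject_id: str
    rank: int
    gap_time: float
    event: int


@dataclass
class RecurrentEventDataset:
    """Ordered gap records plus a per-subject covariate table."""

    records: list[GapRecord] = field(default_factory=list)
    covariates: dict[str, CovariateVector] = field(default_factory=dict)

    def __post_init__(self):
        self.records = sorted(self.records, key=lambda r: (str(r.subject_id), r.rank))

    # -- basic accessors ---------------------------------------------------
    @property
    def subject_ids(self) -> list[str]:
        return sorted(self.covariates)

    @property
    def n_subjects(self) -> int:
        return len(self.covariates)

    def records_for(self, subject_id: str) -> list[GapRecord]:
        return [r for r in self.records if r.subject_id == subject_id]

    def event_counts(self) -> dict[str, int]:
        """Number of observed relapses (event=1 records) per subject."""
        out = {s: 0 for s in self.covariates}
        for r in self.records:
            if r.event == 1:
                out[r.subject_id] = out.get(r.subject_id, 0) + 1
        return out

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RecurrentEventDataset):
            return NotImplemented
        return self.records == other.records and self.covariates == other.covariates

    # -- frame conversion --------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            x = self.covariates[r.subject_id]
            rows.append(
                (
                    r.subject_id,
                    r.rank,
                    r.gap_time,
                    r.event,
                    x.age_onset,
                    x.gender,
                    x.marital,
                    x.mode_onset,
                    x.head_injury,
                    x.family_history,
                )
            )
        return pd.DataFrame(rows, columns=list(COLUMNS))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, *, strict: bool = True) -> "RecurrentEventDataset":
        """Build a dataset from a long-format frame; validates when ``strict``.

        Subjects with any missing covariate value are dropped with a warning
        (the study itself excluded fully-missing records, and no imputation
        rule is defined).
        """
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise DataFormatError(f"missing required column(s): {', '.join(missing)}")
        df = df.copy()
        df["subject_id"] = df["subject_id"].astype(str)

        cov_cols = list(COVARIATE_NAMES)
        bad_subjects = sorted(df.loc[df[cov_cols].isna().any(axis=1), "subject_id"].unique())
        if bad_subjects:
            msg = f"excluding {len(bad_subjects)} subject(s) with missing covariates: {bad_subjects}"
            logger.warning(msg)
            warnings.warn(msg, UserWarning, stacklevel=2)
            df = df[~df["subject_id"].isin(bad_subjects)]

        records = []
        covariates: dict[str, CovariateVector] = {}
        mismatches = []
        for row in df.itertuples(index=False):
            sid = str(row.subject_id)
            x = CovariateVector(
                age_onset=float(row.age_onset),
                gender=int(row.gender),
                marital=int(row.marital),
                mode_onset=int(row.mode_onset),
                head_injury=int(row.head_injury),
                family_history=int(row.family_history),
            )
            if sid in covariates:
                if covariates[sid] != x:
                    mismatches.append((sid, "covariate-mismatch", "covariates differ across gaps"))
            else:
                covariates[sid] = x
            records.append(
                GapRecord(sid, int(row.rank), float(row.gap_weeks), int(row.event))
            )
        ds = cls(records=records, covariates=covariates)
        if strict:
            viol = mismatches + ds.validation_report()
            if viol:
                raise ValidationError(viol)
        return ds

    # -- validation --------------------------------------------------------
    def validation_report(self) -> list[tuple[str, str, str]]:
        """Every invariant violation as (subject_id, rule, message); empty iff valid."""
        out: list[tuple[str, str, str]] = []
        by_subject: dict[str, list[GapRecord]] = {}
        for r in self.records:
            by_subject.setdefault(r.subject_id, []).append(r)

        for sid in sorted(set(by_subject) | set(self.covariates)):
            recs = by_subject.get(sid)
            if recs is None:
                out.append((sid, "no-records", "covariate entry without gap records"))
                continue
            if sid not in self.covariates:
                out.append((sid, "no-covariates", "gap records without covariate entry"))
            else:
                for rule, msg in self.covariates[sid].violations():
                    out.append((sid, rule, msg))
            ranks = [r.rank for r in recs]
            if ranks != list(range(1, len(ranks) + 1)):
                out.append((sid, "rank-sequence", f"ranks {ranks} are not consecutive 1..K"))
            for r in recs:
                if not (np.isfinite(r.gap_time) and r.gap_time > 0):
                    out.append((sid, "nonpositive-gap", f"rank {r.rank}: gap_time={r.gap_time}"))
                if r.event not in (0, 1):
                    out.append((sid, "bad-indicator", f"rank {r.rank}: event={r.event}"))
            censored = [r.rank for r in recs if r.event == 0]
            if len(censored) > 1:
                out.append((sid, "multiple-censored", f"censored at ranks {censored}"))
            elif censored and censored[0] != max(ranks):
                out.append((sid, "censored-not-last", f"censored record at rank {censored[0]} of {max(ranks)}"))
            if not any(r.event == 1 for r in recs):
                out.append((sid, "no-event", "subject has no observed relapse"))
        return out

    def validate(self) -> None:
        """Raise :class:`ValidationError` if any invariant is violated."""
        viol = self.validation_report()
        if viol:
            raise ValidationError(viol)


def validate(ds: RecurrentEventDataset) -> list[tuple[str, str, str]]:
    """Reporting form of validation: list of violations, empty iff valid."""
    return ds.validation_report()


# ---------------------------------------------------------------------------
# I/O


@dataclass(frozen=True)
class Dialect:
    """Delimited-text dialect: separator plus a file→canonical column map."""

    delimiter: str = ","
    columns: Mapping[str, str] = field(default_factory=dict)  # file name -> canonical


def read_dataset(path, dialect: Dialect | None = None) -> RecurrentEventDataset:
    """Read and validate a long-format gap-time CSV."""
    dialect = dialect or Dialect()
    try:
        df = pd.read_csv(path, sep=dialect.delimiter, dtype={"subject_id": str})
    except FileNotFoundError:
        raise
    if dialect.columns:
        df = df.rename(columns=dict(dialect.columns))
    return RecurrentEventDataset.from_frame(df)


def write_dataset(ds: RecurrentEventDataset, path, dialect: Dialect | None = None) -> None:
    """Write a dataset as delimited text; ``read_dataset`` round-trips exactly."""
    dialect = dialect or Dialect()
    df = ds.to_frame()
    # repr-precision floats so that write→read is field-for-field identity
    df.to_csv(path, sep=dialect.delimiter, index=False, float_format=None)


# ---------------------------------------------------------------------------
# Admission histories → gap times


@dataclass(frozen=True)
class AdmissionHistory:
    """Raw hospital stays for one subject, on a common week axis.

    ``onset_week`` is the disease onset (start of follow-up); ``stays`` are
    non-overlapping ``(admission_week, discharge_week)`` pairs in increasing
    order; ``followup_end_week`` closes observation.
    """

    subject_id: str
    onset_week: float
    stays: tuple[tuple[float, float], ...]
    followup_end_week: float

    def violations(self):
        out = []
        sid = self.subject_id
        if self.stays:
            if self.onset_week > self.stays[0][0]:
                out.append((sid, "onset-after-admission", "onset_week exceeds first admission"))
            prev_end = None
            for adm, dis in self.stays:
                if not adm < dis:
                    out.append((sid, "bad-stay", f"admission {adm} not before discharge {dis}"))
                if prev_end is not None and adm < prev_end:
                    out.append((sid, "overlapping-stays", f"admission {adm} before prior discharge {prev_end}"))
                prev_end = dis
            if self.followup_end_week < self.stays[-1][1]:
                out.append((sid, "followup-before-discharge", "followup_end_week before last discharge"))
        return out


def build_gap_times(history: AdmissionHistory) -> list[GapRecord]:
    """Convert an admission history into gap records.

    Gap 1 is first admission − onset; gap k≥2 is the k-th admission minus the
    (k−1)-th discharge — in-hospital time never enters any gap.  If follow-up
    extends past the last discharge the remaining open interval becomes one
    censored record.  Zero-length gaps (readmission on the discharge day) are
    rejected: the continuous-time likelihood needs t > 0.
    """
    viol = history.violations()
    if viol:
        raise ValidationError(viol)
    sid = history.subject_id
    records: list[GapRecord] = []
    at_risk_from = history.onset_week
    for k, (adm, dis) in enumerate(history.stays, start=1):
        gap = adm - at_risk_from
        if gap <= 0:
            raise ValidationError(
                [(sid, "nonpositive-gap", f"rank {k}: admission at {adm} does not follow {at_risk_from}")]
            )
        records.append(GapRecord(sid, k, float(gap), 1))
        at_risk_from = dis
    if history.stays and history.followup_end_week > at_risk_from:
        records.append(
            GapRecord(sid, len(history.stays) + 1, float(history.followup_end_week - at_risk_from), 0)
        )
    return records


def read_admission_histories(path, dialect: Dialect | None = None) -> list[AdmissionHistory]:
    """Read an admission-history CSV: one row per stay.

    Columns: ``subject_id, onset_week, admission_week, discharge_week,
    followup_end_week`` (onset and follow-up end repeated on each of a
    subject's rows).
    """
    dialect = dialect or Dialect()
    df = pd.read_csv(path, sep=dialect.delimiter, dtype={"subject_id": str})
    required = ["subject_id", "onset_week", "admission_week", "discharge_week", "followup_end_week"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataFormatError(f"missing required column(s): {', '.join(missing)}")
    out = []
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("admission_week")
        out.append(
            AdmissionHistory(
                subject_id=str(sid),
                onset_week=float(grp["onset_week"].iloc[0]),
                stays=tuple(
                    (float(a), float(d))
                    for a, d in zip(grp["admission_week"], grp["discharge_week"])
                ),
                followup_end_week=float(grp["followup_end_week"].iloc[0]),
            )
        )
    return out


def dataset_from_histories(
    histories: Iterable[AdmissionHistory],
    covariates: Mapping[str, CovariateVector],
) -> RecurrentEventDataset:
    """Assemble a validated dataset from admission histories plus covariates."""
    records: list[GapRecord] = []
    for h in histories:
        records.extend(build_gap_times(h))
    ds = RecurrentEventDataset(records=records, covariates=dict(covariates))
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# Descriptive cross-tabulation


def _relapse_category(n_events: int) -> str:
    return "5+" if n_events >= 5 else str(n_events)


def frequency_table(
    ds: RecurrentEventDataset,
    strata: Sequence[str] = ("family_history", "gender"),
) -> pd.DataFrame:
    """Cross-tab of per-subject relapse-count category by covariate strata.

    Rows are strata combinations; columns are a MultiIndex with a ``count``
    and a ``pct`` block over relapse-count categories (2, 3, 4, 5+; a ``1``
    category is prepended when single-relapse subjects are present).
    Percentages are within-stratum and sum to 100 over nonempty rows.
    """
    for s in strata:
        if s not in COVARIATE_NAMES:
            raise KeyError(f"unknown stratum {s!r}; choose from {COVARIATE_NAMES}")

    cats = ["2", "3", "4", "5+"]
    counts = ds.event_counts()
    if any(c <= 1 for c in counts.values()):
        cats = ["1"] + cats

    rows: dict[tuple, dict[str, int]] = {}
    for sid, n_ev in counts.items():
        x = ds.covariates[sid]
        key = tuple(
            INDICATOR_LABELS.get(s, {}).get(getattr(x, s), getattr(x, s)) for s in strata
        )
        row = rows.setdefault(key, {c: 0 for c in cats})
        row[_relapse_category(n_ev)] += 1

    index = pd.MultiIndex.from_tuples(sorted(rows), names=list(strata)) if rows else pd.MultiIndex.from_tuples([], names=list(strata))
    count_df = pd.DataFrame([rows[k] for k in sorted(rows)], index=index, columns=cats, dtype=int) if rows else pd.DataFrame(columns=cats, index=index, dtype=int)
    totals = count_df.sum(axis=1)
    pct_df = count_df.div(totals.where(totals > 0), axis=0) * 100.0
    out = pd.concat({"count": count_df, "pct": pct_df}, axis=1)
    return out


def covariate_summary(ds: RecurrentEventDataset) -> pd.DataFrame:
    """Per-covariate cohort description: mean/sd/range for age, frequency for indicators."""
    rows = []
    X = np.array([ds.covariates[s].as_array() for s in ds.subject_ids])
    if X.size == 0:
        return pd.DataFrame(columns=["covariate", "statistic", "value"])
    age = X[:, 0]
    rows += [
        ("age_onset", "mean", float(age.mean())),
        ("age_onset", "sd", float(age.std(ddof=1)) if len(age) > 1 else 0.0),
        ("age_onset", "min", float(age.min())),
        ("age_onset", "max", float(age.max())),
    ]
    for j, name in enumerate(COVARIATE_NAMES[1:], start=1):
        rows.append((name, "proportion_1", float(X[:, j].mean())))
    return pd.DataFrame(rows, columns=["covariate", "statistic", "value"])
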