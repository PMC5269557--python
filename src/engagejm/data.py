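"""Canonical data model for linked longitudinal + survival engagement data.

The package analyses weekly mHealth engagement (days of app use per week,
0-7) together with time to dropout.  Two tables describe a cohort:

* a long-format longitudinal table — one row per subject-week with the
  engagement value observed that week;
* a one-row-per-subject survival table — dropout/censoring time in weeks,
  an event indicator (1 = dropout observed, 0 = administratively censored)
  and baseline covariates (age, male indicator, race category).

Dropout truncates the longitudinal record: no engagement observation may
occur after the subject's event/censoring time.  :class:`LinkedCohort`
enforces that consistency and is the only container downstream models
accept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RACE_LEVELS",
    "LONGITUDINAL_COLUMNS",
    "SURVIVAL_COLUMNS",
    "SURVIVAL_DESIGN_COLUMNS",
    "CohortFormatError",
    "CohortValidationError",
    "LongitudinalDataset",
    "SurvivalDataset",
    "LinkedCohort",
    "Design",
    "read_cohort",
    "write_cohort",
    "build_design",
    "survival_design",
]

#: race categories; "white" is the reference level in the hazard design
RACE_LEVELS = ("white", "black", "hispanic", "other")

LONGITUDINAL_COLUMNS = ("subject_id", "time_weeks", "engagement_days")
SURVIVAL_COLUMNS = ("subject_id", "event_time_weeks", "event", "age_years", "male", "race")
#: fixed column order of the hazard-model design matrix
SURVIVAL_DESIGN_COLUMNS = ("age_centered", "male", "race_black", "race_hispanic", "race_other")

ENGAGEMENT_RANGE = (0.0, 7.0)


class CohortFormatError(ValueError):
    """A file or frame does not match the documented schema."""


class CohortValidationError(ValueError):
    """Data match the schema but violate a cohort invariant."""


def _check_columns(frame: pd.DataFrame, expected: tuple[str, ...], what: str) -> None:
    cols = list(frame.columns)
    if len(set(cols)) != len(cols):
        dupes = sorted({c for c in cols if cols.count(c) > 1})
        raise CohortFormatError(f"{what}: duplicate column(s) {dupes}")
    missing = [c for c in expected if c not in cols]
    if missing:
        raise CohortFormatError(f"{what}: missing column(s) {missing}; expected {list(expected)}")
    extra = [c for c in cols if c not in expected]
    if extra:
        raise CohortFormatError(f"{what}: unexpected column(s) {extra}")


def _require_no_missing(frame: pd.DataFrame, what: str) -> None:
    if frame.isna().any().any():
        bad = [c for c in frame.columns if frame[c].isna().any()]
        raise CohortValidationError(
            f"{what}: missing values in column(s) {bad}; missingness is represented "
            "by record absence, not by empty cells"
        )


class LongitudinalDataset:
    """Repeated engagement observations ``y_ij`` at weeks ``t_ij`` per subject.

    Rows are normalised to (subject_id, time) order on construction.
    Invariants: every subject has at least one record, times within a subject
    are strictly increasing, finite and nonnegative, and every engagement
    value lies in [0, 7] days/week.
    """

    def __init__(self, frame: pd.DataFrame):
        _check_columns(frame, LONGITUDINAL_COLUMNS, "longitudinal table")
        frame = frame.loc[:, list(LONGITUDINAL_COLUMNS)].copy()
        _require_no_missing(frame, "longitudinal table")
        frame["subject_id"] = frame["subject_id"].astype(str)
        try:
            frame["time_weeks"] = frame["time_weeks"].astype(float)
            frame["engagement_days"] = frame["engagement_days"].astype(float)
        except (TypeError, ValueError) as exc:
            raise CohortFormatError(f"longitudinal table: non-numeric data ({exc})") from exc
        if len(frame) == 0:
            raise CohortValidationError("longitudinal table: zero records (zero subjects disallowed)")
        frame = frame.sort_values(["subject_id", "time_weeks"], kind="mergesort").reset_index(drop=True)

        t = frame["time_weeks"].to_numpy()
        y = frame["engagement_days"].to_numpy()
        if not np.all(np.isfinite(t)) or np.any(t < 0):
            bad = frame.loc[~np.isfinite(t) | (t < 0), "subject_id"].iloc[0]
            raise CohortValidationError(f"subject {bad!r}: observation times must be finite and >= 0")
        lo, hi = ENGAGEMENT_RANGE
        if not np.all(np.isfinite(y)) or np.any(y < lo) or np.any(y > hi):
            bad = frame.loc[~np.isfinite(y) | (y < lo) | (y > hi), "subject_id"].iloc[0]
            raise CohortValidationError(
                f"subject {bad!r}: engagement values must lie in [{lo:g}, {hi:g}] days/week"
            )
        same_subject = frame["subject_id"].to_numpy()[1:] == frame["subject_id"].to_numpy()[:-1]
        nondecreasing = t[1:] <= t[:-1]
        if np.any(same_subject & nondecreasing):
            bad = frame["subject_id"].to_numpy()[1:][same_subject & nondecreasing][0]
            raise CohortValidationError(
                f"subject {bad!r}: observation times must be strictly increasing within subject"
            )
        self.frame = frame

    @property
    def subject_ids(self) -> np.ndarray:
        return self.frame["subject_id"].unique()

    @property
    def n_subjects(self) -> int:
        return self.frame["subject_id"].nunique()

    def counts(self) -> pd.Series:
        """Number of records n_i per subject."""
        return self.frame.groupby("subject_id", sort=True).size()

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        return isinstance(other, LongitudinalDataset) and self.frame.equals(other.frame)


class SurvivalDataset:
    """One row per subject: dropout/censoring time, event flag, baseline covariates."""

    def __init__(self, frame: pd.DataFrame):
        _check_columns(frame, SURVIVAL_COLUMNS, "survival table")
        frame = frame.loc[:, list(SURVIVAL_COLUMNS)].copy()
        _require_no_missing(frame, "survival table")
        frame["subject_id"] = frame["subject_id"].astype(str)
        frame["race"] = frame["race"].astype(str)
        try:
            frame["event_time_weeks"] = frame["event_time_weeks"].astype(float)
            frame["event"] = frame["event"].astype(int)
            frame["age_years"] = frame["age_years"].astype(float)
            frame["male"] = frame["male"].astype(int)
        except (TypeError, ValueError) as exc:
            raise CohortFormatError(f"survival table: non-numeric data ({exc})") from exc
        if len(frame) == 0:
            raise CohortValidationError("survival table: zero subjects disallowed")
        if frame["subject_id"].duplicated().any():
            bad = frame.loc[frame["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise CohortValidationError(f"subject {bad!r}: duplicate survival row")
        frame = frame.sort_values("subject_id", kind="mergesort").reset_index(drop=True)

        tev = frame["event_time_weeks"].to_numpy()
        if not np.all(np.isfinite(tev)) or np.any(tev <= 0):
            bad = frame.loc[~np.isfinite(tev) | (tev <= 0), "subject_id"].iloc[0]
            raise CohortValidationError(f"subject {bad!r}: event_time_weeks must be finite and > 0")
        for col, allowed in (("event", (0, 1)), ("male", (0, 1))):
            vals = frame[col].to_numpy()
            if not np.all(np.isin(vals, allowed)):
                bad = frame.loc[~np.isin(vals, allowed), "subject_id"].iloc[0]
                raise CohortValidationError(f"subject {bad!r}: {col} must be 0 or 1")
        if not np.all(np.isfinite(frame["age_years"].to_numpy())):
            bad = frame.loc[~np.isfinite(frame["age_years"]), "subject_id"].iloc[0]
            raise CohortValidationError(f"subject {bad!r}: age_years must be finite")
        bad_race = ~frame["race"].isin(RACE_LEVELS)
        if bad_race.any():
            bad = frame.loc[bad_race, "subject_id"].iloc[0]
            raise CohortValidationError(
                f"subject {bad!r}: race must be one of {list(RACE_LEVELS)}"
            )
        self.frame = frame

    @property
    def subject_ids(self) -> np.ndarray:
        return self.frame["subject_id"].to_numpy()

    @property
    def n_subjects(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        return isinstance(other, SurvivalDataset) and self.frame.equals(other.frame)


class LinkedCohort:
    """A longitudinal and a survival table describing the same subjects.

    Beyond the component invariants this enforces the dropout-truncation
    rule: a subject's last engagement observation cannot occur after their
    event/censoring time (once a participant drops out no engagement data
    exist).
    """

    def __init__(self, longitudinal: LongitudinalDataset, survival: SurvivalDataset):
        ids_long = set(longitudinal.subject_ids)
        ids_surv = set(survival.subject_ids)
        if ids_long != ids_surv:
            only_long = sorted(ids_long - ids_surv)[:3]
            only_surv = sorted(ids_surv - ids_long)[:3]
            raise CohortValidationError(
                "longitudinal and survival tables must cover identical subjects; "
                f"only longitudinal: {only_long}, only survival: {only_surv}"
            )
        last_obs = longitudinal.frame.groupby("subject_id", sort=True)["time_weeks"].max()
        tev = survival.frame.set_index("subject_id")["event_time_weeks"]
        late = last_obs.index[last_obs.to_numpy() > tev.loc[last_obs.index].to_numpy()]
        if len(late):
            raise CohortValidationError(
                f"subject {late[0]!r}: engagement observed after event/censoring time"
            )
        self.longitudinal = longitudinal
        self.survival = survival

    @property
    def subject_ids(self) -> np.ndarray:
        return self.survival.subject_ids

    @property
    def n_subjects(self) -> int:
        return self.survival.n_subjects

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LinkedCohort)
            and self.longitudinal == other.longitudinal
            and self.survival == other.survival
        )


def read_cohort(longitudinal_path, survival_path) -> LinkedCohort:
    """Read and validate the two cohort CSVs into a :class:`LinkedCohort`."""
    long_frame = pd.read_csv(
        longitudinal_path, dtype={"subject_id": str}, float_precision="round_trip"
    )
    surv_frame = pd.read_csv(
        survival_path, dtype={"subject_id": str}, float_precision="round_trip"
    )
    return LinkedCohort(LongitudinalDataset(long_frame), SurvivalDataset(surv_frame))


def write_cohort(cohort: LinkedCohort, longitudinal_path, survival_path) -> None:
    """Write the cohort as two CSVs; floats at full (round-trippable) precision."""
    if not isinstance(cohort, LinkedCohort):
        raise CohortValidationError("write_cohort requires a validated LinkedCohort")
    cohort.longitudinal.frame.to_csv(longitudinal_path, index=False, float_format="%.17g")
    cohort.survival.frame.to_csv(survival_path, index=False, float_format="%.17g")


@dataclass
class Design:
    """Model matrices shared by the longitudinal and hazard submodels.

    The longitudinal fixed-effect row for a record at week ``t`` is
    ``(1, t, t^2)`` and the random-effect row is ``(1, t)`` (random intercept
    and slope).  The hazard design has one row per subject in the fixed
    column order ``(age_centered, male, race_black, race_hispanic,
    race_other)`` with white as the race reference and age centered at the
    sample mean.
    """

    y: np.ndarray                 # (N,) engagement values, record order = (subject, time)
    X: np.ndarray                 # (N, 3) fixed-effect design (1, t, t^2)
    Z: np.ndarray                 # (N, 2) random-effect design (1, t)
    times: np.ndarray             # (N,) observation weeks
    subject_index: np.ndarray     # (N,) int index into subject_ids
    subject_ids: np.ndarray       # (n,) sorted subject ids
    W: np.ndarray                 # (n, 5) hazard covariates
    event_time: np.ndarray        # (n,) event/censoring week
    event: np.ndarray             # (n,) event indicator
    age_mean: float = field(default=0.0)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


def survival_design(survival: SurvivalDataset, age_center: float | None = None) -> tuple[np.ndarray, float]:
    """Hazard covariate matrix (age_centered, male, race dummies) and the age center used."""
    frame = survival.frame
    if age_center is None:
        age_center = float(frame["age_years"].mean())
    W = np.column_stack(
        [
            frame["age_years"].to_numpy() - age_center,
            frame["male"].to_numpy().astype(float),
            (frame["race"] == "black").to_numpy().astype(float),
            (frame["race"] == "hispanic").to_numpy().astype(float),
            (frame["race"] == "other").to_numpy().astype(float),
        ]
    )
    return W, age_center


def build_design(cohort: LinkedCohort, age_center: float | None = None) -> Design:
    """Construct all model matrices for a cohort (deterministic, column-order stable)."""
    lf = cohort.longitudinal.frame
    sf = cohort.survival.frame
    subject_ids = sf["subject_id"].to_numpy()
    index_of = {s: i for i, s in enumerate(subject_ids)}
    t = lf["time_weeks"].to_numpy()
    X = np.column_stack([np.ones_like(t), t, t**2])
    Z = np.column_stack([np.ones_like(t), t])
    W, age_center = survival_design(cohort.survival, age_center)
    return Design(
        y=lf["engagement_days"].to_numpy(),
        X=X,
        Z=Z,
        times=t,
        subject_index=np.array([index_of[s] for s in lf["subject_id"]], dtype=np.intp),
        subject_ids=subject_ids,
        W=W,
        event_time=sf["event_time_weeks"].to_numpy(),
        event=sf["event"].to_numpy().astype(float),
        age_mean=age_center,
    )
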