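"""Derivation of analysis variables from ART line lists.

This module reads and validates the three delimited inputs of the pipeline
(a patient table, a visit table and a Saturday session calendar) and derives
every analysis variable used downstream:

* primary reason for starting ART, deduced from WHO stage, CD4 count and
  pregnancy status against the national guideline thresholds in force in
  the year of initiation;
* the cumulative treatment outcome (transferred out, alive on ART, lost to
  follow-up, stopped, died) and the event/censoring time on the
  days-since-ART-initiation scale;
* eligibility for the adolescent study pool;
* time-dependent exposure to the Saturday peer-support clinic ("Teen Club"),
  ascertained as at least two visits falling on session dates strictly
  before a given index date.

All dates are ``datetime.date``; CSV files use ISO-8601 dates and RFC-4180
quoting (plain :func:`pandas.read_csv` / :meth:`DataFrame.to_csv`).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

SEX_LEVELS = ("male", "female")
WHO_STAGES = ("I", "II", "III", "IV", "unknown")

REASON_STAGE = "WHO Stage III/IV"
REASON_CD4 = "CD4 count"
REASON_PREGNANCY = "pregnancy/breastfeeding"
REASON_OTHER = "other/unknown"
ART_REASONS = (REASON_STAGE, REASON_CD4, REASON_PREGNANCY, REASON_OTHER)

OUTCOME_TRANSFERRED = "transferred_out"
OUTCOME_ALIVE = "alive_on_art"
OUTCOME_LTFU = "ltfu"
OUTCOME_STOPPED = "stopped"
OUTCOME_DIED = "died"
OUTCOMES = (OUTCOME_TRANSFERRED, OUTCOME_ALIVE, OUTCOME_LTFU, OUTCOME_STOPPED, OUTCOME_DIED)
CASE_OUTCOMES = frozenset({OUTCOME_LTFU, OUTCOME_STOPPED, OUTCOME_DIED})

INIT_AGE_GROUPS = ("<10", "10 to 14", "15 to 19")
SELECTION_AGE_GROUPS = ("10 to 14", "15 to 19", ">=20")
YEAR_BINS = ("2004 to 2005", "2006 to 2007", "2008 to 2010", "2011 to 2013", "2014 to 2015")

#: First month of the adolescent Saturday clinic and of study follow-up.
STUDY_WINDOW_START = dt.date(2010, 3, 1)
#: Administrative censoring date for the study.
STUDY_CENSOR_DATE = dt.date(2015, 12, 31)
#: Grace period (days) after the expected ART run-out before a patient is LTFU.
DEFAULT_GRACE_DAYS = 60

PATIENT_COLUMNS = [
    "patient_id", "sex", "birth_date", "art_start_date",
    "who_stage_at_start", "cd4_at_start", "pregnant_or_breastfeeding_at_start",
    "transfer_date", "death_date", "stop_date",
]
VISIT_COLUMNS = ["patient_id", "visit_date", "days_dispensed", "pre_art"]
SESSION_COLUMNS = ["session_date"]


class ValidationError(ValueError):
    """Raised when an input table violates its row-level contract."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


# ---------------------------------------------------------------------------
# Guideline eras (ART eligibility thresholds by calendar period)
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class GuidelineEra:
    """One national-guideline period: CD4 eligibility threshold and whether
    universal ART for pregnant/breastfeeding women ("Option B+") is active."""

    start: dt.date
    end: dt.date  # inclusive
    cd4_threshold: float
    option_b_plus: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"era start {self.start} after end {self.end}")
        if self.cd4_threshold <= 0:
            raise ValueError("cd4_threshold must be positive")


#: Default era table. Guideline revision years are 2003/2006/2008/2011/2014;
#: the CD4 thresholds shipped here (250 up to 2010, 350 for 2011-2013, 500
#: for 2014-2015) are configurable assumptions, not fixed constants.
DEFAULT_GUIDELINE_ERAS: tuple[GuidelineEra, ...] = (
    GuidelineEra(dt.date(2003, 1, 1), dt.date(2005, 12, 31), 250.0, False),
    GuidelineEra(dt.date(2006, 1, 1), dt.date(2007, 12, 31), 250.0, False),
    GuidelineEra(dt.date(2008, 1, 1), dt.date(2010, 12, 31), 250.0, False),
    GuidelineEra(dt.date(2011, 1, 1), dt.date(2013, 12, 31), 350.0, True),
    GuidelineEra(dt.date(2014, 1, 1), dt.date(2015, 12, 31), 500.0, True),
)


def era_for(date: dt.date, eras: Sequence[GuidelineEra] = DEFAULT_GUIDELINE_ERAS) -> GuidelineEra:
    """Return the guideline era covering ``date`` (error if uncovered)."""
    for era in eras:
        if era.start <= date <= era.end:
            return era
    raise ValueError(f"date {date} outside the guideline era table")


# ---------------------------------------------------------------------------
# Small date helpers
# ---------------------------------------------------------------------------

def completed_years(birth_date: dt.date, at: dt.date) -> int:
    """Age in completed years at ``at`` (day-level precision)."""
    years = at.year - birth_date.year
    if (at.month, at.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


def add_years(date: dt.date, years: int) -> dt.date:
    """Anniversary of ``date`` after ``years`` years (29 Feb maps to 28 Feb)."""
    try:
        return date.replace(year=date.year + years)
    except ValueError:
        return date.replace(year=date.year + years, day=28)


def initiation_age_group(birth_date: dt.date, art_start_date: dt.date) -> str:
    age = completed_years(birth_date, art_start_date)
    if age < 10:
        return "<10"
    if age <= 14:
        return "10 to 14"
    if age <= 19:
        return "15 to 19"
    return ">=20"


def selection_age_group(birth_date: dt.date, at: dt.date) -> str:
    """Age-at-selection bin; subjects are under observation only from age 10."""
    age = completed_years(birth_date, at)
    if age <= 14:
        return "10 to 14"
    if age <= 19:
        return "15 to 19"
    return ">=20"


def initiation_year_bin(art_start_date: dt.date) -> str:
    y = art_start_date.year
    if 2004 <= y <= 2005:
        return "2004 to 2005"
    if 2006 <= y <= 2007:
        return "2006 to 2007"
    if 2008 <= y <= 2010:
        return "2008 to 2010"
    if 2011 <= y <= 2013:
        return "2011 to 2013"
    if 2014 <= y <= 2015:
        return "2014 to 2015"
    raise ValueError(f"ART start year {y} outside the study year bins (2004-2015)")


# ---------------------------------------------------------------------------
# Variable derivations
# ---------------------------------------------------------------------------

def deduce_art_reason(
    who_stage: str,
    cd4: float | None,
    pregnant_or_breastfeeding: bool,
    art_start_date: dt.date,
    eras: Sequence[GuidelineEra] = DEFAULT_GUIDELINE_ERAS,
) -> str:
    """Deduce the primary reason for starting ART.

    Precedence follows the guideline algorithm for the initiation year:

    * once universal treatment of pregnant/breastfeeding women is active
      (2011 onward by default), pregnancy/breastfeeding overrides clinical
      and immunological status;
    * WHO clinical stage III/IV confers eligibility regardless of CD4;
    * stage I/II with a CD4 count under the era threshold is classified as
      a CD4-count initiation;
    * anything else (including missing CD4 at stage I/II) is other/unknown.
    """
    era = era_for(art_start_date, eras)
    if era.option_b_plus and pregnant_or_breastfeeding:
        return REASON_PREGNANCY
    if who_stage in ("III", "IV"):
        return REASON_STAGE
    if who_stage in ("I", "II") and cd4 is not None and not pd.isna(cd4) and cd4 < era.cd4_threshold:
        return REASON_CD4
    return REASON_OTHER


def classify_cumulative_outcome(
    record: Mapping,
    visits: Sequence[tuple[dt.date, int]],
    censor_date: dt.date = STUDY_CENSOR_DATE,
    grace_days: int = DEFAULT_GRACE_DAYS,
    ltfu_anchor: str = "runout",
) -> tuple[str, int]:
    """Classify the cumulative treatment outcome and its event/censor time.

    ``record`` is any mapping-like object (``dict``, ``pandas`` row) with
    ``art_start_date`` and the optional ``death_date``/``stop_date``/
    ``transfer_date``; ``visits`` is the patient's on-ART visit history as
    ``(visit_date, days_dispensed)`` pairs sorted by date.

    Outcome precedence is died > stopped > transferred_out > LTFU > alive.
    A patient is LTFU when the censoring date falls more than ``grace_days``
    after the expected run-out of the last dispensed supply. The LTFU event
    time is anchored at the run-out date itself — the last day the patient
    is known to have had treatment in hand — with the grace window acting
    only as the classification criterion; dating the event at the end of
    the grace window (``ltfu_anchor="runout_plus_grace"``) systematically
    over-ages matched controls' exposure in the risk-set sampler, because a
    lost patient's exposure cannot change after their last contact. Times
    are integer days since ART initiation.
    """
    if ltfu_anchor not in ("runout", "runout_plus_grace"):
        raise ValueError(f"unknown ltfu_anchor {ltfu_anchor!r}")
    start = record["art_start_date"]
    death = record.get("death_date")
    stop = record.get("stop_date")
    transfer = record.get("transfer_date")
    if death is not None and not pd.isna(death):
        return OUTCOME_DIED, (death - start).days
    if stop is not None and not pd.isna(stop):
        return OUTCOME_STOPPED, (stop - start).days
    if transfer is not None and not pd.isna(transfer):
        return OUTCOME_TRANSFERRED, (transfer - start).days
    if not visits:
        raise ValueError(
            f"patient {record.get('patient_id', '?')}: no on-ART visits; cannot classify outcome"
        )
    last_date, last_dispensed = visits[-1]
    runout = last_date + dt.timedelta(days=int(last_dispensed))
    if censor_date > runout + dt.timedelta(days=grace_days):
        event = (runout - start).days
        if ltfu_anchor == "runout_plus_grace":
            event += grace_days
        return OUTCOME_LTFU, event
    return OUTCOME_ALIVE, (censor_date - start).days


def ascertain_exposure(
    visit_dates: Iterable[dt.date],
    calendar: Sequence[dt.date],
    index_date: dt.date,
    threshold: int = 2,
) -> bool:
    """True when at least ``threshold`` distinct visit dates fall on session
    dates strictly before ``index_date`` (exposure at the time of selection)."""
    sessions = set(calendar)
    count = len({d for d in visit_dates if d in sessions and d < index_date})
    return count >= threshold


def teen_club_visit_fraction(
    visit_dates: Sequence[dt.date],
    calendar: Sequence[dt.date],
) -> float | None:
    """Fraction of visits on session dates among all visits on or after the
    first session-date visit; ``None`` for patients with no session visit."""
    sessions = set(calendar)
    session_dates = sorted(d for d in set(visit_dates) if d in sessions)
    if not session_dates:
        return None
    first = session_dates[0]
    later = [d for d in visit_dates if d >= first]
    return sum(d in sessions for d in later) / len(later)


# ---------------------------------------------------------------------------
# Study pool
# ---------------------------------------------------------------------------

def build_study_pool(
    patients: pd.DataFrame,
    visits: pd.DataFrame,
    eras: Sequence[GuidelineEra] = DEFAULT_GUIDELINE_ERAS,
    window_start: dt.date = STUDY_WINDOW_START,
    censor_date: dt.date = STUDY_CENSOR_DATE,
    min_followup_days: int = 90,
    ltfu_anchor: str = "runout",
) -> pd.DataFrame:
    """Derive the adolescent study pool with all analysis variables attached.

    Inclusion: initiated ART aged 10-19 on/after ``window_start``, or
    initiated before age ten and turned ten on/after ``window_start`` (and
    survived in care to that tenth birthday). Exclusions: ART started for
    pregnancy/breastfeeding; follow-up shorter than ``min_followup_days``.

    Returns one row per subject with columns: patient_id, sex, birth_date,
    art_start_date, art_initiation_age_group, initiation_year_bin,
    art_reason, cumulative_outcome, is_case, event_or_censor_time,
    observation_start_time.
    """
    visit_hist = _visit_histories(visits)
    rows = []
    for rec in patients.to_dict("records"):
        start: dt.date = rec["art_start_date"]
        birth: dt.date = rec["birth_date"]
        init_age = completed_years(birth, start)
        if init_age >= 20:
            continue
        if 10 <= init_age <= 19:
            if start < window_start:
                continue
            obs_start = 0
        else:  # initiated before age ten
            tenth = add_years(birth, 10)
            if tenth < window_start:
                continue
            obs_start = (tenth - start).days
        reason = deduce_art_reason(
            rec["who_stage_at_start"], rec["cd4_at_start"],
            bool(rec["pregnant_or_breastfeeding_at_start"]), start, eras,
        )
        if reason == REASON_PREGNANCY:
            continue
        outcome, event_time = classify_cumulative_outcome(
            rec, visit_hist.get(rec["patient_id"], ()), censor_date,
            ltfu_anchor=ltfu_anchor,
        )
        if event_time < min_followup_days:
            continue
        if event_time < obs_start:
            # never reached adolescent eligibility while in care
            continue
        rows.append({
            "patient_id": rec["patient_id"],
            "sex": rec["sex"],
            "birth_date": birth,
            "art_start_date": start,
            "art_initiation_age_group": initiation_age_group(birth, start),
            "initiation_year_bin": initiation_year_bin(start),
            "art_reason": reason,
            "cumulative_outcome": outcome,
            "is_case": outcome in CASE_OUTCOMES,
            "event_or_censor_time": event_time,
            "observation_start_time": obs_start,
        })
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "sex", "birth_date", "art_start_date",
            "art_initiation_age_group", "initiation_year_bin", "art_reason",
            "cumulative_outcome", "is_case", "event_or_censor_time",
            "observation_start_time",
        ],
    )


def _visit_histories(visits: pd.DataFrame) -> dict[str, list[tuple[dt.date, int]]]:
    """On-ART visit histories keyed by patient, sorted by date."""
    on_art = visits[visits["pre_art"] == 0] if "pre_art" in visits.columns else visits
    hist: dict[str, list[tuple[dt.date, int]]] = {}
    for pid, date, disp in zip(
        on_art["patient_id"], on_art["visit_date"], on_art["days_dispensed"]
    ):
        hist.setdefault(pid, []).append((date, int(disp)))
    for seq in hist.values():
        seq.sort(key=lambda t: t[0])
    return hist


def session_visit_ordinals(
    visits: pd.DataFrame, calendar: Sequence[dt.date]
) -> dict[str, np.ndarray]:
    """Per-patient sorted arrays of proleptic ordinals of session-date visits.

    Includes flagged pre-ART visits: attendance before ART initiation counts
    toward the exposure threshold.
    """
    sessions = set(calendar)
    out: dict[str, list[int]] = {}
    for pid, date in zip(visits["patient_id"], visits["visit_date"]):
        if date in sessions:
            out.setdefault(pid, []).append(date.toordinal())
    return {pid: np.array(sorted(set(v)), dtype=np.int64) for pid, v in out.items()}


def exposed_at(ordinals: np.ndarray | None, index_date: dt.date, threshold: int = 2) -> bool:
    """Exposure test against a precomputed ordinal array (strictly-before rule)."""
    if ordinals is None or len(ordinals) == 0:
        return False
    return int(np.searchsorted(ordinals, index_date.toordinal(), side="left")) >= threshold


# ---------------------------------------------------------------------------
# Delimited IO with validation
# ---------------------------------------------------------------------------

def _parse_date(value) -> dt.date | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


def _date_str(value: dt.date | None) -> str:
    return "" if value is None else value.isoformat()


def read_patients(path, validate: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError([f"patients table missing columns: {missing}"])
    for col in ("birth_date", "art_start_date", "transfer_date", "death_date", "stop_date"):
        df[col] = df[col].map(_parse_date)
    df["cd4_at_start"] = pd.to_numeric(df["cd4_at_start"], errors="coerce")
    df["pregnant_or_breastfeeding_at_start"] = (
        df["pregnant_or_breastfeeding_at_start"].fillna(0).astype(int)
    )
    if validate:
        errors = validate_patients(df)
        if errors:
            raise ValidationError(errors)
    return df


def validate_patients(df: pd.DataFrame) -> list[str]:
    errors = []
    seen: set[str] = set()
    for rec in df.to_dict("records"):
        pid = rec["patient_id"]
        if pid in seen:
            errors.append(f"{pid}: duplicate patient_id")
        seen.add(pid)
        if rec["sex"] not in SEX_LEVELS:
            errors.append(f"{pid}: invalid sex {rec['sex']!r}")
        if rec["who_stage_at_start"] not in WHO_STAGES:
            errors.append(f"{pid}: invalid WHO stage {rec['who_stage_at_start']!r}")
        if rec["birth_date"] is None or rec["art_start_date"] is None:
            errors.append(f"{pid}: missing birth or ART start date")
            continue
        if rec["art_start_date"] < rec["birth_date"]:
            errors.append(f"{pid}: ART start before birth")
        terminal = [
            d for d in (rec["transfer_date"], rec["death_date"], rec["stop_date"])
            if d is not None
        ]
        if len(terminal) > 1:
            errors.append(f"{pid}: more than one terminal event date recorded")
    return errors


def write_patients(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in ("birth_date", "art_start_date", "transfer_date", "death_date", "stop_date"):
        out[col] = out[col].map(_date_str)
    out["cd4_at_start"] = out["cd4_at_start"].map(
        lambda v: "" if v is None or pd.isna(v) else f"{float(v):g}"
    )
    out.to_csv(path, index=False, lineterminator="\n")


def read_visits(path, validate: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in ("patient_id", "visit_date", "days_dispensed") if c not in df.columns]
    if missing:
        raise ValidationError([f"visits table missing columns: {missing}"])
    df["visit_date"] = df["visit_date"].map(_parse_date)
    if "pre_art" not in df.columns:
        df["pre_art"] = 0
    df["pre_art"] = df["pre_art"].fillna(0).astype(int)
    df["days_dispensed"] = df["days_dispensed"].astype(int)
    if validate:
        errors = validate_visits(df)
        if errors:
            raise ValidationError(errors)
    return df


def validate_visits(df: pd.DataFrame) -> list[str]:
    errors = []
    for i, rec in enumerate(df.to_dict("records")):
        if rec["visit_date"] is None:
            errors.append(f"visit row {i} ({rec['patient_id']}): missing date")
        if rec["days_dispensed"] < 1:
            errors.append(
                f"visit row {i} ({rec['patient_id']}): days_dispensed must be >= 1"
            )
    return errors


def write_visits(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["visit_date"] = out["visit_date"].map(_date_str)
    out.to_csv(path, index=False, lineterminator="\n")


def read_sessions(path, validate: bool = True) -> list[dt.date]:
    df = pd.read_csv(path)
    if "session_date" not in df.columns:
        raise ValidationError(["sessions table missing column session_date"])
    dates = [_parse_date(v) for v in df["session_date"]]
    if validate:
        errors = validate_sessions(dates)
        if errors:
            raise ValidationError(errors)
    return dates


def validate_sessions(dates: Sequence[dt.date]) -> list[str]:
    errors = []
    for i, d in enumerate(dates):
        if d is None:
            errors.append(f"session row {i}: missing date")
            continue
        if d.weekday() != 5:
            errors.append(f"session row {i}: {d} is not a Saturday")
        if i and dates[i - 1] is not None and d <= dates[i - 1]:
            errors.append(f"session row {i}: dates not strictly increasing at {d}")
    return errors


def write_sessions(dates: Sequence[dt.date], path) -> None:
    pd.DataFrame({"session_date": [d.isoformat() for d in dates]}).to_csv(
        path, index=False, lineterminator="\n"
    )
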