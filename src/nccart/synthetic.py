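"""Synthetic EMR cohort generator for the nested case-control pipeline.

Emulates the three line-list tables the analysis consumes — patients,
visits, and a monthly Saturday session calendar — with the statistical
structure the design assumes:

* ART initiation dates uniform over an enrollment window, with initiation
  ages drawn from three strata (<10, 10-14, 15-19 years);
* refill visits every 30 days for the first six months, then every 60-90
  days, shifted onto weekdays (routine clinic days are Monday-Friday);
* delayed adoption of the Saturday peer-support sessions, with post-adoption
  visits landing on session dates with a configurable adherence probability;
* attrition on a 30-day discrete hazard grid, where current exposure
  (having attended at least two session-date visits strictly before the
  cycle start) multiplies the baseline hazard by a rate ratio ``theta``;
* documented transfers, and a configurable fraction of attrition events
  recorded as deaths or treatment stops — the remainder simply stop
  visiting, exactly the silence the LTFU classifier must detect.

A ground-truth table (adoption, exposure-onset, attrition and transfer
dates) accompanies every cohort for parameter-recovery tests; it is not an
input to the analysis.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from bisect import bisect_left
from typing import Sequence

import numpy as np
import pandas as pd

from .derive import STUDY_CENSOR_DATE, STUDY_WINDOW_START

# Adoption-delay strata: sessions attended from before ART initiation,
# within 1 month of it, after 2-3 / 4-12 / 13-24 / >24 months, or never.
ADOPTION_STRATA = (
    "before_art", "within_1_month", "2_to_3_months",
    "4_to_12_months", "13_to_24_months", "over_24_months", "never",
)
#: Delay intervals (days since ART start) for each adopting stratum.
_DELAY_BOUNDS = {
    "before_art": (-180, -1),
    "within_1_month": (0, 30),
    "2_to_3_months": (31, 90),
    "4_to_12_months": (91, 365),
    "13_to_24_months": (366, 730),
    "over_24_months": (731, 1825),
}

#: Observed adopter mix: 302 of 617 subjects attended at least two sessions,
#: with adopter delays distributed 17/30/49/52/31/123 over the six strata.
DEFAULT_ADOPTION_DISTRIBUTION = tuple(
    np.array([17, 30, 49, 52, 31, 123, 315], dtype=float) / 617.0
)

#: Initiation-age stratum mix (<10, 10-14, 15-19) from the study pool.
DEFAULT_AGE_DISTRIBUTION = (0.431, 0.337, 0.232)

CYCLE_DAYS = 30


def _validate_probability_vector(name: str, vec: Sequence[float], length: int) -> None:
    arr = np.asarray(vec, dtype=float)
    if arr.shape != (length,):
        raise ValueError(f"{name} must have length {length}")
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError(f"{name} entries must lie in [0, 1]")
    if abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (got {arr.sum()!r})")


@dataclasses.dataclass
class SimulationConfig:
    """Data-generating assumptions for one synthetic cohort.

    Hazards are per-30-day-cycle probabilities; ``exposure_rate_ratio`` is
    the multiplicative effect of current session exposure on the attrition
    hazard and is the quantity the incidence-density odds ratio estimates.
    """

    n_patients: int = 1200
    enrollment_start: dt.date = dt.date(2004, 1, 1)
    enrollment_end: dt.date = dt.date(2015, 9, 30)
    age_at_start_distribution: tuple[float, float, float] = DEFAULT_AGE_DISTRIBUTION
    baseline_attrition_hazard: float = 0.0035
    exposure_rate_ratio: float = 0.3
    adoption_delay_distribution: tuple[float, ...] = DEFAULT_ADOPTION_DISTRIBUTION
    session_adherence: float = 0.85
    transfer_hazard: float = 0.0025
    death_fraction: float = 18.0 / 135.0
    stop_fraction: float = 1.0 / 135.0
    refill_days_initial: int = 30
    refill_days_later: tuple[int, int] = (60, 90)
    stabilization_days: int = 180
    admin_censor_date: dt.date = STUDY_CENSOR_DATE
    session_calendar_start: dt.date = STUDY_WINDOW_START
    female_fraction: float = 0.569
    pregnancy_fraction: float = 0.08
    stage34_fraction: float = 0.635
    low_cd4_fraction: float = 0.80
    cd4_missing_fraction: float = 0.30
    coarsen_birth_to_year: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if self.enrollment_start >= self.enrollment_end:
            raise ValueError("enrollment window is empty")
        _validate_probability_vector(
            "age_at_start_distribution", self.age_at_start_distribution, 3
        )
        _validate_probability_vector(
            "adoption_delay_distribution", self.adoption_delay_distribution, 7
        )
        for name in (
            "baseline_attrition_hazard", "session_adherence", "transfer_hazard",
            "death_fraction", "stop_fraction", "female_fraction",
            "pregnancy_fraction", "stage34_fraction", "low_cd4_fraction",
            "cd4_missing_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.death_fraction + self.stop_fraction > 1.0:
            raise ValueError("death_fraction + stop_fraction must not exceed 1")
        if self.exposure_rate_ratio <= 0:
            raise ValueError("exposure_rate_ratio must be > 0")
        if self.refill_days_initial < 1 or min(self.refill_days_later) < 1:
            raise ValueError("refill day counts must be >= 1")


@dataclasses.dataclass
class CohortTables:
    """The generated line lists plus the simulation ground truth."""

    patients: pd.DataFrame
    visits: pd.DataFrame
    sessions: list[dt.date]
    truth: pd.DataFrame


# ---------------------------------------------------------------------------
# Session calendar
# ---------------------------------------------------------------------------

def generate_session_calendar(start_date: dt.date, end_date: dt.date) -> list[dt.date]:
    """First-Saturday-of-the-month session dates within ``[start, end]``.

    Exactly one session per calendar month whose first Saturday falls in the
    interval; deterministic given the interval.
    """
    if start_date >= end_date:
        raise ValueError("session calendar interval is empty")
    dates = []
    year, month = start_date.year, start_date.month
    while (year, month) <= (end_date.year, end_date.month):
        first = dt.date(year, month, 1)
        saturday = first + dt.timedelta(days=(5 - first.weekday()) % 7)
        if start_date <= saturday <= end_date:
            dates.append(saturday)
        month += 1
        if month == 13:
            month, year = 1, year + 1
    return dates


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _weekday_shift(ordinal: int) -> int:
    """Move weekend dates to the following Monday (routine clinic days)."""
    wd = (ordinal - 1) % 7  # Monday == 0: proleptic ordinal 1 is a Monday
    if wd == 5:
        return ordinal + 2
    if wd == 6:
        return ordinal + 1
    return ordinal


def _nearest_session(sess: list[int], target: int, window: int = 40) -> int | None:
    """Session ordinal nearest to ``target`` within ``window`` days, if any."""
    if not sess:
        return None
    i = bisect_left(sess, target)
    best = None
    for j in (i - 1, i):
        if 0 <= j < len(sess):
            if best is None or abs(sess[j] - target) < abs(best - target):
                best = sess[j]
    if best is not None and abs(best - target) <= window:
        return best
    return None


def _geometric(rng: np.random.Generator, p: float, size: int) -> np.ndarray:
    """Cycle index (1-based) of the first success; ``inf``-like sentinel for p=0."""
    if p <= 0.0:
        return np.full(size, np.iinfo(np.int64).max // 2, dtype=np.int64)
    return rng.geometric(min(p, 1.0), size=size).astype(np.int64)


def generate_cohort(config: SimulationConfig) -> CohortTables:
    """Simulate one cohort; identical config + seed gives identical tables."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    start_ord0 = config.enrollment_start.toordinal()
    start_ord1 = config.enrollment_end.toordinal()
    censor_ord = config.admin_censor_date.toordinal()

    sessions = generate_session_calendar(
        config.session_calendar_start, config.admin_censor_date
    )
    sess_ords = [d.toordinal() for d in sessions]
    sess_set = set(sess_ords)

    # Pre-drawn randomness in a fixed order (keeps output byte-reproducible).
    strata = rng.choice(3, size=n, p=np.asarray(config.age_at_start_distribution))
    age_u = rng.random(n)
    start_u = rng.random(n)
    sex_u = rng.random(n)
    preg_u = rng.random(n)
    stage_u = rng.random(n)
    lowcd4_u = rng.random(n)
    cd4_u = rng.random(n)
    cd4_missing_u = rng.random(n)
    adoption_cat = rng.choice(7, size=n, p=np.asarray(config.adoption_delay_distribution))
    delay_u = rng.random(n)
    max_visits = (censor_ord - start_ord0) // CYCLE_DAYS + 8
    adherence_u = rng.random((n, max_visits))
    refill_u = rng.random((n, max_visits))
    transfer_cycle = _geometric(rng, config.transfer_hazard, n)
    h0 = config.baseline_attrition_hazard
    h1 = min(h0 * config.exposure_rate_ratio, 1.0)
    attr_unexposed = _geometric(rng, h0, n)
    attr_exposed = _geometric(rng, h1, n)
    type_u = rng.random(n)

    age_bounds = {0: (2 * 365, 10 * 365 - 1), 1: (10 * 365, 15 * 365 - 1), 2: (15 * 365, 20 * 365 - 1)}

    patient_rows, visit_rows, truth_rows = [], [], []
    for i in range(n):
        pid = f"P{i + 1:05d}"
        start = _weekday_shift(start_ord0 + int(start_u[i] * (start_ord1 - start_ord0)))
        lo, hi = age_bounds[int(strata[i])]
        age_days = lo + int(age_u[i] * (hi - lo + 1))
        birth = start - age_days
        if config.coarsen_birth_to_year:
            by = dt.date.fromordinal(birth).year
            birth = dt.date(by, 1, 1).toordinal()
        sex = "female" if sex_u[i] < config.female_fraction else "male"
        init_age_years = age_days // 365
        pregnant = int(
            sex == "female" and init_age_years >= 15 and preg_u[i] < config.pregnancy_fraction
        )
        who_stage, cd4 = _stage_and_cd4(
            config, dt.date.fromordinal(start),
            stage_u[i], lowcd4_u[i], cd4_u[i], cd4_missing_u[i],
        )

        cat = ADOPTION_STRATA[int(adoption_cat[i])]
        if cat == "never":
            adoption_cand = None
        else:
            d_lo, d_hi = _DELAY_BOUNDS[cat]
            adoption_cand = start + d_lo + int(delay_u[i] * (d_hi - d_lo + 1))

        # --- pre-ART session attendance (before-ART adopters only) ---
        j = 0  # per-patient draw index into the (adherence, refill) rows
        pre_visits: list[int] = []
        if adoption_cand is not None and adoption_cand < start:
            k = bisect_left(sess_ords, adoption_cand)
            while k < len(sess_ords) and sess_ords[k] < start:
                if adherence_u[i, j] < config.session_adherence:
                    pre_visits.append(sess_ords[k])
                j += 1
                k += 1

        # --- potential on-ART visit schedule up to administrative censoring ---
        visits: list[tuple[int, int, bool]] = []  # (ordinal, days dispensed, on session)
        session_dates: list[int] = list(pre_visits)
        next_d = start
        while next_d <= censor_ord and len(visits) < max_visits and j < max_visits:
            actual, is_sess = None, False
            if adoption_cand is not None and next_d >= adoption_cand:
                if adherence_u[i, j] < config.session_adherence:
                    s = _nearest_session(sess_ords, next_d)
                    prev = visits[-1][0] if visits else (pre_visits[-1] if pre_visits else -1)
                    if s is not None and s > prev and s > start and s <= censor_ord:
                        actual, is_sess = s, True
            j += 1
            if actual is None:
                actual = _weekday_shift(next_d)
                if actual > censor_ord:
                    break
            if actual - start < config.stabilization_days:
                disp = config.refill_days_initial
            else:
                disp = config.refill_days_later[int(refill_u[i, len(visits)] >= 0.5)]
            visits.append((actual, disp, is_sess))
            if is_sess:
                session_dates.append(actual)
            next_d = actual + disp

        # --- exposure onset and piecewise-geometric attrition cycle ---
        # Exposure (>=2 session visits) multiplies the hazard from the cycle
        # strictly after the second attended session.
        if len(session_dates) >= 2:
            onset = session_dates[1]
            first_exposed_cycle = max((onset - start) // CYCLE_DAYS + 2, 1)
        else:
            first_exposed_cycle = None
        k0 = int(attr_unexposed[i])
        if first_exposed_cycle is None or k0 < first_exposed_cycle:
            attr_cycle = k0
        else:
            attr_cycle = first_exposed_cycle - 1 + int(attr_exposed[i])
        attr_day = start + CYCLE_DAYS * attr_cycle
        trans_day = start + CYCLE_DAYS * int(transfer_cycle[i])

        death_date = stop_date = transfer_date = None
        attrition_date = attrition_type = None
        if attr_day <= censor_ord and attr_day <= trans_day:
            cut = attr_day
            attrition_date = attr_day
            if type_u[i] < config.death_fraction:
                attrition_type = "death"
                death_date = attr_day
            elif type_u[i] < config.death_fraction + config.stop_fraction:
                attrition_type = "stop"
                stop_date = attr_day
            else:
                attrition_type = "ltfu"
        elif trans_day <= censor_ord:
            cut = trans_day
            transfer_date = trans_day
        else:
            cut = censor_ord + 1

        kept = [(d, disp, s) for (d, disp, s) in visits if d < cut]
        realized_sessions = pre_visits + [d for (d, _, s) in kept if s]

        patient_rows.append((
            pid, sex, birth, start, who_stage, cd4, pregnant,
            transfer_date, death_date, stop_date,
        ))
        for d in pre_visits:
            visit_rows.append((pid, d, config.refill_days_initial, 1))
        for d, disp, _ in kept:
            visit_rows.append((pid, d, disp, 0))
        truth_rows.append((
            pid,
            realized_sessions[0] if realized_sessions else None,
            realized_sessions[1] if len(realized_sessions) >= 2 else None,
            attrition_date, attrition_type, transfer_date,
        ))

    patients = pd.DataFrame(
        patient_rows,
        columns=[
            "patient_id", "sex", "birth_date", "art_start_date",
            "who_stage_at_start", "cd4_at_start",
            "pregnant_or_breastfeeding_at_start",
            "transfer_date", "death_date", "stop_date",
        ],
    )
    for col in ("birth_date", "art_start_date", "transfer_date", "death_date", "stop_date"):
        patients[col] = patients[col].map(_from_ordinal)
    visits_df = pd.DataFrame(
        visit_rows, columns=["patient_id", "visit_date", "days_dispensed", "pre_art"]
    )
    visits_df["visit_date"] = visits_df["visit_date"].map(_from_ordinal)
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "patient_id", "true_adoption_date", "true_exposure_onset_date",
            "true_attrition_date", "true_attrition_type", "true_transfer_date",
        ],
    )
    for col in ("true_adoption_date", "true_exposure_onset_date",
                "true_attrition_date", "true_transfer_date"):
        truth[col] = truth[col].map(_from_ordinal)
    return CohortTables(patients, visits_df, sessions, truth)


def _from_ordinal(value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return dt.date.fromordinal(int(value))


def _stage_and_cd4(config, start_date, stage_u, lowcd4_u, cd4_u, miss_u):
    """Baseline WHO stage and CD4 consistent with the era threshold mix."""
    from .derive import era_for

    threshold = era_for(start_date).cd4_threshold
    if stage_u < config.stage34_fraction:
        stage = "III" if stage_u < config.stage34_fraction / 2 else "IV"
        cd4 = 50.0 + round(cd4_u * 850.0)
        if miss_u < config.cd4_missing_fraction:
            cd4 = None
    else:
        stage = "I" if stage_u < (1 + config.stage34_fraction) / 2 else "II"
        if lowcd4_u < config.low_cd4_fraction:
            cd4 = 50.0 + round(cd4_u * (threshold - 51.0))
        else:
            cd4 = threshold + round(cd4_u * (900.0 - threshold))
            if miss_u < config.cd4_missing_fraction:
                cd4 = None
    return stage, cd4


def write_cohort(tables: CohortTables, directory) -> dict[str, str]:
    """Write patients/visits/sessions/truth CSVs; returns the path map."""
    import os

    from . import derive

    os.makedirs(directory, exist_ok=True)
    paths = {
        "patients": os.path.join(directory, "patients.csv"),
        "visits": os.path.join(directory, "visits.csv"),
        "sessions": os.path.join(directory, "sessions.csv"),
        "truth": os.path.join(directory, "truth.csv"),
    }
    derive.write_patients(tables.patients, paths["patients"])
    derive.write_visits(tables.visits, paths["visits"])
    derive.write_sessions(tables.sessions, paths["sessions"])
    truth = tables.truth.copy()
    for col in ("true_adoption_date", "true_exposure_onset_date",
                "true_attrition_date", "true_transfer_date"):
        truth[col] = truth[col].map(lambda d: "" if d is None else d.isoformat())
    truth["true_attrition_type"] = truth["true_attrition_type"].map(lambda v: v or "")
    truth.to_csv(paths["truth"], index=False, lineterminator="\n")
    return paths
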