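"""Variable derivation: ART reason, outcome classification, pool, exposure."""

import datetime as dt

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nccart import (
    ValidationError,
    ascertain_exposure,
    build_study_pool,
    classify_cumulative_outcome,
    deduce_art_reason,
    read_patients,
    read_sessions,
    read_visits,
    teen_club_visit_fraction,
    write_patients,
    write_sessions,
    write_visits,
)
from nccart.derive import exposed_at, session_visit_ordinals


# ---------------------------------------------------------------------------
# ART reason algorithm
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "stage, cd4, pregnant, start, expected",
    [
        # stage III/IV wins regardless of CD4
        ("III", 600.0, False, dt.date(2009, 6, 1), "WHO Stage III/IV"),
        # stage I/II below the era threshold (2009 default threshold 250)
        ("II", 200.0, False, dt.date(2009, 6, 1), "CD4 count"),
        # universal treatment in pregnancy overrides stage after 2011
        ("IV", 100.0, True, dt.date(2013, 6, 1), "pregnancy/breastfeeding"),
        # before 2011 pregnancy does not override the CD4 pathway
        ("I", 180.0, True, dt.date(2009, 6, 1), "CD4 count"),
        # stage I/II above threshold
        ("I", 400.0, False, dt.date(2009, 6, 1), "other/unknown"),
        # missing CD4 at stage I/II cannot be classified
        ("II", None, False, dt.date(2012, 6, 1), "other/unknown"),
        # era-dependent threshold: 300 is below the 2011-2013 threshold of 350
        ("II", 300.0, False, dt.date(2012, 6, 1), "CD4 count"),
    ],
)
def test_art_reason_algorithm(stage, cd4, pregnant, start, expected):
    assert deduce_art_reason(stage, cd4, pregnant, start) == expected


def test_art_reason_outside_era_table_errors():
    with pytest.raises(ValueError, match="era"):
        deduce_art_reason("III", None, False, dt.date(1999, 1, 1))


# ---------------------------------------------------------------------------
# Cumulative outcome classification
# ---------------------------------------------------------------------------

def _record(**kwargs):
    rec = {
        "patient_id": "X1",
        "art_start_date": dt.date(2015, 1, 1),
        "death_date": None,
        "stop_date": None,
        "transfer_date": None,
    }
    rec.update(kwargs)
    return rec


def test_ltfu_when_no_return_within_grace_after_runout():
    visits = [(dt.date(2015, 6, 1), 30)]
    outcome, t = classify_cumulative_outcome(
        _record(), visits, censor_date=dt.date(2015, 12, 31)
    )
    assert outcome == "ltfu"
    # event anchored at the expected run-out of the last 30-day supply
    assert dt.date(2015, 1, 1) + dt.timedelta(days=t) == dt.date(2015, 7, 1)


def test_ltfu_grace_anchor_variant_dates_event_at_end_of_grace():
    visits = [(dt.date(2015, 6, 1), 30)]
    outcome, t = classify_cumulative_outcome(
        _record(), visits, censor_date=dt.date(2015, 12, 31),
        ltfu_anchor="runout_plus_grace",
    )
    assert outcome == "ltfu"
    assert dt.date(2015, 1, 1) + dt.timedelta(days=t) == dt.date(2015, 8, 30)


def test_alive_when_censor_within_grace_of_runout():
    visits = [(dt.date(2015, 11, 15), 60)]
    outcome, t = classify_cumulative_outcome(
        _record(), visits, censor_date=dt.date(2015, 12, 31)
    )
    assert outcome == "alive_on_art"
    assert t == (dt.date(2015, 12, 31) - dt.date(2015, 1, 1)).days


def test_recorded_death_takes_precedence_over_visit_pattern():
    visits = [(dt.date(2015, 6, 1), 30)]
    outcome, t = classify_cumulative_outcome(
        _record(death_date=dt.date(2015, 2, 1)), visits,
        censor_date=dt.date(2015, 12, 31),
    )
    assert outcome == "died"
    assert t == 31


@pytest.mark.parametrize(
    "field, expected",
    [("stop_date", "stopped"), ("transfer_date", "transferred_out")],
)
def test_stop_and_transfer_classification(field, expected):
    visits = [(dt.date(2015, 2, 1), 30)]
    outcome, t = classify_cumulative_outcome(
        _record(**{field: dt.date(2015, 3, 1)}), visits,
        censor_date=dt.date(2015, 12, 31),
    )
    assert outcome == expected
    assert t == 59


def test_no_visits_is_an_error():
    with pytest.raises(ValueError, match="no on-ART visits"):
        classify_cumulative_outcome(_record(), [], censor_date=dt.date(2015, 12, 31))


# ---------------------------------------------------------------------------
# Study pool eligibility
# ---------------------------------------------------------------------------

def _patients_frame(rows):
    base = {
        "sex": "female",
        "who_stage_at_start": "III",
        "cd4_at_start": None,
        "pregnant_or_breastfeeding_at_start": 0,
        "transfer_date": None,
        "death_date": None,
        "stop_date": None,
    }
    return pd.DataFrame([{**base, **r} for r in rows])


def _steady_visits(pid, start, end):
    out = []
    d = start
    while d <= end:
        out.append({"patient_id": pid, "visit_date": d, "days_dispensed": 30, "pre_art": 0})
        d += dt.timedelta(days=30)
    return out


def test_pool_eligibility_rules():
    patients = _patients_frame([
        # child initiator turning ten after the study opened: included
        {"patient_id": "A", "birth_date": dt.date(2001, 6, 1),
         "art_start_date": dt.date(2008, 1, 1)},
        # adolescent initiator during the study window: included
        {"patient_id": "B", "birth_date": dt.date(1998, 1, 1),
         "art_start_date": dt.date(2012, 1, 1)},
        # adolescent initiator BEFORE the study window: excluded
        {"patient_id": "C", "birth_date": dt.date(1996, 1, 1),
         "art_start_date": dt.date(2008, 1, 1)},
        # pregnancy-reason initiation: excluded
        {"patient_id": "D", "birth_date": dt.date(1997, 1, 1),
         "art_start_date": dt.date(2012, 6, 1), "who_stage_at_start": "I",
         "pregnant_or_breastfeeding_at_start": 1},
        # follow-up shorter than three months: excluded
        {"patient_id": "E", "birth_date": dt.date(2000, 1, 1),
         "art_start_date": dt.date(2015, 11, 15)},
        # child initiator who turned ten before March 2010: excluded
        {"patient_id": "F", "birth_date": dt.date(1999, 6, 1),
         "art_start_date": dt.date(2008, 1, 1)},
    ])
    visits = pd.DataFrame(
        _steady_visits("A", dt.date(2008, 1, 1), dt.date(2015, 12, 1))
        + _steady_visits("B", dt.date(2012, 1, 1), dt.date(2015, 12, 1))
        + _steady_visits("C", dt.date(2008, 1, 1), dt.date(2015, 12, 1))
        + _steady_visits("D", dt.date(2012, 6, 1), dt.date(2015, 12, 1))
        + _steady_visits("E", dt.date(2015, 11, 15), dt.date(2015, 12, 15))
        + _steady_visits("F", dt.date(2008, 1, 1), dt.date(2015, 12, 1))
    )
    pool = build_study_pool(patients, visits)
    assert set(pool["patient_id"]) == {"A", "B"}
    a = pool.set_index("patient_id").loc["A"]
    # observation starts at the tenth birthday for child initiators
    assert a["observation_start_time"] == (dt.date(2011, 6, 1) - dt.date(2008, 1, 1)).days
    assert a["art_initiation_age_group"] == "<10"
    b = pool.set_index("patient_id").loc["B"]
    assert b["observation_start_time"] == 0
    assert b["art_initiation_age_group"] == "10 to 14"


def test_pool_outcome_partition_and_case_flag(small_pool):
    assert small_pool["cumulative_outcome"].isin(
        ["transferred_out", "alive_on_art", "ltfu", "stopped", "died"]
    ).all()
    expected_flag = small_pool["cumulative_outcome"].isin(["ltfu", "stopped", "died"])
    assert (small_pool["is_case"] == expected_flag).all()
    assert (small_pool["event_or_censor_time"] >= small_pool["observation_start_time"]).all()
    assert (small_pool["observation_start_time"] >= 0).all()


# ---------------------------------------------------------------------------
# Exposure ascertainment
# ---------------------------------------------------------------------------

CAL = [dt.date(2010, 3, 6), dt.date(2010, 4, 3), dt.date(2010, 5, 1)]


@pytest.mark.parametrize(
    "visit_dates, index_date, expected",
    [
        # one session visit before index: unexposed
        ([dt.date(2010, 3, 6)], dt.date(2010, 6, 1), False),
        # two session visits before index: exposed
        ([dt.date(2010, 3, 6), dt.date(2010, 4, 3)], dt.date(2010, 6, 1), True),
        # second session on the index date itself does not count (strictly before)
        ([dt.date(2010, 3, 6), dt.date(2010, 4, 3)], dt.date(2010, 4, 3), False),
        # weekday visits never count
        ([dt.date(2010, 3, 8), dt.date(2010, 4, 5)], dt.date(2010, 6, 1), False),
        # duplicate session dates count once
        ([dt.date(2010, 3, 6), dt.date(2010, 3, 6)], dt.date(2010, 6, 1), False),
    ],
)
def test_ascertain_exposure_threshold(visit_dates, index_date, expected):
    assert ascertain_exposure(visit_dates, CAL, index_date) is expected


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    offsets=st.lists(st.integers(0, 400), min_size=0, max_size=30),
    t1=st.integers(0, 500),
    t2=st.integers(0, 500),
)
def test_exposure_is_monotone_in_index_time(calendar, offsets, t1, t2):
    """Once exposed, a subject stays exposed at every later index date."""
    base = dt.date(2010, 3, 1)
    visit_dates = [base + dt.timedelta(days=o) for o in offsets]
    lo, hi = sorted((t1, t2))
    early = ascertain_exposure(visit_dates, calendar, base + dt.timedelta(days=lo))
    late = ascertain_exposure(visit_dates, calendar, base + dt.timedelta(days=hi))
    assert late or not early


def test_ascertained_exposure_agrees_with_ground_truth(small_cohort):
    """Cross-module round trip: the generator's true exposure-onset date and
    the ascertainment rule agree at every index date on a quarterly grid."""
    ords = session_visit_ordinals(small_cohort.visits, small_cohort.sessions)
    truth = small_cohort.truth.set_index("patient_id")
    for rec in small_cohort.patients.to_dict("records"):
        pid = rec["patient_id"]
        onset = truth.loc[pid, "true_exposure_onset_date"]
        for days in range(0, 2200, 90):
            index = rec["art_start_date"] + dt.timedelta(days=days)
            expected = onset is not None and onset < index
            assert exposed_at(ords.get(pid), index) == expected


# ---------------------------------------------------------------------------
# Session-visit fraction
# ---------------------------------------------------------------------------

def test_visit_fraction_counts_from_first_session_visit(calendar):
    first = calendar[0]
    later = [calendar[1], calendar[2], calendar[3],
             first + dt.timedelta(days=2)]  # one weekday visit
    assert teen_club_visit_fraction([first] + later, calendar) == 4 / 5


def test_visit_fraction_complete_attendance_is_one(calendar):
    assert teen_club_visit_fraction(calendar[:4], calendar) == 1.0


def test_visit_fraction_undefined_for_non_attender(calendar):
    assert teen_club_visit_fraction([dt.date(2011, 3, 7)], calendar) is None


# ---------------------------------------------------------------------------
# IO round trip and validation
# ---------------------------------------------------------------------------

def test_write_read_round_trip(small_cohort, tmp_path):
    write_patients(small_cohort.patients, tmp_path / "patients.csv")
    write_visits(small_cohort.visits, tmp_path / "visits.csv")
    write_sessions(small_cohort.sessions, tmp_path / "sessions.csv")
    patients = read_patients(tmp_path / "patients.csv")
    visits = read_visits(tmp_path / "visits.csv")
    sessions = read_sessions(tmp_path / "sessions.csv")
    assert sessions == small_cohort.sessions
    pd.testing.assert_frame_equal(
        visits, small_cohort.visits.reset_index(drop=True), check_dtype=False
    )
    for col in small_cohort.patients.columns:
        if col == "cd4_at_start":
            got = patients[col].fillna(-1)
            want = small_cohort.patients[col].astype(float).fillna(-1)
            assert (got.to_numpy() == want.to_numpy()).all()
        else:
            assert patients[col].where(patients[col].notna(), None).tolist() == \
                small_cohort.patients[col].tolist()


def test_validation_reports_row_level_errors(tmp_path):
    df = pd.DataFrame([{
        "patient_id": "BAD1", "sex": "female",
        "birth_date": "2001-01-01", "art_start_date": "2012-01-01",
        "who_stage_at_start": "III", "cd4_at_start": "",
        "pregnant_or_breastfeeding_at_start": 0,
        "transfer_date": "2013-01-01", "death_date": "2013-06-01",
        "stop_date": "",
    }])
    path = tmp_path / "patients.csv"
    df.to_csv(path, index=False)
    with pytest.raises(ValidationError, match="BAD1.*terminal"):
        read_patients(path)


def test_session_validation_rejects_non_saturdays(tmp_path):
    path = tmp_path / "sessions.csv"
    pd.DataFrame({"session_date": ["2010-03-08"]}).to_csv(path, index=False)
    with pytest.raises(ValidationError, match="not a Saturday"):
        read_sessions(path)
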