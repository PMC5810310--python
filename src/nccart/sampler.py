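"""Stratified incidence-density (risk-set) control sampling.

Every subject whose cumulative outcome is LTFU, stopped or died is a case
at its event time (days since ART initiation). For each case, controls are
drawn uniformly without replacement from the risk set: subjects in the same
ART-initiation-age stratum who were under observation and still retained in
care at that follow-up time — including future cases, whose own event lies
strictly later. Exposure and age-at-selection are evaluated at each row's
own index calendar date (the subject's ART start plus the case's follow-up
time), so a late adopter sampled early is correctly unexposed.

Two replacement policies are provided: ``no_reuse_across_cases`` (default;
a subject serves as a control at most once) and ``reuse_allowed`` (classical
risk-set sampling, under which the exposure odds ratio is a consistent
estimator of the attrition rate ratio).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Sequence

import numpy as np
import pandas as pd

from .derive import (
    OUTCOME_TRANSFERRED,
    exposed_at,
    selection_age_group,
    session_visit_ordinals,
)

NO_REUSE = "no_reuse_across_cases"
REUSE = "reuse_allowed"


@dataclasses.dataclass
class SamplerConfig:
    controls_per_case: int = 3
    matching_stratum: str = "art_initiation_age_group"
    time_scale: str = "days_since_art_start"
    replacement_policy: str = NO_REUSE
    exposure_threshold: int = 2
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.controls_per_case < 1:
            raise ValueError("controls_per_case must be >= 1")
        if self.replacement_policy not in (NO_REUSE, REUSE):
            raise ValueError(f"unknown replacement_policy {self.replacement_policy!r}")
        if self.time_scale not in ("days_since_art_start", "days_since_eligibility"):
            raise ValueError(f"unknown time_scale {self.time_scale!r}")


@dataclasses.dataclass
class RiskSet:
    """The eligible control pool for one case at its index time."""

    case_id: str
    index_time: int
    stratum: str
    eligible_ids: list[str]


def _index_times(pool: pd.DataFrame, config: SamplerConfig) -> pd.Series:
    """Follow-up time on the configured scale (event time, optionally shifted
    to the days-since-eligibility origin for child initiators)."""
    t = pool["event_or_censor_time"]
    if config.time_scale == "days_since_eligibility":
        t = t - pool["observation_start_time"]
    return t


def enumerate_case_events(
    pool: pd.DataFrame, config: SamplerConfig | None = None
) -> pd.DataFrame:
    """All cases ordered by index time ascending, ties broken by patient id."""
    config = config or SamplerConfig()
    cases = pool[pool["is_case"]].copy()
    cases["index_time"] = _index_times(cases, config)
    return cases.sort_values(
        ["index_time", "patient_id"], kind="mergesort"
    ).reset_index(drop=True)


def _eligibility_mask(
    t: int,
    case_id: str,
    ids: np.ndarray,
    times: np.ndarray,
    is_case: np.ndarray,
    transferred: np.ndarray,
    obs_start: np.ndarray,
) -> np.ndarray:
    """Risk-set membership at follow-up time ``t``.

    Future cases must have their event strictly after ``t``; transferred
    subjects must transfer strictly after ``t``; administratively censored
    subjects are retained *at* their censor time, so equality is eligible.
    """
    retained = np.where(
        is_case | transferred, times > t, times >= t
    )
    return retained & (obs_start <= t) & (ids != case_id)


def build_risk_set(
    case: pd.Series | dict,
    pool: pd.DataFrame,
    config: SamplerConfig | None = None,
) -> RiskSet:
    """Enumerate the eligible controls for one case (self excluded)."""
    config = config or SamplerConfig()
    t = int(case["index_time"]) if "index_time" in case else int(case["event_or_censor_time"])
    stratum = case[config.matching_stratum]
    sub = pool[pool[config.matching_stratum] == stratum]
    mask = _eligibility_mask(
        t,
        case["patient_id"],
        sub["patient_id"].to_numpy(),
        _index_times(sub, config).to_numpy(),
        sub["is_case"].to_numpy(bool),
        (sub["cumulative_outcome"] == OUTCOME_TRANSFERRED).to_numpy(),
        sub["observation_start_time"].to_numpy(),
    )
    return RiskSet(case["patient_id"], t, stratum, list(sub["patient_id"].to_numpy()[mask]))


def sample_controls(
    risk_set: RiskSet,
    config: SamplerConfig,
    rng: np.random.Generator,
    used: set[str] | None = None,
) -> list[str]:
    """Uniform draw without replacement of up to ``controls_per_case`` ids.

    Under the no-reuse policy, ids in ``used`` are removed before drawing;
    shortfalls yield fewer controls (never borrowed across strata).
    """
    candidates = risk_set.eligible_ids
    if config.replacement_policy == NO_REUSE and used:
        candidates = [c for c in candidates if c not in used]
    k = min(config.controls_per_case, len(candidates))
    if k == 0:
        return []
    chosen = rng.choice(len(candidates), size=k, replace=False)
    return [candidates[int(i)] for i in sorted(chosen)]


def draw_sampled_set(
    pool: pd.DataFrame,
    visits: pd.DataFrame,
    calendar: Sequence[dt.date],
    config: SamplerConfig | None = None,
    case_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Run the full 3:1 (configurable) incidence-density selection.

    Returns the sampled case-control table (one row per subject-role, with
    exposure evaluated at its own index calendar date) and a per-case log of
    risk-set sizes and shortfalls. ``case_ids`` restricts sampling to a
    subset of case events (e.g. an earlier data-extraction cutoff); the
    remaining cases stay eligible as controls before their own events.
    """
    config = config or SamplerConfig()
    rng = np.random.default_rng(config.seed)
    cases = enumerate_case_events(pool, config)
    if case_ids is not None:
        wanted = set(case_ids)
        cases = cases[cases["patient_id"].isin(wanted)].reset_index(drop=True)
    session_ords = session_visit_ordinals(visits, calendar)
    by_id = pool.set_index("patient_id", drop=False)

    # Per-stratum flat arrays for fast risk-set masks.
    strata: dict[str, dict[str, np.ndarray]] = {}
    for stratum, sub in pool.groupby(config.matching_stratum, sort=True):
        strata[stratum] = {
            "ids": sub["patient_id"].to_numpy(),
            "times": _index_times(sub, config).to_numpy(),
            "is_case": sub["is_case"].to_numpy(bool),
            "transferred": (sub["cumulative_outcome"] == OUTCOME_TRANSFERRED).to_numpy(),
            "obs_start": sub["observation_start_time"].to_numpy(),
            "used": np.zeros(len(sub), dtype=bool),
        }

    rows: list[dict] = []
    log: list[dict] = []
    for case in cases.itertuples(index=False):
        t = int(case.index_time)
        arrs = strata[getattr(case, config.matching_stratum)]
        mask = _eligibility_mask(
            t, case.patient_id, arrs["ids"], arrs["times"],
            arrs["is_case"], arrs["transferred"], arrs["obs_start"],
        )
        n_eligible = int(mask.sum())
        if config.replacement_policy == NO_REUSE:
            mask &= ~arrs["used"]
        candidates = np.flatnonzero(mask)
        k = min(config.controls_per_case, len(candidates))
        chosen = np.sort(rng.choice(candidates, size=k, replace=False)) if k else np.array([], int)
        if config.replacement_policy == NO_REUSE:
            arrs["used"][chosen] = True
        log.append({
            "case_id": case.patient_id,
            "index_time": t,
            "stratum": getattr(case, config.matching_stratum),
            "risk_set_size": n_eligible,
            "n_controls": int(k),
            "shortfall": int(config.controls_per_case - k),
        })
        rows.append(_subject_row(case.patient_id, "case", case.patient_id, t,
                                 by_id, session_ords, config))
        for idx in chosen:
            rows.append(_subject_row(str(arrs["ids"][idx]), "control", case.patient_id,
                                     t, by_id, session_ords, config))
    sampled = pd.DataFrame(
        rows,
        columns=[
            "patient_id", "role", "case_id", "index_time", "index_date",
            "exposed", "sex", "age_at_selection_group",
            "art_initiation_age_group", "art_reason", "initiation_year_bin",
        ],
    )
    return sampled, log


def _subject_row(pid, role, case_id, t, by_id, session_ords, config):
    subj = by_id.loc[pid]
    start: dt.date = subj["art_start_date"]
    offset = t
    if config.time_scale == "days_since_eligibility":
        offset = t + int(subj["observation_start_time"])
    index_date = start + dt.timedelta(days=int(offset))
    exposed = exposed_at(session_ords.get(pid), index_date, config.exposure_threshold)
    return {
        "patient_id": pid,
        "role": role,
        "case_id": case_id,
        "index_time": int(t),
        "index_date": index_date,
        "exposed": "yes" if exposed else "no",
        "sex": subj["sex"],
        "age_at_selection_group": selection_age_group(subj["birth_date"], index_date),
        "art_initiation_age_group": subj["art_initiation_age_group"],
        "art_reason": subj["art_reason"],
        "initiation_year_bin": subj["initiation_year_bin"],
    }


def write_sampled_set(sampled: pd.DataFrame, path) -> None:
    out = sampled.copy()
    out["index_date"] = out["index_date"].map(lambda d: d.isoformat())
    out.to_csv(path, index=False, lineterminator="\n")


def read_sampled_set(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "case_id": str})
    df["index_date"] = df["index_date"].map(dt.date.fromisoformat)
    return df
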