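"""End-to-end orchestration: simulate -> derive -> sample -> infer.

One root seed is split per stage (simulation, control sampling) via
``numpy.random.SeedSequence``, and every output is deterministic given the
configuration, so two runs of the same config produce byte-identical
bundles. The report bundle mirrors the shapes a retention study reports:

* a study-pool summary comparing attenders and non-attenders;
* attendance patterns for attenders (adoption delay, age at first session,
  fraction of subsequent visits on session dates);
* case-control characteristics with chi-square comparisons;
* a crude and adjusted odds-ratio table from the multivariable logistic
  model, plus a machine-readable run manifest.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
import os
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import derive, inference, sampler as sampler_mod, synthetic
from .derive import (
    INIT_AGE_GROUPS, OUTCOMES, SELECTION_AGE_GROUPS, YEAR_BINS,
    completed_years, session_visit_ordinals, teen_club_visit_fraction,
)
from .inference import CovariateSpec, EffectEstimate, ZeroCellError
from .sampler import SamplerConfig, draw_sampled_set
from .synthetic import CohortTables, SimulationConfig, generate_cohort

logger = logging.getLogger("nccart")

ADOPTION_DELAY_CATEGORIES = (
    "before ART initiation", "within 1 month", "2 to 3 months",
    "4 to 12 months", "13 to 24 months", "over 24 months",
)
FRACTION_CATEGORIES = ("<75%", "75% to 89%", "90% to 99%", "100%")
FIRST_VISIT_AGE_GROUPS = ("<10", "10 to 14", "15 to 19", ">=20")

ART_REASON_LEVELS = (
    derive.REASON_STAGE, derive.REASON_CD4, derive.REASON_OTHER,
)

#: Covariates of the multivariable model, with Table-style reference levels.
DEFAULT_MODEL_TERMS = (
    CovariateSpec("exposed", "no", ("no", "yes")),
    CovariateSpec("sex", "male", ("male", "female")),
    CovariateSpec("age_at_selection_group", "10 to 14", SELECTION_AGE_GROUPS),
    CovariateSpec("art_initiation_age_group", "<10", INIT_AGE_GROUPS),
    CovariateSpec("art_reason", derive.REASON_STAGE, ART_REASON_LEVELS),
    CovariateSpec("initiation_year_bin", "2008 to 2010", YEAR_BINS),
)


class PipelineError(RuntimeError):
    """A stage failure with the stage label attached."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclasses.dataclass
class PipelineConfig:
    """Either a simulation block or paths to the three input tables."""

    output_dir: str = "nccart_out"
    seed: int = 0
    log_level: str = "INFO"
    simulate: SimulationConfig | None = None
    patients_path: str | None = None
    visits_path: str | None = None
    sessions_path: str | None = None
    sampler: SamplerConfig = dataclasses.field(default_factory=SamplerConfig)
    min_followup_days: int = 90

    def __post_init__(self) -> None:
        has_paths = any((self.patients_path, self.visits_path, self.sessions_path))
        if self.simulate is not None and has_paths:
            raise ValueError("config must set either a simulation block or input paths, not both")
        if self.simulate is None and not (
            self.patients_path and self.visits_path and self.sessions_path
        ):
            raise ValueError("config must set a simulation block or all three input paths")

    @classmethod
    def from_dict(cls, data: dict, seed_override: int | None = None) -> "PipelineConfig":
        data = dict(data)
        sim = data.pop("simulate", None)
        inputs = data.pop("inputs", {}) or {}
        samp = data.pop("sampler", {}) or {}
        cfg = cls(
            output_dir=data.get("output_dir", "nccart_out"),
            seed=int(data.get("seed", 0)),
            log_level=data.get("log_level", "INFO"),
            simulate=_simulation_config(sim) if sim is not None else None,
            patients_path=inputs.get("patients"),
            visits_path=inputs.get("visits"),
            sessions_path=inputs.get("sessions"),
            sampler=SamplerConfig(**samp),
            min_followup_days=int(data.get("min_followup_days", 90)),
        )
        if seed_override is not None:
            cfg.seed = seed_override
        return cfg

    @classmethod
    def from_yaml(cls, path, seed_override: int | None = None) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data, seed_override)


def _simulation_config(block: dict) -> SimulationConfig:
    block = dict(block)
    for key in ("enrollment_start", "enrollment_end", "admin_censor_date",
                "session_calendar_start"):
        if key in block and isinstance(block[key], str):
            block[key] = dt.date.fromisoformat(block[key])
    for key in ("age_at_start_distribution", "adoption_delay_distribution",
                "refill_days_later"):
        if key in block:
            block[key] = tuple(block[key])
    return SimulationConfig(**block)


@dataclasses.dataclass
class ReportBundle:
    pool: pd.DataFrame
    sampled: pd.DataFrame
    risk_set_log: list[dict]
    pool_summary: pd.DataFrame
    attenders: pd.DataFrame
    case_control_summary: pd.DataFrame
    effects: pd.DataFrame
    manifest: dict
    output_dir: str


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def load_or_simulate(config: PipelineConfig) -> CohortTables:
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=_stage_seed(config.seed, 0))
        return generate_cohort(sim)
    for label, path in (("patients", config.patients_path),
                        ("visits", config.visits_path),
                        ("sessions", config.sessions_path)):
        if not os.path.exists(path):
            raise FileNotFoundError(f"{label} file not found: {path}")
    patients = derive.read_patients(config.patients_path)
    visits = derive.read_visits(config.visits_path)
    sessions = derive.read_sessions(config.sessions_path)
    return CohortTables(patients, visits, sessions, pd.DataFrame())


def _stage_seed(root_seed: int, stage: int) -> int:
    children = np.random.SeedSequence(root_seed).spawn(4)
    return int(children[stage].generate_state(1)[0] % (2**31 - 1))


def crude_exposure_estimate(sampled: pd.DataFrame, **kwargs) -> EffectEstimate:
    """Crude exposure odds ratio (exposed vs not) from a sampled set."""
    table = inference.crosstab(
        sampled, "exposed", "role", row_order=("yes", "no"),
        col_order=("case", "control"),
    )
    return inference.odds_ratio_wald(table, **kwargs)


def cohort_crude_exposure_or(
    sim_config: SimulationConfig,
    sampler_config: SamplerConfig | None = None,
) -> tuple[EffectEstimate, pd.DataFrame]:
    """Simulate one cohort, run derivation + sampling, return the crude
    exposure odds ratio and the sampled set (consistency-check workhorse)."""
    tables = generate_cohort(sim_config)
    pool = derive.build_study_pool(tables.patients, tables.visits)
    sampled, _ = draw_sampled_set(pool, tables.visits, tables.sessions, sampler_config)
    return crude_exposure_estimate(sampled), sampled


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def _summary_block(df: pd.DataFrame, var: str, levels: Sequence, group: str,
                   group_levels: Sequence) -> list[dict]:
    table = inference.crosstab(df, var, group, row_order=levels, col_order=group_levels)
    if table.empty or table.shape[0] < 2 or (table.to_numpy().sum(axis=0) == 0).any():
        p = float("nan")
    else:
        try:
            _, _, p = inference.pearson_chi_square(table)
        except ValueError:
            p = float("nan")
    pct = inference.column_percentages(table) if not table.empty else table
    rows = []
    for i, level in enumerate(table.index):
        row = {"variable": var, "level": level}
        for g in table.columns:
            row[f"{g}_n"] = int(table.loc[level, g])
            denom = table[g].sum()
            row[f"{g}_pct"] = round(float(pct.loc[level, g]), 1) if denom else 0.0
        row["p_value"] = round(p, 4) if i == 0 and p == p else None
        rows.append(row)
    return rows


def render_pool_summary(pool: pd.DataFrame, visits: pd.DataFrame,
                        calendar: Sequence[dt.date],
                        censor_date: dt.date = derive.STUDY_CENSOR_DATE) -> pd.DataFrame:
    """Study-pool characteristics by attender status (>=2 sessions ever)."""
    ords = session_visit_ordinals(visits, calendar)
    horizon = censor_date + dt.timedelta(days=1)
    pool = pool.copy()
    pool["attender"] = [
        "attender" if derive.exposed_at(ords.get(pid), horizon) else "non-attender"
        for pid in pool["patient_id"]
    ]
    pool["current_age_group"] = [
        derive.selection_age_group(b, censor_date) for b in pool["birth_date"]
    ]
    rows = []
    groups = ("non-attender", "attender")
    for var, levels in (
        ("sex", derive.SEX_LEVELS),
        ("art_initiation_age_group", INIT_AGE_GROUPS),
        ("current_age_group", SELECTION_AGE_GROUPS),
        ("art_reason", ART_REASON_LEVELS),
        ("initiation_year_bin", YEAR_BINS),
        ("cumulative_outcome", OUTCOMES),
    ):
        rows.extend(_summary_block(pool, var, levels, "attender", groups))
    return pd.DataFrame(rows)


def render_table3(pool: pd.DataFrame, visits: pd.DataFrame,
                  calendar: Sequence[dt.date]) -> pd.DataFrame:
    """Attendance patterns for attenders (>=2 session visits) in the pool.

    Adoption-delay strata use 30-day blocks (<=30 d maps to "within 1
    month", 31-90 d to "2 to 3 months", then 91-365, 366-730, >730);
    fraction categories split at 75/90/100% of post-first-session visits.
    """
    ords = session_visit_ordinals(visits, calendar)
    by_patient = {pid: sub for pid, sub in visits.groupby("patient_id")}
    delay_counts = dict.fromkeys(ADOPTION_DELAY_CATEGORIES, 0)
    age_counts = dict.fromkeys(FIRST_VISIT_AGE_GROUPS, 0)
    frac_counts = dict.fromkeys(FRACTION_CATEGORIES, 0)
    n_attenders = 0
    for rec in pool.to_dict("records"):
        sess = ords.get(rec["patient_id"])
        if sess is None or len(sess) < 2:
            continue
        n_attenders += 1
        first = dt.date.fromordinal(int(sess[0]))
        delay = (first - rec["art_start_date"]).days
        delay_counts[_delay_category(delay)] += 1
        age = completed_years(rec["birth_date"], first)
        age_counts[_first_visit_age_group(age)] += 1
        dates = list(by_patient[rec["patient_id"]]["visit_date"])
        frac = teen_club_visit_fraction(dates, calendar)
        if frac is not None:
            frac_counts[_fraction_category(frac)] += 1
    rows = []
    for section, counts in (
        ("time_on_art_before_first_session", delay_counts),
        ("age_at_first_session", age_counts),
        ("session_visit_fraction", frac_counts),
    ):
        for level, n in counts.items():
            pct = 100.0 * n / n_attenders if n_attenders else 0.0
            rows.append({"section": section, "level": level,
                         "n": n, "pct": round(pct, 1)})
    return pd.DataFrame(rows, columns=["section", "level", "n", "pct"])


def _delay_category(days: int) -> str:
    if days < 0:
        return "before ART initiation"
    if days <= 30:
        return "within 1 month"
    if days <= 90:
        return "2 to 3 months"
    if days <= 365:
        return "4 to 12 months"
    if days <= 730:
        return "13 to 24 months"
    return "over 24 months"


def _first_visit_age_group(age: int) -> str:
    if age < 10:
        return "<10"
    if age <= 14:
        return "10 to 14"
    if age <= 19:
        return "15 to 19"
    return ">=20"


def _fraction_category(frac: float) -> str:
    if frac < 0.75:
        return "<75%"
    if frac < 0.90:
        return "75% to 89%"
    if frac < 1.0:
        return "90% to 99%"
    return "100%"


def render_case_control_summary(sampled: pd.DataFrame) -> pd.DataFrame:
    """Case/control characteristics with chi-square comparisons."""
    rows = []
    for var, levels in (
        ("sex", derive.SEX_LEVELS),
        ("art_initiation_age_group", INIT_AGE_GROUPS),
        ("age_at_selection_group", SELECTION_AGE_GROUPS),
        ("art_reason", ART_REASON_LEVELS),
        ("initiation_year_bin", YEAR_BINS),
        ("exposed", ("no", "yes")),
    ):
        rows.extend(_summary_block(sampled, var, levels, "role", ("control", "case")))
    return pd.DataFrame(rows)


def crude_estimates(
    sampled: pd.DataFrame,
    terms: Sequence[CovariateSpec] = DEFAULT_MODEL_TERMS,
) -> dict[tuple[str, object], EffectEstimate | None]:
    """Per-level crude odds ratios (level vs its term's reference)."""
    out: dict[tuple[str, object], EffectEstimate | None] = {}
    is_case = sampled["role"] == "case"
    for spec in terms:
        values = sampled[spec.name]
        levels = spec.levels or tuple(pd.unique(values))
        for level in levels:
            if level == spec.reference:
                continue
            table = np.array([
                [int((is_case & (values == level)).sum()),
                 int((~is_case & (values == level)).sum())],
                [int((is_case & (values == spec.reference)).sum()),
                 int((~is_case & (values == spec.reference)).sum())],
            ])
            try:
                out[(spec.name, level)] = inference.odds_ratio_wald(table)
            except ZeroCellError:
                out[(spec.name, level)] = None
    return out


def render_effects(
    sampled: pd.DataFrame,
    terms: Sequence[CovariateSpec] = DEFAULT_MODEL_TERMS,
) -> tuple[pd.DataFrame, inference.LogisticFit]:
    """Crude and adjusted odds-ratio table from the multivariable model."""
    work = sampled.copy()
    work["is_case"] = (work["role"] == "case").astype(int)
    terms = [dataclasses.replace(s, levels=_present_levels(work, s)) for s in terms]
    fit = inference.fit_logistic_irls(work, "is_case", terms)
    crude = crude_estimates(work, terms)
    table = inference.summarize_model(fit, crude, terms)
    return table, fit


def _present_levels(df: pd.DataFrame, spec: CovariateSpec) -> tuple:
    present = set(pd.unique(df[spec.name]))
    levels = spec.levels or tuple(sorted(present, key=str))
    return tuple(l for l in levels if l in present)


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run every stage and write the report bundle to ``config.output_dir``."""
    os.makedirs(config.output_dir, exist_ok=True)
    _configure_logging(config)
    stage = "load"
    try:
        tables = load_or_simulate(config)
        if config.simulate is not None:
            synthetic.write_cohort(tables, os.path.join(config.output_dir, "data"))
        logger.info("load: %d patients, %d visits, %d sessions",
                    len(tables.patients), len(tables.visits), len(tables.sessions))

        stage = "derive"
        pool = derive.build_study_pool(
            tables.patients, tables.visits, min_followup_days=config.min_followup_days
        )
        if pool.empty:
            logger.warning("derive: study pool is empty")
        logger.info("derive: pool of %d subjects, %d cases",
                    len(pool), int(pool["is_case"].sum()))

        stage = "sample"
        samp_cfg = dataclasses.replace(config.sampler, seed=_stage_seed(config.seed, 1))
        sampled, risk_log = draw_sampled_set(pool, tables.visits, tables.sessions, samp_cfg)
        for entry in risk_log:
            if entry["shortfall"]:
                logger.warning("sample: case %s shortfall of %d controls (risk set %d)",
                               entry["case_id"], entry["shortfall"], entry["risk_set_size"])
        logger.info("sample: %d rows (%d cases, %d controls)",
                    len(sampled), int((sampled["role"] == "case").sum()),
                    int((sampled["role"] == "control").sum()))

        stage = "analyze"
        pool_summary = render_pool_summary(pool, tables.visits, tables.sessions)
        attenders = render_table3(pool, tables.visits, tables.sessions)
        cc_summary = render_case_control_summary(sampled)
        effects, fit = render_effects(sampled)
        logger.info("analyze: model converged in %d iterations; %d levels dropped",
                    fit.n_iter, len(fit.dropped_levels))

        stage = "report"
        manifest = _manifest(config, tables, pool, sampled, risk_log, fit)
        _write_bundle(config.output_dir, pool, sampled, risk_log, pool_summary,
                      attenders, cc_summary, effects, manifest)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    return ReportBundle(pool, sampled, risk_log, pool_summary, attenders,
                        cc_summary, effects, manifest, config.output_dir)


def _configure_logging(config: PipelineConfig) -> None:
    # Deliberately timestamp-free so report bundles are byte-reproducible.
    handler = logging.FileHandler(
        os.path.join(config.output_dir, "run.log"), mode="w"
    )
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.handlers = [h for h in logger.handlers if not isinstance(h, logging.FileHandler)]
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))


def _config_hash(config: PipelineConfig) -> str:
    def default(obj):
        if isinstance(obj, dt.date):
            return obj.isoformat()
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        return str(obj)

    fields = dataclasses.asdict(config)
    fields.pop("output_dir", None)  # where the bundle lands is not a study condition
    payload = json.dumps(fields, default=default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _manifest(config, tables, pool, sampled, risk_log, fit) -> dict:
    sizes = sorted(e["risk_set_size"] for e in risk_log)
    hist: dict[str, int] = {}
    for s in sizes:
        bucket = f"{(s // 50) * 50}-{(s // 50) * 50 + 49}"
        hist[bucket] = hist.get(bucket, 0) + 1
    return {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_patients": int(len(tables.patients)),
        "n_visits": int(len(tables.visits)),
        "n_sessions": int(len(tables.sessions)),
        "pool_size": int(len(pool)),
        "n_cases": int(pool["is_case"].sum()) if len(pool) else 0,
        "sampled_rows": int(len(sampled)),
        "n_controls": int((sampled["role"] == "control").sum()) if len(sampled) else 0,
        "shortfall_cases": int(sum(1 for e in risk_log if e["shortfall"])),
        "risk_set_size_histogram": hist,
        "model_iterations": fit.n_iter,
        "dropped_levels": [f"{t}[{l}]" for t, l in fit.dropped_levels],
    }


def _write_bundle(outdir, pool, sampled, risk_log, pool_summary, attenders,
                  cc_summary, effects, manifest) -> None:
    pool_out = pool.copy()
    for col in ("birth_date", "art_start_date"):
        pool_out[col] = pool_out[col].map(lambda d: d.isoformat())
    pool_out.to_csv(os.path.join(outdir, "pool.csv"), index=False, lineterminator="\n")
    sampler_mod.write_sampled_set(sampled, os.path.join(outdir, "sampled.csv"))
    pd.DataFrame(risk_log).to_csv(
        os.path.join(outdir, "risk_sets.csv"), index=False, lineterminator="\n"
    )
    pool_summary.to_csv(os.path.join(outdir, "pool_summary.csv"),
                        index=False, lineterminator="\n")
    attenders.to_csv(os.path.join(outdir, "attenders.csv"),
                     index=False, lineterminator="\n")
    cc_summary.to_csv(os.path.join(outdir, "case_control_summary.csv"),
                      index=False, lineterminator="\n")
    effects.to_csv(os.path.join(outdir, "effects.csv"), index=False, lineterminator="\n")
    with open(os.path.join(outdir, "effects.txt"), "w") as fh:
        fh.write(format_effects_text(effects))
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def format_effects_text(effects: pd.DataFrame) -> str:
    """Aligned plain-text rendering of the effects table."""
    widths = {
        col: max(len(col), *(len(str(v)) for v in effects[col])) if len(effects) else len(col)
        for col in effects.columns
    }
    lines = ["  ".join(col.ljust(widths[col]) for col in effects.columns)]
    lines.append("  ".join("-" * widths[col] for col in effects.columns))
    for _, row in effects.iterrows():
        lines.append("  ".join(str(row[col]).ljust(widths[col]) for col in effects.columns))
    return "\n".join(lines) + "\n"
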