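"""Statistics for the case-control analysis.

Self-contained numerics for the three quantities the report needs:

* Pearson chi-square tests on r x c contingency tables (no continuity
  correction);
* crude odds ratios from 2 x 2 tables with Wald confidence intervals on the
  log-odds scale;
* unconditional multivariable logistic regression fitted by iteratively
  reweighted least squares (IRLS), with dummy coding against explicit
  reference levels and transparent handling of perfectly predictive levels
  (they are dropped and reported, never silently absorbed).

``scipy`` supplies only distribution tails; the estimators themselves are
implemented here so that every reported number has a single auditable path.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

# Critical value carried at full precision; rounding happens only in reports.
Z_975 = float(stats.norm.ppf(0.975))


class ZeroCellError(ValueError):
    """A 2x2 cell is zero; suggest the Haldane-Anscombe 0.5 correction."""


class SeparationError(RuntimeError):
    """The likelihood is unbounded (perfect separation)."""


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: list[tuple[int, float, float]]):
        super().__init__(message)
        self.trace = trace


# ---------------------------------------------------------------------------
# Contingency tables
# ---------------------------------------------------------------------------

def crosstab(df: pd.DataFrame, row_var: str, col_var: str,
             row_order: Sequence | None = None,
             col_order: Sequence | None = None) -> pd.DataFrame:
    """Exact integer cross-tabulation of two columns."""
    for var in (row_var, col_var):
        if var not in df.columns:
            raise KeyError(f"unknown variable {var!r}")
    table = pd.crosstab(df[row_var], df[col_var])
    if row_order is not None:
        table = table.reindex(index=[r for r in row_order if r in table.index])
    if col_order is not None:
        table = table.reindex(columns=[c for c in col_order if c in table.columns])
    return table.fillna(0).astype(int)


def column_percentages(table: pd.DataFrame) -> pd.DataFrame:
    """Percentages within each column (Table-style n (%) reporting)."""
    return table / table.sum(axis=0) * 100.0


def pearson_chi_square(table: pd.DataFrame | np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square statistic, degrees of freedom and upper-tail p.

    No continuity correction. Errors if any expected count is zero (the
    statistic is undefined there), naming the offending cell.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    if (expected == 0).any():
        r, c = np.argwhere(expected == 0)[0]
        raise ValueError(f"expected count is zero in cell ({r}, {c})")
    statistic = float(((obs - expected) ** 2 / expected).sum())
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return statistic, dof, float(stats.chi2.sf(statistic, dof))


# ---------------------------------------------------------------------------
# Odds ratios
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EffectEstimate:
    """An odds ratio with its Wald interval (log-scale standard error)."""

    estimate: float
    ci_low: float
    ci_high: float
    se_log: float
    index_label: str = ""
    reference_label: str = ""

    def format(self, dp: int = 2) -> str:
        return (f"{self.estimate:.{dp}f} "
                f"[{self.ci_low:.{dp}f}, {self.ci_high:.{dp}f}]")


def odds_ratio_wald(
    table: pd.DataFrame | np.ndarray,
    alpha: float = 0.05,
    haldane: bool = False,
) -> EffectEstimate:
    """Cross-product odds ratio from a 2x2 table with a Wald CI.

    Layout: rows are the exposure levels (index level first, reference
    second); columns are (case, control). The estimate is the odds of being
    a case at the index level relative to the reference. SE(log OR) is the
    square root of the sum of reciprocal cells; the CI is
    exp(log OR +/- z * SE). A zero cell raises :class:`ZeroCellError` unless
    ``haldane=True`` adds 0.5 to every cell.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("odds_ratio_wald requires a 2x2 table")
    if (arr == 0).any():
        if not haldane:
            raise ZeroCellError(
                "zero cell in 2x2 table; pass haldane=True for the 0.5 correction"
            )
        arr = arr + 0.5
    a, b = arr[0]
    c, d = arr[1]
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = float(stats.norm.ppf(1 - alpha / 2))
    labels = _table_labels(table)
    return EffectEstimate(
        estimate=math.exp(log_or),
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        se_log=se,
        index_label=labels[0],
        reference_label=labels[1],
    )


def _table_labels(table) -> tuple[str, str]:
    if isinstance(table, pd.DataFrame):
        return str(table.index[0]), str(table.index[1])
    return "", ""


# ---------------------------------------------------------------------------
# Logistic regression by IRLS
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CovariateSpec:
    """A categorical model term: column name, reference level, and an
    optional explicit level ordering (reference listed or not)."""

    name: str
    reference: object
    levels: tuple | None = None


@dataclasses.dataclass
class LogisticFit:
    params: pd.Series
    cov: pd.DataFrame
    converged: bool
    n_iter: int
    loglik: float
    dropped_levels: list[tuple[str, object]]
    n_obs: float

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        """Exponentiated non-intercept coefficients with Wald CIs."""
        z = float(stats.norm.ppf(1 - alpha / 2))
        rows = []
        for name in self.params.index:
            if name == "intercept":
                continue
            beta = self.params[name]
            se = math.sqrt(self.cov.loc[name, name])
            rows.append({
                "term": name,
                "odds_ratio": math.exp(beta),
                "ci_low": math.exp(beta - z * se),
                "ci_high": math.exp(beta + z * se),
                "se_log": se,
            })
        return pd.DataFrame(rows).set_index("term") if rows else pd.DataFrame()


def _design_matrix(
    df: pd.DataFrame, terms: Sequence[CovariateSpec]
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for spec in terms:
        values = df[spec.name]
        levels = list(spec.levels) if spec.levels is not None else list(pd.unique(values))
        if spec.reference not in levels:
            raise ValueError(
                f"reference level {spec.reference!r} absent from {spec.name!r}"
            )
        for level in levels:
            if level == spec.reference:
                continue
            col = (values == level).to_numpy(float)
            if col.sum() == 0:  # level absent (possibly dropped): no dummy
                continue
            cols.append(col)
            names.append(f"{spec.name}[{level}]")
    return np.column_stack(cols), names


def _drop_perfect_levels(
    df: pd.DataFrame,
    outcome: np.ndarray,
    weights: np.ndarray,
    terms: Sequence[CovariateSpec],
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, list[tuple[str, object]]]:
    """Remove non-reference levels whose cells contain no case or no control
    (perfect prediction); their rows are excluded and the level reported."""
    dropped: list[tuple[str, object]] = []
    keep = np.ones(len(df), dtype=bool)
    for spec in terms:
        for level in pd.unique(df[spec.name]):
            if level == spec.reference:
                continue
            m = (df[spec.name] == level).to_numpy()
            cases = float(weights[m & (outcome > 0.5)].sum())
            controls = float(weights[m & (outcome <= 0.5)].sum())
            if cases == 0.0 or controls == 0.0:
                dropped.append((spec.name, level))
                keep &= ~m
    if dropped:
        return df[keep].reset_index(drop=True), outcome[keep], weights[keep], dropped
    return df, outcome, weights, dropped


def fit_logistic_irls(
    df: pd.DataFrame,
    outcome: str,
    terms: Sequence[CovariateSpec],
    weight: str | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by Newton/IRLS.

    ``outcome`` must be binary (bool or 0/1). ``weight`` names an optional
    frequency-weight column for grouped data; fitting grouped rows is
    identical to fitting the expanded 0/1 rows. Convergence is declared when
    the score's max-norm falls below ``tol``; non-convergence or detected
    separation raises with the iteration trace attached.
    """
    y = df[outcome].to_numpy(float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary (0/1 or bool)")
    w = df[weight].to_numpy(float) if weight else np.ones(len(df))
    if y[w > 0].min(initial=1.0) == y[w > 0].max(initial=0.0):
        raise ValueError("outcome is constant; the model is not identifiable")
    data, y, w, dropped = _drop_perfect_levels(df, y, w, terms)
    X, names = _design_matrix(data, terms)

    beta = np.zeros(X.shape[1])
    trace: list[tuple[int, float, float]] = []
    converged = False
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        score = X.T @ (w * (y - mu))
        info = (X * (w * mu * (1 - mu))[:, None]).T @ X
        loglik = float(np.sum(w * (y * np.log(mu) + (1 - y) * np.log(1 - mu))))
        max_score = float(np.max(np.abs(score)))
        trace.append((it, loglik, max_score))
        if max_score <= tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                f"singular information matrix at iteration {it}: {exc}"
            ) from exc
        # step-halving keeps Newton ascent monotone on awkward samples
        scale = 1.0
        for _ in range(20):
            if log_likelihood(X, y, w, beta + scale * step) >= loglik:
                break
            scale *= 0.5
        beta = beta + scale * step
        if np.max(np.abs(beta)) > 50:
            raise SeparationError(
                f"coefficients diverging at iteration {it}; data are separated"
            )
    if not converged:
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations", trace
        )
    cov = np.linalg.inv(info)
    return LogisticFit(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        converged=True,
        n_iter=len(trace),
        loglik=trace[-1][1],
        dropped_levels=dropped,
        n_obs=float(w.sum()),
    )


def log_likelihood(X: np.ndarray, y: np.ndarray, w: np.ndarray, beta: np.ndarray) -> float:
    """Bernoulli log-likelihood at an arbitrary coefficient vector."""
    mu = np.clip(1.0 / (1.0 + np.exp(-(X @ beta))), 1e-12, 1 - 1e-12)
    return float(np.sum(w * (y * np.log(mu) + (1 - y) * np.log(1 - mu))))


def design_matrix(df: pd.DataFrame, terms: Sequence[CovariateSpec]):
    """Public wrapper (used by optimality checks and cross-validation tests)."""
    return _design_matrix(df, terms)


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

DASH = "-"


def summarize_model(
    fit: LogisticFit,
    crude: dict[tuple[str, object], EffectEstimate | None],
    terms: Sequence[CovariateSpec],
    level_labels: dict[str, dict] | None = None,
    dp: int = 2,
) -> pd.DataFrame:
    """Side-by-side crude and adjusted odds ratios, Table-style.

    Reference levels are rendered as ``1``; levels dropped for perfect
    prediction (or with a crude zero cell) as a dash. ``crude`` maps
    ``(term name, level)`` to an :class:`EffectEstimate` or ``None``.
    """
    adjusted = fit.odds_ratios()
    dropped = set(fit.dropped_levels)
    rows = []
    for spec in terms:
        levels = list(spec.levels) if spec.levels is not None else None
        if levels is None:
            levels = [spec.reference] + sorted(
                {lvl for (name, lvl) in crude if name == spec.name},
                key=str,
            )
        for level in levels:
            label = level
            if level_labels and spec.name in level_labels:
                label = level_labels[spec.name].get(level, level)
            if level == spec.reference:
                rows.append({"variable": spec.name, "level": label,
                             "crude": "1", "adjusted": "1"})
                continue
            key = f"{spec.name}[{level}]"
            est = crude.get((spec.name, level))
            crude_str = est.format(dp) if est is not None else DASH
            if (spec.name, level) in dropped or key not in adjusted.index:
                adj_str = DASH
            else:
                row = adjusted.loc[key]
                adj_str = EffectEstimate(
                    row["odds_ratio"], row["ci_low"], row["ci_high"], row["se_log"]
                ).format(dp)
            rows.append({"variable": spec.name, "level": label,
                         "crude": crude_str, "adjusted": adj_str})
    return pd.DataFrame(rows, columns=["variable", "level", "crude", "adjusted"])
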