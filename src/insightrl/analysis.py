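"""Inferential stage: descriptives, probit regressions, order-split analyses.

Binary success on each insight task is regressed by maximum-likelihood probit
on the seven estimated learning traits plus bandit performance, with and
without the other task's outcome (the cross-task transfer term); the same
four specifications are re-run on the subsample that faced each task second.
A two-proportion Pearson chi-square (no continuity correction) compares
first- versus second-administration success rates.

Significance stars: *** p<0.01, ** p<0.05, * p<0.1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

logger = logging.getLogger(__name__)

TRAIT_REGRESSORS = ["beta", "mu", "nu", "alpha_pos", "alpha_neg", "lam", "phi", "tab_performance"]
TASKS = ("8coin", "9dot")


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


@dataclass
class RegressionResult:
    """One probit fit: estimates, observed-information SEs, AIC, diagnostics."""

    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    z_values: dict[str, float]
    p_values: dict[str, float]
    aic: float
    n_obs: int
    converged: bool
    log_likelihood: float = np.nan
    label: str = ""

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "regressor": k,
                "coef": self.coefficients[k],
                "se": self.standard_errors[k],
                "z": self.z_values[k],
                "p": self.p_values[k],
                "stars": significance_stars(self.p_values[k]),
            }
            for k in self.coefficients
        ]
        return pd.DataFrame(rows)

    def render(self) -> str:
        """Aligned text block: coefficient with stars, SE in parentheses."""
        lines = [f"{self.label or 'probit fit'}  (n = {self.n_obs})"]
        width = max(len(k) for k in self.coefficients) + 2
        for k in self.coefficients:
            stars = significance_stars(self.p_values[k])
            lines.append(
                f"  {k:<{width}}{self.coefficients[k]:>8.2f}{stars:<4}({self.standard_errors[k]:.2f})"
            )
        lines.append(f"  {'AIC':<{width}}{self.aic:>8.2f}")
        if not self.converged:
            lines.append("  [fit flagged: non-convergence or separation]")
        return "\n".join(lines)


def _check_design(X: pd.DataFrame) -> None:
    arr = np.asarray(X, dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the columns involved via QR pivoting on the correlation structure
        _, r = np.linalg.qr(arr)
        bad = [X.columns[i] for i in range(arr.shape[1]) if abs(r[i, i]) < 1e-8 * max(1.0, abs(r[0, 0]))]
        raise ValueError(f"rank-deficient design; collinear columns: {bad or list(X.columns)}")


def probit_fit(outcome: pd.Series, regressors: pd.DataFrame, label: str = "") -> RegressionResult:
    """Maximum-likelihood probit with intercept.

    Degenerate outcomes and perfect separation come back as flagged
    (``converged=False``) results; a rank-deficient design raises, naming
    the collinear columns.
    """
    y = np.asarray(outcome, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    X = sm.add_constant(regressors.astype(float), has_constant="add")
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than coefficients")
    keys = list(X.columns)
    if y.min() == y.max():
        logger.warning("%s: outcome is constant; returning flagged result", label or "probit")
        nan = {k: np.nan for k in keys}
        return RegressionResult(nan, dict(nan), dict(nan), dict(nan), np.nan, len(y), False, label=label)
    _check_design(X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Probit(y, X).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", True))
    except (PerfectSeparationError, PerfectSeparationWarning):
        logger.warning("%s: perfect separation; returning flagged result", label or "probit")
        nan = {k: np.nan for k in keys}
        return RegressionResult(nan, dict(nan), dict(nan), dict(nan), np.nan, len(y), False, label=label)
    return RegressionResult(
        coefficients=dict(zip(keys, res.params)),
        standard_errors=dict(zip(keys, res.bse)),
        z_values=dict(zip(keys, res.tvalues)),
        p_values=dict(zip(keys, res.pvalues)),
        aic=float(res.aic),
        n_obs=int(res.nobs),
        converged=converged,
        log_likelihood=float(res.llf),
        label=label,
    )


def join_cohort_fits(cohort_table: pd.DataFrame, fits: pd.DataFrame) -> pd.DataFrame:
    """Inner-join cohort rows with fitted traits; listwise-drop failed fits.

    The fitted traits replace the generator's latent ones, reproducing the
    study's errors-in-variables structure. Orphan subject ids on either side
    raise; non-converged subjects are dropped with a logged count.
    """
    cohort_cols = [
        c for c in cohort_table.columns
        if c not in TRAIT_REGRESSORS or c == "tab_performance"
    ]
    merged = cohort_table[cohort_cols].merge(
        fits, on="subject_id", how="outer", indicator=True
    )
    orphans = merged.loc[merged["_merge"] != "both", "subject_id"].tolist()
    if orphans:
        raise ValueError(f"cohort/fits subject_id mismatch: {orphans[:10]}")
    merged = merged.drop(columns="_merge")
    if "converged" in merged.columns:
        n_drop = int((~merged["converged"].astype(bool)).sum())
        if n_drop:
            logger.info("dropping %d non-converged fits listwise", n_drop)
        merged = merged[merged["converged"].astype(bool)]
    return merged.reset_index(drop=True)


def _task_regressions(data: pd.DataFrame, task: str) -> dict[str, RegressionResult]:
    other = "9dot" if task == "8coin" else "8coin"
    outcome = data[f"success_{task}"]
    base = data[TRAIT_REGRESSORS]
    out = {
        task: probit_fit(outcome, base, label=f"success_{task} ~ traits"),
        f"{task}+transfer": probit_fit(
            outcome,
            base.assign(**{f"success_{other}": data[f"success_{other}"]}),
            label=f"success_{task} ~ traits + success_{other}",
        ),
    }
    return out


def success_regressions(data: pd.DataFrame) -> dict[str, RegressionResult]:
    """The four full-sample probit fits: each task, without and with the
    other task's success as the transfer regressor."""
    results = {}
    for task in TASKS:
        results.update(_task_regressions(data, task))
    return results


def second_task_regressions(data: pd.DataFrame) -> dict[str, RegressionResult]:
    """The same four specifications, restricted to subjects who faced the
    modeled task second (after experiencing the other task)."""
    if "task_order" not in data.columns:
        raise ValueError("task_order column required")
    results = {}
    for task in TASKS:
        first_label = "9dot_first" if task == "8coin" else "8coin_first"
        sub = data[data["task_order"] == first_label]
        if sub.empty:
            raise ValueError(f"no subjects faced {task} second")
        results.update(_task_regressions(sub.reset_index(drop=True), task))
    return results


def chi_square_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table, 1 df, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


@dataclass
class RateComparison:
    """First- vs second-administration success rates for one task."""

    task: str
    rate_first: float
    rate_second: float
    chi_square: float
    p_value: float
    n_first: int
    n_second: int
    degenerate: bool = False


def success_rate_comparison(data: pd.DataFrame, task: str) -> RateComparison:
    """Compare a task's success rate between subjects who faced it first
    versus second, with a two-proportion Pearson chi-square."""
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    first_mask = data["task_order"] == f"{task}_first"
    y = data[f"success_{task}"].astype(float)
    y_first = y[first_mask]
    y_second = y[~first_mask]
    if len(y_first) == 0 or len(y_second) == 0:
        raise ValueError("both order groups must be non-empty")
    counts = np.array(
        [
            [y_first.sum(), len(y_first) - y_first.sum()],
            [y_second.sum(), len(y_second) - y_second.sum()],
        ]
    )
    try:
        stat, p = chi_square_2x2(counts)
        degenerate = False
    except ValueError:
        stat, p, degenerate = np.nan, np.nan, True
    return RateComparison(
        task=task,
        rate_first=float(y_first.mean()),
        rate_second=float(y_second.mean()),
        chi_square=stat,
        p_value=p,
        n_first=int(len(y_first)),
        n_second=int(len(y_second)),
        degenerate=degenerate,
    )


@dataclass
class DescriptiveTable:
    """Means, sample SDs and lower-triangular Pearson correlations."""

    means: pd.Series
    sds: pd.Series
    correlations: pd.DataFrame
    p_values: pd.DataFrame
    constant_columns: list[str] = field(default_factory=list)

    def render(self) -> str:
        cols = list(self.means.index)
        width = max(len(c) for c in cols) + 2
        lines = [f"{'variable':<{width}}{'mean':>8}{'sd':>8}  correlations (lower triangle)"]
        for i, c in enumerate(cols):
            cells = []
            for j in range(i):
                r = self.correlations.iloc[i, j]
                stars = significance_stars(self.p_values.iloc[i, j])
                cells.append("   n/a " if not np.isfinite(r) else f"{r:6.2f}{stars:<3}")
            lines.append(f"{c:<{width}}{self.means[c]:>8.2f}{self.sds[c]:>8.2f}  " + "".join(cells))
        return "\n".join(lines)


DESCRIPTIVE_VARIABLES = [
    "success_8coin", "success_9dot", "beta", "mu", "nu",
    "alpha_pos", "alpha_neg", "lam", "phi", "tab_performance",
]


def descriptive_stats(data: pd.DataFrame, variables: list[str] | None = None) -> DescriptiveTable:
    """Per-variable mean and SD (n−1) plus pairwise Pearson correlations with
    two-sided p-values. Pairs involving a constant column are flagged NaN."""
    variables = variables or [v for v in DESCRIPTIVE_VARIABLES if v in data.columns]
    if len(data) < 3:
        raise ValueError("need at least 3 rows")
    sub = data[variables].astype(float)
    means = sub.mean()
    sds = sub.std(ddof=1)
    k = len(variables)
    corr = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    pvals = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables)
    constant = [v for v in variables if sds[v] == 0 or not np.isfinite(sds[v])]
    for i in range(k):
        for j in range(i + 1, k):
            vi, vj = variables[i], variables[j]
            if vi in constant or vj in constant:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(sub[vi], sub[vj])
            corr.iloc[i, j] = corr.iloc[j, i] = r
            pvals.iloc[i, j] = pvals.iloc[j, i] = p
    if constant:
        logger.warning("constant columns, correlations undefined: %s", constant)
    return DescriptiveTable(means, sds, corr, pvals, constant)
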