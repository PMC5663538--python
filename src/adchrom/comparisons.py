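"""Cross-condition comparisons: regressions and dose-response tables.

One :class:`ExperimentPoint` holds the population summary of a single,
independently run experiment.  Relationships such as median rolling V_inst
versus percent rolling are summarized by ordinary least squares with a
two-sided t-test on the slope and Pearson's r with its significance test;
metric-versus-dose (heparin) and metric-versus-shear series are emitted as
tidy mean ± SEM tables suitable for external ANOVA software.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chromatography import PopulationSummary
from .config import FlowCondition

__all__ = [
    "ExperimentPoint",
    "RegressionResult",
    "linear_regression",
    "dose_response_table",
    "points_to_frame",
    "regression_report",
]

_CONDITION_FIELDS = (
    "tau_wall_dyn_cm2",
    "selectin",
    "selectin_conc_ug_ml",
    "heparin_dose_u_ml",
)

_METRICS = (
    "pct_rolling",
    "median_v_inst_rolling_um_s",
    "mean_pct_binding_time",
    "mean_v_avg_um_s",
    "mean_v_ratio_rolling",
    "mean_v_ratio_free",
)


@dataclass
class ExperimentPoint:
    """One independently run experiment: its condition and summary."""

    run_id: str
    condition: FlowCondition
    cell_label: str
    summary: PopulationSummary


@dataclass
class RegressionResult:
    """Ordinary-least-squares fit with slope inference and Pearson's r."""

    slope: float
    intercept: float
    slope_standard_error: float
    p_slope_nonzero: float
    pearson_r: float
    p_pearson: float
    n: int


def linear_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """OLS of y on x with a two-sided slope t-test and Pearson correlation.

    Requires equal lengths and n ≥ 2; x must have nonzero variance.
    p-values are NaN for n < 3 (no residual degrees of freedom).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance: slope undefined")
    fit = stats.linregress(x, y)
    if n >= 3 and np.ptp(y) > 0:
        r, p_r = stats.pearsonr(x, y)
        p_slope = float(fit.pvalue)
    else:
        r, p_r, p_slope = fit.rvalue, math.nan, math.nan
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_standard_error=float(fit.stderr),
        p_slope_nonzero=p_slope,
        pearson_r=float(r),
        p_pearson=float(p_r) if not math.isnan(p_slope) else math.nan,
        n=int(n),
    )


def points_to_frame(points: Sequence[ExperimentPoint]) -> pd.DataFrame:
    """Flatten experiment points into a tidy frame (one row per run)."""
    rows = []
    for p in points:
        row = {"run_id": p.run_id, "cell_label": p.cell_label}
        row.update({f: getattr(p.condition, f) for f in _CONDITION_FIELDS})
        row.update({m: getattr(p.summary, m) for m in _METRICS})
        rows.append(row)
    return pd.DataFrame(rows)


def dose_response_table(
    points: Sequence[ExperimentPoint],
    metric: str,
    group_by: Sequence[str] = ("heparin_dose_u_ml",),
) -> pd.DataFrame:
    """Per-group mean ± SEM of one metric across experiment points.

    ``group_by`` names condition fields (tau_wall_dyn_cm2, selectin,
    selectin_conc_ug_ml, heparin_dose_u_ml) and/or ``cell_label``.  Rows are
    ordered by the grouping values (dose or shear ascending).  Groups with a
    single run have an undefined SEM (NaN, flagged by n == 1).
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {_METRICS}")
    allowed = set(_CONDITION_FIELDS) | {"cell_label"}
    bad = [g for g in group_by if g not in allowed]
    if bad:
        raise ValueError(f"unknown grouping field(s) {bad}; choose from {sorted(allowed)}")
    frame = points_to_frame(points)
    grouped = frame.groupby(list(group_by), sort=True)[metric]
    table = grouped.agg(mean="mean", sem="sem", n="count").reset_index()
    return table


def regression_report(
    results: dict[str, RegressionResult], title: str = "Regression summary"
) -> str:
    """Plain-text report of named regression results."""
    lines = [title, "=" * len(title)]
    for name, res in results.items():
        lines.append(
            f"{name}: slope = {res.slope:.4g} ± {res.slope_standard_error:.3g} "
            f"(p = {res.p_slope_nonzero:.3g}), r = {res.pearson_r:.3f} "
            f"(p = {res.p_pearson:.3g}), n = {res.n}"
        )
    return "\n".join(lines)
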