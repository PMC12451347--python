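"""Random-intercept comparison of quality metrics across the five windows.

Model: y_ij = beta_0 + sum_p beta_p 1[window_j = p] + b_i + eps_ij with
b_i ~ N(0, sigma_b^2) and eps_ij ~ N(0, sigma^2).  The five observation
periods enter as a 5-level categorical with the first (window -2) as
reference; estimation is restricted maximum likelihood (REML) via
statsmodels MixedLM and 95% CIs are Wald intervals beta +/- 1.96 SE
(normal quantile, no df correction).  Missing subject-windows are omitted
row-wise (unbalanced designs allowed).  On balanced complete data the
fixed-effect estimates equal the raw window-mean differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

Z95 = 1.959963984540054


@dataclass
class PeriodModelResult:
    """Fixed window effects plus variance components from one REML fit."""

    effects: pd.DataFrame  # window, beta, se, ci_low, ci_high, reference
    var_subject: float
    var_residual: float
    n_obs: int
    n_subjects: int
    converged: bool
    degenerate: bool = False
    metric: str | None = None


def fit_period_model(
    data: pd.DataFrame,
    value_col: str = "value",
    window_col: str = "window",
    subject_col: str = "subject_id",
    reference: int = -2,
    metric: str | None = None,
) -> PeriodModelResult:
    """Fit the subject-random-intercept period model for one metric.

    Rows with a missing value are dropped.  Requires >=2 subjects with >=2
    non-missing windows and >=2 distinct windows overall.  All-identical
    values short-circuit to the degenerate zero-variance solution (all
    betas 0) with a flag.
    """
    df = data[[subject_col, window_col, value_col]].dropna().copy()
    if df.empty:
        raise ValueError("no non-missing observations")
    windows = sorted(df[window_col].unique())
    if reference not in windows:
        raise ValueError(f"reference window {reference} absent from data")
    if len(windows) < 2:
        raise ValueError("no estimable contrasts: single window present")
    repeat_counts = df.groupby(subject_col)[window_col].nunique()
    if (repeat_counts >= 2).sum() < 2:
        raise ValueError("need >=2 subjects observed in >=2 windows")

    non_ref = [w for w in windows if w != reference]
    values = df[value_col].to_numpy(dtype=float)
    if np.ptp(values) == 0.0:
        effects = _effects_frame(non_ref, {w: (0.0, 0.0) for w in non_ref}, reference)
        return PeriodModelResult(
            effects=effects, var_subject=0.0, var_residual=0.0,
            n_obs=len(df), n_subjects=df[subject_col].nunique(),
            converged=True, degenerate=True, metric=metric,
        )

    formula = f"{value_col} ~ C({window_col}, Treatment(reference={reference}))"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df[subject_col])
        fit = model.fit(reml=True)
    prefix = f"C({window_col}, Treatment(reference={reference}))[T."
    est = {}
    for w in non_ref:
        name = f"{prefix}{w}]"
        est[w] = (float(fit.params[name]), float(fit.bse[name]))
    effects = _effects_frame(non_ref, est, reference)
    return PeriodModelResult(
        effects=effects,
        var_subject=float(fit.cov_re.iloc[0, 0]),
        var_residual=float(fit.scale),
        n_obs=len(df),
        n_subjects=df[subject_col].nunique(),
        converged=bool(fit.converged),
        metric=metric,
    )


def _effects_frame(non_ref, est, reference) -> pd.DataFrame:
    rows = [
        {
            "window": reference, "beta": 0.0, "se": np.nan,
            "ci_low": np.nan, "ci_high": np.nan, "reference": True,
        }
    ]
    for w in non_ref:
        beta, se = est[w]
        rows.append(
            {
                "window": w, "beta": beta, "se": se,
                "ci_low": beta - Z95 * se, "ci_high": beta + Z95 * se,
                "reference": False,
            }
        )
    return pd.DataFrame(rows).sort_values("window", ignore_index=True)


def summarize_metric(
    data: pd.DataFrame,
    value_col: str = "value",
    window_col: str = "window",
) -> pd.DataFrame:
    """Descriptive per-window rows: n, mean +/- SD, median (IQR)."""
    df = data[[window_col, value_col]].dropna()
    rows = []
    for window, g in df.groupby(window_col):
        v = g[value_col].to_numpy(dtype=float)
        rows.append(
            {
                "window": window,
                "n": v.size,
                "mean": float(np.mean(v)),
                "sd": float(np.std(v, ddof=1)) if v.size > 1 else np.nan,
                "median": float(np.median(v)),
                "q25": float(np.percentile(v, 25)),
                "q75": float(np.percentile(v, 75)),
            }
        )
    return pd.DataFrame(rows, columns=["window", "n", "mean", "sd", "median", "q25", "q75"])
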