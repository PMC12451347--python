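"""Per-subject, per-window VKA treatment-quality metrics.

The central quantity is the Rosendaal time in therapeutic range: the INR is
linearly interpolated between consecutive measurements and the covered time
is partitioned into below-/in-/above-range segments by exact crossing-time
solutions.  Boundary values (INR exactly on a limit) count as in range.
INR variability is the variance growth rate (VGR): the mean squared INR
change between consecutive measurements per unit elapsed time (weeks by
default).  A clinically relevant dose adjustment is a >=10% change in the
recommended average daily dose between two consecutive INR visits.

Windowing conventions (one anchor set used uniformly):

* a subject-window is eligible when a VKA episode is active at the window
  start, follow-up has not ended, and the window holds >=2 INR measurements
  - or >=1 plus a borrowed anchor, the latest measurement of the previous
  30-day period;
* the anchor sequence = [borrowed anchor?] + in-window measurements, and
  Rosendaal interpolation, VGR pairs, dose-change pairs and monitoring
  intervals all run over consecutive anchors (so every pair's later member
  lies inside the window);
* measurement-count metrics (n_inr, median/mean INR and dose, the INR
  proportions) use only measurements dated inside the window;
* measurements on/after the follow-up exit are ignored, and interpolated
  time is clipped to [window start, min(window end, exit, last anchor)] -
  no carry-forward beyond the last measurement.  The Rosendaal denominator
  is that covered time (configurable to the full 30 days).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._types import WINDOW_DAYS, FollowUp, Subject
from .windows import at_risk_at

DAYS_PER_WEEK = 7.0

QUALITY_COLUMNS = [
    "subject_id",
    "window",
    "eligible",
    "n_inr",
    "median_inr",
    "mean_inr",
    "median_interval_days",
    "ttr",
    "tbr",
    "tar",
    "vgr",
    "prop_in",
    "prop_below",
    "prop_above",
    "prop_ge5",
    "prop_ge8",
    "median_dose",
    "mean_dose",
    "dose_increase_flag",
    "dose_reduction_flag",
    "switched_vka_type",
    "switched_doac",
]


@dataclass(frozen=True)
class QualityConfig:
    """Switchable conventions that the source literature leaves open."""

    vgr_denominator: str = "weeks"  # "weeks" | "days"
    denominator: str = "covered"  # "covered" | "full_window"
    boundary_inclusive: bool = True  # INR exactly on a limit counts in range
    dose_change_threshold: float = 0.10

    def __post_init__(self):
        if self.vgr_denominator not in ("weeks", "days"):
            raise ValueError(f"vgr_denominator {self.vgr_denominator!r}")
        if self.denominator not in ("covered", "full_window"):
            raise ValueError(f"denominator {self.denominator!r}")


def _time_below(a, b, ya, yb, thr, strict=True):
    """Lebesgue measure of {t in [a,b] : y(t) < thr} for linear y."""
    if ya == yb:
        hit = ya < thr if strict else ya <= thr
        return b - a if hit else 0.0
    tc = a + (thr - ya) * (b - a) / (yb - ya)
    tc = min(max(tc, a), b)
    return tc - a if yb > ya else b - tc


def _time_above(a, b, ya, yb, thr, strict=True):
    return _time_below(a, b, -ya, -yb, -thr, strict=strict)


def rosendaal(
    days,
    inrs,
    target_low: float,
    target_high: float,
    window_start: float,
    window_end: float,
    exit_day: float | None = None,
    config: QualityConfig = QualityConfig(),
):
    """Rosendaal linear-interpolation time in/below/above range.

    ``days`` are measurement times (float days on any common origin,
    strictly increasing); ``window_start``/``window_end`` bound the 30-day
    period on the same scale, and ``exit_day`` optionally truncates it.
    Returns ``(ttr, tbr, tar)`` as percentages, or ``None`` when the
    covered duration is zero.
    """
    days = np.asarray(days, dtype=float)
    inrs = np.asarray(inrs, dtype=float)
    if days.size < 2:
        return None
    if np.any(np.diff(days) <= 0):
        raise ValueError("measurement dates must be strictly increasing")
    cov_start = max(window_start, float(days[0]))
    cov_end = min(window_end, float(days[-1]))
    if exit_day is not None:
        cov_end = min(cov_end, float(exit_day))
    if cov_end <= cov_start:
        return None

    strict = config.boundary_inclusive
    below = above = 0.0
    for i in range(days.size - 1):
        a = max(float(days[i]), cov_start)
        b = min(float(days[i + 1]), cov_end)
        if b <= a:
            continue
        span = days[i + 1] - days[i]
        ya = inrs[i] + (inrs[i + 1] - inrs[i]) * (a - days[i]) / span
        yb = inrs[i] + (inrs[i + 1] - inrs[i]) * (b - days[i]) / span
        below += _time_below(a, b, ya, yb, target_low, strict=strict)
        above += _time_above(a, b, ya, yb, target_high, strict=strict)

    covered = cov_end - cov_start
    denom = covered if config.denominator == "covered" else float(WINDOW_DAYS)
    in_range = covered - below - above
    return (
        100.0 * in_range / denom,
        100.0 * below / denom,
        100.0 * above / denom,
    )


def vgr(days, inrs, config: QualityConfig = QualityConfig()):
    """Variance growth rate over consecutive measurement pairs.

    VGR = (1/n) * sum (INR_i - INR_{i-1})^2 / dt_i with dt in weeks (or
    days, per config).  Returns ``None`` with fewer than two measurements.
    """
    days = np.asarray(days, dtype=float)
    inrs = np.asarray(inrs, dtype=float)
    if days.size < 2:
        return None
    dt_ = np.diff(days)
    if np.any(dt_ <= 0):
        raise ValueError("measurement dates must be strictly increasing")
    if config.vgr_denominator == "weeks":
        dt_ = dt_ / DAYS_PER_WEEK
    return float(np.mean(np.diff(inrs) ** 2 / dt_))


def inr_proportions(
    inrs, target_low: float, target_high: float, config: QualityConfig = QualityConfig()
):
    """Measurement-count proportions (percent) of in-window INR values.

    Returns ``(prop_in, prop_below, prop_above, prop_ge5, prop_ge8)`` or
    ``None`` when the window holds no measurement.  Boundary equality
    counts as within range; >=5 / >=8 are inclusive thresholds.
    """
    inrs = np.asarray(inrs, dtype=float)
    if inrs.size == 0:
        return None
    n = inrs.size
    if config.boundary_inclusive:
        below = np.count_nonzero(inrs < target_low)
        above = np.count_nonzero(inrs > target_high)
    else:
        below = np.count_nonzero(inrs <= target_low)
        above = np.count_nonzero(inrs >= target_high)
    within = n - below - above
    return (
        100.0 * within / n,
        100.0 * below / n,
        100.0 * above / n,
        100.0 * np.count_nonzero(inrs >= 5.0) / n,
        100.0 * np.count_nonzero(inrs >= 8.0) / n,
    )


def classify_dose_change(
    dose_prev: float, dose_next: float, threshold: float = 0.10
) -> str:
    """Classify a dose change between consecutive visits.

    Relative to the earlier dose; the >=10% threshold is inclusive both
    ways.  A jump from zero to a positive dose counts as an increase.
    """
    if dose_prev == 0:
        return "increase" if dose_next > 0 else "none"
    rel = (dose_next - dose_prev) / dose_prev
    # small epsilon so decimal doses sitting exactly on the threshold
    # (e.g. 2.00 -> 1.80) classify inclusively despite float rounding
    eps = 1e-9
    if rel >= threshold - eps:
        return "increase"
    if -rel >= threshold - eps:
        return "reduction"
    return "none"


def window_eligibility(n_in_window: int, has_borrowed_anchor: bool, on_vka: bool, in_follow_up: bool):
    """Eligibility flag for one subject-window.

    Requires active VKA treatment at window start, follow-up not yet ended,
    and >=2 in-window INRs or >=1 plus the borrowed previous-period anchor.
    """
    return bool(
        on_vka and in_follow_up and (n_in_window >= 2 or (n_in_window >= 1 and has_borrowed_anchor))
    )


def monitoring_stats(in_window_count: int, anchor_days):
    """Measurement count and median day-gap between consecutive visits."""
    anchor_days = np.asarray(anchor_days, dtype=float)
    median_interval = (
        float(np.median(np.diff(anchor_days))) if anchor_days.size >= 2 else np.nan
    )
    return int(in_window_count), median_interval


def _vka_switch_dates(subject: Subject):
    eps = subject.vka_episodes
    return [
        eps[i].start
        for i in range(1, len(eps))
        if eps[i].vka_type != eps[i - 1].vka_type
    ]


def switch_flags(subject: Subject, window_start: dt.date, window_end: dt.date):
    """(switched_vka_type, switched_doac) for dates falling in the window."""
    d0 = subject.anchor_d0
    switched_vka = any(window_start <= d < window_end for d in _vka_switch_dates(subject))
    switched_doac = any(
        window_start <= d < window_end for d in subject.doac_dispensings if d >= d0
    )
    return switched_vka, switched_doac


def _window_row(subject, window, days, inrs, doses, fu_exit_day, on_vka, in_follow_up, config):
    ws = float((window.start - subject.anchor_d0).days)
    we = ws + WINDOW_DAYS
    clip_end = min(we, fu_exit_day)

    lo_idx = int(np.searchsorted(days, ws, side="left"))
    hi_idx = int(np.searchsorted(days, clip_end, side="left"))
    prev_lo = int(np.searchsorted(days, ws - WINDOW_DAYS, side="left"))
    borrowed_idx = lo_idx - 1 if lo_idx - 1 >= prev_lo else None

    n_in = hi_idx - lo_idx
    eligible = window_eligibility(n_in, borrowed_idx is not None, on_vka, in_follow_up)

    sw_vka, sw_doac = switch_flags(
        subject, window.start, window.end
    )
    row = {
        "subject_id": subject.subject_id,
        "window": window.index,
        "eligible": eligible,
        "n_inr": n_in,
        "switched_vka_type": sw_vka,
        "switched_doac": sw_doac,
    }
    nan_metrics = dict.fromkeys(
        (
            "median_inr", "mean_inr", "median_interval_days", "ttr", "tbr", "tar",
            "vgr", "prop_in", "prop_below", "prop_above", "prop_ge5", "prop_ge8",
            "median_dose", "mean_dose",
        ),
        np.nan,
    )
    row.update(nan_metrics)
    row["dose_increase_flag"] = pd.NA
    row["dose_reduction_flag"] = pd.NA
    if not eligible:
        return row

    first = borrowed_idx if borrowed_idx is not None else lo_idx
    a_days = days[first:hi_idx]
    a_inrs = inrs[first:hi_idx]
    a_doses = doses[first:hi_idx]
    in_inrs = inrs[lo_idx:hi_idx]
    in_doses = doses[lo_idx:hi_idx]

    target = subject.target_range_at_d0
    if target is not None:
        t_lo, t_hi = target
        ros = rosendaal(a_days, a_inrs, t_lo, t_hi, ws, we, exit_day=fu_exit_day, config=config)
        if ros is not None:
            row["ttr"], row["tbr"], row["tar"] = ros
        props = inr_proportions(in_inrs, t_lo, t_hi, config=config)
        if props is not None:
            (
                row["prop_in"], row["prop_below"], row["prop_above"],
                row["prop_ge5"], row["prop_ge8"],
            ) = props

    row["vgr"] = vgr(a_days, a_inrs, config=config)
    if row["vgr"] is None:
        row["vgr"] = np.nan
    if in_inrs.size:
        row["median_inr"] = float(np.median(in_inrs))
        row["mean_inr"] = float(np.mean(in_inrs))
    row["n_inr"], row["median_interval_days"] = monitoring_stats(n_in, a_days)

    dose_in = in_doses[~np.isnan(in_doses)]
    if dose_in.size:
        row["median_dose"] = float(np.median(dose_in))
        row["mean_dose"] = float(np.mean(dose_in))
    inc = red = False
    assessed = False
    for i in range(1, a_doses.size):
        dp, dn = a_doses[i - 1], a_doses[i]
        if np.isnan(dp) or np.isnan(dn):
            continue
        assessed = True
        change = classify_dose_change(dp, dn, threshold=config.dose_change_threshold)
        inc |= change == "increase"
        red |= change == "reduction"
    row["dose_increase_flag"] = inc if assessed else pd.NA
    row["dose_reduction_flag"] = red if assessed else pd.NA
    return row


def compute_window_quality(
    subjects,
    inr: pd.DataFrame,
    follow_ups,
    windows_by_subject: dict,
    config: QualityConfig = QualityConfig(),
) -> pd.DataFrame:
    """Compute the full WindowQuality table (one row per subject-window).

    ``windows_by_subject`` maps subject_id to its five ObservationWindows.
    Ineligible subject-windows keep NaN quality metrics (missing, not
    zero); descriptive fields (n_inr, switch flags) are always present.
    """
    fu_by_id: dict[str, FollowUp] = {f.subject_id: f for f in follow_ups}
    grouped = {
        sid: (
            g["date"].to_numpy(),
            g["inr"].to_numpy(dtype=float),
            g["dose"].to_numpy(dtype=float),
        )
        for sid, g in inr.groupby("subject_id", sort=False)
    }
    rows = []
    for subject in subjects:
        fu = fu_by_id[subject.subject_id]
        windows = windows_by_subject[subject.subject_id]
        dates, vals, doses = grouped.get(
            subject.subject_id, (np.array([], dtype=object), np.array([]), np.array([]))
        )
        d0 = subject.anchor_d0
        days = np.array([(d - d0).days for d in dates], dtype=float)
        fu_exit_day = float((fu.exit - d0).days)
        for window in windows:
            on_vka = subject.episode_at(window.start) is not None
            rows.append(
                _window_row(
                    subject, window, days, vals, doses, fu_exit_day,
                    on_vka, at_risk_at(fu, window.start), config,
                )
            )
    df = pd.DataFrame(rows, columns=QUALITY_COLUMNS)
    for col in ("dose_increase_flag", "dose_reduction_flag"):
        df[col] = df[col].astype("boolean")
    return df
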