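"""Readers and writers for the long-format tabular interchange files.

Three canonical inputs:

``subjects.csv``
    One row per subject: ``subject_id, cohort_label, year, anchor_d0,
    age_at_d0, target_low, target_high, vka_episodes, doac_dispensings,
    vka_dispensings, doac_clinic_dates`` plus arbitrary extra covariate
    columns.  List-valued cells are ``;``-separated; an episode is encoded
    ``start|end|type`` with an empty ``end`` for an ongoing episode.

``inr.csv``
    One row per INR measurement: ``subject_id, date, inr, target_low,
    target_high, dose`` (targets and dose may be blank).

``events.csv``
    One row per clinical event: ``subject_id, date, event_class``.

Validation is total: every malformed row is reported with its 1-based data
row number; nothing is silently dropped.  Dates are ISO-8601 and all
intervals in the package are half-open ``[start, end)``.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path

import numpy as np
import pandas as pd

from ._types import EVENT_CLASSES, Subject, VkaEpisode

SUBJECT_COLUMNS = [
    "subject_id",
    "cohort_label",
    "year",
    "anchor_d0",
    "age_at_d0",
    "target_low",
    "target_high",
    "vka_episodes",
    "doac_dispensings",
    "vka_dispensings",
    "doac_clinic_dates",
]
INR_COLUMNS = ["subject_id", "date", "inr", "target_low", "target_high", "dose"]
EVENT_COLUMNS = ["subject_id", "date", "event_class"]


class ValidationError(ValueError):
    """Raised when input rows violate the documented schemas/invariants."""

    def __init__(self, issues):
        self.issues = list(issues)
        lines = [f"{len(self.issues)} invalid row(s):"]
        for file, row, subject_id, message in self.issues[:50]:
            lines.append(f"  {file} row {row} (subject {subject_id}): {message}")
        if len(self.issues) > 50:
            lines.append(f"  ... and {len(self.issues) - 50} more")
        super().__init__("\n".join(lines))


def _parse_date(text) -> dt.date:
    return dt.date.fromisoformat(str(text).strip())


def _parse_date_list(cell) -> list[dt.date]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell) == "":
        return []
    return [_parse_date(tok) for tok in str(cell).split(";") if tok]


def _parse_episodes(cell) -> list[VkaEpisode]:
    episodes = []
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell) == "":
        return episodes
    for tok in str(cell).split(";"):
        if not tok:
            continue
        start_s, end_s, vka_type = tok.split("|")
        episodes.append(
            VkaEpisode(
                start=_parse_date(start_s),
                end=_parse_date(end_s) if end_s else None,
                vka_type=vka_type,
            )
        )
    return episodes


def encode_episodes(episodes) -> str:
    return ";".join(
        f"{ep.start.isoformat()}|{ep.end.isoformat() if ep.end else ''}|{ep.vka_type}"
        for ep in episodes
    )


def encode_dates(dates) -> str:
    return ";".join(d.isoformat() for d in dates)


def _is_blank(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value)) or str(value) == ""


def read_subjects(path, strict: bool = True):
    """Read ``subjects.csv`` into a list of :class:`Subject`.

    Returns ``(subjects, issues)``; with ``strict`` (default) any issue
    raises :class:`ValidationError` instead.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = set(SUBJECT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError([(path.name, 0, "-", f"missing columns {sorted(missing)}")])
    covariate_cols = [c for c in df.columns if c not in SUBJECT_COLUMNS]

    subjects, issues = [], []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = row._asdict()
        sid = str(rowd["subject_id"])
        try:
            anchor = _parse_date(rowd["anchor_d0"])
            episodes = _parse_episodes(rowd["vka_episodes"])
            for a, b in zip(episodes, episodes[1:]):
                if a.end is None or b.start < a.end:
                    raise ValueError(
                        f"episodes overlap or are unordered at {b.start.isoformat()}"
                    )
            lo, hi = rowd["target_low"], rowd["target_high"]
            if _is_blank(lo) or _is_blank(hi):
                target = None
            else:
                lo, hi = float(lo), float(hi)
                if not lo < hi:
                    raise ValueError(f"target range {lo}-{hi} has low >= high")
                target = (lo, hi)
            age = float(rowd["age_at_d0"])
            covariates = {c: rowd[c] for c in covariate_cols if not _is_blank(rowd[c])}
            if not _is_blank(rowd["year"]):
                covariates["year"] = int(rowd["year"])
            subjects.append(
                Subject(
                    subject_id=sid,
                    cohort_label=str(rowd["cohort_label"]),
                    anchor_d0=anchor,
                    age_at_d0=age,
                    vka_episodes=episodes,
                    target_range_at_d0=target,
                    doac_dispensings=_parse_date_list(rowd["doac_dispensings"]),
                    vka_dispensings=_parse_date_list(rowd["vka_dispensings"]),
                    doac_clinic_dates=_parse_date_list(rowd["doac_clinic_dates"]),
                    covariates=covariates,
                )
            )
        except (ValueError, TypeError) as exc:
            issues.append((path.name, i, sid, str(exc)))
    if issues and strict:
        raise ValidationError(issues)
    return subjects, issues


def read_inr(path, strict: bool = True):
    """Read ``inr.csv`` into a validated, per-subject date-sorted DataFrame.

    Invariants: INR finite and > 0; target low < high when both present;
    dose >= 0 when present; strictly increasing dates per subject (same-day
    duplicates are rejected at ingest).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = set(INR_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError([(path.name, 0, "-", f"missing columns {sorted(missing)}")])

    issues = []
    dates = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
    inr = pd.to_numeric(df["inr"], errors="coerce")
    lo = pd.to_numeric(df["target_low"], errors="coerce")
    hi = pd.to_numeric(df["target_high"], errors="coerce")
    dose = pd.to_numeric(df["dose"], errors="coerce")

    bad = pd.Series(False, index=df.index)
    for mask, msg in [
        (dates.isna(), "malformed date"),
        (~(inr > 0) | ~np.isfinite(inr.fillna(np.inf)), "INR must be finite and > 0"),
        (lo.notna() & hi.notna() & ~(lo < hi), "target range has low >= high"),
        (lo.notna() ^ hi.notna(), "target range must have both or neither bound"),
        (df["dose"].notna() & (dose.isna() | (dose < 0)), "dose must be >= 0"),
    ]:
        for idx in df.index[mask & ~bad]:
            issues.append((path.name, int(idx) + 1, str(df.at[idx, "subject_id"]), msg))
        bad |= mask
    dup = df.duplicated(subset=["subject_id", "date"], keep=False) & ~bad
    for idx in df.index[dup]:
        issues.append(
            (path.name, int(idx) + 1, str(df.at[idx, "subject_id"]),
             "duplicate same-day INR measurement")
        )
    bad |= dup

    if issues and strict:
        raise ValidationError(issues)
    out = pd.DataFrame(
        {
            "subject_id": df["subject_id"],
            "date": dates.dt.date,
            "inr": inr,
            "target_low": lo,
            "target_high": hi,
            "dose": dose,
        }
    )[~bad].sort_values(["subject_id", "date"], kind="stable").reset_index(drop=True)
    return out, issues


def read_events(path, strict: bool = True):
    """Read ``events.csv``; event classes come from a closed enumeration."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError([(path.name, 0, "-", f"missing columns {sorted(missing)}")])
    issues = []
    dates = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
    bad = dates.isna()
    for idx in df.index[bad]:
        issues.append((path.name, int(idx) + 1, str(df.at[idx, "subject_id"]), "malformed date"))
    unknown = ~df["event_class"].isin(EVENT_CLASSES) & ~bad
    for idx in df.index[unknown]:
        issues.append(
            (path.name, int(idx) + 1, str(df.at[idx, "subject_id"]),
             f"unknown event class {df.at[idx, 'event_class']!r}")
        )
    bad |= unknown
    if issues and strict:
        raise ValidationError(issues)
    out = pd.DataFrame(
        {"subject_id": df["subject_id"], "date": dates.dt.date, "event_class": df["event_class"]}
    )[~bad].sort_values(["subject_id", "date"], kind="stable").reset_index(drop=True)
    return out, issues


def read_tables(subjects_path, inr_path, events_path, strict: bool = True):
    """Read the three canonical inputs, pooling validation reports."""
    issues = []
    subjects, s_issues = read_subjects(subjects_path, strict=False)
    inr, i_issues = read_inr(inr_path, strict=False)
    events, e_issues = read_events(events_path, strict=False)
    issues = s_issues + i_issues + e_issues
    if issues and strict:
        raise ValidationError(issues)
    return subjects, inr, events, issues


def subjects_to_frame(subjects) -> pd.DataFrame:
    """Serialize Subject records to the canonical subjects.csv layout."""
    rows = []
    extra_cols: list[str] = []
    for s in subjects:
        lo, hi = (s.target_range_at_d0 or (None, None))
        row = {
            "subject_id": s.subject_id,
            "cohort_label": s.cohort_label,
            "year": s.covariates.get("year", ""),
            "anchor_d0": s.anchor_d0.isoformat(),
            "age_at_d0": s.age_at_d0,
            "target_low": lo,
            "target_high": hi,
            "vka_episodes": encode_episodes(s.vka_episodes),
            "doac_dispensings": encode_dates(s.doac_dispensings),
            "vka_dispensings": encode_dates(s.vka_dispensings),
            "doac_clinic_dates": encode_dates(s.doac_clinic_dates),
        }
        for k, v in s.covariates.items():
            if k == "year":
                continue
            row[k] = v
            if k not in extra_cols:
                extra_cols.append(k)
        rows.append(row)
    return pd.DataFrame(rows, columns=SUBJECT_COLUMNS + extra_cols)


def write_cohort(subjects, inr: pd.DataFrame, events: pd.DataFrame, out_dir) -> dict:
    """Write subjects/inr/events CSVs; returns the file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "subjects": out_dir / "subjects.csv",
        "inr": out_dir / "inr.csv",
        "events": out_dir / "events.csv",
    }
    subjects_to_frame(subjects).to_csv(paths["subjects"], index=False)
    inr.reindex(columns=INR_COLUMNS).to_csv(paths["inr"], index=False)
    events.reindex(columns=EVENT_COLUMNS).to_csv(paths["events"], index=False)
    return paths


def write_results(tables: dict, out_dir) -> dict:
    """Write result tables as ``<name>.csv`` with deterministic columns.

    Writing is idempotent: write -> read -> write reproduces the bytes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths
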