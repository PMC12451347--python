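"""Inclusion/exclusion filtering and the one-calendar-year random selection.

Inclusion (prevalent-user design): adults (>=18 y at d0) with a single VKA
episode covering the full run-in [d0 - 60 d, d0], i.e. treatment started at
least two months before the start of Ramadan (d0 itself sits 60 days before
Ramadan).

Exclusion, applied in fixed order with each subject counted once at its
first failing rule (flowchart convention):

1. ``no_vka_dispensing`` - no dispensed VKA prescription within the 6 months
   (183 days, half-open) before d0;
2. ``doac_prior`` - any dispensed DOAC prescription in that interval;
3. ``vka_type`` - the episode active at d0 is neither acenocoumarol nor
   phenprocoumon;
4. ``missing_target_range`` - no INR target range at the last measurement
   before d0.
"""

from __future__ import annotations

import datetime as dt
import hashlib

import numpy as np
import pandas as pd

from ._types import Subject

RUN_IN_DAYS = 60
DISPENSING_LOOKBACK_DAYS = 183
ALLOWED_VKA_TYPES = frozenset({"acenocoumarol", "phenprocoumon"})

INCLUSION_RULES = ("age", "treatment<2months")
EXCLUSION_RULES = ("no_vka_dispensing", "doac_prior", "vka_type", "missing_target_range")


def check_inclusion(subject: Subject) -> tuple[bool, str | None]:
    """Return ``(passed, first_failing_rule)``; missing data counts as fail."""
    if subject.age_at_d0 is None or not subject.age_at_d0 >= 18:
        return False, "age"
    d0 = subject.anchor_d0
    run_in_start = d0 - dt.timedelta(days=RUN_IN_DAYS)
    for ep in subject.vka_episodes:
        if ep.start <= run_in_start and ep.active_at(d0):
            return True, None
    return False, "treatment<2months"


def check_exclusion(subject: Subject) -> tuple[bool, str | None]:
    """Return ``(retained, first_failing_rule)``; assumes inclusion passed."""
    d0 = subject.anchor_d0
    lookback = d0 - dt.timedelta(days=DISPENSING_LOOKBACK_DAYS)
    if not any(lookback <= d < d0 for d in subject.vka_dispensings):
        return False, "no_vka_dispensing"
    if any(lookback <= d < d0 for d in subject.doac_dispensings):
        return False, "doac_prior"
    episode = subject.episode_at(d0)
    if episode is None or episode.vka_type not in ALLOWED_VKA_TYPES:
        return False, "vka_type"
    if subject.target_range_at_d0 is None:
        return False, "missing_target_range"
    return True, None


def apply_filters(subjects) -> tuple[list[Subject], pd.DataFrame, pd.DataFrame]:
    """Run the full filter chain over a subject list.

    Returns ``(included_subjects, flow, reasons)`` where ``flow`` is the
    ordered stage->count flowchart table and ``reasons`` records the first
    failing rule per excluded subject.  Subject order never affects who is
    included.
    """
    included = []
    reason_rows = []
    counts: dict[str, int] = {"eligible": len(subjects)}
    for rule in INCLUSION_RULES + EXCLUSION_RULES:
        counts[f"excluded_{rule}"] = 0
    for s in subjects:
        ok, rule = check_inclusion(s)
        if ok:
            ok, rule = check_exclusion(s)
        if ok:
            included.append(s)
        else:
            counts[f"excluded_{rule}"] += 1
            reason_rows.append({"subject_id": s.subject_id, "rule": rule})
    counts["included"] = len(included)
    flow = pd.DataFrame({"stage": list(counts), "count": list(counts.values())})
    reasons = pd.DataFrame(reason_rows, columns=["subject_id", "rule"])
    return included, flow, reasons


def _subject_stream(seed: int, subject_id: str) -> np.random.Generator:
    """Per-subject RNG keyed on (seed, stable hash of the id).

    Hash-keyed substreams make the draw independent of subject order and of
    the presence of other subjects.
    """
    digest = hashlib.sha256(str(subject_id).encode()).digest()
    key = int.from_bytes(digest[:8], "little")
    return np.random.default_rng([int(seed), key])


def select_one_year(eligibility: dict, seed: int) -> dict:
    """Pick one calendar year per subject, uniformly at random.

    ``eligibility`` maps subject_id -> iterable of eligible calendar years.
    Subjects with a single eligible year map to it deterministically; the
    choice is reproducible under ``seed`` and invariant to dict ordering.
    """
    chosen = {}
    for subject_id, years in eligibility.items():
        years = sorted(set(int(y) for y in years))
        if not years:
            raise ValueError(f"subject {subject_id}: empty eligibility set")
        if len(years) == 1:
            chosen[subject_id] = years[0]
        else:
            rng = _subject_stream(seed, subject_id)
            chosen[subject_id] = int(rng.choice(years))
    return chosen
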