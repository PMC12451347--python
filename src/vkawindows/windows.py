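"""Observation-window construction and per-subject follow-up.

Five contiguous 30-day half-open windows partition the 150-day follow-up
[d0, d5): d2 is the Ramadan start date, d3 = d2 + 30 days (the Ramadan end
date plus one or more days so each window is exactly 30 days), d1/d0 sit 30
and 60 days before d2, and d4/d5 sit 30 and 60 days after d3.

Follow-up runs from d0 to the first of: end of the last window, first DOAC
dispensing on/after d0, first clinic-recorded DOAC use, end of the VKA
episode active at d0 (discontinuation), first clinical event of interest,
or death.  Same-day ties resolve by the fixed priority
death > clinical event > DOAC dispensing > clinic DOAC record >
discontinuation > window end.
"""

from __future__ import annotations

import datetime as dt

from ._types import (
    EXIT_PRIORITY,
    WINDOW_DAYS,
    WINDOW_INDICES,
    FollowUp,
    ObservationWindow,
    Subject,
)

_PRIORITY_RANK = {reason: i for i, reason in enumerate(EXIT_PRIORITY)}


def build_windows(ramadan_start: dt.date, ramadan_end: dt.date) -> list[ObservationWindow]:
    """Build the five 30-day windows anchored on the Ramadan start date."""
    ndays = (ramadan_end - ramadan_start).days + 1
    if not 28 <= ndays <= 30:
        raise ValueError(f"Ramadan spans {ndays} days, expected 28-30")
    d0 = ramadan_start - dt.timedelta(days=2 * WINDOW_DAYS)
    boundaries = [d0 + dt.timedelta(days=WINDOW_DAYS * i) for i in range(6)]
    return [
        ObservationWindow(index=idx, start=boundaries[i], end=boundaries[i + 1])
        for i, idx in enumerate(WINDOW_INDICES)
    ]


def compute_follow_up(subject: Subject, events, windows) -> FollowUp:
    """Derive the follow-up exit date and reason for one included subject.

    ``events`` is an iterable of (date, event_class) or EventRecord for this
    subject.  Events strictly before d0 never censor (prevalent-user
    design).
    """
    d0 = windows[0].start
    d5 = windows[-1].end
    candidates: list[tuple[dt.date, str]] = [(d5, "window_end")]

    doac = [d for d in subject.doac_dispensings if d >= d0]
    if doac:
        candidates.append((min(doac), "doac_dispensing"))
    clinic = [d for d in subject.doac_clinic_dates if d >= d0]
    if clinic:
        candidates.append((min(clinic), "doac_clinic_record"))
    episode = subject.episode_at(d0)
    if episode is not None and episode.end is not None:
        candidates.append((episode.end, "vka_discontinuation"))

    for ev in events:
        date, event_class = (ev.date, ev.event_class) if hasattr(ev, "date") else ev
        if date < d0:
            continue
        reason = "death" if event_class == "death" else "clinical_event"
        candidates.append((date, reason))

    exit_date, exit_reason = min(
        candidates, key=lambda c: (c[0], _PRIORITY_RANK[c[1]])
    )
    exit_date = min(exit_date, d5)
    if exit_date == d5 and exit_reason != "window_end":
        # an exit cause dated after follow-up end does not censor
        later = [(d, r) for d, r in candidates if d <= d5]
        exit_date, exit_reason = min(later, key=lambda c: (c[0], _PRIORITY_RANK[c[1]]))
    return FollowUp(
        subject_id=subject.subject_id, entry=d0, exit=exit_date, exit_reason=exit_reason
    )


def at_risk_at(follow_up: FollowUp, window_start: dt.date) -> bool:
    """True if the subject enters the window alive, uncensored, event-free.

    A subject whose clinical event or death falls exactly on the window
    start is still counted at risk there (the event belongs to that window).
    """
    if follow_up.exit > window_start:
        return True
    return follow_up.exit == window_start and follow_up.exit_reason in (
        "clinical_event",
        "death",
    )


def subjects_at_risk(follow_ups, window: ObservationWindow) -> int:
    """Count subjects at risk at the start of ``window``."""
    return sum(at_risk_at(fu, window.start) for fu in follow_ups)
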