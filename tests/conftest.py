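"""Shared fixtures: hand-built miniature cohorts with explicit structure."""

from __future__ import annotations

import itertools

import pandas as pd
import pytest

from engagekit.cohort import (
    CHARACTERISTICS,
    Cohort,
    SURVEY_ITEM_COLUMNS,
    empty_events,
    empty_sessions,
)

BASE = pd.Timestamp("2024-04-01")

_session_counter = itertools.count(1)
_event_counter = itertools.count(1)


def make_profile(pid: str, enroll=BASE, **chars) -> dict:
    row = {c: cats[0] for c, cats in CHARACTERISTICS.items()}
    row.update(chars)
    return {"participant_id": pid, "enrollment_date": pd.Timestamp(enroll), **row}


def make_session(pid, day=0, hour=9, minutes=10.0, pages=5, enroll=BASE, sid=None):
    start = pd.Timestamp(enroll) + pd.Timedelta(days=day, hours=hour)
    return {
        "session_id": sid or f"{pid}-T{next(_session_counter):04d}",
        "participant_id": pid,
        "session_start": start,
        "session_end": start + pd.Timedelta(minutes=minutes),
        "page_views": pages,
    }


def make_event(pid, kind, sid="", day=0, hour=10, enroll=BASE):
    return {
        "event_id": f"{pid}-X{next(_event_counter):04d}",
        "participant_id": pid,
        "session_id": sid,
        "timestamp": pd.Timestamp(enroll) + pd.Timedelta(days=day, hours=hour),
        "kind": kind,
    }


def make_survey(pid, total=80):
    base, rem = divmod(total, 20)
    items = [base + (1 if j < rem else 0) for j in range(20)]
    row = {"participant_id": pid}
    row.update({col: items[j] for j, col in enumerate(SURVEY_ITEM_COLUMNS)})
    row["total"] = sum(items)
    return row


def build_cohort(profiles, sessions=(), events=(), surveys=()) -> Cohort:
    return Cohort(
        profiles=pd.DataFrame(list(profiles)),
        sessions=pd.DataFrame(list(sessions)) if sessions else empty_sessions(),
        events=pd.DataFrame(list(events)) if events else empty_events(),
        surveys=pd.DataFrame(list(surveys))
        if surveys
        else pd.DataFrame(columns=["participant_id", *SURVEY_ITEM_COLUMNS, "total"]),
    )


@pytest.fixture
def two_person_cohort():
    """Two participants, a handful of sessions and events, both surveyed."""
    profiles = [make_profile("A", self_help="yes"), make_profile("B")]
    sessions = [
        make_session("A", day=0, pages=5, minutes=10.0),
        make_session("A", day=1, pages=3, minutes=17.2),
        make_session("A", day=2, pages=8, minutes=5.0),
        make_session("B", day=0, pages=4, minutes=2.0),
    ]
    events = [
        make_event("A", "comment", day=0),
        make_event("A", "public_question", day=1),
        make_event("B", "rating", day=0),
    ]
    surveys = [make_survey("A", total=84), make_survey("B", total=60)]
    return build_cohort(profiles, sessions, events, surveys)
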