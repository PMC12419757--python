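"""Cohort data model and on-disk layout.

A cohort is held as four tidy :class:`pandas.DataFrame` tables:

``profiles``
    One row per participant: id, enrollment date and the eight categorical
    characteristics used for group comparisons (age group, marital status,
    living status, education, employment, perceived economic status, HIV care
    stage, self-help group participation).
``sessions``
    One row per app session: id, participant, start/end timestamps and the
    number of pages viewed.
``events``
    One row per typed interaction event (comment, public/private question,
    rating, medication/mood/sexual-health record), linked to its session.
``surveys``
    One row per post-intervention usability survey: twenty 1-5 Likert items
    and their total (range 20-100).

On disk a cohort is three CSV files plus a JSON-lines event file; all
timestamps are ISO-8601.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Closed set of interaction-event kinds recorded by the app.
EVENT_KINDS: tuple[str, ...] = (
    "comment",
    "public_question",
    "private_question",
    "rating",
    "medication_record",
    "mood_record",
    "sexual_health_record",
)

#: In-app reward points per event ("mileage"): self-care records, ratings and
#: comments earn 100 points each, private Q&A posts 1000, public Q&A posts 2000.
MILEAGE_TARIFF: dict[str, int] = {
    "comment": 100,
    "rating": 100,
    "medication_record": 100,
    "mood_record": 100,
    "sexual_health_record": 100,
    "private_question": 1000,
    "public_question": 2000,
}

#: Participant characteristics and their closed, ordered category sets.
CHARACTERISTICS: dict[str, tuple[str, ...]] = {
    "age_group": ("<29", "30-39", "40-49", ">=50"),
    "marital_status": ("spouse", "no_spouse"),
    "living_status": ("alone", "with_others"),
    "education": ("<=high_school", ">=college"),
    "employment": ("unemployed", "employed"),
    "economic_status": ("low", "middle", "high"),
    "care_stage": (
        "diagnosis_to_medication",
        "medication_to_familiarization",
        "familiarization_to_sustaining",
    ),
    "self_help": ("yes", "no"),
}

PROFILE_COLUMNS = ["participant_id", "enrollment_date", *CHARACTERISTICS]
SESSION_COLUMNS = ["session_id", "participant_id", "session_start", "session_end", "page_views"]
EVENT_COLUMNS = ["event_id", "participant_id", "session_id", "timestamp", "kind"]
SURVEY_ITEM_COLUMNS = [f"item_{i:02d}" for i in range(1, 21)]
SURVEY_COLUMNS = ["participant_id", *SURVEY_ITEM_COLUMNS, "total"]

_TS_FORMAT = "%Y-%m-%dT%H:%M:%S"


@dataclass
class Cohort:
    """In-memory cohort: profiles, sessions, events and surveys tables.

    ``truth`` optionally carries the latent per-participant generation
    parameters of a synthetic cohort (login propensity); it is never used by
    the scoring or statistics code.
    """

    profiles: pd.DataFrame
    sessions: pd.DataFrame
    events: pd.DataFrame
    surveys: pd.DataFrame
    truth: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_participants(self) -> int:
        return len(self.profiles)

    def copy(self) -> "Cohort":
        return Cohort(
            profiles=self.profiles.copy(),
            sessions=self.sessions.copy(),
            events=self.events.copy(),
            surveys=self.surveys.copy(),
            truth=None if self.truth is None else self.truth.copy(),
        )


def empty_sessions() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "session_id": pd.Series(dtype=str),
            "participant_id": pd.Series(dtype=str),
            "session_start": pd.Series(dtype="datetime64[s]"),
            "session_end": pd.Series(dtype="datetime64[s]"),
            "page_views": pd.Series(dtype=np.int64),
        }
    )


def empty_events() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "event_id": pd.Series(dtype=str),
            "participant_id": pd.Series(dtype=str),
            "session_id": pd.Series(dtype=str),
            "timestamp": pd.Series(dtype="datetime64[s]"),
            "kind": pd.Series(dtype=str),
        }
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort to ``out_dir`` as profiles/sessions/surveys CSV plus an
    events JSONL file. Returns the paths written. Deterministic byte-for-byte
    for identical cohorts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "profiles": out / "profiles.csv",
        "sessions": out / "sessions.csv",
        "surveys": out / "surveys.csv",
        "events": out / "events.jsonl",
    }

    profiles = cohort.profiles.copy()
    profiles["enrollment_date"] = pd.to_datetime(profiles["enrollment_date"]).dt.strftime("%Y-%m-%d")
    profiles[PROFILE_COLUMNS].to_csv(paths["profiles"], index=False)

    sessions = cohort.sessions.copy()
    for col in ("session_start", "session_end"):
        sessions[col] = pd.to_datetime(sessions[col]).dt.strftime(_TS_FORMAT)
    sessions[SESSION_COLUMNS].to_csv(paths["sessions"], index=False)

    cohort.surveys[SURVEY_COLUMNS].to_csv(paths["surveys"], index=False)

    events = cohort.events
    with open(paths["events"], "w") as fh:
        for row in events.itertuples(index=False):
            rec = {
                "event_id": row.event_id,
                "participant_id": row.participant_id,
                "session_id": row.session_id,
                "timestamp": pd.Timestamp(row.timestamp).strftime(_TS_FORMAT),
                "kind": row.kind,
            }
            fh.write(json.dumps(rec, separators=(",", ":")) + "\n")
    return paths


def read_cohort(in_dir: str | Path) -> Cohort:
    """Read a cohort from the CSV/JSONL layout produced by :func:`write_cohort`."""
    d = Path(in_dir)
    profiles = pd.read_csv(d / "profiles.csv", dtype={"participant_id": str})
    profiles["enrollment_date"] = pd.to_datetime(profiles["enrollment_date"])

    sessions = pd.read_csv(d / "sessions.csv", dtype={"participant_id": str, "session_id": str})
    if len(sessions):
        for col in ("session_start", "session_end"):
            sessions[col] = pd.to_datetime(sessions[col])
    else:
        sessions = empty_sessions()

    surveys = pd.read_csv(d / "surveys.csv", dtype={"participant_id": str})

    rows = []
    with open(d / "events.jsonl") as fh:
        for line in fh:
            line = line.strip()
            if line:
                rows.append(json.loads(line))
    if rows:
        events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
        events["timestamp"] = pd.to_datetime(events["timestamp"])
    else:
        events = empty_events()
    return Cohort(profiles=profiles, sessions=sessions, events=events, surveys=surveys)
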