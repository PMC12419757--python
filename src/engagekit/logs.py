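"""Usage-log preprocessing: validation, engagement time, visit gaps,
daily-active-user curves and mileage accounting.

Conventions (fixed so the downstream subindices are deterministic):

* calendar days are counted relative to each participant's enrollment date;
  a session is attributed to the day it starts on, even if it spans midnight;
* the observation window is the half-open interval
  ``[enrollment, enrollment + window_days)``; sessions must start inside it,
  and durations extending past the boundary are truncated there;
* overlapping sessions of one participant are merged before durations are
  summed, so engagement time never double-counts wall-clock time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, EVENT_KINDS, MILEAGE_TARIFF, SURVEY_ITEM_COLUMNS
from .errors import CohortValidationError, UndefinedInputError

__all__ = [
    "ValidationReport",
    "validate_log",
    "engagement_time",
    "engagement_time_by_participant",
    "visit_gaps",
    "mean_visit_gap_by_participant",
    "daily_active_users",
    "mileage_total",
    "mileage_by_participant",
    "sessionize_events",
]


@dataclass
class ValidationReport:
    """Outcome of structural validation of a cohort.

    ``analyzable_ids`` are participants with a survey and at least one
    in-window session — the set the engagement index is computed over.
    Participants lacking a survey are flagged (mirroring exclusion of
    post-survey non-completers from analysis), not errors.
    """

    n_profiles: int
    analyzable_ids: list[str]
    missing_survey_ids: list[str] = field(default_factory=list)
    no_session_ids: list[str] = field(default_factory=list)

    @property
    def n_analyzable(self) -> int:
        return len(self.analyzable_ids)


def validate_log(cohort: Cohort, window_days: int = 28) -> ValidationReport:
    """Validate a cohort structurally and return a :class:`ValidationReport`.

    Raises
    ------
    CohortValidationError
        On structural violations (unknown participants, negative durations,
        out-of-window session starts, survey checksum failures, unknown event
        kinds), with a record locator per problem.
    """
    problems: list[str] = []
    profiles, sessions, events, surveys = (
        cohort.profiles,
        cohort.sessions,
        cohort.events,
        cohort.surveys,
    )

    dup = profiles["participant_id"][profiles["participant_id"].duplicated()]
    for pid in dup.unique():
        problems.append(f"profiles[{pid!r}]: duplicate participant_id")
    known = set(profiles["participant_id"])
    enroll = profiles.set_index("participant_id")["enrollment_date"]

    if len(sessions):
        s_pid = sessions["participant_id"]
        bad_pid = ~s_pid.isin(known).to_numpy()
        for idx in np.flatnonzero(bad_pid):
            problems.append(f"sessions[row {idx}]: unknown participant {s_pid.iloc[idx]!r}")
        ok = ~bad_pid
        if ok.any():
            e0 = s_pid.map(enroll).to_numpy()
            start = sessions["session_start"].to_numpy()
            end = sessions["session_end"].to_numpy()
            neg = ok & (end < start)
            for idx in np.flatnonzero(neg):
                problems.append(f"sessions[row {idx}]: negative duration (end before start)")
            wend = e0 + np.timedelta64(window_days, "D").astype("timedelta64[ns]")
            oow = ok & ((start < e0) | (start >= wend))
            for idx in np.flatnonzero(oow):
                problems.append(
                    f"sessions[row {idx}]: session_start outside [enrollment, +{window_days}d)"
                )

    if len(events):
        bad_pid = ~events["participant_id"].isin(known)
        for idx in np.flatnonzero(bad_pid.to_numpy()):
            problems.append(f"events[row {idx}]: unknown participant")
        bad_kind = ~events["kind"].isin(EVENT_KINDS)
        for idx in np.flatnonzero(bad_kind.to_numpy()):
            problems.append(f"events[row {idx}]: unknown kind {events['kind'].iloc[idx]!r}")

    if len(surveys):
        dup_s = surveys["participant_id"][surveys["participant_id"].duplicated()]
        for pid in dup_s.unique():
            problems.append(f"surveys[{pid!r}]: more than one survey")
        unknown_s = ~surveys["participant_id"].isin(known)
        for idx in np.flatnonzero(unknown_s.to_numpy()):
            problems.append(f"surveys[row {idx}]: unknown participant")
        items = surveys[SURVEY_ITEM_COLUMNS].to_numpy()
        if ((items < 1) | (items > 5)).any():
            for idx in np.flatnonzero(((items < 1) | (items > 5)).any(axis=1)):
                problems.append(f"surveys[row {idx}]: item score outside [1, 5]")
        mismatch = surveys["total"].to_numpy() != items.sum(axis=1)
        for idx in np.flatnonzero(mismatch):
            problems.append(f"surveys[row {idx}]: total does not equal the sum of items")

    if problems:
        raise CohortValidationError(problems)

    surveyed = set(surveys["participant_id"])
    with_sessions = set(sessions["participant_id"]) if len(sessions) else set()
    all_ids = list(profiles["participant_id"])
    missing_survey = sorted(set(all_ids) - surveyed)
    no_sessions = sorted(set(all_ids) - with_sessions)
    analyzable = sorted(set(all_ids) & surveyed & with_sessions)
    return ValidationReport(
        n_profiles=len(all_ids),
        analyzable_ids=analyzable,
        missing_survey_ids=missing_survey,
        no_session_ids=no_sessions,
    )


def _merge_intervals(start: np.ndarray, end: np.ndarray) -> float:
    """Total covered length (in ns if datetime64, else same units) of a union
    of intervals."""
    order = np.argsort(start, kind="stable")
    start, end = start[order], end[order]
    total = 0.0
    cur_s, cur_e = start[0], end[0]
    for s, e in zip(start[1:], end[1:]):
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            total += float(cur_e - cur_s)
            cur_s, cur_e = s, e
    total += float(cur_e - cur_s)
    return total


def engagement_time(
    sessions: pd.DataFrame,
    enrollment: pd.Timestamp,
    window_days: int = 28,
    merge_overlaps: bool = True,
) -> float:
    """Cumulative app-use duration in minutes for one participant.

    Sums ``session_end - session_start`` over the participant's sessions,
    truncating at the window boundary ``enrollment + window_days``; returns
    0.0 for an empty session table. Overlapping sessions are merged first by
    default so concurrent records do not double-count.
    """
    if len(sessions) == 0:
        return 0.0
    wend = pd.Timestamp(enrollment) + pd.Timedelta(days=window_days)
    start = np.maximum(sessions["session_start"].to_numpy(), np.datetime64(pd.Timestamp(enrollment)))
    end = np.minimum(sessions["session_end"].to_numpy(), np.datetime64(wend))
    end = np.maximum(end, start)
    if merge_overlaps:
        total_ns = _merge_intervals(start.astype("datetime64[ns]"), end.astype("datetime64[ns]"))
    else:
        total_ns = float((end - start).astype("timedelta64[ns]").astype(np.int64).sum())
    return total_ns / 1e9 / 60.0


def engagement_time_by_participant(
    sessions: pd.DataFrame,
    profiles: pd.DataFrame,
    window_days: int = 28,
    merge_overlaps: bool = True,
) -> pd.Series:
    """Vectorised engagement time (minutes) for every profiled participant.

    Participants without sessions get 0.0. Equivalent to calling
    :func:`engagement_time` per participant, but in a single pandas sweep.
    """
    ids = profiles["participant_id"]
    if len(sessions) == 0:
        return pd.Series(0.0, index=pd.Index(ids, name="participant_id"))
    df = sessions[["participant_id", "session_start", "session_end"]].merge(
        profiles[["participant_id", "enrollment_date"]], on="participant_id", how="inner"
    )
    wend = df["enrollment_date"] + pd.Timedelta(days=window_days)
    s = np.maximum(df["session_start"].to_numpy(), df["enrollment_date"].to_numpy())
    e = np.minimum(df["session_end"].to_numpy(), wend.to_numpy())
    e = np.maximum(e, s)
    df = df.assign(_s=s, _e=e).sort_values(["participant_id", "_s"], kind="stable")
    if merge_overlaps:
        grp = df.groupby("participant_id", sort=False)
        cummax_end = grp["_e"].cummax()
        prev_end = cummax_end.groupby(df["participant_id"], sort=False).shift(1)
        new_block = prev_end.isna() | (df["_s"] > prev_end)
        df = df.assign(_block=new_block.cumsum())
        blocks = df.groupby(["participant_id", "_block"], sort=False).agg(
            _s=("_s", "min"), _e=("_e", "max")
        )
        per = (blocks["_e"] - blocks["_s"]).groupby("participant_id").sum()
    else:
        per = (df["_e"] - df["_s"]).groupby(df["participant_id"]).sum()
    minutes = per.dt.total_seconds() / 60.0
    return minutes.reindex(ids, fill_value=0.0).rename_axis("participant_id")


def _visit_days(sessions: pd.DataFrame, enrollment: pd.Timestamp) -> np.ndarray:
    days = (
        (sessions["session_start"].dt.normalize() - pd.Timestamp(enrollment).normalize())
        .dt.days.to_numpy()
    )
    return np.unique(days)


def visit_gaps(sessions: pd.DataFrame, enrollment: pd.Timestamp) -> np.ndarray:
    """Day gaps between consecutive distinct visit days of one participant.

    Sessions are collapsed to distinct calendar days since enrollment;
    consecutive differences are returned. A participant with a single visit
    day yields an empty array. Zero sessions is undefined input.
    """
    if len(sessions) == 0:
        raise UndefinedInputError("visit_gaps requires at least one session")
    days = _visit_days(sessions, enrollment)
    return np.diff(days)


def mean_visit_gap_by_participant(
    sessions: pd.DataFrame, profiles: pd.DataFrame
) -> pd.Series:
    """Mean day-gap between distinct visit days per participant (NaN when the
    participant has fewer than two distinct visit days or no sessions)."""
    ids = pd.Index(profiles["participant_id"], name="participant_id")
    if len(sessions) == 0:
        return pd.Series(np.nan, index=ids)
    df = sessions[["participant_id", "session_start"]].merge(
        profiles[["participant_id", "enrollment_date"]], on="participant_id", how="inner"
    )
    day = (df["session_start"].dt.normalize() - df["enrollment_date"]).dt.days
    dd = (
        pd.DataFrame({"participant_id": df["participant_id"], "day": day})
        .drop_duplicates()
        .sort_values(["participant_id", "day"], kind="stable")
    )
    gaps = dd.groupby("participant_id", sort=False)["day"].diff()
    mean_gap = gaps.groupby(dd["participant_id"], sort=False).mean()
    return mean_gap.reindex(ids)


def daily_active_users(
    sessions: pd.DataFrame,
    profiles: pd.DataFrame,
    window_days: int = 28,
    origin: str = "enrollment",
) -> np.ndarray:
    """Active-user counts by participant-relative day.

    ``counts[d]`` is the number of participants with at least one session on
    their personal day ``d`` for ``d`` in ``[0, window_days)``. Days are
    counted from each participant's enrollment date by default
    (``origin="enrollment"``); ``origin="first_session"`` re-anchors each
    participant at their first visit day instead.
    """
    if origin not in ("enrollment", "first_session"):
        raise ValueError("origin must be 'enrollment' or 'first_session'")
    counts = np.zeros(window_days, dtype=np.int64)
    if len(sessions) == 0:
        return counts
    df = sessions[["participant_id", "session_start"]].merge(
        profiles[["participant_id", "enrollment_date"]], on="participant_id", how="inner"
    )
    day = (df["session_start"].dt.normalize() - df["enrollment_date"]).dt.days
    dd = pd.DataFrame({"participant_id": df["participant_id"], "day": day}).drop_duplicates()
    if origin == "first_session":
        first = dd.groupby("participant_id")["day"].transform("min")
        dd = dd.assign(day=dd["day"] - first)
    dd = dd[(dd["day"] >= 0) & (dd["day"] < window_days)]
    binc = np.bincount(dd["day"].to_numpy(), minlength=window_days)
    counts[: len(binc)] = binc[:window_days]
    return counts


def mileage_total(events) -> int:
    """Reward points for one participant's events under the in-app tariff
    (records/ratings/comments 100, private questions 1000, public 2000).

    Accepts an events DataFrame (with a ``kind`` column) or an iterable of
    kind strings.
    """
    if isinstance(events, pd.DataFrame):
        kinds = events["kind"]
    else:
        kinds = pd.Series(list(events), dtype=object)
    if len(kinds) == 0:
        return 0
    unknown = set(kinds) - set(MILEAGE_TARIFF)
    if unknown:
        raise UndefinedInputError(f"unknown event kind(s): {sorted(unknown)}")
    return int(kinds.map(MILEAGE_TARIFF).sum())


def mileage_by_participant(events: pd.DataFrame, profiles: pd.DataFrame) -> pd.Series:
    """Vectorised mileage per profiled participant (0 for no events)."""
    ids = pd.Index(profiles["participant_id"], name="participant_id")
    if len(events) == 0:
        return pd.Series(0, index=ids, dtype=np.int64)
    pts = events["kind"].map(MILEAGE_TARIFF)
    per = pts.groupby(events["participant_id"]).sum()
    return per.reindex(ids, fill_value=0).astype(np.int64)


def sessionize_events(
    events: pd.DataFrame, gap_minutes: float = 30.0
) -> pd.DataFrame:
    """Reconstruct sessions from a raw event stream by inactivity gaps.

    Auxiliary tool for logs that arrive without session boundaries: events of
    one participant separated by more than ``gap_minutes`` start a new
    session. ``page_views`` is the number of events in the session. The
    reference analysis uses recorded sessions; this is provided for raw
    streams only.
    """
    if len(events) == 0:
        return pd.DataFrame(
            columns=["session_id", "participant_id", "session_start", "session_end", "page_views"]
        )
    ev = events.sort_values(["participant_id", "timestamp"], kind="stable")
    gap = pd.Timedelta(minutes=gap_minutes)
    prev = ev.groupby("participant_id", sort=False)["timestamp"].shift(1)
    new_session = prev.isna() | ((ev["timestamp"] - prev) > gap)
    block = new_session.cumsum()
    out = ev.groupby(block).agg(
        participant_id=("participant_id", "first"),
        session_start=("timestamp", "min"),
        session_end=("timestamp", "max"),
        page_views=("timestamp", "size"),
    )
    seq = out.groupby("participant_id").cumcount() + 1
    out.insert(
        0,
        "session_id",
        out["participant_id"] + "-R" + seq.astype(str).str.zfill(4),
    )
    return out.reset_index(drop=True)
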