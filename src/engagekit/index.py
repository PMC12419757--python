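"""The five-subindex engagement index.

Per participant, five subindices are computed on a 0-100 scale and averaged
into a composite engagement index:

* **click depth** — share of sessions with at least ``threshold`` (default 4)
  page views; filters out open-and-close visits;
* **loyalty** — ``100 * (1 - 1/n_sessions)``; one-time visitors score 0,
  frequent visitors approach 100;
* **recency** — ``100 * min(1, 1 / mean day-gap between visits)``; daily
  users score 100, capped so same-day repeat visits cannot exceed the scale;
* **feedback** — the post-intervention 20-item usability survey total (range
  20-100) read as a percentage of its 100-point maximum;
* **interaction** — mean of a participant's comment/question/rating counts,
  each normalised by the cohort maximum of that count.

The interaction subindex is the only cohort-relative quantity, so scoring is
a fit/transform operation: :class:`EngagementIndexScorer.fit` learns the
cohort interaction maxima over the analyzable set (survey returned, at least
one session), and ``transform`` emits one summary row per participant.
"""

from __future__ import annotations

from dataclasses import dataclass
from numbers import Integral, Real

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import Cohort
from .errors import BoundsError, ConsistencyError, EmptyCohortError, UndefinedInputError
from .logs import (
    engagement_time_by_participant,
    mean_visit_gap_by_participant,
    mileage_by_participant,
    validate_log,
)

SUBINDEX_NAMES = ("click_depth", "loyalty", "recency", "feedback", "interaction")


@dataclass(frozen=True)
class InteractionMaxima:
    """Cohort-wide maxima of the three interaction counts."""

    max_comments: int
    max_questions: int
    max_ratings: int


def click_depth_index(page_views, threshold: int = 4) -> float:
    """Percent of sessions with at least ``threshold`` page views.

    A session navigating home -> input screen -> date selection -> completion
    renders four pages and qualifies at the default threshold.
    """
    pv = np.asarray(page_views)
    if pv.size == 0:
        raise UndefinedInputError("click_depth_index requires at least one session")
    if threshold < 1:
        raise ValueError("threshold must be a positive integer")
    return 100.0 * float(np.mean(pv >= threshold))


def loyalty_index(n_sessions: int) -> float:
    """``100 * (1 - 1/n_sessions)``: 0 for a one-time visitor, approaching 100
    for frequent visitors."""
    if not isinstance(n_sessions, (int, np.integer)) or n_sessions < 1:
        raise UndefinedInputError("loyalty_index requires an integer session count >= 1")
    return 100.0 * (1.0 - 1.0 / float(n_sessions))


def recency_index(gaps, window_days: int = 28) -> float:
    """``100 * min(1, 1 / mean(gaps))`` over the day-gaps between distinct
    visit days; capped at 100 for sub-daily gaps. A participant with a single
    visit day (empty gap list) scores ``100 / window_days``, the least-recent
    pattern the reciprocal-gap idea extends to."""
    g = np.asarray(gaps, dtype=float)
    if g.size == 0:
        return 100.0 / float(window_days)
    if (g <= 0).any():
        raise ValueError("day gaps must be positive")
    return 100.0 * min(1.0, 1.0 / float(np.mean(g)))


def feedback_index(total: int) -> float:
    """Usability-survey total (20-100) as a percent of the 100-point maximum."""
    if not isinstance(total, (int, np.integer)) or not (20 <= total <= 100):
        raise BoundsError("survey total must be an integer in [20, 100]")
    return float(total)


def interaction_index(
    comments: int, questions: int, ratings: int, maxima: InteractionMaxima
) -> float:
    """Mean of the three count/cohort-maximum ratios, as a percent.

    A category whose cohort maximum is 0 contributes a ratio of 0 for
    everyone; a participant count above its maximum is inconsistent.
    """
    ratios = []
    for count, mx, label in (
        (comments, maxima.max_comments, "comments"),
        (questions, maxima.max_questions, "questions"),
        (ratings, maxima.max_ratings, "ratings"),
    ):
        if count < 0:
            raise ValueError(f"{label} count must be non-negative")
        if count > mx:
            raise ConsistencyError(f"{label} count {count} exceeds cohort maximum {mx}")
        ratios.append(0.0 if mx == 0 else count / mx)
    return 100.0 * float(np.mean(ratios))


def engagement_index(subindices) -> float:
    """Arithmetic mean of the five subindices (each 0-100)."""
    sub = np.asarray(subindices, dtype=float)
    if sub.shape != (5,):
        raise ValueError("expected exactly five subindices")
    if (sub < 0).any() or (sub > 100).any():
        raise BoundsError("every subindex must lie in [0, 100]")
    return float(np.mean(sub))


class EngagementIndexScorer(BaseEstimator, TransformerMixin):
    """Score a cohort's engagement: five subindices, composite index,
    engagement time, session count and mileage per participant.

    Parameters
    ----------
    click_depth_threshold : int, default=4
        Minimum page views for a session to count as meaningful engagement.
    window_days : int, default=28
        Observation-window length; also the recency fallback denominator.
    pool_questions : bool, default=True
        Count public and private questions as a single "questions" category
        in the interaction subindex (the mileage tariff still distinguishes
        them).
    merge_overlapping : bool, default=True
        Merge overlapping sessions before summing engagement time.

    Attributes
    ----------
    interaction_maxima_ : InteractionMaxima
        Cohort maxima of the interaction counts, learned in ``fit`` over the
        analyzable set.
    analyzable_ids_ : list of str
        Participants with a survey and >= 1 session at fit time.
    validation_report_ : ValidationReport
        Structural-validation outcome of the fitted cohort.
    """

    def __init__(
        self,
        click_depth_threshold: int = 4,
        window_days: int = 28,
        pool_questions: bool = True,
        merge_overlapping: bool = True,
    ):
        self.click_depth_threshold = click_depth_threshold
        self.window_days = window_days
        self.pool_questions = pool_questions
        self.merge_overlapping = merge_overlapping

    # -- helpers ----------------------------------------------------------

    def _check_params(self):
        if not isinstance(self.click_depth_threshold, Integral) or self.click_depth_threshold < 1:
            raise ValueError("click_depth_threshold must be a positive integer")
        if not isinstance(self.window_days, Integral) or self.window_days < 1:
            raise ValueError("window_days must be a positive integer")

    def _interaction_counts(self, cohort: Cohort, ids: list[str]) -> pd.DataFrame:
        """Comment/question/rating counts per participant in ``ids``."""
        idx = pd.Index(ids, name="participant_id")
        ev = cohort.events
        ev = ev[ev["participant_id"].isin(idx)] if len(ev) else ev
        counts = pd.DataFrame(0, index=idx, columns=["comments", "questions", "ratings"], dtype=np.int64)
        if len(ev):
            pivot = ev.pivot_table(index="participant_id", columns="kind", aggfunc="size", fill_value=0)
            def col(kind):
                return pivot[kind] if kind in pivot else pd.Series(0, index=pivot.index)
            counts["comments"] = col("comment").reindex(idx, fill_value=0)
            if self.pool_questions:
                q = col("public_question").add(col("private_question"), fill_value=0)
            else:
                q = col("public_question")
            counts["questions"] = q.reindex(idx, fill_value=0)
            counts["ratings"] = col("rating").reindex(idx, fill_value=0)
        return counts.astype(np.int64)

    # -- estimator API ----------------------------------------------------

    def fit(self, X: Cohort, y=None):
        """Validate the cohort and learn the interaction maxima over the
        analyzable participants."""
        self._check_params()
        report = validate_log(X, window_days=int(self.window_days))
        if not report.analyzable_ids:
            raise EmptyCohortError(
                "no analyzable participant (survey returned and >= 1 session)"
            )
        counts = self._interaction_counts(X, report.analyzable_ids)
        self.validation_report_ = report
        self.analyzable_ids_ = list(report.analyzable_ids)
        self.interaction_maxima_ = InteractionMaxima(
            max_comments=int(counts["comments"].max()),
            max_questions=int(counts["questions"].max()),
            max_ratings=int(counts["ratings"].max()),
        )
        return self

    def transform(self, X: Cohort) -> pd.DataFrame:
        """Per-participant engagement summaries for the analyzable set of ``X``.

        Returns a DataFrame indexed by ``participant_id`` with the five
        subindices, the composite ``engagement_index``, ``engagement_time_min``,
        ``n_sessions`` and ``mileage``.
        """
        if not hasattr(self, "interaction_maxima_"):
            raise AttributeError("EngagementIndexScorer is not fitted; call fit first")
        report = validate_log(X, window_days=int(self.window_days))
        ids = report.analyzable_ids
        if not ids:
            raise EmptyCohortError("no analyzable participant in the cohort to transform")
        idx = pd.Index(ids, name="participant_id")
        profiles = X.profiles[X.profiles["participant_id"].isin(idx)]
        sessions = X.sessions[X.sessions["participant_id"].isin(idx)]

        n_sessions = sessions.groupby("participant_id").size().reindex(idx, fill_value=0)
        deep = (
            sessions.assign(_deep=sessions["page_views"] >= int(self.click_depth_threshold))
            .groupby("participant_id")["_deep"]
            .mean()
            .reindex(idx)
        )
        click_depth = 100.0 * deep

        loyalty = 100.0 * (1.0 - 1.0 / n_sessions.astype(float))

        mean_gap = mean_visit_gap_by_participant(sessions, profiles).reindex(idx)
        recency = pd.Series(
            np.where(
                mean_gap.isna(),
                100.0 / float(self.window_days),
                100.0 * np.minimum(1.0, 1.0 / mean_gap.to_numpy(dtype=float)),
            ),
            index=idx,
        )

        feedback = (
            X.surveys.set_index("participant_id")["total"].reindex(idx).astype(float)
        )

        counts = self._interaction_counts(X, ids)
        mx = self.interaction_maxima_
        for col, cap in (
            ("comments", mx.max_comments),
            ("questions", mx.max_questions),
            ("ratings", mx.max_ratings),
        ):
            if (counts[col] > cap).any():
                bad = counts.index[counts[col] > cap][0]
                raise ConsistencyError(
                    f"{col} count for {bad!r} exceeds fitted cohort maximum {cap}"
                )
        def ratio(col, cap):
            return counts[col].to_numpy(float) / cap if cap > 0 else np.zeros(len(counts))
        interaction = pd.Series(
            100.0
            * (
                ratio("comments", mx.max_comments)
                + ratio("questions", mx.max_questions)
                + ratio("ratings", mx.max_ratings)
            )
            / 3.0,
            index=idx,
        )

        composite = (click_depth + loyalty + recency + feedback + interaction) / 5.0

        out = pd.DataFrame(
            {
                "n_sessions": n_sessions.astype(np.int64),
                "click_depth": click_depth,
                "loyalty": loyalty,
                "recency": recency,
                "feedback": feedback,
                "interaction": interaction,
                "engagement_index": composite,
                "engagement_time_min": engagement_time_by_participant(
                    sessions, profiles, int(self.window_days), self.merge_overlapping
                ).reindex(idx),
                "mileage": mileage_by_participant(
                    X.events[X.events["participant_id"].isin(idx)] if len(X.events) else X.events,
                    profiles,
                ).reindex(idx, fill_value=0),
            }
        )
        bounded = out[list(SUBINDEX_NAMES) + ["engagement_index"]].to_numpy()
        if (bounded < -1e-9).any() or (bounded > 100 + 1e-9).any():
            raise BoundsError("computed subindex outside [0, 100]")
        return out.sort_index()


def score_cohort(cohort: Cohort, **params) -> pd.DataFrame:
    """Fit an :class:`EngagementIndexScorer` on ``cohort`` and return the
    per-participant summary table. Keyword arguments are scorer parameters."""
    return EngagementIndexScorer(**params).fit(cohort).transform(cohort)
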