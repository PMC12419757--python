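"""Seeded synthetic cohort generator.

Generates participant profiles, session logs, interaction events and
usability surveys with the statistical structure the downstream analysis
assumes:

* each participant has a fixed latent daily-login probability drawn from a
  Beta distribution (overdispersed session counts across the cohort);
* participants in a self-help group get an additive shift of the Beta
  location (a configurable engagement effect; 0 = null);
* each login day yields one or more sessions with shifted-negative-binomial
  page views and lognormal durations; a per-participant lognormal duration
  multiplier creates the "super-user" heavy right tail seen in cumulative
  engagement time;
* interaction events are assigned to sessions; counts are negative-binomial
  (a few prolific commenters/raters dominate the cohort maxima) with
  expected counts scaling with login propensity;
* survey totals follow a left-skewed Beta on the instrument range [20, 100],
  decomposed exactly into twenty 1-5 Likert items.

Every participant has an independent RNG stream derived from
``(seed, participant index)``, so changing the cohort size leaves the
participants already generated unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import (
    CHARACTERISTICS,
    EVENT_KINDS,
    Cohort,
    empty_events,
    empty_sessions,
)
from .config import CohortConfig

_SECONDS_PER_DAY = 86400


def _survey_items(total: int, rng: np.random.Generator) -> np.ndarray:
    """Decompose a survey total in [20, 100] into twenty 1-5 items summing to it."""
    base = total // 20
    rem = total - 20 * base
    items = np.full(20, base, dtype=np.int64)
    if rem:
        bump = rng.choice(20, size=rem, replace=False)
        items[bump] += 1
    return items


class _Columns:
    """Column-wise accumulator: append per-participant arrays, concatenate once."""

    def __init__(self, names):
        self.data = {n: [] for n in names}

    def append(self, **cols):
        for name, values in cols.items():
            self.data[name].append(values)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {n: np.concatenate(v) if v else np.array([]) for n, v in self.data.items()}
        )


def generate_cohort(config: CohortConfig, seed: int | None = None) -> Cohort:
    """Generate a synthetic cohort under ``config``.

    Parameters
    ----------
    config : CohortConfig
        Validated generator configuration.
    seed : int, optional
        Overrides ``config.seed`` without mutating the config.

    Returns
    -------
    Cohort
        Profiles, sessions, events and surveys; ``truth`` holds each
        participant's latent login propensity and duration multiplier.
    """
    config.validate()
    root_seed = config.seed if seed is None else int(seed)
    if root_seed < 0:
        raise ValueError("seed must be non-negative")

    window = config.window_days
    base_date = np.datetime64(config.start_date, "D")
    prop_mean = config.session_propensity["mean"]
    conc = config.session_propensity["concentration"]
    page_mean = config.pages_per_session["mean"]
    page_r = config.pages_per_session["dispersion"]
    page_p = page_r / (page_r + page_mean)
    dur_sigma = config.session_duration["sigma"]
    dur_psigma = config.session_duration.get("participant_sigma", 0.0)
    sv_a = config.survey_score["alpha"]
    sv_b = config.survey_score["beta"]
    inter_r = config.interaction_dispersion

    profile_rows: list[dict] = []
    truth_rows: list[dict] = []
    survey_rows: list[dict] = []
    sess = _Columns(["session_id", "participant_id", "session_start", "session_end", "page_views"])
    evs = _Columns(["event_id", "participant_id", "session_id", "timestamp", "kind"])

    for i in range(config.n_participants):
        rng = np.random.default_rng(np.random.SeedSequence([root_seed, i]))
        pid = f"P{i + 1:05d}"

        chars = {}
        for char, cats in CHARACTERISTICS.items():
            probs = np.array([config.characteristic_marginals[char][c] for c in cats])
            chars[char] = cats[rng.choice(len(cats), p=probs / probs.sum())]

        offset = int(rng.integers(0, config.enrollment_span_days + 1))
        enroll_s = (base_date + offset).astype("datetime64[s]")

        mu_i = prop_mean + (config.selfhelp_effect if chars["self_help"] == "yes" else 0.0)
        mu_i = float(np.clip(mu_i, 0.02, 0.98))
        p_login = float(rng.beta(mu_i * conc, (1.0 - mu_i) * conc))
        dur_mult = float(rng.lognormal(0.0, dur_psigma)) if dur_psigma > 0 else 1.0
        dur_mu = np.log(config.session_duration["median_minutes"] * dur_mult)

        profile_rows.append({"participant_id": pid, "enrollment_date": enroll_s, **chars})
        truth_rows.append(
            {
                "participant_id": pid,
                "login_propensity": p_login,
                "propensity_mean": mu_i,
                "duration_multiplier": dur_mult,
            }
        )

        login_days = np.flatnonzero(rng.random(window) < p_login)
        if login_days.size:
            per_day = 1 + rng.poisson(config.sessions_per_day, size=login_days.size)
            days = np.repeat(login_days, per_day)
            ns = days.size

            start_sec = days * _SECONDS_PER_DAY + np.floor(
                rng.random(ns) * _SECONDS_PER_DAY
            ).astype(np.int64)
            dur_sec = np.maximum(
                1, np.round(60.0 * rng.lognormal(dur_mu, dur_sigma, ns))
            ).astype(np.int64)
            end_sec = np.minimum(start_sec + dur_sec, window * _SECONDS_PER_DAY)
            pages = (1 + rng.negative_binomial(page_r, page_p, ns)).astype(np.int64)

            order = np.argsort(start_sec, kind="stable")
            start_sec, end_sec, pages = start_sec[order], end_sec[order], pages[order]
            session_ids = np.array([f"{pid}-S{j + 1:04d}" for j in range(ns)])

            sess.append(
                session_id=session_ids,
                participant_id=np.repeat(pid, ns),
                session_start=enroll_s + start_sec.astype("timedelta64[s]"),
                session_end=enroll_s + end_sec.astype("timedelta64[s]"),
                page_views=pages,
            )

            # interaction events: negative-binomial counts whose expectation
            # scales with the participant's realised login propensity
            ev_kind: list[str] = []
            ev_sess: list[np.ndarray] = []
            for kind in EVENT_KINDS:
                lam = config.interaction_rates[kind] * (p_login / prop_mean)
                if lam <= 0:
                    continue
                count = int(rng.negative_binomial(inter_r, inter_r / (inter_r + lam)))
                if count:
                    ev_kind.extend([kind] * count)
                    ev_sess.append(rng.integers(0, ns, size=count))
            if ev_kind:
                sidx = np.concatenate(ev_sess)
                span = (end_sec[sidx] - start_sec[sidx]).astype(float)
                t_sec = start_sec[sidx] + np.floor(
                    rng.random(sidx.size) * np.maximum(span, 1.0)
                ).astype(np.int64)
                t_sec = np.minimum(t_sec, end_sec[sidx])
                evs.append(
                    event_id=np.array([f"{pid}-E{j + 1:04d}" for j in range(sidx.size)]),
                    participant_id=np.repeat(pid, sidx.size),
                    session_id=session_ids[sidx],
                    timestamp=enroll_s + t_sec.astype("timedelta64[s]"),
                    kind=np.array(ev_kind, dtype=object),
                )

        if rng.random() >= config.survey_dropout:
            total = int(np.clip(np.round(20.0 + 80.0 * rng.beta(sv_a, sv_b)), 20, 100))
            items = _survey_items(total, rng)
            row = {"participant_id": pid}
            row.update({f"item_{j + 1:02d}": int(v) for j, v in enumerate(items)})
            row["total"] = total
            survey_rows.append(row)

    profiles = pd.DataFrame(profile_rows)
    profiles["enrollment_date"] = pd.to_datetime(profiles["enrollment_date"])
    sessions = sess.frame() if sess.data["session_id"] else empty_sessions()
    if len(sessions):
        sessions["page_views"] = sessions["page_views"].astype(np.int64)
    events = evs.frame() if evs.data["event_id"] else empty_events()
    surveys = pd.DataFrame(survey_rows)
    if surveys.empty:
        surveys = pd.DataFrame(
            columns=["participant_id", *[f"item_{j:02d}" for j in range(1, 21)], "total"]
        )
    truth = pd.DataFrame(truth_rows)
    return Cohort(profiles=profiles, sessions=sessions, events=events, surveys=surveys, truth=truth)
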