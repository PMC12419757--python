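"""Simulator configuration.

:class:`CohortConfig` collects every knob of the synthetic cohort generator.
:func:`default_config` returns the reference calibration: a 261-participant
cohort observed over a 28-day window whose characteristic marginals match the
published cohort composition of the mHealth study this package models (e.g.
32.2% self-help group participation), and whose usage distributions are
chosen to reproduce the qualitative shape of the real usage data — a
right-skewed engagement-time distribution and a left-skewed engagement-index
distribution.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .cohort import CHARACTERISTICS, EVENT_KINDS
from .errors import ConfigurationError

#: Category marginals of the reference cohort (published proportions, N=261).
DEFAULT_MARGINALS: dict[str, dict[str, float]] = {
    "age_group": {"<29": 0.164, "30-39": 0.318, "40-49": 0.234, ">=50": 0.284},
    "marital_status": {"spouse": 0.077, "no_spouse": 0.923},
    "living_status": {"alone": 0.544, "with_others": 0.456},
    "education": {"<=high_school": 0.429, ">=college": 0.571},
    "employment": {"unemployed": 0.375, "employed": 0.625},
    "economic_status": {"low": 0.556, "middle": 0.410, "high": 0.034},
    "care_stage": {
        "diagnosis_to_medication": 0.038,
        "medication_to_familiarization": 0.054,
        "familiarization_to_sustaining": 0.908,
    },
    "self_help": {"yes": 0.322, "no": 0.678},
}

#: Expected interaction-event counts over the window for a participant of
#: average login propensity. Self-care records dominate; public/private
#: questions are rare, matching a cohort whose median interaction subindex
#: is close to zero.
DEFAULT_INTERACTION_RATES: dict[str, float] = {
    "comment": 1.0,
    "public_question": 0.3,
    "private_question": 0.4,
    "rating": 2.0,
    "medication_record": 12.0,
    "mood_record": 6.0,
    "sexual_health_record": 2.0,
}


@dataclass
class CohortConfig:
    """Parameters of the synthetic usage-log generator.

    Attributes
    ----------
    n_participants : int
        Cohort size (>= 2).
    window_days : int
        Length of the per-participant observation window in days (default 28).
    seed : int
        Root seed; each participant gets an independent RNG stream derived
        from ``(seed, participant index)``.
    characteristic_marginals : dict
        Per-characteristic category probabilities; each characteristic's
        probabilities must sum to 1.
    session_propensity : dict
        ``{"mean", "concentration"}`` of the Beta distribution from which each
        participant's fixed daily-login probability is drawn. The Beta spread
        produces overdispersed session counts across the cohort.
    sessions_per_day : float
        Mean of the Poisson number of *extra* sessions on a login day (each
        login day yields at least one session).
    pages_per_session : dict
        ``{"mean", "dispersion"}`` of the shifted negative-binomial page-view
        count (support >= 1 page: opening the app renders at least one page).
    session_duration : dict
        ``{"median_minutes", "sigma", "participant_sigma"}`` of the lognormal
        session duration, a heavy-right-tailed positive distribution;
        ``participant_sigma`` is the SD of a per-participant lognormal
        duration multiplier, the "super-user" heterogeneity that drives the
        strong right skew of cumulative engagement time.
    interaction_rates : dict
        Expected event counts per kind over the window for a participant of
        average login propensity; realised rates scale with propensity.
    interaction_dispersion : float
        Negative-binomial size of the interaction counts; small values make
        a few prolific participants dominate the cohort maxima, pushing the
        median interaction subindex toward zero.
    survey_score : dict
        ``{"alpha", "beta"}`` of the Beta distribution of usability-survey
        totals, affinely mapped to the instrument range [20, 100].
    selfhelp_effect : float
        Additive shift of the login-propensity Beta location (mean) for
        participants in a self-help group; 0 disables the effect.
    survey_dropout : float
        Probability that a participant never returns the post survey.
    start_date : str
        First possible enrollment date (ISO date).
    enrollment_span_days : int
        Enrollment dates are staggered uniformly over this many days so the
        calendar-time active-user curve is nontrivial.
    """

    n_participants: int = 261
    window_days: int = 28
    seed: int = 0
    characteristic_marginals: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARGINALS.items()}
    )
    session_propensity: dict = field(
        default_factory=lambda: {"mean": 0.55, "concentration": 3.0}
    )
    sessions_per_day: float = 0.8
    pages_per_session: dict = field(default_factory=lambda: {"mean": 10.0, "dispersion": 1.5})
    session_duration: dict = field(
        default_factory=lambda: {"median_minutes": 0.6, "sigma": 1.0, "participant_sigma": 0.9}
    )
    interaction_rates: dict = field(default_factory=lambda: dict(DEFAULT_INTERACTION_RATES))
    interaction_dispersion: float = 0.4
    survey_score: dict = field(default_factory=lambda: {"alpha": 4.5, "beta": 1.5})
    selfhelp_effect: float = 0.08
    survey_dropout: float = 0.0
    start_date: str = "2024-03-27"
    enrollment_span_days: int = 120

    # -- validation -------------------------------------------------------

    def validate(self) -> "CohortConfig":
        """Raise :class:`ConfigurationError` naming the first offending field."""
        if not isinstance(self.n_participants, (int,)) or self.n_participants < 2:
            raise ConfigurationError("n_participants", "must be an integer >= 2")
        if not isinstance(self.window_days, int) or self.window_days < 1:
            raise ConfigurationError("window_days", "must be an integer >= 1")
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ConfigurationError("seed", "must be a non-negative integer")

        for char, cats in CHARACTERISTICS.items():
            marg = self.characteristic_marginals.get(char)
            if marg is None:
                raise ConfigurationError(
                    f"characteristic_marginals[{char}]", "missing characteristic"
                )
            if set(marg) != set(cats):
                raise ConfigurationError(
                    f"characteristic_marginals[{char}]",
                    f"categories must be exactly {sorted(cats)}",
                )
            probs = list(marg.values())
            if any(p < 0 or p > 1 for p in probs):
                raise ConfigurationError(
                    f"characteristic_marginals[{char}]", "probabilities must lie in [0, 1]"
                )
            if abs(sum(probs) - 1.0) > 1e-6:
                raise ConfigurationError(
                    f"characteristic_marginals[{char}]",
                    f"probabilities must sum to 1 (got {sum(probs):.6f})",
                )

        mean = self.session_propensity.get("mean")
        conc = self.session_propensity.get("concentration")
        if mean is None or not (0.0 < mean < 1.0):
            raise ConfigurationError("session_propensity.mean", "must lie in (0, 1)")
        if conc is None or conc <= 0:
            raise ConfigurationError("session_propensity.concentration", "must be > 0")
        if self.sessions_per_day < 0:
            raise ConfigurationError("sessions_per_day", "must be >= 0")
        if self.pages_per_session.get("mean", -1) <= 0:
            raise ConfigurationError("pages_per_session.mean", "must be > 0")
        if self.pages_per_session.get("dispersion", -1) <= 0:
            raise ConfigurationError("pages_per_session.dispersion", "must be > 0")
        if self.session_duration.get("median_minutes", -1) <= 0:
            raise ConfigurationError("session_duration.median_minutes", "must be > 0")
        if self.session_duration.get("sigma", -1) <= 0:
            raise ConfigurationError("session_duration.sigma", "must be > 0")
        if self.session_duration.get("participant_sigma", 0.0) < 0:
            raise ConfigurationError("session_duration.participant_sigma", "must be >= 0")
        if self.interaction_dispersion <= 0:
            raise ConfigurationError("interaction_dispersion", "must be > 0")
        for kind in EVENT_KINDS:
            if self.interaction_rates.get(kind, -1) < 0:
                raise ConfigurationError(
                    f"interaction_rates[{kind}]", "must be present and >= 0"
                )
        if self.survey_score.get("alpha", -1) <= 0 or self.survey_score.get("beta", -1) <= 0:
            raise ConfigurationError("survey_score", "alpha and beta must be > 0")
        if not (0.0 <= self.survey_dropout <= 1.0):
            raise ConfigurationError("survey_dropout", "must lie in [0, 1]")
        if self.enrollment_span_days < 0:
            raise ConfigurationError("enrollment_span_days", "must be >= 0")
        return self

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "CohortConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(sorted(unknown)[0], "unknown configuration field")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortConfig":
        """Load a config from a YAML or JSON file."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigurationError(str(path), "config file must contain a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Short SHA-256 of the canonical JSON form; recorded in report headers."""
        canon = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def default_config(**overrides) -> CohortConfig:
    """The reference cohort configuration (N=261, 28-day window, published
    characteristic marginals). Keyword overrides replace individual fields."""
    cfg = CohortConfig(**overrides)
    return cfg.validate()
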