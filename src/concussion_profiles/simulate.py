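"""Synthetic collegiate-concussion cohort generator.

Emulates the statistical structure the downstream models assume: total symptom
severity declines exponentially over ~0-80 days post-injury with zero-inflated
negative-binomial observation noise, athletes carry random intercepts nested
within sport groups, and total severity is allocated across the 22 SCAT5
symptoms by a weighted multinomial draw so that clinical-profile co-occurrence
rises mechanically with severity.  Severity is generated first and symptoms
second: the total drives profile counts, which is the relationship the
cross-sectional models downstream must be able to recover.

The generator's defaults define the study conditions and are documented in
``docs/methods.md``; they are calibrations, not estimates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .cohort import ConcussionEpisode
from .scat5 import SCAT5_SYMPTOMS, SymptomChecklist, ValidationError

__all__ = [
    "SimulationConfig",
    "default_symptom_weights",
    "generate_cohort",
    "truth_record",
]

_MAX_ITEM = 6  # per-symptom severity cap
_MECHANISM_CHOICES = np.array(["sport", "non_sport", "uncertain"])


def default_symptom_weights() -> dict[str, float]:
    """Default multinomial allocation weights over the 22 symptoms.

    Common acute post-concussion complaints (headache, pressure, dizziness,
    concentration difficulty, fatigue, photo-/phonophobia) carry more weight
    than rarer affective items, loosely mirroring reported endorsement
    frequencies in collegiate cohorts.
    """
    weights = {name: 1.0 for name in SCAT5_SYMPTOMS}
    weights.update(
        {
            "headache": 3.0,
            "pressure_in_head": 2.0,
            "dizziness": 2.0,
            "difficulty_concentrating": 2.0,
            "fatigue_or_low_energy": 2.0,
            "sensitivity_to_light": 1.5,
            "sensitivity_to_noise": 1.2,
            "nausea_or_vomiting": 1.2,
            "feeling_slowed_down": 1.2,
            "drowsiness": 1.2,
        }
    )
    return weights


@dataclass
class SimulationConfig:
    """Generative parameters for a synthetic cohort.

    Attributes
    ----------
    n_athletes : cohort size (one episode per athlete).
    sex_ratio : probability an athlete is female (~1:1 in the target cohort).
    n_sport_groups : number of sport clusters (collapsed sport groups).
    sport_group_sd, athlete_sd : random-intercept SDs on the log-mean scale;
        athletes are nested within sport groups.
    baseline_mean_severity : expected day-0 total severity before the
        random-intercept and zero-inflation adjustments.
    decay_rate : per-day exponential decline of expected severity; the default
        0.18/day yields a ~92% drop in the expected mean by day 14.
    nb_dispersion : NB2 size parameter theta (variance mu + mu^2/theta).
    zi_prob : structural-zero probability of each evaluation.
    profile_weights : per-symptom multinomial allocation weights
        (default :func:`default_symptom_weights`).
    symptom_concentration : Dirichlet concentration of each athlete's
        personal symptom-weight vector (drawn once per athlete around
        ``profile_weights``).  Smaller values concentrate severity on fewer
        symptoms, lowering profile counts at a given severity; ``None``
        disables the per-athlete draw (all athletes share the base weights).
    non_sport_frac, uncertain_frac : mechanism mixture (defaults reproduce an
        82:18:479 split at n=579).
    rtp_lag_mean : mean of the Poisson(+1) lag from recovery to RTP clearance.
    max_followup_days : censoring horizon for daily evaluations.
    female_severity_log_ratio : log-scale shift of female mean severity
        (0 = no sex effect; used only for power studies).
    female_profile_weight_boost : optional per-profile multiplier applied to
        females' allocation weights for that profile's symptoms (power studies).
    seed : RNG seed; fixed seed gives bit-identical cohorts.
    """

    n_athletes: int = 500
    sex_ratio: float = 0.5
    n_sport_groups: int = 11
    sport_group_sd: float = 0.45
    athlete_sd: float = 0.9
    baseline_mean_severity: float = 30.0
    decay_rate: float = 0.18
    nb_dispersion: float = 2.0
    zi_prob: float = 0.02
    profile_weights: Optional[Mapping[str, float]] = None
    symptom_concentration: Optional[float] = 0.6
    non_sport_frac: float = 82 / 579
    uncertain_frac: float = 18 / 579
    rtp_lag_mean: float = 4.0
    max_followup_days: int = 80
    female_severity_log_ratio: float = 0.0
    female_profile_weight_boost: Optional[Mapping[str, float]] = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_athletes < 1:
            raise ValidationError("n_athletes must be >= 1")
        for name in ("sex_ratio", "zi_prob", "non_sport_frac", "uncertain_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.non_sport_frac + self.uncertain_frac > 1.0:
            raise ValidationError("mechanism fractions must sum to <= 1")
        for name in (
            "sport_group_sd",
            "athlete_sd",
            "baseline_mean_severity",
            "decay_rate",
            "rtp_lag_mean",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be > 0")
        if self.symptom_concentration is not None and self.symptom_concentration <= 0:
            raise ValidationError("symptom_concentration must be > 0 or None")
        if self.n_sport_groups < 1 or self.max_followup_days < 0:
            raise ValidationError("n_sport_groups >= 1 and max_followup_days >= 0 required")
        self.resolved_weights()

    def resolved_weights(self) -> dict[str, float]:
        weights = dict(self.profile_weights or default_symptom_weights())
        unknown = set(weights) - set(SCAT5_SYMPTOMS)
        if unknown:
            raise ValidationError(f"profile_weights for unknown symptoms: {sorted(unknown)}")
        missing = set(SCAT5_SYMPTOMS) - set(weights)
        if missing:
            raise ValidationError(f"profile_weights missing symptoms: {sorted(missing)}")
        if any(w < 0 for w in weights.values()) or sum(weights.values()) <= 0:
            raise ValidationError("profile_weights must be non-negative with positive sum")
        return weights


def truth_record(config: SimulationConfig) -> dict:
    """The exact generative parameters, serializable, for parameter-recovery tests."""
    config.validate()
    record = dataclasses.asdict(config)
    record["profile_weights"] = config.resolved_weights()
    if record["female_profile_weight_boost"] is not None:
        record["female_profile_weight_boost"] = dict(record["female_profile_weight_boost"])
    return record


def _draw_zinb(rng: np.random.Generator, mu: float, theta: float, zi_prob: float) -> int:
    """One draw from a zero-inflated NB2 with mean parameter ``mu``."""
    if zi_prob > 0 and rng.random() < zi_prob:
        return 0
    if mu <= 0:
        return 0
    p = theta / (theta + mu)
    return int(rng.negative_binomial(theta, p))


def _allocate_symptoms(
    rng: np.random.Generator, total: int, weights: np.ndarray
) -> np.ndarray:
    """Allocate ``total`` severity points over 22 symptoms, capped at 6 each.

    Weighted multinomial draw with iterative redistribution of the overflow
    above the per-item cap; terminates because total <= 132 = 22 * 6.
    """
    counts = np.zeros(len(weights), dtype=int)
    remaining = int(total)
    w = weights.astype(float).copy()
    while remaining > 0:
        capacity = _MAX_ITEM - counts
        open_items = capacity > 0
        if not open_items.any():
            break
        w_eff = np.where(open_items, w, 0.0)
        if w_eff.sum() <= 0:
            w_eff = open_items.astype(float)
        draw = rng.multinomial(remaining, w_eff / w_eff.sum())
        counts = counts + draw
        overflow = np.clip(counts - _MAX_ITEM, 0, None)
        counts = np.minimum(counts, _MAX_ITEM)
        remaining = int(overflow.sum())
    return counts


def generate_cohort(config: SimulationConfig) -> list[ConcussionEpisode]:
    """Simulate one cohort of concussion episodes.

    Per athlete: sex ~ Bernoulli(sex_ratio); sport group uniform; group and
    athlete random intercepts ~ Normal(0, sd) on the log scale; expected total
    severity mu(t) = baseline * exp(intercepts) * exp(-decay_rate * t);
    observed total severity ~ ZINB(mu(t), theta, zi_prob) capped at 132;
    severity allocated across symptoms by weighted multinomial.  Daily
    evaluations run from day 0 until the first zero-severity evaluation (the
    recovery day and final form) or the censoring horizon.  RTP day =
    recovery + 1 + Poisson(rtp_lag_mean); censored recoveries have no RTP.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    weights = config.resolved_weights()
    base_w = np.array([weights[s] for s in SCAT5_SYMPTOMS], dtype=float)

    female_w = base_w.copy()
    if config.female_profile_weight_boost:
        from .scat5 import default_registry

        registry = default_registry()
        for profile, mult in config.female_profile_weight_boost.items():
            if profile not in registry.profiles:
                raise ValidationError(f"unknown profile in weight boost: {profile!r}")
            for sym in registry.profiles[profile]:
                female_w[SCAT5_SYMPTOMS.index(sym)] *= float(mult)

    group_names = [f"group_{i + 1:02d}" for i in range(config.n_sport_groups)]
    group_intercepts = rng.normal(0.0, config.sport_group_sd, size=config.n_sport_groups)

    p_sport = 1.0 - config.non_sport_frac - config.uncertain_frac
    episodes: list[ConcussionEpisode] = []
    for i in range(config.n_athletes):
        athlete_id = f"ath_{i + 1:05d}"
        sex = "female" if rng.random() < config.sex_ratio else "male"
        g = int(rng.integers(config.n_sport_groups))
        a_int = rng.normal(0.0, config.athlete_sd)
        mechanism = rng.choice(
            _MECHANISM_CHOICES, p=[p_sport, config.non_sport_frac, config.uncertain_frac]
        )
        sex_shift = config.female_severity_log_ratio if sex == "female" else 0.0
        mu0 = config.baseline_mean_severity * np.exp(group_intercepts[g] + a_int + sex_shift)
        w = female_w if sex == "female" else base_w
        if config.symptom_concentration is not None:
            # athlete-specific symptom phenotype, stable across days
            alpha = config.symptom_concentration * w / w.mean()
            w = rng.dirichlet(alpha)

        trajectory: list[SymptomChecklist] = []
        recovery_day: Optional[int] = None
        for day in range(config.max_followup_days + 1):
            mu_t = mu0 * np.exp(-config.decay_rate * day)
            total = min(_draw_zinb(rng, mu_t, config.nb_dispersion, config.zi_prob), 132)
            counts = _allocate_symptoms(rng, total, w)
            trajectory.append(
                SymptomChecklist(
                    symptom_severities={
                        s: int(c) for s, c in zip(SCAT5_SYMPTOMS, counts)
                    },
                    day_post_injury=day,
                )
            )
            if total == 0:
                recovery_day = day
                break

        rtp_day: Optional[int] = None
        if recovery_day is not None:
            rtp_day = recovery_day + 1 + int(rng.poisson(config.rtp_lag_mean))

        episodes.append(
            ConcussionEpisode(
                athlete_id=athlete_id,
                sex=sex,
                sport=group_names[g],
                sport_group=group_names[g],
                mechanism=str(mechanism),
                trajectory=trajectory,
                rtp_day=rtp_day,
            )
        )
    return episodes
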