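"""Cohort assembly: inclusion filtering, sport-group collapsing, outcomes, summaries.

A :class:`ConcussionEpisode` is one athlete-injury with its trajectory of daily
SCAT5 evaluations and its return-to-play (RTP) clearance day.  Only episodes
whose concussion mechanism is ``sport`` enter the analysis; non-sport and
uncertain-origin injuries are excluded.  Time-to-recovery is the day of the
final evaluation provided that evaluation is asymptomatic (by default, total
severity zero); time-to-RTP is the recorded clearance day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scat5 import (
    PROFILE_NAMES,
    ProfileRegistry,
    SymptomChecklist,
    ValidationError,
    classify_profiles,
    score_severity,
)

__all__ = [
    "MECHANISMS",
    "ConcussionEpisode",
    "CohortSummary",
    "apply_inclusion_filter",
    "collapse_sport",
    "time_to_recovery",
    "time_to_rtp",
    "summarize_cohort",
    "summarize_assignment_table",
    "build_initial_table",
    "build_daily_table",
]

logger = logging.getLogger(__name__)

MECHANISMS = ("sport", "non_sport", "uncertain")
_SEXES = ("female", "male")


@dataclass
class ConcussionEpisode:
    """One athlete-injury: demographics, mechanism, evaluation trajectory, RTP day."""

    athlete_id: str
    sex: str
    sport: str
    mechanism: str
    trajectory: Sequence[SymptomChecklist]
    sport_group: Optional[str] = None
    rtp_day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise ValidationError(
                f"episode {self.athlete_id!r}: sex must be one of {_SEXES}, "
                f"got {self.sex!r}"
            )
        if self.mechanism is not None and self.mechanism not in MECHANISMS:
            raise ValidationError(
                f"episode {self.athlete_id!r}: mechanism must be one of "
                f"{MECHANISMS}, got {self.mechanism!r}"
            )
        days = [c.day_post_injury for c in self.trajectory]
        if days and days[0] > 2:
            raise ValidationError(
                f"episode {self.athlete_id!r}: first evaluation must occur within "
                f"48 h of injury (day <= 2), got day {days[0]}"
            )
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValidationError(
                f"episode {self.athlete_id!r}: evaluation days must be strictly "
                f"increasing, got {days}"
            )

    @property
    def initial_checklist(self) -> SymptomChecklist:
        if not self.trajectory:
            raise ValidationError(f"episode {self.athlete_id!r} has no evaluations")
        return self.trajectory[0]


def apply_inclusion_filter(
    episodes: Sequence[ConcussionEpisode],
) -> list[ConcussionEpisode]:
    """Retain only sport-mechanism episodes, preserving order.

    Exclusion counts are logged by reason.  Episodes with a missing mechanism
    are a data error, reported collectively.
    """
    missing = [e.athlete_id for e in episodes if e.mechanism is None]
    if missing:
        raise ValidationError(f"episodes with missing mechanism: {missing}")
    kept = [e for e in episodes if e.mechanism == "sport"]
    removed: dict[str, int] = {}
    for e in episodes:
        if e.mechanism != "sport":
            removed[e.mechanism] = removed.get(e.mechanism, 0) + 1
    for reason, count in sorted(removed.items()):
        logger.info("inclusion filter: excluded %d episode(s) with mechanism=%s", count, reason)
    return kept


def collapse_sport(
    sport: str, mapping: Mapping[str, str], other_group: str = "other"
) -> str:
    """Map a free-text sport name onto its configured sport group.

    Unmapped sports fall into ``other_group`` with a logged warning; the
    grouping exists to give mixed models adequately sized clusters.
    """
    if sport in mapping:
        return mapping[sport]
    logger.warning("sport %r not in mapping; assigning group %r", sport, other_group)
    return other_group


def _asymptomatic_total_zero(checklist: SymptomChecklist) -> bool:
    return score_severity(checklist) == 0


def time_to_recovery(
    episode: ConcussionEpisode,
    asymptomatic_rule: Callable[[SymptomChecklist], bool] | None = None,
) -> Optional[int]:
    """Days from injury to the final evaluation at asymptomatic status.

    Returns the day of the trajectory's last evaluation iff that evaluation
    satisfies the asymptomatic rule (default: total severity == 0).  An
    athlete whose last observed evaluation is still symptomatic — including
    one who rebounded after a transient asymptomatic day — has no observed
    recovery (returns ``None``).
    """
    if not episode.trajectory:
        raise ValidationError(f"episode {episode.athlete_id!r} has an empty trajectory")
    rule = asymptomatic_rule or _asymptomatic_total_zero
    final = episode.trajectory[-1]
    return final.day_post_injury if rule(final) else None


def time_to_rtp(
    episode: ConcussionEpisode,
    recovery_day: Optional[int] = None,
) -> Optional[int]:
    """Days from injury to full return-to-play clearance (missingness propagates).

    When both are known, RTP should not precede recovery; a violation is
    logged (the value is still returned — the record, not the reader, is wrong).
    """
    if episode.rtp_day is None:
        return None
    if recovery_day is not None and episode.rtp_day < recovery_day:
        logger.warning(
            "episode %s: rtp_day %d precedes recovery day %d",
            episode.athlete_id,
            episode.rtp_day,
            recovery_day,
        )
    return episode.rtp_day


@dataclass
class CohortSummary:
    """Descriptive cohort table: sex split and per-profile counts/percentages."""

    n_total: int
    n_by_sex: dict[str, int]
    profile_counts: dict[str, dict[str, float]]  # per profile: n, pct_total, n_female, pct_female, n_male, pct_male
    sex_chi2: float
    sex_chi2_p: float
    denominator: int

    def to_frame(self) -> pd.DataFrame:
        """Table-1-style frame with percentages rounded to one decimal."""
        rows = []
        for profile, d in self.profile_counts.items():
            rows.append(
                {
                    "profile": profile,
                    "n": int(d["n"]),
                    "pct_total": round(d["pct_total"], 1),
                    "n_female": int(d["n_female"]),
                    "pct_female": round(d["pct_female"], 1),
                    "n_male": int(d["n_male"]),
                    "pct_male": round(d["pct_male"], 1),
                }
            )
        return pd.DataFrame(rows).set_index("profile")


def summarize_assignment_table(
    table: pd.DataFrame,
    profile_names: Sequence[str] = PROFILE_NAMES,
    denominator: Optional[int] = None,
) -> CohortSummary:
    """Summarize a classified cohort.

    ``table`` needs a ``sex`` column plus one boolean column per profile.
    ``denominator`` overrides the percentage base for the per-profile totals
    (default: number of rows); sex splits within a profile always use the
    profile's own count as the base.
    """
    if table.empty:
        raise ValidationError("cannot summarize an empty cohort")
    n_total = len(table)
    denom = denominator if denominator is not None else n_total
    n_by_sex = {s: int((table["sex"] == s).sum()) for s in _SEXES}
    counts: dict[str, dict[str, float]] = {}
    for profile in profile_names:
        member = table[profile].astype(bool)
        n = int(member.sum())
        n_f = int((member & (table["sex"] == "female")).sum())
        n_m = int((member & (table["sex"] == "male")).sum())
        counts[profile] = {
            "n": n,
            "pct_total": 100.0 * n / denom if denom else float("nan"),
            "n_female": n_f,
            "pct_female": 100.0 * n_f / n if n else float("nan"),
            "n_male": n_m,
            "pct_male": 100.0 * n_m / n if n else float("nan"),
        }
    observed = [n_by_sex["female"], n_by_sex["male"]]
    chi2, p = stats.chisquare(observed)  # goodness of fit against 1:1
    return CohortSummary(
        n_total=n_total,
        n_by_sex=n_by_sex,
        profile_counts=counts,
        sex_chi2=float(chi2),
        sex_chi2_p=float(p),
        denominator=denom,
    )


def summarize_cohort(
    episodes: Sequence[ConcussionEpisode],
    registry: ProfileRegistry,
    denominator: Optional[int] = None,
) -> CohortSummary:
    """Classify each episode's initial checklist and summarize the cohort."""
    if not episodes:
        raise ValidationError("cannot summarize an empty cohort")
    rows = []
    for e in episodes:
        assignment = classify_profiles(e.initial_checklist, registry)
        row: dict[str, object] = {"sex": e.sex}
        for profile in registry.profile_names:
            row[profile] = profile in assignment.present_profiles
        rows.append(row)
    table = pd.DataFrame(rows)
    return summarize_assignment_table(
        table, profile_names=registry.profile_names, denominator=denominator
    )


def build_initial_table(
    episodes: Sequence[ConcussionEpisode], registry: ProfileRegistry
) -> pd.DataFrame:
    """Per-episode analysis table from the *initial* evaluation plus outcomes.

    Columns: athlete_id, sex, sport_group, severity0, n_profiles0, one boolean
    per profile, recovery (days or NaN), rtp (days or NaN).  Downstream
    cross-sectional models consume only this table, never later evaluations.
    """
    rows = []
    for e in episodes:
        assignment = classify_profiles(e.initial_checklist, registry)
        recovery = time_to_recovery(e)
        row: dict[str, object] = {
            "athlete_id": e.athlete_id,
            "sex": e.sex,
            "sport_group": e.sport_group or e.sport,
            "severity0": assignment.severity_score,
            "n_profiles0": assignment.n_profiles,
            "recovery": np.nan if recovery is None else recovery,
            "rtp": np.nan if time_to_rtp(e, recovery) is None else e.rtp_day,
        }
        for profile in registry.profile_names:
            row[profile] = profile in assignment.present_profiles
        rows.append(row)
    return pd.DataFrame(rows)


def build_daily_table(
    episodes: Sequence[ConcussionEpisode], registry: ProfileRegistry
) -> pd.DataFrame:
    """Long repeated-measures table: one row per evaluation.

    Columns: athlete_id, sex, sport_group, day, severity, n_profiles.
    """
    rows = []
    for e in episodes:
        for checklist in e.trajectory:
            assignment = classify_profiles(checklist, registry)
            rows.append(
                {
                    "athlete_id": e.athlete_id,
                    "sex": e.sex,
                    "sport_group": e.sport_group or e.sport,
                    "day": checklist.day_post_injury,
                    "severity": assignment.severity_score,
                    "n_profiles": assignment.n_profiles,
                }
            )
    return pd.DataFrame(rows)
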