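"""SCAT5 symptom-checklist data model, severity scoring, and clinical-profile classification.

The SCAT5 (Sport Concussion Assessment Tool, 5th edition) symptom checklist
rates 22 symptoms on a 0 (absent) to 6 (severe) Likert scale.  The injury
severity score is the sum of the 22 ratings (0-132).  A concussion *clinical
profile* (vestibular, cognitive, fatigue, anxiety/mood, headache/migraine,
ocular) is assigned when an athlete endorses at least a threshold fraction of
the symptoms that define that profile; profiles are not mutually exclusive and
membership ignores severity beyond the endorsement cut.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, FrozenSet, Iterable, Mapping

import yaml

__all__ = [
    "SCAT5_SYMPTOMS",
    "PROFILE_NAMES",
    "MAX_SEVERITY_SCORE",
    "ValidationError",
    "SymptomChecklist",
    "ProfileRegistry",
    "ProfileAssignment",
    "score_severity",
    "endorsed_symptoms",
    "profile_threshold",
    "classify_profiles",
    "default_registry",
    "registry_from_dict",
]

#: Canonical vocabulary of the 22 SCAT5 symptom-checklist items.
SCAT5_SYMPTOMS: tuple[str, ...] = (
    "headache",
    "pressure_in_head",
    "neck_pain",
    "nausea_or_vomiting",
    "dizziness",
    "blurred_vision",
    "balance_problems",
    "sensitivity_to_light",
    "sensitivity_to_noise",
    "feeling_slowed_down",
    "feeling_like_in_a_fog",
    "dont_feel_right",
    "difficulty_concentrating",
    "difficulty_remembering",
    "fatigue_or_low_energy",
    "confusion",
    "drowsiness",
    "trouble_falling_asleep",
    "more_emotional",
    "irritability",
    "sadness",
    "nervous_or_anxious",
)

_SYMPTOM_SET = frozenset(SCAT5_SYMPTOMS)

#: The six clinical profiles, in reporting order.
PROFILE_NAMES: tuple[str, ...] = (
    "vestibular",
    "cognitive",
    "fatigue",
    "anxiety_mood",
    "headache_migraine",
    "ocular",
)

#: Maximum attainable injury severity score (22 symptoms x severity 6).
MAX_SEVERITY_SCORE = 6 * len(SCAT5_SYMPTOMS)

#: Profiles whose defining subsets contain exactly seven symptoms.
_SEVEN_SYMPTOM_PROFILES = ("cognitive", "anxiety_mood", "ocular")


class ValidationError(ValueError):
    """Raised when clinical data violate the SCAT5 schema."""


@dataclass(frozen=True)
class SymptomChecklist:
    """One SCAT5 symptom evaluation.

    Parameters
    ----------
    symptom_severities
        Mapping from each of the 22 canonical symptom names to an integer
        severity in [0, 6].  All 22 symptoms must be present.
    day_post_injury
        Integer day of the evaluation, with day 0 the day of injury.
    """

    symptom_severities: Mapping[str, int]
    day_post_injury: int

    def __post_init__(self) -> None:
        sev = dict(self.symptom_severities)
        unknown = set(sev) - _SYMPTOM_SET
        if unknown:
            raise ValidationError(f"unknown symptom name(s): {sorted(unknown)}")
        missing = _SYMPTOM_SET - set(sev)
        if missing:
            raise ValidationError(f"missing symptom(s): {sorted(missing)}")
        for name, value in sev.items():
            if isinstance(value, bool) or not isinstance(value, (int,)):
                # SCAT5 is a Likert instrument: reject rather than round.
                if not (hasattr(value, "is_integer") and float(value).is_integer()):
                    raise ValidationError(
                        f"severity for {name!r} must be an integer, got {value!r}"
                    )
                value = int(value)
            if not 0 <= int(value) <= 6:
                raise ValidationError(
                    f"severity for {name!r} out of range [0, 6]: {value!r}"
                )
            sev[name] = int(value)
        if not isinstance(self.day_post_injury, int) or self.day_post_injury < 0:
            raise ValidationError(
                f"day_post_injury must be a non-negative integer, "
                f"got {self.day_post_injury!r}"
            )
        object.__setattr__(self, "symptom_severities", sev)

    def severity(self, symptom: str) -> int:
        return self.symptom_severities[symptom]


def score_severity(checklist: SymptomChecklist) -> int:
    """Injury severity score: the sum of the 22 symptom ratings (0-132)."""
    return sum(checklist.symptom_severities.values())


def endorsed_symptoms(
    checklist: SymptomChecklist, min_severity: int = 1
) -> frozenset[str]:
    """Symptoms rated at or above ``min_severity`` (endorsement cut, default 1)."""
    if not isinstance(min_severity, int) or not 1 <= min_severity <= 6:
        raise ValueError(f"min_severity must be an integer in [1, 6], got {min_severity!r}")
    return frozenset(
        name
        for name, value in checklist.symptom_severities.items()
        if value >= min_severity
    )


def profile_threshold(n_symptoms: int, rule: str = "half_floor") -> int:
    """Endorsed-symptom count required for a profile defined by ``n_symptoms``.

    The default ``half_floor`` rule is floor(n/2) clamped to a minimum of 1,
    the operationalization under which a seven-symptom profile requires three
    endorsed symptoms.  ``half_ceil`` is a strict >=50% alternative
    (ceil(n/2)).
    """
    if not isinstance(n_symptoms, int) or n_symptoms < 1:
        raise ValueError(f"n_symptoms must be a positive integer, got {n_symptoms!r}")
    if rule == "half_floor":
        return max(1, n_symptoms // 2)
    if rule == "half_ceil":
        return max(1, math.ceil(n_symptoms / 2))
    raise ValueError(f"unknown threshold rule {rule!r}")


@dataclass(frozen=True)
class ProfileRegistry:
    """The six clinical-profile definitions: symptom subsets plus the endorsement rule.

    The symptom-to-profile mapping is configuration, not code: alternative
    mappings load from YAML via :func:`concussion_profiles.io.load_registry`.
    """

    profiles: Mapping[str, FrozenSet[str]]
    endorsement_min_severity: int = 1
    threshold_rule: str = "half_floor"

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValidationError("registry must define at least one profile")
        clean: dict[str, frozenset[str]] = {}
        for name, subset in self.profiles.items():
            subset = frozenset(subset)
            if not subset:
                raise ValidationError(f"profile {name!r} has an empty symptom subset")
            unknown = subset - _SYMPTOM_SET
            if unknown:
                raise ValidationError(
                    f"profile {name!r} uses symptoms outside the SCAT5 "
                    f"vocabulary: {sorted(unknown)}"
                )
            clean[name] = subset
        if not 1 <= self.endorsement_min_severity <= 6:
            raise ValidationError(
                "endorsement_min_severity must be in [1, 6], "
                f"got {self.endorsement_min_severity!r}"
            )
        # exercise the rule once so an unknown name fails fast
        profile_threshold(1, self.threshold_rule)
        for name in _SEVEN_SYMPTOM_PROFILES:
            if name in clean and len(clean[name]) != 7:
                warnings.warn(
                    f"profile {name!r} is conventionally defined by 7 symptoms "
                    f"but this registry lists {len(clean[name])}",
                    stacklevel=2,
                )
        object.__setattr__(self, "profiles", clean)

    def threshold(self, profile: str) -> int:
        """Required endorsed-symptom count for ``profile``."""
        return profile_threshold(len(self.profiles[profile]), self.threshold_rule)

    @property
    def profile_names(self) -> tuple[str, ...]:
        return tuple(self.profiles)


@dataclass(frozen=True)
class ProfileAssignment:
    """Classification of a single checklist: which profiles are present."""

    present_profiles: FrozenSet[str]
    n_profiles: int
    severity_score: int

    def __post_init__(self) -> None:
        if self.n_profiles != len(self.present_profiles):
            raise ValidationError("n_profiles must equal len(present_profiles)")
        if self.severity_score == 0 and self.n_profiles != 0:
            raise ValidationError("severity 0 implies no profiles")


def classify_profiles(
    checklist: SymptomChecklist, registry: ProfileRegistry
) -> ProfileAssignment:
    """Assign clinical profiles to one checklist.

    Profile ``p`` is present iff the number of endorsed symptoms (severity >=
    the registry's endorsement cut) within ``p``'s defining subset reaches the
    registry's threshold for that subset size.  Severity beyond the endorsement
    cut does not affect membership, and profiles are not mutually exclusive.
    """
    endorsed = endorsed_symptoms(checklist, registry.endorsement_min_severity)
    present = frozenset(
        name
        for name, subset in registry.profiles.items()
        if len(endorsed & subset) >= registry.threshold(name)
    )
    return ProfileAssignment(
        present_profiles=present,
        n_profiles=len(present),
        severity_score=score_severity(checklist),
    )


def registry_from_dict(payload: Mapping) -> ProfileRegistry:
    """Build a registry from a parsed config mapping (see ``data/default_registry.yaml``)."""
    allowed = {"profiles", "endorsement_min_severity", "threshold_rule"}
    unknown = set(payload) - allowed
    if unknown:
        raise ValidationError(f"unknown registry config key(s): {sorted(unknown)}")
    if "profiles" not in payload:
        raise ValidationError("registry config must contain a 'profiles' mapping")
    profiles = {
        str(name): frozenset(symptoms)
        for name, symptoms in dict(payload["profiles"]).items()
    }
    return ProfileRegistry(
        profiles=profiles,
        endorsement_min_severity=int(payload.get("endorsement_min_severity", 1)),
        threshold_rule=str(payload.get("threshold_rule", "half_floor")),
    )


def default_registry() -> ProfileRegistry:
    """The packaged default profile registry.

    The default symptom subsets approximate the AMSSM clinical-profile
    descriptions under the constraints that the cognitive, anxiety/mood and
    ocular subsets contain exactly seven symptoms; the mapping ships as YAML so
    alternative operationalizations are drop-in replacements.
    """
    text = (
        resources.files("concussion_profiles")
        .joinpath("data/default_registry.yaml")
        .read_text(encoding="utf-8")
    )
    return registry_from_dict(yaml.safe_load(text))
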