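"""Checklist scoring, endorsement, and the clinical-profile classification rule."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from concussion_profiles.scat5 import (
    MAX_SEVERITY_SCORE,
    PROFILE_NAMES,
    SCAT5_SYMPTOMS,
    ProfileAssignment,
    ProfileRegistry,
    SymptomChecklist,
    ValidationError,
    classify_profiles,
    endorsed_symptoms,
    profile_threshold,
    score_severity,
)

from conftest import make_checklist, random_checklist


severity_vectors = st.lists(st.integers(0, 6), min_size=22, max_size=22)


def checklist_from_vector(vec, day=0):
    return SymptomChecklist(
        symptom_severities=dict(zip(SCAT5_SYMPTOMS, vec)), day_post_injury=day
    )


class TestScoring:
    @pytest.mark.parametrize(
        "severities,expected",
        [
            ({s: 6 for s in SCAT5_SYMPTOMS}, 132),
            ({s: 0 for s in SCAT5_SYMPTOMS}, 0),
            ({"headache": 3}, 3),
        ],
    )
    def test_examples(self, severities, expected):
        assert score_severity(make_checklist(**severities)) == expected

    @given(severity_vectors)
    def test_permutation_invariance(self, vec):
        baseline = score_severity(checklist_from_vector(vec))
        rng = np.random.default_rng(0)
        shuffled = list(vec)
        rng.shuffle(shuffled)
        # same multiset of severities mapped to a different symptom order
        assert score_severity(checklist_from_vector(shuffled)) == baseline
        assert 0 <= baseline <= MAX_SEVERITY_SCORE

    def test_rejects_malformed_checklists(self):
        base = {s: 0 for s in SCAT5_SYMPTOMS}
        with pytest.raises(ValidationError, match="missing"):
            SymptomChecklist({k: v for k, v in base.items() if k != "headache"}, 0)
        with pytest.raises(ValidationError, match="unknown"):
            SymptomChecklist({**base, "vertigo": 1}, 0)
        with pytest.raises(ValidationError, match="headache"):
            SymptomChecklist({**base, "headache": 7}, 0)
        with pytest.raises(ValidationError, match="integer"):
            SymptomChecklist({**base, "headache": 1.5}, 0)
        with pytest.raises(ValidationError, match="day_post_injury"):
            SymptomChecklist(base, -1)


class TestEndorsement:
    def test_filter_by_minimum_severity(self):
        cl = make_checklist(headache=2, dizziness=1)
        assert endorsed_symptoms(cl, 1) == {"headache", "dizziness"}
        assert endorsed_symptoms(cl, 2) == {"headache"}
        assert endorsed_symptoms(make_checklist(), 1) == frozenset()
        all_one = make_checklist(**{s: 1 for s in SCAT5_SYMPTOMS})
        assert endorsed_symptoms(all_one, 1) == frozenset(SCAT5_SYMPTOMS)

    @pytest.mark.parametrize("bad", [0, 7, -1])
    def test_min_severity_range(self, bad):
        with pytest.raises(ValueError):
            endorsed_symptoms(make_checklist(), bad)


class TestThreshold:
    @pytest.mark.parametrize("n,expected", [(7, 3), (2, 1), (4, 2), (1, 1), (5, 2)])
    def test_default_rule(self, n, expected):
        assert profile_threshold(n) == expected

    def test_strict_rule_rounds_up(self):
        assert profile_threshold(7, "half_ceil") == 4
        assert profile_threshold(4, "half_ceil") == 2

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            profile_threshold(0)
        with pytest.raises(ValueError):
            profile_threshold(7, "strictest")


class TestClassification:
    def test_degenerate_checklists(self, registry):
        zero = classify_profiles(make_checklist(), registry)
        assert zero.n_profiles == 0 and zero.severity_score == 0
        full = classify_profiles(
            make_checklist(**{s: 1 for s in SCAT5_SYMPTOMS}), registry
        )
        assert full.present_profiles == frozenset(PROFILE_NAMES)

    def test_three_cognitive_symptoms_suffice(self, registry):
        chosen = sorted(registry.profiles["cognitive"])[:3]
        assignment = classify_profiles(
            make_checklist(**{s: 1 for s in chosen}), registry
        )
        assert "cognitive" in assignment.present_profiles

    def test_severity_beyond_endorsement_cut_is_ignored(self, registry):
        chosen = sorted(registry.profiles["cognitive"])[:3]
        mild = classify_profiles(make_checklist(**{s: 1 for s in chosen}), registry)
        severe = classify_profiles(make_checklist(**{s: 6 for s in chosen}), registry)
        assert mild.present_profiles == severe.present_profiles

    def test_monotone_in_severity(self, registry):
        rng = np.random.default_rng(3)
        for _ in range(50):
            cl = random_checklist(rng)
            before = classify_profiles(cl, registry).present_profiles
            for symptom in SCAT5_SYMPTOMS:
                sev = dict(cl.symptom_severities)
                if sev[symptom] == 6:
                    continue
                sev[symptom] += 1
                after = classify_profiles(
                    SymptomChecklist(sev, cl.day_post_injury), registry
                ).present_profiles
                assert before <= after

    @given(severity_vectors)
    def test_agrees_with_naive_count_loop(self, vec):
        from concussion_profiles.scat5 import default_registry

        registry = default_registry()
        cl = checklist_from_vector(vec)
        assignment = classify_profiles(cl, registry)
        endorsed = {s for s, v in cl.symptom_severities.items() if v >= 1}
        naive = set()
        for name, subset in registry.profiles.items():
            hits = sum(1 for s in subset if s in endorsed)
            if hits >= max(1, len(subset) // 2):
                naive.add(name)
        assert assignment.present_profiles == frozenset(naive)
        if assignment.severity_score == 0:
            assert assignment.n_profiles == 0


class TestRegistry:
    def test_assignment_invariants_enforced(self):
        with pytest.raises(ValidationError):
            ProfileAssignment(frozenset({"cognitive"}), 2, 10)
        with pytest.raises(ValidationError):
            ProfileAssignment(frozenset({"cognitive"}), 1, 0)

    def test_seven_symptom_constraint_warns(self):
        with pytest.warns(UserWarning, match="7 symptoms"):
            ProfileRegistry(profiles={"cognitive": frozenset(list(SCAT5_SYMPTOMS)[:6])})

    def test_rejects_bad_registries(self):
        with pytest.raises(ValidationError):
            ProfileRegistry(profiles={})
        with pytest.raises(ValidationError):
            ProfileRegistry(profiles={"vestibular": frozenset()})
        with pytest.raises(ValidationError):
            ProfileRegistry(profiles={"vestibular": frozenset({"spinning"})})

    def test_default_registry_loads_clean(self, recwarn, registry):
        assert set(registry.profiles) == set(PROFILE_NAMES)
        for name in ("cognitive", "anxiety_mood", "ocular"):
            assert len(registry.profiles[name]) == 7
        assert registry.threshold("cognitive") == 3
        assert not [w for w in recwarn.list if "symptoms" in str(w.message)]
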