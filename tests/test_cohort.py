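"""Inclusion filtering, sport collapsing, outcome derivation, cohort summaries."""

import logging

import numpy as np
import pandas as pd
import pytest

from concussion_profiles.cohort import (
    ConcussionEpisode,
    apply_inclusion_filter,
    collapse_sport,
    summarize_assignment_table,
    summarize_cohort,
    time_to_recovery,
    time_to_rtp,
)
from concussion_profiles.scat5 import PROFILE_NAMES, ValidationError

from conftest import make_checklist


def episode(mechanism="sport", severities_by_day=((0, 10),), rtp=None, athlete="a1", sex="female"):
    trajectory = [make_checklist(day=d, headache=min(s, 6), pressure_in_head=max(0, min(s - 6, 6)),
                                 neck_pain=max(0, min(s - 12, 6)), dizziness=max(0, min(s - 18, 6)))
                  for d, s in severities_by_day]
    return ConcussionEpisode(
        athlete_id=athlete, sex=sex, sport="soccer", mechanism=mechanism,
        trajectory=trajectory, rtp_day=rtp,
    )


class TestInclusionFilter:
    def test_mechanism_mix_counts(self):
        episodes = (
            [episode("sport", athlete=f"s{i}") for i in range(479)]
            + [episode("non_sport", athlete=f"n{i}") for i in range(82)]
            + [episode("uncertain", athlete=f"u{i}") for i in range(18)]
        )
        kept = apply_inclusion_filter(episodes)
        assert len(kept) == 479
        assert [e.athlete_id for e in kept] == [f"s{i}" for i in range(479)]

    def test_trivial_cases_and_idempotence(self):
        assert apply_inclusion_filter([]) == []
        episodes = [episode("sport", athlete=f"s{i}") for i in range(5)]
        once = apply_inclusion_filter(episodes)
        assert once == episodes
        assert apply_inclusion_filter(once) == once

    def test_missing_mechanism_is_an_error(self):
        ep = episode("sport")
        ep.mechanism = None
        with pytest.raises(ValidationError, match="a1"):
            apply_inclusion_filter([ep])


class TestSportCollapse:
    def test_mapping_and_fallback(self):
        mapping = {"soccer": "soccer", "futsal": "soccer", "rugby": "football"}
        assert collapse_sport("futsal", mapping) == "soccer"
        assert collapse_sport("soccer", {"soccer": "soccer"}) == "soccer"
        assert collapse_sport("golf", mapping) == "other"

    def test_many_to_few_grouping(self):
        sports = [f"sport_{i}" for i in range(27)]
        mapping = {s: f"group_{i % 11}" for i, s in enumerate(sports)}
        groups = {collapse_sport(s, mapping) for s in sports}
        assert len(groups) == 11


class TestOutcomes:
    def test_recovery_is_final_asymptomatic_evaluation(self):
        assert time_to_recovery(episode(severities_by_day=[(0, 30), (5, 10), (12, 0)])) == 12
        assert time_to_recovery(episode(severities_by_day=[(0, 30), (5, 10)])) is None
        # transient zero followed by rebound: the day-15 final zero counts
        assert time_to_recovery(
            episode(severities_by_day=[(0, 20), (6, 0), (9, 4), (15, 0)])
        ) == 15

    def test_recovery_censored_by_trailing_symptoms(self):
        recovered = episode(severities_by_day=[(0, 20), (6, 0)])
        assert time_to_recovery(recovered) == 6
        relapsed = episode(severities_by_day=[(0, 20), (6, 0), (9, 4)])
        assert time_to_recovery(relapsed) is None  # censored: larger in the censoring order

    def test_empty_trajectory_rejected(self):
        ep = episode()
        ep.trajectory = []
        with pytest.raises(ValidationError):
            time_to_recovery(ep)

    def test_rtp_passthrough_and_ordering_warning(self, caplog):
        assert time_to_rtp(episode(rtp=17), recovery_day=12) == 17
        assert time_to_rtp(episode()) is None
        with caplog.at_level(logging.WARNING):
            assert time_to_rtp(episode(rtp=10), recovery_day=12) == 10
        assert "precedes" in caplog.text

    def test_trajectory_day_invariants(self):
        with pytest.raises(ValidationError, match="48 h"):
            episode(severities_by_day=[(3, 10)])
        with pytest.raises(ValidationError, match="increasing"):
            episode(severities_by_day=[(0, 10), (0, 5)])
        with pytest.raises(ValidationError, match="sex"):
            ConcussionEpisode("x", "other", "soccer", "sport", [])


def _assignment_table(n_female, n_male, memberships):
    """Rows with given sex counts; per profile (n_f, n_m) memberships."""
    sex = ["female"] * n_female + ["male"] * n_male
    table = pd.DataFrame({"sex": sex})
    females = np.arange(n_female)
    males = n_female + np.arange(n_male)
    for profile in PROFILE_NAMES:
        col = np.zeros(len(sex), dtype=bool)
        n_f, n_m = memberships.get(profile, (0, 0))
        col[females[:n_f]] = True
        col[males[:n_m]] = True
        table[profile] = col
    return table


class TestSummaries:
    def test_percentages_and_sex_split(self):
        table = _assignment_table(275, 304, {"cognitive": (175, 208), "anxiety_mood": (99, 107)})
        summary = summarize_assignment_table(table)
        frame = summary.to_frame()
        assert summary.n_total == 579
        assert frame.loc["cognitive", "pct_total"] == 66.1
        assert frame.loc["cognitive", "pct_female"] == 45.7
        assert frame.loc["anxiety_mood", "pct_female"] == 48.1

    def test_sex_shares_sum_to_100(self):
        rng = np.random.default_rng(5)
        memberships = {p: (int(rng.integers(1, 100)), int(rng.integers(1, 100))) for p in PROFILE_NAMES}
        summary = summarize_assignment_table(_assignment_table(120, 130, memberships))
        for profile, row in summary.profile_counts.items():
            if row["n"]:
                assert row["pct_female"] + row["pct_male"] == pytest.approx(100, abs=0.1)
                assert row["n_female"] + row["n_male"] == row["n"]

    def test_balanced_cohort_has_zero_chi_square(self):
        summary = summarize_assignment_table(_assignment_table(50, 50, {}))
        assert summary.sex_chi2 == 0.0

    def test_empty_cohort_rejected(self, registry):
        with pytest.raises(ValidationError):
            summarize_assignment_table(pd.DataFrame())
        with pytest.raises(ValidationError):
            summarize_cohort([], registry)

    def test_classification_path_counts(self, registry):
        cognitive_symptoms = sorted(registry.profiles["cognitive"])[:4]
        eps = [
            ConcussionEpisode(
                f"a{i}", "female" if i % 2 else "male", "soccer", "sport",
                [make_checklist(**{s: 2 for s in cognitive_symptoms})],
            )
            for i in range(10)
        ]
        summary = summarize_cohort(eps, registry)
        assert summary.profile_counts["cognitive"]["n"] == 10
        assert summary.profile_counts["cognitive"]["pct_total"] == 100.0
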