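import numpy as np
import pytest
from hypothesis import settings

from concussion_profiles.scat5 import SCAT5_SYMPTOMS, SymptomChecklist, default_registry

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


def make_checklist(day=0, **severities) -> SymptomChecklist:
    """Checklist with the named severities and zeros elsewhere."""
    base = {s: 0 for s in SCAT5_SYMPTOMS}
    base.update(severities)
    return SymptomChecklist(symptom_severities=base, day_post_injury=day)


def random_checklist(rng: np.random.Generator, day=0, p_zero=0.5) -> SymptomChecklist:
    sev = np.where(
        rng.random(len(SCAT5_SYMPTOMS)) < p_zero, 0, rng.integers(0, 7, len(SCAT5_SYMPTOMS))
    )
    return SymptomChecklist(
        symptom_severities={s: int(v) for s, v in zip(SCAT5_SYMPTOMS, sev)},
        day_post_injury=day,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One shared synthetic cohort for pipeline-level tests."""
    from concussion_profiles.cohort import apply_inclusion_filter, build_initial_table
    from concussion_profiles.simulate import SimulationConfig, generate_cohort

    config = SimulationConfig(n_athletes=250, seed=7)
    episodes = apply_inclusion_filter(generate_cohort(config))
    registry = default_registry()
    return episodes, build_initial_table(episodes, registry)
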