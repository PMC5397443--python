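import numpy as np
import pytest

from cathskill.synthetic_cohort import (
    CohortDesign,
    default_profiles,
    generate_cohort,
)
from cathskill.trial_model import synchronize


@pytest.fixture(scope="session")
def profiles():
    """(expert, novice) default skill profiles."""
    return default_profiles()


@pytest.fixture(scope="session")
def distal_cohort():
    """Default distal study: 4 expert + 10 novice operators, 3 arch-vessel
    tasks, 3 repetitions each (126 trials), seed 42."""
    design = CohortDesign(
        n_expert_operators=4,
        n_novice_operators=10,
        tasks=("LSA", "LCCA", "RCCA"),
        repetitions_per_task=3,
        setup="distal",
        seed=42,
    )
    return generate_cohort(design)


@pytest.fixture(scope="session")
def distal_cohort_synced(distal_cohort):
    return [synchronize(t) for t in distal_cohort]


@pytest.fixture(scope="session")
def proximal_lra_cohort():
    """Default proximal study restricted to the left renal artery task:
    6 expert + 10 novice operators, 3 repetitions (48 trials), seed 42."""
    design = CohortDesign(
        n_expert_operators=6,
        n_novice_operators=10,
        tasks=("LRA",),
        repetitions_per_task=3,
        setup="proximal",
        seed=42,
    )
    return generate_cohort(design)


@pytest.fixture(scope="session")
def proximal_lra_synced(proximal_lra_cohort):
    return [synchronize(t) for t in proximal_lra_cohort]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
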