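import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from pporl import (CohortSpec, ORLParams, build_deck_specs,
                   generate_cohort, generate_payout_sequence,
                   task_components)


@pytest.fixture(scope="session")
def deck_specs():
    return build_deck_specs()


@pytest.fixture(scope="session")
def canonical_sequences(deck_specs):
    return {s.label: generate_payout_sequence(s) for s in deck_specs}


@pytest.fixture(scope="session")
def task():
    """(specs, schedule, sequences) for the canonical task."""
    return task_components()


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-subject synthetic cohort shared by fast inference tests."""
    return generate_cohort(CohortSpec(n_subjects=12))


@pytest.fixture
def mid_params():
    return ORLParams(a_rew=0.2, a_pun=0.1, beta_f=2.0, beta_b=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
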