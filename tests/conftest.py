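"""Shared fixtures: small synthetic cohorts and stimulus configurations."""

import numpy as np
import pytest
from hypothesis import settings as _hsettings

from cfctacs.stimgen import StimConfig
from cfctacs.synthetic import CohortConfig, generate_cohort

# property tests run derandomised so the suite is reproducible end to end
_hsettings.register_profile("deterministic", derandomize=True)
_hsettings.load_profile("deterministic")


@pytest.fixture(scope="session")
def stim_config():
    return StimConfig()


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two participants, 12 trials per condition — enough for shape and
    container tests, too small for decoding."""
    return generate_cohort(
        CohortConfig(n_participants=2, trials_per_condition=12, seed=42)
    )


@pytest.fixture(scope="session")
def decoding_cohort():
    """One participant at the study trial count, default planted effect."""
    return generate_cohort(
        CohortConfig(n_participants=1, trials_per_condition=60, seed=7)
    )
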