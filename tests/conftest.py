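"""Shared fixtures: small synthetic cohorts and their feature tables.

Everything is generated programmatically at fixture time; session scope keeps
the Welch featurization cost paid once per run.
"""

import numpy as np
import pytest

from ledgaze.pipeline import featurize_bank, featurize_stage1
from ledgaze.simulate import SimulationConfig, synth_cohort, synth_recording


@pytest.fixture(scope="session")
def small_cohort():
    """2 subjects x 2 reps/class = 32 recordings at default amplitudes."""
    return synth_cohort(n_subjects=2, reps_per_class=2, seed=11)


@pytest.fixture(scope="session")
def small_tables(small_cohort):
    """Aligned (stage-1, stage-2) feature tables for the small cohort."""
    return featurize_stage1(small_cohort), featurize_bank(small_cohort)


@pytest.fixture(scope="session")
def default_recording():
    """One LED-on right_left recording at default settings."""
    return synth_recording(SimulationConfig(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
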