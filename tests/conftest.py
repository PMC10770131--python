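import numpy as np
import pytest

from tremorkit.modeling import build_cohort_data
from tremorkit.preprocess import PreprocessConfig
from tremorkit.scenarios import REDUCED_PROTOCOL
from tremorkit.synth import GeneratorConfig, SubjectProfile, generate_cohort


@pytest.fixture(scope="session")
def reduced_protocol():
    return REDUCED_PROTOCOL


@pytest.fixture(scope="session")
def small_cohort_sessions(reduced_protocol):
    """15 PD / 15 HC sessions on the reduced three-step protocol."""
    config = GeneratorConfig(n_pd=15, n_hc=15, n_dd=0, seed=3, protocol=reduced_protocol)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def small_cohort_data(small_cohort_sessions, reduced_protocol):
    """Preprocessed cohort with cached manual features (shared, read-only)."""
    return build_cohort_data(
        small_cohort_sessions,
        PreprocessConfig(removed_steps=frozenset()),
        protocol=reduced_protocol,
    )


def make_profile(**overrides) -> SubjectProfile:
    """A plain PD profile with deterministic fields; overridable per test."""
    defaults = dict(
        subject_id="s0",
        condition="PD",
        gender="male",
        age=65.0,
        tremor_freq=4.0,
        tremor_amp=0.2,
        laterality=0.8,
        dominant_wrist="right",
        tremor_context=frozenset({"rest"}),
        symptom_probs=np.full(30, 0.5),
    )
    defaults.update(overrides)
    return SubjectProfile(**defaults)
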