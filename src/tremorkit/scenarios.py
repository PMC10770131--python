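"""Constructed evaluation cohorts for calibration and recovery studies.

Each scenario fixes the generative structure (where the class signal lives)
so that downstream behaviour has a known expected outcome: a strongly
separated PD-vs-HC contrast, an exchangeable null, a cohort whose two data
modalities carry complementary information, and a cohort whose only signal
sits in the resting-task tremor.  A reduced three-step protocol (one step
per task category) keeps repeated-seed studies cheap without changing the
pipeline's structure.
"""

from __future__ import annotations

import numpy as np

from . import pdnms
from .protocol import ProtocolStep
from .session_io import AssessmentSession
from .synth import (
    ClassPhenotype,
    GeneratorConfig,
    SubjectProfile,
    default_phenotypes,
    generate_cohort,
    sessions_from_profiles,
)

__all__ = [
    "REDUCED_PROTOCOL",
    "strong_contrast_cohort",
    "null_cohort",
    "complementary_cohort",
    "rest_signal_cohort",
]

#: One step per task category; 10 s each.
REDUCED_PROTOCOL: tuple[ProtocolStep, ...] = (
    ProtocolStep("step1a", 10.0, "Resting"),
    ProtocolStep("step2", 10.0, "Postural"),
    ProtocolStep("step6", 10.0, "Kinetic"),
)


def strong_contrast_cohort(
    n_per_class: int, seed: int, protocol=None
) -> list[AssessmentSession]:
    """PD vs HC with the default phenotypes: tremor amplitude far above noise."""
    kwargs = {} if protocol is None else {"protocol": protocol}
    config = GeneratorConfig(n_pd=n_per_class, n_hc=n_per_class, n_dd=0, seed=seed, **kwargs)
    return generate_cohort(config)


def null_cohort(
    n_per_class: int, seed: int, protocol=REDUCED_PROTOCOL
) -> list[AssessmentSession]:
    """PD and HC labels drawn from identical generative parameters.

    Both classes use the healthy-control phenotype (no tremor, identical
    questionnaire probabilities), so any systematic deviation of downstream
    accuracy from chance indicates leakage or bias.
    """
    hc = default_phenotypes()["HC"]
    phenotypes = {"PD": hc, "HC": hc, "DD": hc}
    config = GeneratorConfig(
        n_pd=n_per_class, n_hc=n_per_class, n_dd=0, seed=seed,
        protocol=protocol, phenotypes=phenotypes,
    )
    return generate_cohort(config)


def complementary_cohort(
    n_per_class: int, seed: int, protocol=REDUCED_PROTOCOL
) -> list[AssessmentSession]:
    """PD vs HC where each modality resolves a different half of the cases.

    Half of the PD subjects carry a strong rest tremor but healthy-looking
    questionnaires; the other half have no tremor but strongly positive
    questionnaires.  HC subjects have neither.  Either modality alone tops
    out near 75% balanced accuracy; combining them can resolve everyone.
    """
    rng = np.random.default_rng(seed)
    strong_q = np.full(pdnms.N_ITEMS, 0.05)
    strong_q[:10] = 0.9
    weak_q = np.full(pdnms.N_ITEMS, 0.05)

    profiles: list[SubjectProfile] = []
    for i in range(n_per_class):
        tremor_half = i < n_per_class // 2
        profiles.append(
            SubjectProfile(
                subject_id=f"pd_{i:04d}", condition="PD",
                gender="male" if rng.random() < 0.5 else "female",
                age=float(rng.uniform(50, 80)),
                tremor_freq=float(rng.uniform(4, 6)) if tremor_half else 0.0,
                tremor_amp=float(rng.uniform(0.1, 0.25)) if tremor_half else 0.0,
                laterality=0.8,
                dominant_wrist="right",
                tremor_context=frozenset({"rest"}) if tremor_half else frozenset(),
                symptom_probs=weak_q if tremor_half else strong_q,
            )
        )
    for i in range(n_per_class):
        profiles.append(
            SubjectProfile(
                subject_id=f"hc_{i:04d}", condition="HC",
                gender="male" if rng.random() < 0.5 else "female",
                age=float(rng.uniform(50, 80)),
                symptom_probs=weak_q,
            )
        )
    config = GeneratorConfig(
        n_pd=n_per_class, n_hc=n_per_class, n_dd=0, seed=seed, protocol=protocol
    )
    return sessions_from_profiles(profiles, config)


def rest_signal_cohort(
    n_per_class: int, seed: int, protocol=REDUCED_PROTOCOL
) -> list[AssessmentSession]:
    """PD vs HC where the only class signal is rest-context tremor.

    Questionnaire probabilities are identical across classes, so the
    resting-task sensor features are the sole informative feature group.
    """
    phen = default_phenotypes()
    flat_q = np.full(pdnms.N_ITEMS, 0.2)
    phenotypes = {
        "PD": ClassPhenotype(
            phen["PD"].freq_range, phen["PD"].amp_range, frozenset({"rest"}),
            phen["PD"].laterality_range, flat_q,
        ),
        "HC": ClassPhenotype((0.0, 0.0), (0.0, 0.0), frozenset(), (0.5, 0.5), flat_q),
        "DD": phen["DD"],
    }
    config = GeneratorConfig(
        n_pd=n_per_class, n_hc=n_per_class, n_dd=0, seed=seed,
        protocol=protocol, phenotypes=phenotypes,
    )
    return generate_cohort(config)
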