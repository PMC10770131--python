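"""Non-motor-symptom questionnaire structure.

The questionnaire is a 30-item yes/no instrument covering the classic
non-motor symptom domains of Parkinson's disease.  The item-to-domain map
below is the package's configurable default grouping into nine conventional
domains; studies using a different item ordering can supply their own map.
"""

from __future__ import annotations

import numpy as np

__all__ = ["N_ITEMS", "DEFAULT_DOMAINS", "default_class_symptom_probs"]

N_ITEMS = 30

#: Default grouping of the 30 items into nine symptom domains.
DEFAULT_DOMAINS: dict[str, list[int]] = {
    "gastrointestinal": [0, 1, 2, 3, 4],        # drooling, swallowing, nausea, constipation, bowel
    "urinary": [5, 6],
    "apathy/attention/memory": [7, 8, 9],
    "hallucinations/delusions": [10, 11],
    "depression/anxiety": [12, 13, 14],
    "sexual function": [15, 16],
    "cardiovascular/falls": [17, 18],
    "sleep/fatigue": [19, 20, 21, 22, 23],      # insomnia, vivid dreams, RBD, RLS, daytime sleepiness
    "miscellaneous": [24, 25, 26, 27, 28, 29],  # pain, taste/smell, weight, sweating, diplopia, swelling
}


def default_class_symptom_probs() -> dict[str, np.ndarray]:
    """Per-class Bernoulli probabilities for the 30 questionnaire items.

    PD cases report non-motor symptoms frequently (sleep/fatigue and
    gastrointestinal domains most of all), healthy controls rarely, and the
    differential-diagnosis group at an intermediate, less PD-specific rate.
    """
    pd = np.full(N_ITEMS, 0.40)
    pd[DEFAULT_DOMAINS["sleep/fatigue"]] = 0.60
    pd[DEFAULT_DOMAINS["gastrointestinal"]] = 0.50

    hc = np.full(N_ITEMS, 0.08)
    hc[DEFAULT_DOMAINS["sleep/fatigue"]] = 0.15

    dd = np.full(N_ITEMS, 0.25)
    dd[DEFAULT_DOMAINS["sleep/fatigue"]] = 0.35
    return {"PD": pd, "HC": hc, "DD": dd}
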