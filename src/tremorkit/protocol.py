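"""Assessment protocol and study-scale constants.

The interactive smartwatch assessment consists of 11 movement steps performed
while seated, each recorded on both wrists with 3-axis accelerometer and
3-axis gyroscope at 100 Hz.  Three steps last 20 s, the remaining eight 10 s.
Each step belongs to one of three task categories — Resting, Postural,
Kinetic — according to the tremor regime it provokes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "ProtocolStep",
    "DEFAULT_PROTOCOL",
    "DEFAULT_REMOVED_STEPS",
    "TASK_CATEGORIES",
    "WRISTS",
    "SENSORS",
    "AXES",
    "CONDITIONS",
    "GENDERS",
    "CLASS_SIZES",
    "CLASS_GENDER_COUNTS",
    "CLASS_AGE_MEAN_SD",
    "N_RECORDED_PARTICIPANTS",
    "N_DROPPED_MISSING",
    "N_REMOVED_AGE_MATCHING",
    "included_cohort_size",
    "recorded_step_count",
    "task_segment_count",
    "channel_count",
]


@dataclass(frozen=True)
class ProtocolStep:
    """One step of the assessment protocol."""

    name: str
    duration_s: float
    category: str  # one of TASK_CATEGORIES

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"step {self.name!r}: duration must be positive")
        if self.category not in TASK_CATEGORIES:
            raise ValueError(
                f"step {self.name!r}: category {self.category!r} not in {TASK_CATEGORIES}"
            )


TASK_CATEGORIES = ("Resting", "Postural", "Kinetic")
WRISTS = ("left", "right")
SENSORS = ("acceleration", "rotation")
AXES = ("x", "y", "z")
CONDITIONS = ("PD", "DD", "HC")
GENDERS = ("male", "female")

#: The 11-step assessment protocol: three 20-s steps (relaxed sitting,
#: relaxed with serial-sevens counting, entrainment) and eight 10-s steps.
DEFAULT_PROTOCOL: tuple[ProtocolStep, ...] = (
    ProtocolStep("step1a", 20.0, "Resting"),   # relaxed, eyes closed
    ProtocolStep("step1b", 20.0, "Resting"),   # relaxed, counting serial sevens
    ProtocolStep("step2", 10.0, "Postural"),   # lift and extend arms
    ProtocolStep("step3", 10.0, "Postural"),   # lift and hold
    ProtocolStep("step4", 10.0, "Postural"),   # hold 1-kg weight
    ProtocolStep("step5", 10.0, "Kinetic"),    # point finger
    ProtocolStep("step6", 10.0, "Kinetic"),    # drink from glass
    ProtocolStep("step7", 10.0, "Kinetic"),    # cross and extend arms
    ProtocolStep("step8", 10.0, "Kinetic"),    # touch index fingers
    ProtocolStep("step9", 10.0, "Kinetic"),    # tap nose
    ProtocolStep("step10", 20.0, "Postural"),  # entrainment (paced stomping)
)

#: Steps dropped before feature extraction (no added classification value):
#: "lift and hold", "point finger", "touch index".
DEFAULT_REMOVED_STEPS = frozenset({"step3", "step5", "step8"})

# Study-scale constants (cohort marginals the synthetic generator emulates).
N_RECORDED_PARTICIPANTS = 504     # participants originally recorded
N_DROPPED_MISSING = 2             # removed for missing data
N_REMOVED_AGE_MATCHING = 33       # youngest controls removed for age matching

CLASS_SIZES = {"PD": 276, "HC": 79, "DD": 114}
CLASS_GENDER_COUNTS = {"PD": (195, 81), "HC": (29, 50), "DD": (57, 57)}  # (male, female)
CLASS_AGE_MEAN_SD = {"PD": (65.4, 9.6), "HC": (62.9, 12.5), "DD": (62.4, 11.5)}


def included_cohort_size() -> int:
    """Number of participants retained after exclusions and age matching."""
    return N_RECORDED_PARTICIPANTS - N_DROPPED_MISSING - N_REMOVED_AGE_MATCHING


def recorded_step_count(protocol: Iterable[ProtocolStep] = DEFAULT_PROTOCOL) -> int:
    """Total assessment steps recorded before any exclusion."""
    return N_RECORDED_PARTICIPANTS * len(tuple(protocol))


def task_segment_count(
    protocol: Iterable[ProtocolStep] = DEFAULT_PROTOCOL,
    removed_steps: frozenset[str] = frozenset(),
    split_long: bool = True,
) -> int:
    """Number of 10-s task segments after step removal and 20-s splitting."""
    n = 0
    for step in protocol:
        if step.name in removed_steps:
            continue
        n += 2 if (split_long and step.duration_s > 15.0) else 1
    return n


def channel_count(
    protocol: Iterable[ProtocolStep] = DEFAULT_PROTOCOL,
    removed_steps: frozenset[str] = frozenset(),
    n_sensors: int = 2,
) -> int:
    """Channels per participant: segments x 2 wrists x sensors x 3 axes."""
    return task_segment_count(protocol, removed_steps) * 2 * n_sensors * 3
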