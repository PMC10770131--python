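"""Synthetic assessment-cohort generator.

Emulates the statistical structure of a dual-smartwatch movement-disorder
study: class-conditional wrist tremor (rest-dominant 4-6 Hz with side
dominance for PD, postural/kinetic 5-8 Hz for the differential-diagnosis
group, none for healthy controls), slow gravitational-orientation drift, a
short vibration burst announcing the start of each recording, the 11-step
assessment protocol, and class-conditional Bernoulli questionnaire answers.

Units: acceleration in g (gravity magnitude 1.0), rotation rate in rad/s.
A single ``numpy`` Generator seeded from the config drives everything, so
identical configs produce bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import pdnms
from .protocol import (
    CLASS_AGE_MEAN_SD,
    CLASS_GENDER_COUNTS,
    CLASS_SIZES,
    DEFAULT_PROTOCOL,
    ProtocolStep,
    SENSORS,
    WRISTS,
)
from .session_io import AssessmentRecording, AssessmentSession

__all__ = [
    "SubjectProfile",
    "ClassPhenotype",
    "GeneratorConfig",
    "default_phenotypes",
    "sample_profiles",
    "generate_signal",
    "generate_questionnaire",
    "build_session",
    "generate_cohort",
    "sessions_from_profiles",
]

#: Map protocol task categories to the tremor contexts they provoke.
CATEGORY_CONTEXT = {"Resting": "rest", "Postural": "postural", "Kinetic": "kinetic"}
TREMOR_CONTEXTS = frozenset(CATEGORY_CONTEXT.values())


@dataclass
class SubjectProfile:
    """Latent phenotype of one synthetic participant."""

    subject_id: str
    condition: str              # PD | DD | HC
    gender: str                 # male | female
    age: float                  # years
    tremor_freq: float = 0.0    # Hz; 0 if no tremor
    tremor_amp: float = 0.0     # g
    laterality: float = 0.5     # fraction of amplitude on the dominant side
    dominant_wrist: str = "right"
    tremor_context: frozenset[str] = frozenset()
    symptom_probs: np.ndarray = field(default_factory=lambda: np.zeros(pdnms.N_ITEMS))

    def __post_init__(self) -> None:
        if self.tremor_amp < 0:
            raise ValueError("tremor_amp must be >= 0")
        if not 0.0 <= self.laterality <= 1.0:
            raise ValueError("laterality must lie in [0, 1]")
        if not self.tremor_context <= TREMOR_CONTEXTS:
            raise ValueError(f"tremor_context must be a subset of {sorted(TREMOR_CONTEXTS)}")
        self.symptom_probs = np.asarray(self.symptom_probs, dtype=float)
        if self.symptom_probs.shape != (pdnms.N_ITEMS,):
            raise ValueError(f"exactly {pdnms.N_ITEMS} symptom probabilities required")

    def wrist_amplitude(self, wrist: str) -> float:
        """Tremor amplitude on a wrist under the side-dominance split."""
        share = self.laterality if wrist == self.dominant_wrist else 1.0 - self.laterality
        return self.tremor_amp * share


@dataclass
class ClassPhenotype:
    """Parameter ranges from which a class's subject profiles are drawn."""

    freq_range: tuple[float, float]          # Hz
    amp_range: tuple[float, float]           # g
    contexts: frozenset[str]
    laterality_range: tuple[float, float]
    symptom_probs: np.ndarray


def default_phenotypes() -> dict[str, ClassPhenotype]:
    """Clinical-description defaults: PD rest tremor 4-6 Hz with strong side
    dominance; DD action/postural tremor 5-8 Hz, more symmetric; HC none."""
    probs = pdnms.default_class_symptom_probs()
    return {
        "PD": ClassPhenotype((4.0, 6.0), (0.05, 0.25), frozenset({"rest"}),
                             (0.70, 0.95), probs["PD"]),
        "DD": ClassPhenotype((5.0, 8.0), (0.05, 0.25), frozenset({"postural", "kinetic"}),
                             (0.50, 0.70), probs["DD"]),
        "HC": ClassPhenotype((0.0, 0.0), (0.0, 0.0), frozenset(),
                             (0.5, 0.5), probs["HC"]),
    }


@dataclass
class GeneratorConfig:
    """Cohort-level generator settings (defaults mirror the study marginals)."""

    n_pd: int = CLASS_SIZES["PD"]
    n_hc: int = CLASS_SIZES["HC"]
    n_dd: int = CLASS_SIZES["DD"]
    fs: float = 100.0
    protocol: tuple[ProtocolStep, ...] = DEFAULT_PROTOCOL
    seed: int = 0
    phenotypes: dict[str, ClassPhenotype] = field(default_factory=default_phenotypes)
    gravity_drift_scale: float = 0.02   # g per second of random orientation drift
    noise_sd: float = 0.01              # g, white sensor noise
    vibration_duration: float = 0.5     # s, start-of-recording notification buzz
    vibration_amp: float = 0.3          # g
    vibration_freq: float = 25.0        # Hz
    rotation_scale: float = 2.0         # rad/s of gyro tremor per g of accel tremor

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate fs must be positive")
        if len(self.protocol) == 0:
            raise ValueError("protocol must contain at least one step")
        if min(self.n_pd, self.n_hc, self.n_dd) < 0:
            raise ValueError("cohort counts must be >= 0")


def _gender_probability(condition: str) -> float:
    male, female = CLASS_GENDER_COUNTS[condition]
    return male / (male + female)


def sample_profiles(config: GeneratorConfig) -> list[SubjectProfile]:
    """Draw subject profiles for the configured class counts (deterministic)."""
    rng = np.random.default_rng(config.seed)
    profiles: list[SubjectProfile] = []
    counts = {"PD": config.n_pd, "HC": config.n_hc, "DD": config.n_dd}
    idx = 0
    for condition in ("PD", "HC", "DD"):
        phen = config.phenotypes[condition]
        mean_age, sd_age = CLASS_AGE_MEAN_SD[condition]
        p_male = _gender_probability(condition)
        for _ in range(counts[condition]):
            has_tremor = phen.amp_range[1] > 0
            profiles.append(
                SubjectProfile(
                    subject_id=f"{condition.lower()}_{idx:04d}",
                    condition=condition,
                    gender="male" if rng.random() < p_male else "female",
                    age=float(np.clip(rng.normal(mean_age, sd_age), 30.0, 95.0)),
                    tremor_freq=float(rng.uniform(*phen.freq_range)) if has_tremor else 0.0,
                    tremor_amp=float(rng.uniform(*phen.amp_range)) if has_tremor else 0.0,
                    laterality=float(rng.uniform(*phen.laterality_range)),
                    dominant_wrist=WRISTS[rng.integers(2)],
                    tremor_context=phen.contexts,
                    symptom_probs=phen.symptom_probs.copy(),
                )
            )
            idx += 1
    return profiles


def _piecewise_linear(rng, n: int, fs: float, knot_spacing_s: float, step_sd: float) -> np.ndarray:
    """Random walk sampled at knots, linearly interpolated to all samples."""
    duration = n / fs
    n_knots = max(2, int(np.ceil(duration / knot_spacing_s)) + 1)
    knots_t = np.linspace(0.0, duration, n_knots)
    values = np.concatenate([[0.0], np.cumsum(rng.normal(0.0, step_sd, n_knots - 1))])
    return np.interp(np.arange(n) / fs, knots_t, values)


def generate_signal(
    profile: SubjectProfile,
    step: ProtocolStep,
    wrist: str,
    sensor: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Synthesize one 3-axis recording: gravity drift + gated tremor + noise + buzz."""
    fs = config.fs
    n = int(round(step.duration_s * fs))
    t = np.arange(n) / fs
    out = np.zeros((3, n))

    # gravitational offset and slow orientation drift (acceleration only)
    if sensor == "acceleration":
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        knot_sd = config.gravity_drift_scale * 2.0  # per 2-s knot interval
        for ax in range(3):
            drift = _piecewise_linear(rng, n, fs, 2.0, knot_sd)
            out[ax] = direction[ax] + drift

    # tremor oscillation, gated by task context and scaled by side dominance
    context = CATEGORY_CONTEXT[step.category]
    amp = profile.wrist_amplitude(wrist)
    if context in profile.tremor_context and amp > 0 and profile.tremor_freq > 0:
        if sensor == "rotation":
            amp *= config.rotation_scale
        loading = rng.normal(size=3)
        loading /= np.linalg.norm(loading)
        # slow multiplicative log-normal envelope keeps the spectral peak sharp
        envelope = np.exp(_piecewise_linear(rng, n, fs, 1.0, 0.2))
        phase = rng.uniform(0, 2 * np.pi)
        carrier = envelope * np.sin(2 * np.pi * profile.tremor_freq * t + phase)
        out += amp * loading[:, None] * carrier[None, :]

    # start-of-recording notification vibration (high-frequency burst)
    if config.vibration_amp > 0 and config.vibration_duration > 0:
        m = min(n, int(round(config.vibration_duration * fs)))
        out[:, :m] += config.vibration_amp * np.sin(
            2 * np.pi * config.vibration_freq * t[:m]
        )[None, :]

    if config.noise_sd > 0:
        out += rng.normal(0.0, config.noise_sd, size=(3, n))
    return out


def generate_questionnaire(profile: SubjectProfile, rng: np.random.Generator) -> np.ndarray:
    """30 independent Bernoulli yes/no answers from the profile's probabilities."""
    p = profile.symptom_probs
    if np.any((p < 0) | (p > 1)):
        raise ValueError("symptom probabilities must lie in [0, 1]")
    return (rng.random(pdnms.N_ITEMS) < p).astype(int)


def build_session(
    profile: SubjectProfile,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> AssessmentSession:
    """Full assessment for one subject: questionnaire + every (step, wrist, sensor)."""
    questionnaire = generate_questionnaire(profile, rng)
    recordings = []
    for step in config.protocol:
        for wrist in WRISTS:
            for sensor in SENSORS:
                samples = generate_signal(profile, step, wrist, sensor, config, rng)
                recordings.append(
                    AssessmentRecording(step.name, wrist, sensor, samples, config.fs)
                )
    return AssessmentSession(
        subject_id=profile.subject_id,
        condition=profile.condition,
        gender=profile.gender,
        age=profile.age,
        questionnaire=questionnaire,
        recordings=recordings,
    )


def generate_cohort(config: GeneratorConfig) -> list[AssessmentSession]:
    """Generate the full cohort; deterministic for a given config/seed."""
    profiles = sample_profiles(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, len(profiles)]))
    return [build_session(p, config, rng) for p in profiles]


def sessions_from_profiles(
    profiles: list[SubjectProfile],
    config: GeneratorConfig,
) -> list[AssessmentSession]:
    """Generate sessions for externally constructed profiles (same determinism)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, len(profiles)]))
    return [build_session(p, config, rng) for p in profiles]
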