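"""Read/write assessment sessions as plain JSON files and build channel tensors.

A session directory holds one ``metadata.json`` (subject id, condition,
gender, age, 30-item questionnaire) plus one ``<step>_<wrist>_<sensor>.json``
per recording, each carrying the three axis arrays as decimal numbers so the
files stay readable and editable in any text editor and round-trip
losslessly.  The reader tolerates (and preserves) unknown metadata keys so
directories following richer schemas still load.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .protocol import AXES, CONDITIONS, GENDERS, SENSORS, WRISTS

__all__ = [
    "AssessmentRecording",
    "AssessmentSession",
    "ChannelTensor",
    "SessionValidationError",
    "write_session",
    "read_session",
    "assemble_channels",
]

N_QUESTIONNAIRE_ITEMS = 30


class SessionValidationError(ValueError):
    """A session file violates the documented layout."""


@dataclass
class AssessmentRecording:
    """One wrist-worn sensor recording of a single assessment step."""

    step_name: str
    wrist: str
    sensor: str
    samples: np.ndarray  # shape (3, n_samples)
    fs: float = 100.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != 3:
            raise SessionValidationError(
                f"recording {self.step_name}/{self.wrist}/{self.sensor}: "
                f"samples must have shape (3, n), got {self.samples.shape}"
            )
        if self.wrist not in WRISTS:
            raise SessionValidationError(f"wrist must be one of {WRISTS}, got {self.wrist!r}")
        if self.sensor not in SENSORS:
            raise SessionValidationError(f"sensor must be one of {SENSORS}, got {self.sensor!r}")
        if self.fs <= 0:
            raise SessionValidationError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.step_name, self.wrist, self.sensor)


@dataclass
class AssessmentSession:
    """One participant's full assessment: metadata, questionnaire, recordings."""

    subject_id: str
    condition: str
    gender: str
    age: float
    questionnaire: np.ndarray  # 30 binary answers
    recordings: list[AssessmentRecording] = field(default_factory=list)
    extra: dict = field(default_factory=dict)  # unknown metadata keys, preserved

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise SessionValidationError(
                f"condition {self.condition!r} not allowed; must be one of {list(CONDITIONS)}"
            )
        if self.gender not in GENDERS:
            raise SessionValidationError(
                f"gender {self.gender!r} not allowed; must be one of {list(GENDERS)}"
            )
        self.questionnaire = np.asarray(self.questionnaire, dtype=int)
        if self.questionnaire.shape != (N_QUESTIONNAIRE_ITEMS,):
            raise SessionValidationError(
                f"questionnaire must have {N_QUESTIONNAIRE_ITEMS} answers, "
                f"got shape {self.questionnaire.shape}"
            )
        if not np.isin(self.questionnaire, (0, 1)).all():
            raise SessionValidationError("questionnaire answers must be 0 or 1")
        keys = [r.key for r in self.recordings]
        if len(set(keys)) != len(keys):
            raise SessionValidationError("duplicate (step, wrist, sensor) recording")

    def recording(self, step_name: str, wrist: str, sensor: str) -> AssessmentRecording:
        for r in self.recordings:
            if r.key == (step_name, wrist, sensor):
                return r
        raise KeyError((step_name, wrist, sensor))


@dataclass
class ChannelTensor:
    """Fixed-order stack of single-axis 10-s series for one participant.

    Channel order is task-segment-major, then arm (left, right), sensor
    (acceleration, rotation), axis (x, y, z) — a pure function of the
    protocol and sensor selection, never of file enumeration order.
    """

    subject_id: str
    data: np.ndarray            # (n_channels, n_samples)
    labels: list[str]           # "<segment>/<wrist>/<sensor>/<axis>"
    categories: list[str]       # task category per channel
    sensors: list[str]          # sensor per channel (for input-source selection)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = self.data.shape[0]
        if not (len(self.labels) == len(self.categories) == len(self.sensors) == n):
            raise ValueError("channel annotations must match data row count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


def _recording_filename(rec: AssessmentRecording) -> str:
    return f"{rec.step_name}_{rec.wrist}_{rec.sensor}.json"


def write_session(session: AssessmentSession, directory: str | Path) -> list[Path]:
    """Write a session as one metadata document plus one file per recording."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    meta = {
        "subject_id": session.subject_id,
        "condition": session.condition,
        "gender": session.gender,
        "age": session.age,
        "questionnaire": [int(v) for v in session.questionnaire],
        **session.extra,
    }
    meta_path = directory / "metadata.json"
    meta_path.write_text(json.dumps(meta, indent=1), encoding="utf-8")
    written.append(meta_path)

    for rec in session.recordings:
        doc = {
            "step_name": rec.step_name,
            "wrist": rec.wrist,
            "sensor": rec.sensor,
            "fs": rec.fs,
            # json round-trips Python floats exactly (shortest-repr encoding)
            "samples": {ax: rec.samples[i].tolist() for i, ax in enumerate(AXES)},
        }
        path = directory / _recording_filename(rec)
        path.write_text(json.dumps(doc), encoding="utf-8")
        written.append(path)
    return written


_KNOWN_META_KEYS = {"subject_id", "condition", "gender", "age", "questionnaire"}


def read_session(directory: str | Path) -> AssessmentSession:
    """Read a session directory written by :func:`write_session`."""
    directory = Path(directory)
    meta_path = directory / "metadata.json"
    if not meta_path.is_file():
        raise SessionValidationError(f"missing metadata file: {meta_path}")
    try:
        meta = json.loads(meta_path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SessionValidationError(f"unparseable metadata file {meta_path}: {exc}") from exc

    for key in ("subject_id", "condition", "gender", "age", "questionnaire"):
        if key not in meta:
            raise SessionValidationError(f"{meta_path}: missing required key {key!r}")

    recordings = []
    for path in sorted(directory.glob("*.json")):
        if path.name == "metadata.json":
            continue
        try:
            doc = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise SessionValidationError(f"unparseable recording file {path}: {exc}") from exc
        try:
            axes = [doc["samples"][ax] for ax in AXES]
        except (KeyError, TypeError) as exc:
            raise SessionValidationError(f"{path}: malformed sample arrays") from exc
        lengths = {len(a) for a in axes}
        if len(lengths) != 1:
            raise SessionValidationError(
                f"{path}: axis arrays have unequal lengths {sorted(len(a) for a in axes)}"
            )
        try:
            samples = np.asarray(axes, dtype=float)
        except (TypeError, ValueError) as exc:
            raise SessionValidationError(f"{path}: non-numeric sample values") from exc
        try:
            recordings.append(
                AssessmentRecording(
                    step_name=doc["step_name"],
                    wrist=doc["wrist"],
                    sensor=doc["sensor"],
                    samples=samples,
                    fs=float(doc.get("fs", 100.0)),
                )
            )
        except (KeyError, SessionValidationError) as exc:
            raise SessionValidationError(f"{path}: {exc}") from exc

    extra = {k: v for k, v in meta.items() if k not in _KNOWN_META_KEYS}
    # deterministic recording order regardless of file-system enumeration
    recordings.sort(key=lambda r: r.key)
    try:
        return AssessmentSession(
            subject_id=str(meta["subject_id"]),
            condition=meta["condition"],
            gender=meta["gender"],
            age=float(meta["age"]),
            questionnaire=np.asarray(meta["questionnaire"]),
            recordings=recordings,
            extra=extra,
        )
    except SessionValidationError as exc:
        raise SessionValidationError(f"{meta_path}: {exc}") from exc


def assemble_channels(
    subject_id: str,
    segments: list,  # list[preprocess.ProcessedSegment]
    segment_order: list[tuple[str, str]],
    selected_sensors: tuple[str, ...] = SENSORS,
) -> ChannelTensor:
    """Stack preprocessed segments into the fixed-order channel tensor.

    ``segment_order`` is the (segment_name, task_category) list derived from
    the protocol (see :func:`tremorkit.preprocess.segment_plan`); it, not the
    order of ``segments``, determines channel order.
    """
    for s in selected_sensors:
        if s not in SENSORS:
            raise ValueError(f"unknown sensor {s!r}; must be a subset of {SENSORS}")
    by_key = {(s.name, s.wrist, s.sensor): s for s in segments}

    rows, labels, categories, sensors_out = [], [], [], []
    for seg_name, category in segment_order:
        for wrist in WRISTS:
            for sensor in SENSORS:
                if sensor not in selected_sensors:
                    continue
                seg = by_key.get((seg_name, wrist, sensor))
                if seg is None:
                    raise KeyError(
                        f"missing segment for (step={seg_name!r}, wrist={wrist!r}, "
                        f"sensor={sensor!r})"
                    )
                for ai, axis in enumerate(AXES):
                    rows.append(seg.samples[ai])
                    labels.append(f"{seg_name}/{wrist}/{sensor}/{axis}")
                    categories.append(category)
                    sensors_out.append(sensor)

    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise ValueError(f"segments have unequal lengths: {sorted(lengths)}")
    data = np.asarray(rows, dtype=float) if rows else np.empty((0, 0))
    return ChannelTensor(subject_id, data, labels, categories, sensors_out)
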