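"""Raw recordings to clean uniform 10-s channels.

Pipeline order: drop excluded steps -> trim the 0.5-s start-of-recording
vibration -> split 20-s recordings into two halves -> equalise segment
lengths -> remove the slow gravitational-orientation trend from the
acceleration channels by l1 trend filtering.

l1 trend filtering finds the piecewise-linear trend z minimising

    (1/2) * sum_t (x_t - z_t)^2 + lam * sum_t |z_{t-1} - 2 z_t + z_{t+1}|

i.e. squared error plus an l1 penalty on second differences.  The convex
problem is solved by ADMM with a cached banded Cholesky factorisation, so
repeated calls at the study's fixed segment length are cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse

from .protocol import DEFAULT_REMOVED_STEPS
from .session_io import AssessmentRecording, AssessmentSession

__all__ = [
    "PreprocessConfig",
    "ProcessedSegment",
    "trim_onset",
    "split_long",
    "l1_trend_filter",
    "l1_trend_objective",
    "degravitate",
    "segment_plan",
    "preprocess_session",
]


@dataclass
class PreprocessConfig:
    trim_seconds: float = 0.5
    split_long_recordings: bool = True
    removed_steps: frozenset[str] = DEFAULT_REMOVED_STEPS
    trend_lambda: float = 1e4
    apply_degravitation_to: frozenset[str] = frozenset({"acceleration"})

    def __post_init__(self) -> None:
        if self.trim_seconds < 0:
            raise ValueError("trim_seconds must be >= 0")
        if self.trend_lambda < 0:
            raise ValueError("trend_lambda must be >= 0")
        self.removed_steps = frozenset(self.removed_steps)
        self.apply_degravitation_to = frozenset(self.apply_degravitation_to)


@dataclass
class ProcessedSegment:
    """One cleaned single-wrist, single-sensor task segment (3 axes)."""

    name: str       # e.g. "step1a_1" (half of a 20-s step) or "step2"
    category: str   # task category inherited from the protocol step
    wrist: str
    sensor: str
    samples: np.ndarray  # (3, n)


def trim_onset(series: np.ndarray, fs: float, trim_seconds: float) -> np.ndarray:
    """Drop the first ``round(trim_seconds * fs)`` samples (watch vibration)."""
    series = np.asarray(series)
    n_drop = int(round(trim_seconds * fs))
    if series.shape[-1] <= n_drop:
        raise ValueError(
            f"series of {series.shape[-1]} samples too short to trim {n_drop} samples"
        )
    return series[..., n_drop:]


def split_long(recording: AssessmentRecording) -> list[AssessmentRecording]:
    """Split a 20-s recording into two consecutive halves; pass 10-s through.

    Halves are named ``<step>_1`` and ``<step>_2``; the split point is the
    floor midpoint, so the first half ends exactly where the second begins.
    Durations are judged on the nominal (possibly already-trimmed) length.
    """
    duration = recording.n_samples / recording.fs
    if 8.0 <= duration <= 12.0:
        return [recording]
    if 16.0 <= duration <= 22.0:
        half = recording.n_samples // 2
        return [
            AssessmentRecording(
                f"{recording.step_name}_1", recording.wrist, recording.sensor,
                recording.samples[:, :half], recording.fs,
            ),
            AssessmentRecording(
                f"{recording.step_name}_2", recording.wrist, recording.sensor,
                recording.samples[:, half:2 * half], recording.fs,
            ),
        ]
    raise ValueError(
        f"recording {recording.step_name!r}: unsupported duration {duration:.2f} s "
        "(expected ~10 s or ~20 s)"
    )


# --- l1 trend filtering ----------------------------------------------------

def _second_difference(n: int) -> scipy.sparse.csr_matrix:
    return scipy.sparse.diags(
        [np.ones(n - 2), -2 * np.ones(n - 2), np.ones(n - 2)],
        offsets=[0, 1, 2], shape=(n - 2, n), format="csr",
    )


def l1_trend_objective(x: np.ndarray, z: np.ndarray, lam: float) -> float:
    """Value of the trend-filtering objective at candidate trend ``z``."""
    d2 = np.diff(z, n=2)
    return 0.5 * float(np.sum((x - z) ** 2)) + lam * float(np.sum(np.abs(d2)))


def l1_trend_filter(
    series: np.ndarray,
    lam: float,
    *,
    max_iter: int = 60,
    tol: float = 1e-6,
) -> np.ndarray:
    """Piecewise-linear trend of ``series`` via the l1 trend-filtering objective.

    Solves the box-constrained dual QP

        minimise (1/2) v' D D' v - v' D x   s.t.  |v_i| <= lam

    with a primal-dual interior-point method (banded Newton systems), then
    recovers the trend as ``z = x - D' v``.  Terminates when the duality gap
    falls below ``tol`` relative to the objective scale.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("l1_trend_filter expects a 1-D series")
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite samples")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    n = x.size
    if n < 3:
        raise ValueError("series must have at least 3 samples")
    if lam == 0:
        return x.copy()

    m = n - 2
    D = _second_difference(n)
    Dt = D.T
    Dx = D @ x

    # constant pentadiagonal bands of D D' (upper form for solveh_banded)
    ddt_ab = np.zeros((3, m))
    ddt_ab[0, 2:] = 1.0
    ddt_ab[1, 1:] = -4.0
    ddt_ab[1, 1] = ddt_ab[1, -1] = -4.0
    ddt_ab[2, :] = 6.0
    ddt_ab[2, 0] = ddt_ab[2, -1] = 6.0  # rows are full because D has no boundary rows

    alpha, beta, mu = 0.01, 0.5, 2.0
    v = np.zeros(m)
    mu1 = np.ones(m)
    mu2 = np.ones(m)
    f1 = v - lam
    f2 = -v - lam
    t = 1e-10
    step = np.inf

    def _ddt_mul(u: np.ndarray) -> np.ndarray:
        return D @ (Dt @ u)

    for _ in range(max_iter):
        DTv = Dt @ v
        DDTv = D @ DTv
        w = Dx - (mu1 - mu2)

        pobj2 = 0.5 * DTv @ DTv + lam * np.abs(Dx - DDTv).sum()
        sol = scipy.linalg.solveh_banded(ddt_ab, w)
        pobj1 = 0.5 * w @ sol + lam * (mu1 + mu2).sum()
        pobj = min(pobj1, pobj2)
        dobj = -0.5 * DTv @ DTv + Dx @ v
        gap = pobj - dobj
        if gap <= tol * max(1.0, abs(pobj)):
            break
        if step >= 0.2:
            t = max(2.0 * m * mu / gap, 1.2 * t)

        # Newton system: (DD' + diag(mu1/-f1 + mu2/-f2)) dv = r
        r = -DDTv + Dx + (1.0 / t) / f1 - (1.0 / t) / f2
        ab = ddt_ab.copy()
        ab[2, :] += -(mu1 / f1 + mu2 / f2)
        dv = scipy.linalg.solveh_banded(ab, r)
        dmu1 = -(mu1 + ((1.0 / t) + dv * mu1) / f1)
        dmu2 = -(mu2 + ((1.0 / t) - dv * mu2) / f2)

        res_dual = DDTv - w
        residual = np.concatenate([res_dual, -mu1 * f1 - 1.0 / t, -mu2 * f2 - 1.0 / t])

        neg1 = dmu1 < 0
        neg2 = dmu2 < 0
        step = 1.0
        if neg1.any():
            step = min(step, 0.99 * (-mu1[neg1] / dmu1[neg1]).min())
        if neg2.any():
            step = min(step, 0.99 * (-mu2[neg2] / dmu2[neg2]).min())
        res_norm = np.linalg.norm(residual)
        for _ls in range(20):
            new_v = v + step * dv
            new_mu1 = mu1 + step * dmu1
            new_mu2 = mu2 + step * dmu2
            new_f1 = new_v - lam
            new_f2 = -new_v - lam
            if max(new_f1.max(), new_f2.max()) < 0:
                new_DDTv = _ddt_mul(new_v)
                new_w = Dx - (new_mu1 - new_mu2)
                new_res = np.concatenate([
                    new_DDTv - new_w,
                    -new_mu1 * new_f1 - 1.0 / t,
                    -new_mu2 * new_f2 - 1.0 / t,
                ])
                if np.linalg.norm(new_res) <= (1 - alpha * step) * res_norm:
                    break
            step *= beta
        v, mu1, mu2, f1, f2 = new_v, new_mu1, new_mu2, new_f1, new_f2

    return x - Dt @ v


def degravitate(series: np.ndarray, lam: float, **solver_kwargs) -> np.ndarray:
    """Remove the slow gravitational trend: ``series - l1_trend_filter(series)``.

    The decomposition identity ``degravitate(x) + trend(x) == x`` holds
    exactly because the residual is computed by subtraction.
    """
    return np.asarray(series, dtype=float) - l1_trend_filter(series, lam, **solver_kwargs)


# --- session-level pipeline ------------------------------------------------

def segment_plan(
    protocol,
    removed_steps: frozenset[str] = DEFAULT_REMOVED_STEPS,
    split_long_recordings: bool = True,
) -> list[tuple[str, str]]:
    """Ordered (segment_name, task_category) list implied by the protocol."""
    plan: list[tuple[str, str]] = []
    for step in protocol:
        if step.name in removed_steps:
            continue
        if split_long_recordings and step.duration_s > 15.0:
            plan.append((f"{step.name}_1", step.category))
            plan.append((f"{step.name}_2", step.category))
        else:
            plan.append((step.name, step.category))
    return plan


def preprocess_session(
    session: AssessmentSession,
    config: PreprocessConfig,
    protocol,
) -> list[ProcessedSegment]:
    """Apply trim -> split -> length equalisation -> degravitation."""
    categories = {step.name: step.category for step in protocol}

    segments: list[ProcessedSegment] = []
    for rec in session.recordings:
        if rec.step_name in config.removed_steps:
            continue
        if rec.step_name not in categories:
            continue  # recording outside the analysis protocol
        trimmed = AssessmentRecording(
            rec.step_name, rec.wrist, rec.sensor,
            trim_onset(rec.samples, rec.fs, config.trim_seconds), rec.fs,
        )
        parts = split_long(trimmed) if config.split_long_recordings else [trimmed]
        for part in parts:
            segments.append(
                ProcessedSegment(
                    name=part.step_name,
                    category=categories[rec.step_name],
                    wrist=part.wrist,
                    sensor=part.sensor,
                    samples=part.samples,
                )
            )

    if not segments:
        return segments

    n_min = min(s.samples.shape[1] for s in segments)
    for s in segments:
        s.samples = s.samples[:, :n_min]

    if config.trend_lambda > 0:
        for s in segments:
            if s.sensor in config.apply_degravitation_to:
                s.samples = np.vstack(
                    [degravitate(axis, config.trend_lambda) for axis in s.samples]
                )
    return segments
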