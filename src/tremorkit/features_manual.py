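"""Manually engineered per-channel features (31 per channel).

Two blocks per single-axis channel:

* 19 spectral features — Welch power spectral density at a 1-Hz resolution
  (1-s Hann sub-windows, 50% overlap), keeping the 1..19 Hz bins and taking
  the logarithm of each (with a small additive floor for zero-power bins);
* 12 segment statistics — the channel is cut into four equal-length
  contiguous segments and each contributes its standard deviation, maximum
  absolute amplitude, and absolute energy (sum of squares).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal

from .feature_matrix import FeatureMatrix
from .session_io import ChannelTensor

__all__ = [
    "ManualFeatureConfig",
    "psd_features",
    "segment_features",
    "channel_features",
    "featurize_manual",
    "featurize_manual_cohort",
]


@dataclass
class ManualFeatureConfig:
    fs: float = 100.0
    freq_step: float = 1.0      # Hz; Welch resolution
    f_min: float = 1.0          # Hz; lowest retained bin (DC discarded)
    f_max: float = 19.0         # Hz; highest retained bin
    n_segments: int = 4
    log_floor: float = 1e-12
    energy: str = "squared"     # "squared" (sum x^2) or "abs" (sum |x|)

    def __post_init__(self) -> None:
        if self.f_min < self.freq_step:
            raise ValueError("f_min must be >= freq_step")
        if self.f_max >= self.fs / 2:
            raise ValueError("f_max must be below the Nyquist frequency")
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if self.energy not in ("squared", "abs"):
            raise ValueError("energy must be 'squared' or 'abs'")

    @property
    def n_psd_features(self) -> int:
        return int(round((self.f_max - self.f_min) / self.freq_step)) + 1

    @property
    def n_segment_features(self) -> int:
        return 3 * self.n_segments

    @property
    def n_features(self) -> int:
        return self.n_psd_features + self.n_segment_features


def psd_features(channel: np.ndarray, config: ManualFeatureConfig) -> np.ndarray:
    """Log-scaled Welch PSD at 1-Hz bins from f_min to f_max (19 values)."""
    x = np.asarray(channel, dtype=float)
    nperseg = int(round(config.fs / config.freq_step))
    if x.size < nperseg:
        raise ValueError(
            f"channel of {x.size} samples shorter than one Welch segment ({nperseg})"
        )
    freqs, power = scipy.signal.welch(
        x, fs=config.fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2,
        detrend=False, average="mean",
    )
    eps = config.freq_step / 4
    mask = (freqs >= config.f_min - eps) & (freqs <= config.f_max + eps)
    selected = power[mask]
    assert selected.size == config.n_psd_features
    return np.log(selected + config.log_floor)


def segment_features(channel: np.ndarray, config: ManualFeatureConfig) -> np.ndarray:
    """(std, max|x|, energy) for each of n_segments equal slices (12 values).

    Remainder samples that do not divide evenly are dropped from the tail so
    segments stay exactly equal in length.
    """
    x = np.asarray(channel, dtype=float)
    k = config.n_segments
    if x.size < k:
        raise ValueError(f"channel of {x.size} samples too short for {k} segments")
    seg_len = x.size // k
    segs = x[: seg_len * k].reshape(k, seg_len)
    std = segs.std(axis=1)
    amax = np.abs(segs).max(axis=1)
    if config.energy == "squared":
        energy = (segs ** 2).sum(axis=1)
    else:
        energy = np.abs(segs).sum(axis=1)
    return np.column_stack([std, amax, energy]).ravel()


def channel_features(channel: np.ndarray, config: ManualFeatureConfig) -> np.ndarray:
    """Concatenated spectral and segment features (31 values by default)."""
    return np.concatenate([psd_features(channel, config), segment_features(channel, config)])


def _feature_names(config: ManualFeatureConfig) -> list[str]:
    names = [
        f"psd_{config.f_min + i * config.freq_step:g}Hz"
        for i in range(config.n_psd_features)
    ]
    for s in range(config.n_segments):
        names += [f"seg{s + 1}_std", f"seg{s + 1}_maxabs", f"seg{s + 1}_energy"]
    return names


def _feature_row(tensor: ChannelTensor, config: ManualFeatureConfig) -> np.ndarray:
    rows = [channel_features(tensor.data[c], config) for c in range(tensor.n_channels)]
    return np.concatenate(rows) if rows else np.empty(0)


def featurize_manual(
    tensor: ChannelTensor, config: ManualFeatureConfig
) -> tuple[np.ndarray, pd.DataFrame]:
    """One subject's feature row (31 x n_channels) plus column annotations."""
    per_channel = _feature_names(config)
    values = _feature_row(tensor, config)
    columns = pd.DataFrame(
        {
            "name": [
                f"{tensor.labels[c]}|{fname}"
                for c in range(tensor.n_channels)
                for fname in per_channel
            ],
            "channel": [
                tensor.labels[c] for c in range(tensor.n_channels) for _ in per_channel
            ],
            "group": [
                tensor.categories[c] for c in range(tensor.n_channels) for _ in per_channel
            ],
            "sensor": [
                tensor.sensors[c] for c in range(tensor.n_channels) for _ in per_channel
            ],
        }
    )
    return values, columns


def featurize_manual_cohort(
    tensors: list[ChannelTensor], config: ManualFeatureConfig
) -> FeatureMatrix:
    """Stack per-subject manual feature rows into a FeatureMatrix."""
    if not tensors:
        raise ValueError("no channel tensors supplied")
    _, columns = featurize_manual(tensors[0], config)
    rows = [_feature_row(t, config) for t in tensors]
    return FeatureMatrix(np.vstack(rows), [t.subject_id for t in tensors], columns)
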