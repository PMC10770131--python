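"""Bag-of-SFA-Symbols (BOSS) multi-scale channel features.

Symbolic Fourier Approximation (SFA) slides a window over the series
(stride 1), optionally z-normalises each window, takes its DFT, and
quantises the first ``word_length`` low-frequency coefficient components
(real and imaginary parts interleaved) into ``alphabet_size`` symbols using
bin edges fitted on training data only.  BOSS then counts the resulting
words — with numerosity reduction, runs of consecutive identical words
count once — giving a histogram over the fixed vocabulary of
``alphabet_size ** word_length`` words.  The transform is applied per
channel at three window scales (20, 40, 80 samples by default) and all
histograms are concatenated channel-major, window-minor.

When windows are z-normalised the DC coefficient is constant (zero) and is
dropped; without normalisation it is kept, making the words offset-aware.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .feature_matrix import FeatureMatrix
from .session_io import ChannelTensor

__all__ = [
    "SFAConfig",
    "window_coefficients",
    "fit_sfa_bins",
    "sfa_transform",
    "boss_histogram",
    "BossFeaturizer",
    "DEFAULT_WINDOWS",
]

DEFAULT_WINDOWS = (20, 40, 80)


@dataclass(frozen=True)
class SFAConfig:
    window_length: int
    word_length: int = 4
    alphabet_size: int = 4
    normalize_windows: bool = True
    numerosity_reduction: bool = True
    binning: str = "equi-depth"  # or "equi-width"

    def __post_init__(self) -> None:
        if self.word_length > self.window_length:
            raise ValueError("word_length must not exceed window_length")
        if self.alphabet_size < 2:
            raise ValueError("alphabet_size must be >= 2")
        if self.binning not in ("equi-depth", "equi-width"):
            raise ValueError("binning must be 'equi-depth' or 'equi-width'")

    @property
    def vocabulary_size(self) -> int:
        return self.alphabet_size ** self.word_length


def window_coefficients(series: np.ndarray, config: SFAConfig) -> np.ndarray:
    """Per-window Fourier coefficient components, shape (n_windows, word_length).

    Components are [Re c_k0, Im c_k0, Re c_{k0+1}, ...] truncated to
    ``word_length``, with k0 = 1 when windows are z-normalised (DC dropped)
    and k0 = 0 otherwise.
    """
    x = np.asarray(series, dtype=float)
    L = config.window_length
    if x.size < L:
        raise ValueError(f"series of {x.size} samples shorter than window ({L})")
    windows = sliding_window_view(x, L).astype(float)
    if config.normalize_windows:
        mean = windows.mean(axis=1, keepdims=True)
        std = windows.std(axis=1, keepdims=True)
        windows = (windows - mean) / np.where(std < 1e-12, 1.0, std)
    coeffs = np.fft.rfft(windows, axis=1)
    k0 = 1 if config.normalize_windows else 0
    comps = np.empty((windows.shape[0], 2 * (coeffs.shape[1] - k0)))
    comps[:, 0::2] = coeffs[:, k0:].real
    comps[:, 1::2] = coeffs[:, k0:].imag
    return comps[:, : config.word_length]


def fit_sfa_bins(training_series: list[np.ndarray], config: SFAConfig) -> np.ndarray:
    """Fit per-position quantisation edges on training series only.

    Returns an array of shape (word_length, alphabet_size - 1) of interior
    bin edges.  Equi-depth uses empirical quantiles; equi-width splits the
    observed range evenly.
    """
    if not training_series:
        raise ValueError("no training series supplied")
    coeffs = np.vstack([window_coefficients(s, config) for s in training_series])
    a = config.alphabet_size
    if config.binning == "equi-depth":
        qs = np.linspace(0, 1, a + 1)[1:-1]
        return np.quantile(coeffs, qs, axis=0).T
    lo, hi = coeffs.min(axis=0), coeffs.max(axis=0)
    edges = np.linspace(lo, hi, a + 1, axis=-1)  # includes endpoints
    return edges[..., 1:-1]


def sfa_transform(series: np.ndarray, config: SFAConfig, fitted_bins: np.ndarray) -> np.ndarray:
    """Encode each sliding window as an integer word using fitted bins."""
    fitted_bins = np.asarray(fitted_bins, dtype=float)
    if fitted_bins.shape != (config.word_length, config.alphabet_size - 1):
        raise ValueError(
            f"fitted_bins must have shape {(config.word_length, config.alphabet_size - 1)}"
        )
    comps = window_coefficients(series, config)
    symbols = np.empty(comps.shape, dtype=np.int64)
    for j in range(config.word_length):
        # a value equal to an edge falls in the lower bin
        symbols[:, j] = np.searchsorted(fitted_bins[j], comps[:, j], side="left")
    powers = config.alphabet_size ** np.arange(config.word_length, dtype=np.int64)
    return symbols @ powers


def boss_histogram(words: np.ndarray, config: SFAConfig) -> np.ndarray:
    """Word-count vector over the full vocabulary (alphabet ** word_length)."""
    words = np.asarray(words, dtype=np.int64)
    if config.numerosity_reduction and words.size > 1:
        keep = np.concatenate([[True], words[1:] != words[:-1]])
        words = words[keep]
    return np.bincount(words, minlength=config.vocabulary_size)


class BossFeaturizer:
    """Per-channel, multi-scale BOSS transform with train-fold-only bin fitting.

    ``fit`` learns quantisation bins per (channel, window length) from the
    training subjects' channels; ``transform`` produces the concatenated
    histogram feature matrix.  Fitting and transforming are deterministic.
    """

    def __init__(
        self,
        windows: tuple[int, ...] = DEFAULT_WINDOWS,
        word_length: int = 4,
        alphabet_size: int = 4,
        normalize_windows: bool = True,
        numerosity_reduction: bool = True,
        binning: str = "equi-depth",
    ):
        self.windows = tuple(windows)
        self.base_config = SFAConfig(
            window_length=max(self.windows),
            word_length=word_length,
            alphabet_size=alphabet_size,
            normalize_windows=normalize_windows,
            numerosity_reduction=numerosity_reduction,
            binning=binning,
        )
        self.bins_: dict[tuple[int, int], np.ndarray] | None = None
        self.channel_labels_: list[str] | None = None

    def _config_for(self, window: int) -> SFAConfig:
        return replace(self.base_config, window_length=window)

    def fit(self, tensors: list[ChannelTensor]) -> "BossFeaturizer":
        if not tensors:
            raise ValueError("no training tensors supplied")
        ref = tensors[0]
        self.channel_labels_ = list(ref.labels)
        self.channel_categories_ = list(ref.categories)
        self.channel_sensors_ = list(ref.sensors)
        self.bins_ = {}
        for c in range(ref.n_channels):
            series = [t.data[c] for t in tensors]
            for w in self.windows:
                cfg = self._config_for(w)
                self.bins_[(c, w)] = fit_sfa_bins(series, cfg)
        return self

    def transform(self, tensors: list[ChannelTensor]) -> FeatureMatrix:
        if self.bins_ is None:
            raise RuntimeError("BossFeaturizer must be fitted before transform")
        n_channels = len(self.channel_labels_)
        vocab = self.base_config.vocabulary_size
        rows = np.zeros((len(tensors), n_channels * len(self.windows) * vocab))
        for i, tensor in enumerate(tensors):
            if tensor.n_channels != n_channels:
                raise ValueError("tensor channel count differs from fitted layout")
            col = 0
            for c in range(n_channels):
                for w in self.windows:
                    cfg = self._config_for(w)
                    words = sfa_transform(tensor.data[c], cfg, self.bins_[(c, w)])
                    rows[i, col:col + vocab] = boss_histogram(words, cfg)
                    col += vocab
        names, channels, groups, sensors = [], [], [], []
        for c in range(n_channels):
            for w in self.windows:
                for v in range(vocab):
                    names.append(f"{self.channel_labels_[c]}|boss_w{w}_word{v}")
                    channels.append(self.channel_labels_[c])
                    groups.append(self.channel_categories_[c])
                    sensors.append(self.channel_sensors_[c])
        columns = pd.DataFrame(
            {"name": names, "channel": channels, "group": groups, "sensor": sensors}
        )
        return FeatureMatrix(rows, [t.subject_id for t in tensors], columns)

    def fit_transform(self, tensors: list[ChannelTensor]) -> FeatureMatrix:
        return self.fit(tensors).transform(tensors)
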