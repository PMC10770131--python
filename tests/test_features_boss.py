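"""SFA word extraction and BOSS histograms against a brute-force oracle."""

import numpy as np
import pytest

from tremorkit.features_boss import (
    BossFeaturizer,
    SFAConfig,
    boss_histogram,
    fit_sfa_bins,
    sfa_transform,
    window_coefficients,
)
from tremorkit.session_io import ChannelTensor


def brute_force_sfa(series, training, window, word, alphabet, normalize, equi_depth=True):
    """Independent SFA: explicit DFT sums and explicit threshold comparisons."""
    def coeffs_of(x):
        out = []
        for start in range(len(x) - window + 1):
            w = np.array(x[start:start + window], dtype=float)
            if normalize:
                mu, sd = w.mean(), w.std()
                w = (w - mu) / (sd if sd >= 1e-12 else 1.0)
            comps = []
            k0 = 1 if normalize else 0
            k = k0
            while len(comps) < word:
                re = sum(w[t] * np.cos(-2 * np.pi * k * t / window) for t in range(window))
                im = sum(w[t] * np.sin(-2 * np.pi * k * t / window) for t in range(window))
                comps.extend([re, im])
                k += 1
            out.append(comps[:word])
        return out

    train_coeffs = [c for x in training for c in coeffs_of(x)]
    edges = []
    for j in range(word):
        vals = sorted(c[j] for c in train_coeffs)
        if equi_depth:
            qs = [np.quantile(vals, q) for q in np.linspace(0, 1, alphabet + 1)[1:-1]]
        else:
            lo, hi = min(vals), max(vals)
            qs = [lo + (hi - lo) * i / alphabet for i in range(1, alphabet)]
        edges.append(qs)

    words = []
    for comps in coeffs_of(series):
        value = 0
        for j in range(word):
            symbol = sum(1 for e in edges[j] if comps[j] > e)
            value += symbol * alphabet ** j
        words.append(value)
    return words


class TestSfaTransform:
    def test_sliding_window_count(self):
        cfg = SFAConfig(window_length=20)
        x = np.random.default_rng(0).normal(size=100)
        bins = fit_sfa_bins([x], cfg)
        assert sfa_transform(x, cfg, bins).shape == (81,)

    def test_constant_series_gives_identical_words(self):
        cfg = SFAConfig(window_length=8, word_length=2, alphabet_size=2)
        x = np.full(32, 3.14)
        bins = fit_sfa_bins([x], cfg)
        words = sfa_transform(x, cfg, bins)
        assert np.unique(words).size == 1

    @pytest.mark.parametrize("normalize", [True, False])
    @pytest.mark.parametrize("binning", ["equi-depth", "equi-width"])
    def test_matches_brute_force_oracle_on_toys(self, normalize, binning):
        rng = np.random.default_rng(17)
        cfg = SFAConfig(window_length=8, word_length=2, alphabet_size=2,
                        normalize_windows=normalize, binning=binning)
        for _ in range(10):
            train = [rng.normal(size=16), rng.normal(size=16)]
            x = rng.normal(size=16)
            bins = fit_sfa_bins(train, cfg)
            got = sfa_transform(x, cfg, bins)
            expected = brute_force_sfa(
                x, train, 8, 2, 2, normalize, equi_depth=(binning == "equi-depth")
            )
            assert got.tolist() == expected

    def test_window_longer_than_series_rejected(self):
        cfg = SFAConfig(window_length=64)
        with pytest.raises(ValueError, match="shorter"):
            window_coefficients(np.zeros(32), cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SFAConfig(window_length=4, word_length=8)
        with pytest.raises(ValueError):
            SFAConfig(window_length=8, alphabet_size=1)


class TestBossHistogram:
    def test_run_length_collapse(self):
        cfg = SFAConfig(window_length=8, word_length=2, alphabet_size=2)
        # words [A, A, B, A] -> {A: 2, B: 1} under numerosity reduction
        hist = boss_histogram(np.array([0, 0, 1, 0]), cfg)
        assert hist[0] == 2 and hist[1] == 1

    def test_constant_series_reduction_on_and_off(self):
        x = np.full(32, 1.0)
        cfg_on = SFAConfig(window_length=8, word_length=2, alphabet_size=2)
        cfg_off = SFAConfig(window_length=8, word_length=2, alphabet_size=2,
                            numerosity_reduction=False)
        bins = fit_sfa_bins([x], cfg_on)
        words = sfa_transform(x, cfg_on, bins)
        assert boss_histogram(words, cfg_on).sum() == 1
        assert boss_histogram(words, cfg_off).sum() == 25  # all windows counted

    def test_totals_bounded_by_window_count(self):
        rng = np.random.default_rng(3)
        cfg = SFAConfig(window_length=10, word_length=4, alphabet_size=4)
        x = rng.normal(size=200)
        hist = boss_histogram(sfa_transform(x, cfg, fit_sfa_bins([x], cfg)), cfg)
        assert hist.sum() <= 200 - 10 + 1
        assert (hist >= 0).all()


def _tensors(data, n_subjects=1):
    rng = np.random.default_rng(0)
    out = []
    for s in range(n_subjects):
        arr = data if s == 0 else rng.normal(size=data.shape)
        out.append(ChannelTensor(
            f"s{s}", arr, [f"ch{i}" for i in range(arr.shape[0])],
            ["Resting"] * arr.shape[0], ["acceleration"] * arr.shape[0],
        ))
    return out


class TestBossFeaturizer:
    def test_row_length_per_channel_and_scale(self):
        data = np.random.default_rng(1).normal(size=(1, 200))
        fm = BossFeaturizer(windows=(20, 40, 80)).fit_transform(_tensors(data))
        assert fm.values.shape == (1, 3 * 256)  # vocabulary 4^4 per scale

    def test_identical_channels_give_identical_blocks(self):
        rng = np.random.default_rng(2)
        row = rng.normal(size=200)
        data = np.vstack([row, row])
        fm = BossFeaturizer(windows=(20,)).fit_transform(_tensors(data))
        assert np.array_equal(fm.values[0, :256], fm.values[0, 256:])

    def test_period_shift_leaves_histogram_unchanged(self):
        period = 20
        x = np.tile(np.sin(2 * np.pi * np.arange(period) / period), 10)
        shifted = np.roll(x, period)
        cfg = SFAConfig(window_length=20)
        bins = fit_sfa_bins([x], cfg)
        h1 = boss_histogram(sfa_transform(x, cfg, bins), cfg)
        h2 = boss_histogram(sfa_transform(shifted, cfg, bins), cfg)
        assert np.array_equal(h1, h2)

    def test_fitted_bins_deterministic_and_fold_sensitive(self):
        rng = np.random.default_rng(4)
        fold_a = [rng.normal(size=200) for _ in range(5)]
        fold_b = [rng.normal(2.0, 3.0, size=200) for _ in range(5)]
        cfg = SFAConfig(window_length=20, normalize_windows=False)
        bins_a1 = fit_sfa_bins(fold_a, cfg)
        bins_a2 = fit_sfa_bins(fold_a, cfg)
        bins_b = fit_sfa_bins(fold_b, cfg)
        assert np.array_equal(bins_a1, bins_a2)   # refitting is deterministic
        assert not np.allclose(bins_a1, bins_b)   # disjoint fold changes bins

    def test_transform_requires_fit(self):
        with pytest.raises(RuntimeError, match="fitted"):
            BossFeaturizer().transform(_tensors(np.zeros((1, 100))))
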