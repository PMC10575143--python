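"""Shared helpers for the test suite."""

from __future__ import annotations

import numpy as np

from vmdseiz import FeatureMatrix


def subset_channels(fm: FeatureMatrix, channels: list[int]) -> FeatureMatrix:
    """FeatureMatrix restricted to the given channels, re-indexed 0..len-1."""
    cols: list[int] = []
    index: list[tuple[int, int, str]] = []
    for new_ch, ch in enumerate(channels):
        for j in fm.channel_groups[ch]:
            cols.append(j)
            _, mode, name = fm.feature_index[j]
            index.append((new_ch, mode, name))
    groups: dict[int, list[int]] = {}
    for j, (ch, _, _) in enumerate(index):
        groups.setdefault(ch, []).append(j)
    return FeatureMatrix(
        values=fm.values[:, cols],
        feature_index=index,
        labels=fm.labels.copy(),
        channel_groups=groups,
    )


def fft_peak_hz(x: np.ndarray, fs: float) -> float:
    """Frequency of the largest FFT magnitude (DC excluded)."""
    spec = np.abs(np.fft.rfft(x))
    spec[0] = 0.0
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    return float(freqs[np.argmax(spec)])


def fft_amplitude_at(x: np.ndarray, fs: float, f0: float) -> float:
    """Single-bin amplitude estimate at f0 (assumes f0 on the FFT grid)."""
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    k = int(np.argmin(np.abs(freqs - f0)))
    return 2.0 * np.abs(np.fft.rfft(x)[k]) / x.size
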