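"""Synthetic test signals: tone mixtures, known-fractal-dimension series, and
labeled pseudo-EEG datasets with planted informative channels.

The dataset generator emulates the study layout this package targets: 2-s
epochs at 256 Hz, equal interictal/ictal counts, and a small subset of
channels carrying class signal. Interictal background is 1/f-shaped noise
with a 10 Hz alpha rhythm. On informative channels, ictal epochs replace part
of that background with a 3 Hz spike-and-wave train (hypersynchronous, hence
lower differential entropy across bands) plus broadband high-frequency noise
(hence higher Higuchi fractal dimension). Non-informative channels are drawn
from the same distribution in both classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import Epoch, ParameterError


@dataclass
class SyntheticSpec:
    """Dataset recipe; identical spec + seed gives bit-identical output."""

    n_channels: int = 8
    informative_channels: tuple[int, ...] = (0, 2, 3, 5, 6)
    fs: float = 256.0
    window_s: float = 2.0
    n_epochs_per_class: int = 100
    ictal_effect: float = 3.0  # spike-wave amplitude gain over background sd
    spike_rate_hz: float = 3.0
    noise_sd: float = 2.0  # broadband sensor noise, uV
    background_sd: float = 20.0  # 1/f background, uV
    seed: int = 0

    def __post_init__(self) -> None:
        self.informative_channels = tuple(sorted(set(self.informative_channels)))
        if any(c < 0 or c >= self.n_channels for c in self.informative_channels):
            raise ParameterError("informative_channels outside 0..n_channels-1")
        if self.n_epochs_per_class <= 0:
            raise ParameterError("n_epochs_per_class must be positive")
        if self.fs <= 0 or self.window_s <= 0:
            raise ParameterError("fs and window_s must be positive")


def make_tone_mixture(
    freqs: list[float],
    amps: list[float],
    fs: float,
    duration_s: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Sum of cosines plus white Gaussian noise; the standard VMD fixture."""
    if len(freqs) != len(amps):
        raise ParameterError("freqs and amps must have equal length")
    nyq = fs / 2.0
    for f in freqs:
        if f >= nyq:
            raise ParameterError(f"tone at {f} Hz >= Nyquist {nyq} Hz")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    for f, a in zip(freqs, amps):
        x += a * np.cos(2 * np.pi * f * t)
    if noise_sd > 0:
        x += np.random.default_rng(seed).normal(0.0, noise_sd, n)
    return x


def _fgn_davies_harte(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Exact fractional Gaussian noise via circulant embedding."""
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * (
        np.abs(k + 1) ** (2 * hurst)
        - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k - 1) ** (2 * hurst)
    )
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # circulant first row, len 2n
    eig = np.fft.fft(row).real
    eig = np.clip(eig, 0.0, None)  # tiny negatives from round-off
    m = 2 * n
    w = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    z = np.fft.fft(np.sqrt(eig / (2 * m)) * w)
    return z.real[:n]


def make_fd_series(
    kind: str, n: int, hurst: float | None = None, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Series with known theoretical Higuchi fractal dimension.

    kind="line" gives a straight line (FD 1), "white_noise" Gaussian white
    noise (FD 2), "fbm" fractional Brownian motion with Hurst exponent H
    (FD 2 - H, synthesized as the cumulative sum of exact Davies-Harte
    fractional Gaussian noise). Returns ``(series, fd_true)``.
    """
    if n < 128:
        raise ParameterError("n must be >= 128")
    rng = np.random.default_rng(seed)
    if kind == "line":
        slope = rng.uniform(0.5, 2.0)
        return rng.uniform(-1, 1) + slope * np.arange(n) / n, 1.0
    if kind == "white_noise":
        return rng.standard_normal(n), 2.0
    if kind == "fbm":
        if hurst is None or not 0 < hurst < 1:
            raise ParameterError("fbm requires 0 < hurst < 1")
        return np.cumsum(_fgn_davies_harte(n, hurst, rng)), 2.0 - hurst
    raise ParameterError(f"unknown series kind {kind!r}")


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-shaped noise (spectral slope -1 in power)."""
    freqs = np.fft.rfftfreq(n)
    shape = np.zeros_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = shape * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _spike_wave_train(
    n: int, fs: float, rate_hz: float, rng: np.random.Generator
) -> np.ndarray:
    """Periodic biphasic spike (~50 ms) followed by a half-sine slow wave,
    unit peak amplitude, random phase per call."""
    period = int(round(fs / rate_hz))
    t_spike = np.arange(int(round(0.05 * fs))) / fs  # 50 ms sharp transient
    spike = np.sin(2 * np.pi * t_spike / 0.05) * np.exp(-((t_spike - 0.015) ** 2) / (2 * 0.008**2))
    n_slow = int(round(0.18 * fs))  # 180 ms slow wave
    slow = 0.6 * np.sin(np.pi * np.arange(n_slow) / n_slow)
    template = np.zeros(period)
    template[: spike.size] = spike / np.abs(spike).max()
    stop = min(period, spike.size + n_slow)
    template[spike.size : stop] += slow[: stop - spike.size]
    reps = int(np.ceil(n / period)) + 1
    train = np.tile(template, reps)
    phase = rng.integers(0, period)
    return train[phase : phase + n]


def _interictal_channel(n: int, fs: float, spec: SyntheticSpec,
                        rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / fs
    x = spec.background_sd * _pink_noise(n, rng)
    x += 0.5 * spec.background_sd * np.sin(
        2 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi)
    )
    x += rng.normal(0.0, spec.noise_sd, n)
    return x


def _ictal_channel(n: int, fs: float, spec: SyntheticSpec,
                   rng: np.random.Generator) -> np.ndarray:
    # hypersynchronous discharge: desynchronized background largely
    # suppressed (lower band power, hence lower DE), rhythmic spike-wave
    # dominant, extra broadband roughness (higher HFD)
    x = 0.2 * spec.background_sd * _pink_noise(n, rng)
    x += (spec.ictal_effect * spec.background_sd / 3.0) * _spike_wave_train(
        n, fs, spec.spike_rate_hz, rng
    )
    x += rng.normal(0.0, spec.noise_sd, n)
    x += rng.normal(0.0, 4.0 * spec.noise_sd, n)  # broadband high-frequency
    return x


def make_dataset(spec: SyntheticSpec) -> tuple[list[Epoch], set[int]]:
    """Generate ``2 * n_epochs_per_class`` labeled epochs.

    Returns the epoch list (interictal first, then ictal) and the planted
    ground-truth set of informative channel indices.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.window_s * spec.fs))
    informative = set(spec.informative_channels)
    epochs: list[Epoch] = []
    idx = 0
    for label in (0, 1):
        for _ in range(spec.n_epochs_per_class):
            data = np.empty((spec.n_channels, n))
            for ch in range(spec.n_channels):
                if label == 1 and ch in informative:
                    data[ch] = _ictal_channel(n, spec.fs, spec, rng)
                else:
                    data[ch] = _interictal_channel(n, spec.fs, spec, rng)
            epochs.append(
                Epoch(data=data, label=label, source_id="synthetic", index=idx)
            )
            idx += 1
    return epochs, informative
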