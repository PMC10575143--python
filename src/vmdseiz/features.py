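"""Differential entropy and Higuchi fractal dimension of VMD modes.

Each 2-s epoch is decomposed channel-by-channel into K modes; every mode
contributes one differential-entropy (DE) and one Higuchi-fractal-dimension
(HFD) value, giving 2K features per channel. DE treats the band-limited
signal as Gaussian, so per band it reduces to 0.5*ln(2*pi*e*var_band) with
the band variance estimated from a short-time periodogram (1-s non-overlapping
Hamming windows) and averaged across the five canonical EEG bands. HFD
measures roughness on a 1 (smooth) .. 2 (space-filling) scale from the
log-log slope of delay-decimated curve lengths.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signal_io import Epoch, ParameterError
from .vmd import VMDParams, vmd_decompose

logger = logging.getLogger(__name__)

#: canonical EEG rhythm bands (Hz)
DEFAULT_BANDS: list[tuple[str, float, float]] = [
    ("delta", 1.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("beta", 13.0, 30.0),
    ("gamma", 30.0, 50.0),
]


@dataclass
class BandSet:
    """Ordered, non-overlapping frequency bands for DE averaging."""

    bands: list[tuple[str, float, float]] = field(
        default_factory=lambda: list(DEFAULT_BANDS)
    )

    def __post_init__(self) -> None:
        prev_high = 0.0
        for name, low, high in self.bands:
            if not 0 < low < high:
                raise ParameterError(f"band {name}: need 0 < low < high")
            if low < prev_high:
                raise ParameterError(f"band {name} overlaps its predecessor")
            prev_high = high


@dataclass
class HiguchiParams:
    """k_max is the largest decimation delay; fit_range optionally restricts
    the delays entering the log-log fit (default: all of 1..k_max)."""

    k_max: int = 8
    fit_range: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.k_max < 2:
            raise ParameterError("k_max must be >= 2")


@dataclass
class FeatureMatrix:
    """Epochs x features, channel-major / mode-minor / DE-before-HFD columns.

    ``feature_index`` holds (channel, mode, name) triples aligned with the
    columns of ``values``; ``channel_groups`` maps each channel index to its
    column indices so channel-subset selection can slice consistently.
    """

    values: np.ndarray
    feature_index: list[tuple[int, int, str]]
    labels: np.ndarray
    channel_groups: dict[int, list[int]]

    @property
    def n_channels(self) -> int:
        return len(self.channel_groups)

    def select_channels(self, mask: np.ndarray) -> np.ndarray:
        """Column submatrix for channels where ``mask`` is truthy."""
        mask = np.asarray(mask)
        if mask.size != self.n_channels:
            raise ParameterError(
                f"mask length {mask.size} != channel count {self.n_channels}"
            )
        cols: list[int] = []
        for ch in sorted(self.channel_groups):
            if mask[ch]:
                cols.extend(self.channel_groups[ch])
        return self.values[:, cols]

    def to_dataframe(self):
        import pandas as pd

        names = [f"ch{c}_m{m}_{f.lower()}" for c, m, f in self.feature_index]
        df = pd.DataFrame(self.values, columns=names)
        df["label"] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        import pandas as pd

        df = pd.read_csv(path)
        labels = df.pop("label").to_numpy(dtype=int)
        index: list[tuple[int, int, str]] = []
        for col in df.columns:
            ch_part, m_part, feat = col.split("_")
            index.append((int(ch_part[2:]), int(m_part[1:]), feat.upper()))
        groups: dict[int, list[int]] = {}
        for j, (ch, _, _) in enumerate(index):
            groups.setdefault(ch, []).append(j)
        return cls(
            values=df.to_numpy(dtype=float),
            feature_index=index,
            labels=labels,
            channel_groups=groups,
        )


def band_differential_entropy(
    series: np.ndarray, fs: float, bands: BandSet | None = None
) -> dict[str, float]:
    """Per-band DE in nats from 1-s non-overlapping Hamming windows.

    The band variance is the periodogram power integrated over the band
    (half-open [low, high) in Hz), pooled (averaged) across windows before
    the logarithm: pooling first keeps the estimator close to the Gaussian
    closed form 0.5*ln(2*pi*e*var) even for narrow bands, where taking the
    log per window first would bias DE low by psi(k) - ln(k) for k bins. A
    band with zero estimated power is omitted with a logged warning.
    """
    if bands is None:
        bands = BandSet()
    x = np.asarray(series, dtype=float).ravel()
    win = int(round(fs))
    if x.size < win:
        raise ParameterError(f"need at least one 1-s window ({win} samples)")
    n_win = x.size // win
    freqs = np.fft.rfftfreq(win, d=1.0 / fs)
    psd = np.empty((n_win, freqs.size))
    for w in range(n_win):
        f, p = sps.periodogram(x[w * win : (w + 1) * win], fs=fs, window="hamming")
        psd[w] = p
    df = fs / win
    out: dict[str, float] = {}
    for name, low, high in bands.bands:
        sel = (freqs >= low) & (freqs < high)
        var = float(np.mean(psd[:, sel].sum(axis=1) * df))  # pooled band variance
        if var <= 0:
            logger.warning("band %s silent; skipped in DE", name)
            continue
        out[name] = float(0.5 * np.log(2 * np.pi * np.e * var))
    if not out:
        raise ParameterError("all bands silent; DE undefined")
    return out


def differential_entropy(
    series: np.ndarray, fs: float, bands: BandSet | None = None
) -> float:
    """DE in nats: mean of the per-band values of
    :func:`band_differential_entropy`."""
    per_band = band_differential_entropy(series, fs, bands)
    return float(np.mean(list(per_band.values())))


def higuchi_fd(series: np.ndarray, params: HiguchiParams | None = None) -> float:
    """Higuchi fractal dimension from the log-log curve-length slope.

    For each delay z the z decimated subsequences' normalized curve lengths
    are averaged into L(z); FD is minus the least-squares slope of ln L(z)
    against ln z. The result is clamped into [1, 2] (a warning is emitted if
    it falls outside by more than 0.05).
    """
    if params is None:
        params = HiguchiParams()
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    if n < 4 * params.k_max:
        raise ParameterError(f"series length {n} < 4*k_max = {4 * params.k_max}")
    ks = (
        np.asarray(params.fit_range, dtype=int)
        if params.fit_range is not None
        else np.arange(1, params.k_max + 1)
    )
    lengths = np.empty(ks.size)
    for j, z in enumerate(ks):
        lw = np.empty(z)
        for w in range(z):
            idx = np.arange(w, n, z)
            m = idx.size - 1  # int((n - 1 - w) / z)
            if m < 1:
                lw[w] = np.nan
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            lw[w] = dist * (n - 1) / (m * z) / z
        lengths[j] = np.nanmean(lw)
    if np.any(lengths <= 0):
        raise ParameterError("zero curve length (constant series?)")
    slope = np.polyfit(np.log(ks.astype(float)), np.log(lengths), 1)[0]
    fd = -slope
    if fd < 1.0 - 0.05 or fd > 2.0 + 0.05:
        warnings.warn(f"Higuchi FD {fd:.3f} outside [1, 2]; clamping", stacklevel=2)
    return float(np.clip(fd, 1.0, 2.0))


def extract_features(
    epochs: list[Epoch],
    fs: float,
    vmd_params: VMDParams | None = None,
    bands: BandSet | None = None,
    higuchi: HiguchiParams | None = None,
    de_source: str = "vmf",
) -> FeatureMatrix:
    """Assemble the epochs x (channels x K x {DE, HFD}) feature matrix.

    Per epoch and channel: VMD into K modes (sorted by center frequency),
    then DE and HFD of each mode. ``de_source="raw"`` computes DE on the raw
    channel instead of each mode (the per-mode HFD is unaffected). Column
    order is channel-major, mode-minor, DE before HFD, and is deterministic.
    """
    if vmd_params is None:
        vmd_params = VMDParams()
    if bands is None:
        bands = BandSet()
    if higuchi is None:
        higuchi = HiguchiParams()
    if de_source not in ("vmf", "raw"):
        raise ParameterError(f"de_source must be 'vmf' or 'raw', got {de_source!r}")
    if not epochs:
        raise ParameterError("no epochs given")
    n_ch = epochs[0].data.shape[0]
    if any(ep.data.shape[0] != n_ch for ep in epochs):
        raise ParameterError("epochs have differing channel counts")
    K = vmd_params.K
    index = [
        (ch, m, feat)
        for ch in range(n_ch)
        for m in range(K)
        for feat in ("DE", "HFD")
    ]
    values = np.empty((len(epochs), len(index)))
    labels = np.empty(len(epochs), dtype=int)
    for i, ep in enumerate(epochs):
        labels[i] = ep.label
        col = 0
        for ch in range(n_ch):
            try:
                res = vmd_decompose(ep.data[ch], fs, vmd_params)
                if de_source == "raw":
                    de_raw = differential_entropy(ep.data[ch], fs, bands)
                for m in range(K):
                    de = (
                        de_raw
                        if de_source == "raw"
                        else differential_entropy(res.modes[m], fs, bands)
                    )
                    values[i, col] = de
                    values[i, col + 1] = higuchi_fd(res.modes[m], higuchi)
                    col += 2
            except Exception as exc:
                raise RuntimeError(
                    f"feature extraction failed at epoch {i}, channel {ch}: {exc}"
                ) from exc
    groups: dict[int, list[int]] = {}
    for j, (ch, _, _) in enumerate(index):
        groups.setdefault(ch, []).append(j)
    return FeatureMatrix(
        values=values, feature_index=index, labels=labels, channel_groups=groups
    )
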