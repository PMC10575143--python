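"""EDF input, preprocessing, and epoch segmentation.

Recordings are held as channels x samples matrices in microvolts. Epochs are
fixed-length non-overlapping windows cut from annotated intervals; a window
that straddles an interval boundary is discarded, so every epoch carries a
single unambiguous class label (0 = interictal, 1 = ictal).
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps


class ParameterError(ValueError):
    """Invalid user-supplied parameter."""


@dataclass
class EEGRecording:
    """Multichannel EEG time series.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Amplitudes in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        One unique label per row of ``data``.
    start_time : float
        Offset of the first sample in seconds (default 0).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ParameterError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ParameterError("sampling rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ParameterError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ParameterError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class AnnotationTable:
    """Labeled time intervals, half-open ``[start_s, end_s)`` in seconds.

    Label 0 marks interictal (healthy-period) spans, label 1 ictal (seizure)
    spans. Ictal intervals must not overlap one another.
    """

    intervals: list[tuple[float, float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for start, end, label in self.intervals:
            if not start < end:
                raise ParameterError(f"interval ({start}, {end}) has start >= end")
            if label not in (0, 1):
                raise ParameterError(f"label must be 0 or 1, got {label}")
        ictal = sorted((s, e) for s, e, lab in self.intervals if lab == 1)
        for (s1, e1), (s2, e2) in zip(ictal, ictal[1:]):
            if s2 < e1:
                raise ParameterError(
                    f"ictal intervals ({s1}, {e1}) and ({s2}, {e2}) overlap"
                )

    @classmethod
    def from_csv(cls, path: str | Path) -> "AnnotationTable":
        """Read a ``start_s,end_s,label`` CSV."""
        df = pd.read_csv(path)
        required = {"start_s", "end_s", "label"}
        if not required.issubset(df.columns):
            raise ParameterError(
                f"annotation CSV must have columns {sorted(required)}, "
                f"got {list(df.columns)}"
            )
        return cls(
            [
                (float(r.start_s), float(r.end_s), int(r.label))
                for r in df.itertuples()
            ]
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.intervals, columns=["start_s", "end_s", "label"]).to_csv(
            path, index=False
        )


@dataclass
class Epoch:
    """One labeled fixed-length window, channels x samples in microvolts."""

    data: np.ndarray
    label: int
    source_id: str = ""
    index: int = 0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.label not in (0, 1):
            raise ParameterError(f"epoch label must be 0 or 1, got {self.label}")


def read_edf(path: str | Path) -> EEGRecording:
    """Read all signal channels of an EDF file at native rate.

    Amplitudes are returned in microvolts as declared by the EDF physical
    dimension fields. Files whose signals are stored at differing sampling
    rates are rejected with an error naming the offending channels.
    """
    import mne

    path = Path(path)
    if not path.is_file():
        raise OSError(f"EDF file not found: {path}")
    _check_uniform_rate(path)
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on corrupt files
        raise OSError(f"could not read EDF file {path}: {exc}") from exc
    data_uv = raw.get_data() * 1e6  # mne holds EEG in volts
    return EEGRecording(
        data=data_uv,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
    )


def _check_uniform_rate(path: Path) -> None:
    # The per-signal sample counts live in the EDF signal header; mne silently
    # resamples mixed-rate files, so the rate check reads the header directly.
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise OSError(f"truncated EDF header in {path}")
        try:
            ns = int(header[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise OSError(f"invalid EDF header in {path}") from exc
        sig_header = fh.read(ns * 256)
        if len(sig_header) < ns * 256:
            raise OSError(f"truncated EDF signal header in {path}")
    labels = [
        sig_header[16 * i : 16 * (i + 1)].decode("ascii", "replace").strip()
        for i in range(ns)
    ]
    offset = ns * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    counts = [
        int(sig_header[offset + 8 * i : offset + 8 * (i + 1)].decode("ascii").strip())
        for i in range(ns)
    ]
    if len(set(counts)) > 1:
        per = ", ".join(f"{lab}={c}" for lab, c in zip(labels, counts))
        raise OSError(
            f"EDF channels have differing sampling rates (samples/record: {per})"
        )


def preprocess(
    rec: EEGRecording,
    band: tuple[float, float] = (1.0, 60.0),
    notch_hz: float | None = 60.0,
) -> EEGRecording:
    """Zero-phase band-pass (4th-order Butterworth, forward-backward) plus an
    optional power-line notch, applied per channel.

    The default 1-60 Hz band keeps the clinically informative EEG range; the
    notch defaults to 60 Hz (US mains) and should be set to 50 Hz for
    recordings from 50 Hz grids, or None to disable.
    """
    low, high = band
    nyq = rec.fs / 2.0
    if not (0 < low < high < nyq):
        raise ParameterError(
            f"band ({low}, {high}) must satisfy 0 < low < high < fs/2 = {nyq}"
        )
    sos = sps.butter(4, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    out = sps.sosfiltfilt(sos, rec.data, axis=1)
    if notch_hz is not None:
        if not 0 < notch_hz < nyq:
            raise ParameterError(f"notch frequency {notch_hz} outside (0, fs/2)")
        b, a = sps.iirnotch(notch_hz, Q=30.0, fs=rec.fs)
        out = sps.filtfilt(b, a, out, axis=1)
    return EEGRecording(
        data=out,
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        start_time=rec.start_time,
    )


def segment(
    rec: EEGRecording,
    ann: AnnotationTable,
    window_s: float = 2.0,
    source_id: str = "",
) -> list[Epoch]:
    """Cut non-overlapping ``window_s`` windows from each annotated interval.

    Windows are left-aligned to the interval start; only windows lying fully
    inside an interval are kept, labeled by that interval. An empty annotation
    table yields an empty list.
    """
    n_win = window_s * rec.fs
    if abs(n_win - round(n_win)) > 1e-9:
        raise ParameterError(
            f"window_s * fs = {n_win} must be an integral sample count"
        )
    n_win = int(round(n_win))
    epochs: list[Epoch] = []
    idx = 0
    for start_s, end_s, label in ann.intervals:
        first = int(round((start_s - rec.start_time) * rec.fs))
        last = int(round((end_s - rec.start_time) * rec.fs))
        first = max(first, 0)
        last = min(last, rec.n_samples)
        pos = first
        while pos + n_win <= last:
            epochs.append(
                Epoch(
                    data=rec.data[:, pos : pos + n_win].copy(),
                    label=label,
                    source_id=source_id,
                    index=idx,
                )
            )
            idx += 1
            pos += n_win
    return epochs


def save_epochs(epochs: list[Epoch], path: str | Path, fs: float) -> None:
    """Write epochs to a single ``.npz`` archive with a JSON sidecar inside
    (source ids, labels, sampling rate)."""
    if not epochs:
        raise ParameterError("cannot save an empty epoch list")
    path = Path(path)
    stack = np.stack([ep.data for ep in epochs])
    meta = {
        "fs": fs,
        "labels": [int(ep.label) for ep in epochs],
        "source_ids": [ep.source_id for ep in epochs],
        "indices": [int(ep.index) for ep in epochs],
    }
    buf = io.BytesIO()
    np.lib.format.write_array(buf, stack)
    # fixed zip timestamps so identical inputs give byte-identical archives
    epoch0 = (1980, 1, 1, 0, 0, 0)
    with zipfile.ZipFile(path, "w") as zf:
        for name, payload in (
            ("data.npy", buf.getvalue()),
            ("meta.json", json.dumps(meta, sort_keys=True)),
        ):
            info = zipfile.ZipInfo(name, date_time=epoch0)
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, payload)


def load_epochs(path: str | Path) -> tuple[list[Epoch], float]:
    """Inverse of :func:`save_epochs`; returns (epochs, fs)."""
    path = Path(path)
    with np.load(path) as npz:
        stack = npz["data"]
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
    epochs = [
        Epoch(
            data=stack[i],
            label=int(meta["labels"][i]),
            source_id=meta["source_ids"][i],
            index=int(meta["indices"][i]),
        )
        for i in range(stack.shape[0])
    ]
    return epochs, float(meta["fs"])
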