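"""Minimal EDF writer used to create test fixtures programmatically.

Writes a standards-conformant EDF file (ASCII header, int16 little-endian
data records) with 1-second data records. Only what the tests need: no
annotations channel, no EDF+ extensions.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def _field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    path: str | Path,
    data_uv: np.ndarray,
    fs: int,
    labels: list[str] | None = None,
    samples_per_record: list[int] | None = None,
) -> None:
    """Write channels x samples microvolt data at integer rate ``fs``.

    ``samples_per_record`` overrides the per-channel samples-per-record
    header fields (default: ``fs`` for every channel); passing differing
    values creates a mixed-rate file for error-path tests, with every
    channel's data stream simply truncated/padded to fit.
    """
    data_uv = np.atleast_2d(np.asarray(data_uv, dtype=float))
    n_ch, n_samp = data_uv.shape
    if labels is None:
        labels = [f"EEG ch{i}" for i in range(n_ch)]
    if samples_per_record is None:
        samples_per_record = [int(fs)] * n_ch
    n_records = n_samp // int(fs)
    if n_records * int(fs) != n_samp:
        raise ValueError("sample count must be a multiple of fs")

    phys_max = max(1.0, float(np.abs(data_uv).max()) * 1.0001)
    phys_min = -phys_max
    dig_min, dig_max = -32768, 32767

    header = b"".join(
        [
            _field("0", 8),  # version
            _field("X X X X", 80),  # patient id
            _field("Startdate 01-JAN-2000 X X X", 80),  # recording id
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(256 * (n_ch + 1), 8),  # header bytes
            _field("", 44),
            _field(n_records, 8),
            _field("1", 8),  # record duration, seconds
            _field(n_ch, 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_field(lab, 16) for lab in labels),
            b"".join(_field("", 80) for _ in range(n_ch)),  # transducer
            b"".join(_field("uV", 8) for _ in range(n_ch)),
            b"".join(_field(f"{phys_min:.6g}"[:8], 8) for _ in range(n_ch)),
            b"".join(_field(f"{phys_max:.6g}"[:8], 8) for _ in range(n_ch)),
            b"".join(_field(dig_min, 8) for _ in range(n_ch)),
            b"".join(_field(dig_max, 8) for _ in range(n_ch)),
            b"".join(_field("", 80) for _ in range(n_ch)),  # prefiltering
            b"".join(_field(nr, 8) for nr in samples_per_record),
            b"".join(_field("", 32) for _ in range(n_ch)),
        ]
    )

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((data_uv - phys_min) * scale + dig_min).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for rec in range(n_records):
            for ch in range(n_ch):
                nr = samples_per_record[ch]
                chunk = digital[ch, rec * int(fs) : rec * int(fs) + nr]
                if chunk.size < nr:
                    chunk = np.pad(chunk, (0, nr - chunk.size))
                fh.write(chunk.tobytes())
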