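"""Minimal EDF (European Data Format) writer and reader.

Implements the classic 16-bit EDF layout: a 256-byte ASCII header, one
256-byte ASCII block per signal, then data records of little-endian int16
samples.  Samples are scaled linearly between the physical range (default
+/-200 uV) and the digital range +/-32767, i.e. 16-bit quantization.

The record duration is 1 s; recordings whose length is not a whole number
of seconds are zero-padded to the next record boundary.  The true sample
count is stored in the free-text recording-id field (``NSAMP=<n>``) so the
reader can trim the padding; third-party EDF readers simply see trailing
zeros in the final record.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np

DIGITAL_MIN = -32768
DIGITAL_MAX = 32767


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"header field too long: {text!r} (max {width})")
    return b.ljust(width)


def write_edf(
    path: str | Path,
    data: np.ndarray,
    labels: list[str] | tuple[str, ...],
    fs_hz: float,
    physical_max_uv: float = 200.0,
    patient_id: str = "X",
) -> Path:
    """Write ``data`` (channels x samples, uV) to an EDF file.

    Samples outside +/-``physical_max_uv`` are clipped.  ``fs_hz`` must be
    a positive integer (samples per 1 s data record).
    """
    path = Path(path)
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.size == 0:
        raise ValueError("data must be a non-empty channels x samples array")
    if len(labels) != data.shape[0]:
        raise ValueError("one label per channel required")
    if len(set(labels)) != len(labels):
        raise ValueError("channel labels must be unique")
    if fs_hz <= 0 or fs_hz != int(fs_hz):
        raise ValueError("fs_hz must be a positive integer for 1 s records")
    fs = int(fs_hz)
    n_ch, n_samp = data.shape
    n_rec = int(np.ceil(n_samp / fs))

    phys_min, phys_max = -physical_max_uv, physical_max_uv
    scale = (DIGITAL_MAX - DIGITAL_MIN) / (phys_max - phys_min)
    clipped = np.clip(data, phys_min, phys_max)
    digital = np.round((clipped - phys_min) * scale + DIGITAL_MIN).astype("<i2")
    padded = np.zeros((n_ch, n_rec * fs), dtype="<i2")
    # zero uV maps to a nonzero digital code only if the range is asymmetric;
    # it is symmetric here up to the half-code offset, pad with the 0 uV code
    zero_code = np.round((0.0 - phys_min) * scale + DIGITAL_MIN).astype("<i2")
    padded[:] = zero_code
    padded[:, :n_samp] = digital

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _pad("0", 8),
            _pad(patient_id, 80),
            _pad(f"NSAMP={n_samp}", 80),
            _pad(now.strftime("%d.%m.%y"), 8),
            _pad(now.strftime("%H.%M.%S"), 8),
            _pad(str(256 * (1 + n_ch)), 8),
            _pad("", 44),
            _pad(str(n_rec), 8),
            _pad("1", 8),
            _pad(str(n_ch), 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_pad(lab, 16) for lab in labels),
            b"".join(_pad("AgAgCl electrode", 80) for _ in labels),
            b"".join(_pad("uV", 8) for _ in labels),
            b"".join(_pad(f"{phys_min:g}", 8) for _ in labels),
            b"".join(_pad(f"{phys_max:g}", 8) for _ in labels),
            b"".join(_pad(str(DIGITAL_MIN), 8) for _ in labels),
            b"".join(_pad(str(DIGITAL_MAX), 8) for _ in labels),
            b"".join(_pad("HP:0.1Hz N:50Hz", 80) for _ in labels),
            b"".join(_pad(str(fs), 8) for _ in labels),
            b"".join(_pad("", 32) for _ in labels),
        ]
    )
    # records are signal-major within each record: rec0 ch0 samples, rec0 ch1...
    records = padded.reshape(n_ch, n_rec, fs).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        fh.write(records.tobytes())
    return path


def read_edf(path: str | Path) -> tuple[np.ndarray, list[str], float]:
    """Read an EDF file; returns (data channels x samples in uV, labels, fs)."""
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError("truncated EDF header")
        recording_id = head[88:168].decode("ascii").strip()
        n_rec = int(head[236:244])
        rec_dur = float(head[244:252])
        n_ch = int(head[252:256])
        sig = fh.read(256 * n_ch)
        labels = [
            sig[16 * i : 16 * (i + 1)].decode("ascii").strip() for i in range(n_ch)
        ]
        off = 16 * n_ch + 80 * n_ch + 8 * n_ch

        def field(base: int, i: int, width: int = 8) -> str:
            start = base + width * i
            return sig[start : start + width].decode("ascii").strip()

        phys_min = np.array([float(field(off, i)) for i in range(n_ch)])
        phys_max = np.array([float(field(off + 8 * n_ch, i)) for i in range(n_ch)])
        dig_min = np.array([float(field(off + 16 * n_ch, i)) for i in range(n_ch)])
        dig_max = np.array([float(field(off + 24 * n_ch, i)) for i in range(n_ch)])
        ns_base = off + 32 * n_ch + 80 * n_ch
        n_per_rec = np.array([int(field(ns_base, i)) for i in range(n_ch)], dtype=int)
        if not np.all(n_per_rec == n_per_rec[0]):
            raise ValueError("heterogeneous per-signal rates not supported")
        raw = np.frombuffer(fh.read(), dtype="<i2")

    fs = n_per_rec[0] / rec_dur
    expected = n_rec * n_ch * n_per_rec[0]
    if raw.size < expected:
        raise ValueError("truncated EDF data section")
    data = (
        raw[:expected]
        .reshape(n_rec, n_ch, n_per_rec[0])
        .transpose(1, 0, 2)
        .reshape(n_ch, -1)
        .astype(float)
    )
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    data = (data - dig_min[:, None]) * gain[:, None] + phys_min[:, None]
    if recording_id.startswith("NSAMP="):
        n_samp = int(recording_id.split("=", 1)[1])
        data = data[:, :n_samp]
    return data, labels, fs
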