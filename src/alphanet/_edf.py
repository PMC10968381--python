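"""Minimal EDF (European Data Format) writer and reader.

Covers plain continuous EDF with identical sampling rate across signals,
1-second data records and microvolt physical units — sufficient for storing
synthetic resting-state studies.  Physical scaling factors are derived from
the ASCII header fields *as written*, so a write/read round-trip is exact up
to the format's 16-bit quantization.
"""

from __future__ import annotations

import datetime
import warnings
from pathlib import Path

import numpy as np

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"field {s!r} exceeds {width} ASCII chars")
    return s.ljust(width).encode("ascii")


def _fmt_phys(x: float) -> str:
    """Format a physical bound into <= 8 ASCII chars."""
    for fmt in ("%.6g", "%.5g", "%.4g", "%.3g"):
        s = fmt % x
        if len(s) <= 8:
            return s
    raise ValueError(f"cannot format {x} in 8 chars")


def write_edf(path, data: np.ndarray, fs: float, labels: list[str]) -> Path:
    """Write channels x samples microvolt data as EDF.

    ``fs`` must be a whole number of samples per second.  Recordings whose
    length is not a whole number of seconds are zero-padded to the next
    record boundary (with a warning).
    """
    path = Path(path)
    data = np.asarray(data, dtype=float)
    n_ch, n_samp = data.shape
    if len(labels) != n_ch:
        raise ValueError("label count does not match data rows")
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_rec = int(np.ceil(n_samp / spr))
    if n_rec * spr != n_samp:
        warnings.warn("recording padded with zeros to a whole number of EDF records")
        pad = np.zeros((n_ch, n_rec * spr - n_samp))
        data = np.hstack([data, pad])

    # per-channel physical range, re-parsed from its ASCII form so the
    # digitization scale matches what a reader will see
    pmins, pmaxs, digital = [], [], []
    for row in data:
        lo, hi = float(row.min()), float(row.max())
        if hi - lo < 1e-9:
            lo, hi = lo - 1.0, hi + 1.0
        lo_s, hi_s = _fmt_phys(lo), _fmt_phys(hi)
        lo_p, hi_p = float(lo_s), float(hi_s)
        if lo_p > lo:  # rounding must not shrink the range
            lo_p = lo - abs(lo) * 1e-4 - 1e-6
            lo_s = _fmt_phys(lo_p)
            lo_p = float(lo_s)
        if hi_p < hi:
            hi_p = hi + abs(hi) * 1e-4 + 1e-6
            hi_s = _fmt_phys(hi_p)
            hi_p = float(hi_s)
        scale = (_DIG_MAX - _DIG_MIN) / (hi_p - lo_p)
        dig = np.round((row - lo_p) * scale + _DIG_MIN)
        n_clip = int(np.sum((dig < _DIG_MIN) | (dig > _DIG_MAX)))
        if n_clip:
            warnings.warn(f"{n_clip} samples clipped to the EDF digitization range")
        digital.append(np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2"))
        pmins.append(lo_s)
        pmaxs.append(hi_s)

    now = datetime.datetime(2000, 1, 1)
    header = b"".join(
        [
            _ascii("0", 8),
            _ascii("X X X X", 80),
            _ascii("Startdate X X X X", 80),
            _ascii(now.strftime("%d.%m.%y"), 8),
            _ascii(now.strftime("%H.%M.%S"), 8),
            _ascii(256 * (1 + n_ch), 8),
            _ascii("", 44),
            _ascii(n_rec, 8),
            _ascii(1, 8),
            _ascii(n_ch, 4),
        ]
    )
    sig_fields = [
        [_ascii(l, 16) for l in labels],
        [_ascii("", 80)] * n_ch,
        [_ascii("uV", 8)] * n_ch,
        [_ascii(s, 8) for s in pmins],
        [_ascii(s, 8) for s in pmaxs],
        [_ascii(_DIG_MIN, 8)] * n_ch,
        [_ascii(_DIG_MAX, 8)] * n_ch,
        [_ascii("", 80)] * n_ch,
        [_ascii(spr, 8)] * n_ch,
        [_ascii("", 32)] * n_ch,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for field in sig_fields:
            fh.write(b"".join(field))
        for r in range(n_rec):
            sl = slice(r * spr, (r + 1) * spr)
            for ch in range(n_ch):
                fh.write(digital[ch][sl].tobytes())
    return path


def read_edf(path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file; returns (channels x samples in uV, fs, labels)."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise ValueError(f"{path} is not an EDF file (truncated header)")

    def f(lo, hi):
        return raw[lo:hi].decode("ascii", errors="replace").strip()

    header_bytes = int(f(184, 192))
    n_rec = int(f(236, 244))
    rec_dur = float(f(244, 252))
    n_ch = int(f(252, 256))
    if header_bytes != 256 * (1 + n_ch):
        raise ValueError("EDF header size inconsistent with channel count")

    widths = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]

    def sig(idx):
        base = 256 + n_ch * sum(widths[:idx])
        w = widths[idx]
        return [f(base + i * w, base + (i + 1) * w) for i in range(n_ch)]

    labels = sig(0)
    pmin = np.array([float(x) for x in sig(3)])
    pmax = np.array([float(x) for x in sig(4)])
    dmin = np.array([float(x) for x in sig(5)])
    dmax = np.array([float(x) for x in sig(6)])
    spr = np.array([int(x) for x in sig(8)])
    if len(set(spr)) != 1:
        raise ValueError("mixed sampling rates are not supported")
    spr = int(spr[0])
    fs = spr / rec_dur

    payload = raw[header_bytes:]
    expected = n_rec * n_ch * spr * 2
    if len(payload) < expected:
        raise ValueError(
            f"EDF data section holds {len(payload) // (n_ch * spr * 2)} records "
            f"but the header declares {n_rec}"
        )
    ints = np.frombuffer(payload[:expected], dtype="<i2")
    ints = ints.reshape(n_rec, n_ch, spr)
    scale = (pmax - pmin) / (dmax - dmin)
    data = (ints.transpose(1, 0, 2).reshape(n_ch, -1) - dmin[:, None]) * scale[:, None] + pmin[:, None]
    return data, fs, labels
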