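"""Continuous-data preprocessing: re-referencing, filtering, epoching and
amplitude-based artifact rejection.

Filtering is zero-phase: recordings are convolved once with a symmetric
(linear-phase) windowed-sinc FIR and the group delay is removed exactly by
shifting, which is both fast on long records and free of the phase
distortion that would corrupt phase-lag connectivity downstream.  The
band-pass is realised as two cascaded stages because a windowed-sinc
high-pass with the literal 0.1 Hz transition would need hundreds of
thousands of taps; the high-pass transition is instead one cutoff width,
with the tap count ``ceil(3.3 * fs / transition)`` capped at 8193.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .io import Recording

__all__ = [
    "Epochs",
    "rereference_average",
    "bandpass_fir",
    "notch",
    "segment_epochs",
    "reject_amplitude",
]

MAX_TAPS = 8193


@dataclass
class Epochs:
    """Fixed-length segments: ``blocks`` is epoch x channel x sample in uV."""

    blocks: np.ndarray
    fs: float
    channel_labels: list[str]
    rejected_count: int = 0

    def __post_init__(self):
        self.blocks = np.asarray(self.blocks, dtype=float)
        if self.blocks.ndim != 3:
            raise ValueError("blocks must be 3-D (epoch, channel, sample)")
        if self.blocks.shape[1] != len(self.channel_labels):
            raise ValueError("channel axis does not match labels")
        if self.rejected_count < 0:
            raise ValueError("rejected_count must be non-negative")

    @property
    def n_epochs(self) -> int:
        return self.blocks.shape[0]

    @property
    def epoch_length(self) -> float:
        return self.blocks.shape[2] / self.fs


def rereference_average(rec: Recording) -> Recording:
    """Whole-head average reference: subtract the cross-channel mean at every
    sample, so the included channels sum to zero."""
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy_with(data=data)


def _zero_phase_fir(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a symmetric odd-length FIR with exact group-delay compensation.

    The signal is reflect-padded by half the filter length on both sides, so
    edges see a mirrored continuation rather than zeros.
    """
    n_taps = len(taps)
    half = (n_taps - 1) // 2
    pad = min(half, data.shape[-1] - 1)
    padded = np.pad(data, [(0, 0)] * (data.ndim - 1) + [(pad, pad)], mode="reflect")
    out = sps.fftconvolve(padded, taps[None, :], mode="full", axes=-1)
    start = half + pad
    return out[..., start:start + data.shape[-1]]


def _n_taps(fs: float, transition: float, n_samples: int) -> int:
    n = int(np.ceil(3.3 * fs / transition))
    n = min(n, MAX_TAPS)
    n = min(n, max(3, (n_samples // 3) * 2 - 1))  # short records get short filters
    if n % 2 == 0:
        n += 1
    return n


def bandpass_fir(rec: Recording, low: float, high: float,
                 lp_transition: float = 5.0) -> Recording:
    """Zero-phase band-pass via cascaded Hamming windowed-sinc high- and
    low-pass stages (defaults mirror a 0.1–50 Hz resting-state band)."""
    nyq = rec.fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band edges must satisfy 0 < {low} < {high} < {nyq}")
    n_hp = _n_taps(rec.fs, low, rec.n_samples)  # transition = one cutoff width
    n_lp = _n_taps(rec.fs, lp_transition, rec.n_samples)
    hp = sps.firwin(n_hp, low, window="hamming", pass_zero="highpass", fs=rec.fs)
    # a capped-length high-pass leaves a residual DC gain (its tap sum);
    # redistributing that sum across the taps forces an exact spectral zero
    # at 0 Hz while perturbing other frequencies by O(sum / n_taps)
    hp -= hp.sum() / len(hp)
    lp = sps.firwin(n_lp, high, window="hamming", pass_zero="lowpass", fs=rec.fs)
    data = _zero_phase_fir(rec.data, hp)
    data = _zero_phase_fir(data, lp)
    return rec.copy_with(data=data)


def notch(rec: Recording, freqs: list[float], width: float = 1.0,
          transition: float = 0.5) -> Recording:
    """Zero-phase FIR band-stop at each listed line frequency.

    ``width`` is the half-width of the stop band in Hz (stop edges at
    ``f - width`` and ``f + width``).
    """
    nyq = rec.fs / 2.0
    data = rec.data
    for f in freqs:
        if not 0 < f < nyq:
            raise ValueError(f"notch frequency {f} Hz outside (0, Nyquist={nyq})")
        n = _n_taps(rec.fs, transition, rec.n_samples)
        lo, hi = max(f - width, 0.01), min(f + width, nyq - 0.01)
        taps = sps.firwin(n, [lo, hi], window="hamming", pass_zero="bandstop", fs=rec.fs)
        data = _zero_phase_fir(data, taps)
    return rec.copy_with(data=data)


def segment_epochs(rec: Recording, epoch_length: float = 2.0) -> Epochs:
    """Cut into non-overlapping epochs; a trailing partial epoch is dropped."""
    if epoch_length <= 0:
        raise ValueError("epoch_length must be positive")
    n_per = int(round(epoch_length * rec.fs))
    if abs(n_per - epoch_length * rec.fs) > 1e-9:
        raise ValueError("epoch_length * fs must be an integer sample count")
    n_ep = rec.n_samples // n_per
    if n_ep < 1:
        raise ValueError(
            f"recording of {rec.duration:.3f} s is shorter than one "
            f"{epoch_length} s epoch"
        )
    trimmed = rec.data[:, : n_ep * n_per]
    blocks = trimmed.reshape(rec.n_channels, n_ep, n_per).transpose(1, 0, 2)
    return Epochs(blocks=blocks.copy(), fs=rec.fs,
                  channel_labels=list(rec.channel_labels))


def reject_amplitude(ep: Epochs, threshold: float = 75.0) -> Epochs:
    """Discard epochs whose absolute amplitude strictly exceeds ``threshold``
    uV on any channel; epochs peaking exactly at the threshold are kept."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    peak = np.abs(ep.blocks).max(axis=(1, 2))
    keep = peak <= threshold
    n_rej = int(np.sum(~keep))
    if not np.any(keep):
        raise ValueError(
            f"all {ep.n_epochs} epochs exceed {threshold} uV; "
            "review the rejection threshold or the input scaling"
        )
    if np.any(peak == threshold):
        warnings.warn("epoch peak exactly at the rejection threshold; kept")
    return replace(ep, blocks=ep.blocks[keep],
                   rejected_count=ep.rejected_count + n_rej)
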