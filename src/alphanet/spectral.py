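"""Epoch-wise power spectral density and band-power group statistics.

PSD is the classic segment-averaged periodogram: each epoch is Hanning
windowed, FFT'd, and the squared magnitudes are averaged over epochs.  The
density normalization divides by the window's energy ``fs * sum(w**2)`` so
the integral of the PSD over frequency recovers signal variance (Parseval)
and a unit sinusoid integrates to 0.5 regardless of window choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import Epochs

__all__ = [
    "BandDefinition",
    "PSDResult",
    "ALPHA",
    "ALPHA1",
    "ALPHA2",
    "psd_epochs",
    "grand_average_psd",
    "band_power",
    "compare_psd_groups",
]


@dataclass(frozen=True)
class BandDefinition:
    """Half-open frequency band [lo, hi): the shared 10.5 Hz boundary of the
    slow/fast alpha split belongs to the upper band only, so the sub-bands
    partition the full band without double-counting a bin."""

    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not 0 <= self.lo < self.hi:
            raise ValueError(f"band must satisfy 0 <= lo < hi, got ({self.lo}, {self.hi})")

    def bins(self, freqs: np.ndarray) -> np.ndarray:
        return (freqs >= self.lo) & (freqs < self.hi)


ALPHA = BandDefinition("alpha", 8.0, 13.0)
ALPHA1 = BandDefinition("alpha1", 8.0, 10.5)
ALPHA2 = BandDefinition("alpha2", 10.5, 13.0)


@dataclass
class PSDResult:
    freqs: np.ndarray  # Hz, starts at 0, step 1/epoch_length
    psd: np.ndarray  # channel x frequency, power density (uV^2/Hz)
    n_epochs: int
    channel_labels: list[str]

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def psd_epochs(ep: Epochs) -> PSDResult:
    """Hanning-windowed, epoch-averaged one-sided PSD per channel."""
    if ep.n_epochs < 1:
        raise ValueError("need at least one epoch")
    n = ep.blocks.shape[2]
    w = np.hanning(n)
    spec = np.fft.rfft(ep.blocks * w, axis=2)
    power = np.abs(spec) ** 2 / (ep.fs * np.sum(w**2))
    power[..., 1:] *= 2.0  # one-sided
    if n % 2 == 0:
        power[..., -1] /= 2.0  # Nyquist bin is not mirrored
    psd = power.mean(axis=0)
    freqs = np.fft.rfftfreq(n, d=1.0 / ep.fs)
    return PSDResult(freqs=freqs, psd=psd, n_epochs=ep.n_epochs,
                     channel_labels=list(ep.channel_labels))


def grand_average_psd(psd: PSDResult) -> np.ndarray:
    """Arithmetic mean over channels: one overall spectrum per subject."""
    if psd.psd.shape[0] < 1:
        raise ValueError("need at least one channel")
    return psd.psd.mean(axis=0)


def band_power(psd: PSDResult, band: BandDefinition) -> np.ndarray:
    """Per-channel mean PSD over the band's bins (lo inclusive, hi exclusive)."""
    mask = band.bins(psd.freqs)
    if not np.any(mask):
        raise ValueError(
            f"band {band.name} ({band.lo}-{band.hi} Hz) contains no frequency bins "
            f"of the {psd.freqs[0]}-{psd.freqs[-1]} Hz grid"
        )
    return psd.psd[:, mask].mean(axis=1)


def two_sample_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-variance two-sample t along axis 0, orientation ``a - b``.

    Degenerate positions (zero pooled variance) get t = 0, p = 1 when the
    means agree, +/-inf and p = 0 otherwise.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 subjects")
    diff = a.mean(axis=0) - b.mean(axis=0)
    sp2 = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    zero = denom == 0
    t = np.where(zero & (diff == 0), 0.0, t)
    t = np.where(zero & (diff != 0), np.sign(diff) * np.inf, t)
    p = 2.0 * stats.t.sf(np.abs(t), df=na + nb - 2)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where(zero & (diff == 0), 1.0, p)
    return np.squeeze(t), np.squeeze(p)


def compare_psd_groups(group_a: np.ndarray, group_b: np.ndarray,
                       fdr: bool = False):
    """Two-sample t per column (frequency bin or electrode) between groups.

    ``group_a``/``group_b`` are subject x column arrays — grand-average PSD
    curves for per-bin comparison, or per-electrode band powers.  Returns
    ``(t, p)`` or ``(t, p, p_fdr)`` with a Benjamini-Hochberg column.
    """
    t, p = two_sample_t(group_a, group_b)
    if fdr:
        p_fdr = stats.false_discovery_control(np.atleast_1d(p))
        return t, p, np.squeeze(p_fdr)
    return t, p
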