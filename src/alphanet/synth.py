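"""Synthetic two-group resting-state EEG with known ground truth.

Every downstream stage of the pipeline is validated against data produced
here: narrowband alpha oscillators (random-walk phase, so the linewidth is
controllable), pairwise nonzero-lag phase coupling through a shared source,
1/f background noise, zero-lag volume-conduction mixing, and EOG/mastoid-like
non-scalp channels.  The default design mirrors a 64-channel, 1000 Hz,
210 s eyes-closed recording session with two groups of 24 subjects.

All randomness descends from a single integer seed through
``numpy.random.SeedSequence`` spawn keys, so individual subjects are
independent yet bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np

from .io import Montage, Recording, hemisphere_of, write_montage, write_recording

__all__ = [
    "OscillatorSpec",
    "CouplingSpec",
    "MixingModel",
    "GroupDesign",
    "StudySet",
    "make_montage_fixture",
    "make_simple_montage",
    "generate_recording",
    "generate_group_study",
    "write_study",
    "sample_wpli_matrices",
]

# 10-10 scalp rows, front to back: (labels, front-back coordinate in [-1, 1])
_SCALP_ROWS = [
    (["Fp1", "Fp2"], -1.0),
    (["AF7", "AF3", "AFz", "AF4", "AF8"], -0.75),
    (["F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8"], -0.5),
    (["FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8"], -0.25),
    (["T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8"], 0.0),
    (["TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8"], 0.25),
    (["P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8"], 0.5),
    (["PO7", "PO3", "POz", "PO4", "PO8"], 0.75),
    (["O1", "Oz", "O2"], 1.0),
]
NON_SCALP_LABELS = ["HEOG", "VEOG", "M1", "M2"]


def _row_positions(labels: list[str], t: float) -> np.ndarray:
    """Unit-sphere positions for one front-to-back row of a 10-10 cap."""
    n = len(labels)
    beta = t * np.deg2rad(81.0)  # tilt from vertex toward front (-) / back (+)
    out = np.empty((n, 3))
    for i, lab in enumerate(labels):
        u = 0.0 if n == 1 else 2.0 * i / (n - 1) - 1.0  # -1 left ... +1 right
        alpha = u * np.deg2rad(81.0)
        # rotate the vertex unit vector toward the back (beta), then laterally (alpha)
        v = np.array([
            np.sin(alpha) * np.cos(beta),
            -np.sin(beta),
            np.cos(alpha) * np.cos(beta),
        ])
        out[i] = v / np.linalg.norm(v)
        if hemisphere_of(lab) == "left" and out[i, 0] > 0:
            out[i, 0] *= -1.0
        if hemisphere_of(lab) == "right" and out[i, 0] < 0:
            out[i, 0] *= -1.0
    return out


def make_montage_fixture() -> Montage:
    """The 64-channel cap: 60 scalp 10-10 electrodes on a unit sphere plus
    two EOG and two mastoid channels flagged non-scalp."""
    labels: list[str] = []
    positions: list[np.ndarray] = []
    for row, t in _SCALP_ROWS:
        labels.extend(row)
        positions.append(_row_positions(row, t))
    pos = np.vstack(positions)
    # non-scalp electrodes sit below the equator of the sphere model
    extra = np.array(
        [
            [0.45, -1.0, -0.3],   # HEOG, right outer canthus
            [-0.25, -1.0, -0.35],  # VEOG, below left eye
            [-1.0, 0.15, -0.45],  # M1, left mastoid
            [1.0, 0.15, -0.45],   # M2, right mastoid
        ]
    )
    extra = extra / np.linalg.norm(extra, axis=1, keepdims=True)
    all_labels = labels + NON_SCALP_LABELS
    return Montage(
        labels=tuple(all_labels),
        positions=np.vstack([pos, extra]),
        hemisphere=tuple(hemisphere_of(l) for l in all_labels),
        is_scalp=np.array([True] * len(labels) + [False] * 4),
    )


def make_simple_montage(labels: list[str]) -> Montage:
    """Small all-scalp montage for focused experiments; positions spread on a ring."""
    n = len(labels)
    ang = 2 * np.pi * np.arange(n) / max(n, 1)
    pos = np.column_stack([np.sin(ang) * 0.8, np.cos(ang) * 0.8, np.full(n, 0.6)])
    pos = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    return Montage(
        labels=tuple(labels),
        positions=pos,
        hemisphere=tuple(hemisphere_of(l) for l in labels),
        is_scalp=np.ones(n, dtype=bool),
    )


@dataclass(frozen=True)
class OscillatorSpec:
    """Narrowband oscillator: random-walk phase around ``2*pi*center_freq*t``.

    ``phase_jitter_sd`` is the per-sample standard deviation of the phase
    increments (radians); it sets the linewidth, roughly
    ``sd**2 * fs / (2*pi)`` Hz.
    """

    center_freq: float = 10.0  # Hz
    amplitude: float = 10.0  # uV
    phase_jitter_sd: float = 0.1  # rad per sample

    def __post_init__(self):
        if not self.center_freq > 0:
            raise ValueError("center_freq must be positive")
        if self.amplitude < 0 or self.phase_jitter_sd < 0:
            raise ValueError("amplitude and phase_jitter_sd must be non-negative")


@dataclass(frozen=True)
class CouplingSpec:
    """Phase coupling of a channel pair through a shared oscillatory source.

    The first channel carries the source directly; the second mixes a lagged
    copy (``phase_lag`` radians) at fraction ``coupling_strength`` of its
    oscillatory power with an independent oscillator for the remainder.
    A lag of 0 or pi carries no imaginary cross-spectrum and thus no
    expected wPLI.
    """

    channel_pair: tuple[str, str]
    phase_lag: float = np.pi / 4
    coupling_strength: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [0, 1]")


@dataclass(frozen=True)
class ModuleSpec:
    """A phase-locked module: every listed channel draws a fraction of its
    oscillatory power from one shared source, at a channel-specific lag.

    Channel i's lag is ``i * lag_spacing`` radians, so all pairwise lags are
    nonzero multiples of the spacing (keep ``(n-1) * lag_spacing`` clear of
    pi to avoid near-antiphase pairs with vanishing imaginary coupling).
    All within-module pairs then carry an elevated expected wPLI.
    """

    channels: tuple[str, ...]
    coupling_strength: float = 0.6
    lag_spacing: float = 0.25  # rad

    def __post_init__(self):
        if len(self.channels) < 2:
            raise ValueError("a module needs at least 2 channels")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [0, 1]")


@dataclass(frozen=True)
class MixingModel:
    """Instantaneous (zero-lag) volume-conduction mixing.

    ``mixing_matrix`` is row-stochastic and diagonally dominant: each observed
    channel is a spatial smoothing of the underlying sources with no temporal
    filtering, the worst case a phase-lag measure must reject.
    """

    mixing_matrix: np.ndarray

    def __post_init__(self):
        m = self.mixing_matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("mixing matrix must be square")
        if np.any(m < 0):
            raise ValueError("mixing weights must be non-negative")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("mixing matrix rows must sum to 1")

    @classmethod
    def from_montage(cls, montage: Montage, spread: float = 0.3) -> "MixingModel":
        """Gaussian spatial smoothing over scalp electrode distances;
        ``spread`` is the kernel width in unit-sphere distance."""
        pos = montage.positions[montage.is_scalp]
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        w = np.exp(-(d**2) / (2 * spread**2))
        w = w / w.sum(axis=1, keepdims=True)
        return cls(mixing_matrix=w)

    @classmethod
    def identity(cls, n: int) -> "MixingModel":
        return cls(mixing_matrix=np.eye(n))


@dataclass
class GroupDesign:
    """Everything that defines a two-group synthetic study.

    Group-specific oscillator overrides and coupling lists are the planted
    effects; with both empty the design is a null (both groups drawn from
    one distribution).
    """

    montage: Montage = field(default_factory=make_montage_fixture)
    n_per_group: int = 24
    group_labels: tuple[str, str] = ("athlete", "control")
    fs: float = 1000.0
    duration: float = 210.0
    oscillator: OscillatorSpec = field(default_factory=OscillatorSpec)
    group_oscillator: dict[str, OscillatorSpec] = field(default_factory=dict)
    couplings: list[CouplingSpec] = field(default_factory=list)
    group_couplings: dict[str, list[CouplingSpec]] = field(default_factory=dict)
    modules: list[ModuleSpec] = field(default_factory=list)
    group_modules: dict[str, list[ModuleSpec]] = field(default_factory=dict)
    noise_exponent: float = 1.0
    noise_amplitude: float = 5.0  # uV RMS of the 1/f background
    nonscalp_noise_amplitude: float = 20.0
    mixing: MixingModel | None = None  # None = no volume conduction
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        n = self.fs * self.duration
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration * fs must be an integer sample count")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    def oscillator_for(self, group: str) -> OscillatorSpec:
        return self.group_oscillator.get(group, self.oscillator)

    def couplings_for(self, group: str) -> list[CouplingSpec]:
        return list(self.couplings) + list(self.group_couplings.get(group, []))

    def modules_for(self, group: str) -> list[ModuleSpec]:
        return list(self.modules) + list(self.group_modules.get(group, []))


@dataclass
class StudySet:
    """All recordings of a simulated study plus their group assignment."""

    design: GroupDesign
    subject_ids: list[str]
    groups: list[str]
    recordings: list[Recording]

    def by_group(self, group: str) -> list[Recording]:
        return [r for r, g in zip(self.recordings, self.groups) if g == group]

    def manifest(self) -> list[dict]:
        return [
            {"subject_id": s, "group": g, "seed": self.design.seed}
            for s, g in zip(self.subject_ids, self.groups)
        ]


# ---------------------------------------------------------------------------
# signal synthesis


def _oscillator_wave(rng: np.random.Generator, spec: OscillatorSpec, n: int,
                     fs: float, shared_phase: np.ndarray | None = None,
                     lag: float = 0.0) -> np.ndarray:
    if shared_phase is None:
        phase0 = rng.uniform(0, 2 * np.pi)
        drift = np.cumsum(rng.normal(0.0, spec.phase_jitter_sd, size=n))
        t = np.arange(n) / fs
        phase = 2 * np.pi * spec.center_freq * t + phase0 + drift
    else:
        phase = shared_phase - lag
    return spec.amplitude * np.cos(phase), phase


def _one_over_f_noise(rng: np.random.Generator, n: int, exponent: float,
                      rms: float) -> np.ndarray:
    """Spectrally shaped white noise with power spectrum ~ 1/f**exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    with np.errstate(divide="ignore"):
        shape = np.where(f > 0, f ** (-exponent / 2.0), 0.0)
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    if sd > 0 and rms > 0:
        x *= rms / sd
    else:
        x = np.zeros(n)
    return x


def generate_recording(design: GroupDesign, subject_index: int, group: str) -> Recording:
    """One subject's recording, deterministic in (design.seed, group, index).

    Scalp channels are ``mixing @ (oscillators + 1/f noise)``; coupled pairs
    share a source with the configured lag; non-scalp channels carry
    independent low-frequency noise only.
    """
    if group not in design.group_labels:
        raise ValueError(f"unknown group {group!r}")
    montage = design.montage
    scalp = montage.scalp_labels
    for cp in design.couplings_for(group):
        for lab in cp.channel_pair:
            if lab not in scalp:
                raise KeyError(f"coupling names unknown scalp channel {lab!r}")
    for mod in design.modules_for(group):
        for lab in mod.channels:
            if lab not in scalp:
                raise KeyError(f"module names unknown scalp channel {lab!r}")

    g_idx = design.group_labels.index(group)
    ss = np.random.SeedSequence(design.seed, spawn_key=(g_idx, subject_index))
    rng = np.random.Generator(np.random.PCG64(ss))
    n = design.n_samples
    osc_spec = design.oscillator_for(group)

    # oscillatory component per scalp channel
    waves = {lab: None for lab in scalp}
    for mod in design.modules_for(group):
        _, src_phase = _oscillator_wave(rng, osc_spec, n, design.fs)
        c = mod.coupling_strength
        for i, lab in enumerate(mod.channels):
            lagged, _ = _oscillator_wave(rng, osc_spec, n, design.fs,
                                         shared_phase=src_phase,
                                         lag=i * mod.lag_spacing)
            own, _ = _oscillator_wave(rng, osc_spec, n, design.fs)
            wave = np.sqrt(c) * lagged + np.sqrt(1.0 - c) * own
            waves[lab] = wave if waves[lab] is None else waves[lab] + wave
    for cp in design.couplings_for(group):
        a, b = cp.channel_pair
        src_wave, src_phase = _oscillator_wave(rng, osc_spec, n, design.fs)
        lagged, _ = _oscillator_wave(rng, osc_spec, n, design.fs,
                                     shared_phase=src_phase, lag=cp.phase_lag)
        c = cp.coupling_strength
        own, _ = _oscillator_wave(rng, osc_spec, n, design.fs)
        waves[a] = src_wave if waves[a] is None else waves[a] + src_wave
        mix = np.sqrt(c) * lagged + np.sqrt(1.0 - c) * own
        waves[b] = mix if waves[b] is None else waves[b] + mix
    for lab in scalp:
        if waves[lab] is None:
            waves[lab], _ = _oscillator_wave(rng, osc_spec, n, design.fs)

    sources = np.vstack([waves[lab] for lab in scalp])
    if design.noise_amplitude > 0:
        for i in range(len(scalp)):
            sources[i] += _one_over_f_noise(rng, n, design.noise_exponent,
                                            design.noise_amplitude)
    if design.mixing is not None:
        if design.mixing.mixing_matrix.shape[0] != len(scalp):
            raise ValueError("mixing matrix dimension does not match scalp channel count")
        sources = design.mixing.mixing_matrix @ sources

    data = np.zeros((len(montage), n))
    scalp_idx = {lab: i for i, lab in enumerate(scalp)}
    for row, lab in enumerate(montage.labels):
        if montage.is_scalp[row]:
            data[row] = sources[scalp_idx[lab]]
        else:
            data[row] = _one_over_f_noise(rng, n, 2.0, design.nonscalp_noise_amplitude)
    return Recording(
        data=data,
        fs=design.fs,
        channel_labels=list(montage.labels),
        montage=montage,
        meta={"group": group, "subject_index": subject_index, "seed": design.seed},
    )


def generate_group_study(design: GroupDesign) -> StudySet:
    """Simulate both groups; group-specific overrides are the planted effect."""
    ids, groups, recs = [], [], []
    for group in design.group_labels:
        for k in range(design.n_per_group):
            ids.append(f"{group}_{k:02d}")
            groups.append(group)
            recs.append(generate_recording(design, k, group))
    return StudySet(design=design, subject_ids=ids, groups=groups, recordings=recs)


def write_study(study: StudySet, outdir, format: str = "delimited") -> Path:
    """Write one file per subject plus the montage table and a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = ".edf" if format == "edf" else ".tsv"
    manifest = []
    for sid, group, rec in zip(study.subject_ids, study.groups, study.recordings):
        fname = f"{sid}{ext}"
        write_recording(rec, outdir / fname, format=format)
        manifest.append({"subject_id": sid, "group": group, "file": fname,
                         "fs": rec.fs, "seed": study.design.seed})
    write_montage(study.design.montage, outdir / "montage.tsv")
    (outdir / "manifest.json").write_text(json.dumps(
        {"format": format, "montage": "montage.tsv", "subjects": manifest}, indent=2))
    return outdir


# ---------------------------------------------------------------------------
# matrix-level study sampler (for permutation/NBS experiments)


def sample_wpli_matrices(
    rng: np.random.Generator,
    n_subjects: int,
    labels: list[str],
    base_mean: float = 0.25,
    base_sd: float = 0.08,
    subject_sd: float = 0.06,
    planted_edges: list[tuple[str, str]] | None = None,
    delta: float = 0.0,
    planted: list[tuple[list[tuple[str, str]], float]] | None = None,
) -> np.ndarray:
    """Sample subject-level connectivity matrices directly.

    Each edge has a population mean (``base_mean``, jittered once per study
    with ``base_sd``) and per-subject Gaussian variation ``subject_sd``;
    values are clipped to [0, 1].  Planted effects add ``delta`` to the
    population mean of ``planted_edges``; ``planted`` generalizes this to
    several edge sets with their own deltas (e.g. a strong hub core plus
    weaker spokes).  Returns ``(n_subjects, n, n)`` symmetric matrices with
    zero diagonals.
    """
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    pop = np.clip(rng.normal(base_mean, base_sd, size=len(iu[0])), 0.01, 0.95)
    plants = list(planted or [])
    if planted_edges:
        plants.append((list(planted_edges), delta))
    if plants:
        index = {lab: i for i, lab in enumerate(labels)}
        edge_pos = {(min(i, j), max(i, j)): k
                    for k, (i, j) in enumerate(zip(*iu))}
        for edges, d in plants:
            for a, b in edges:
                i, j = index[a], index[b]
                pop[edge_pos[(min(i, j), max(i, j))]] += d
    out = np.zeros((n_subjects, n, n))
    for s in range(n_subjects):
        vals = np.clip(pop + rng.normal(0.0, subject_sd, size=len(pop)), 0.0, 1.0)
        m = np.zeros((n, n))
        m[iu] = vals
        out[s] = m + m.T
    return out


def sample_study_wpli(
    rng: np.random.Generator,
    n_per_group: int,
    labels: list[str],
    base_mean: float = 0.25,
    base_sd: float = 0.08,
    subject_sd: float = 0.06,
    planted: list[tuple[list[tuple[str, str]], float]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-group matrix study sharing one population of edge means.

    Both groups draw subjects around the same per-edge population means;
    ``planted`` edge sets (with their deltas) shift group A's means only —
    the ground-truth group difference.  Returns ``(group_a, group_b)``
    stacks of shape ``(n_per_group, n, n)``.
    """
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    pop = np.clip(rng.normal(base_mean, base_sd, size=len(iu[0])), 0.01, 0.95)
    pop_a = pop.copy()
    if planted:
        index = {lab: i for i, lab in enumerate(labels)}
        edge_pos = {(min(i, j), max(i, j)): k for k, (i, j) in enumerate(zip(*iu))}
        for edges, d in planted:
            for a, b in edges:
                i, j = index[a], index[b]
                pop_a[edge_pos[(min(i, j), max(i, j))]] += d

    def draw(mean_vec):
        out = np.zeros((n_per_group, n, n))
        for s in range(n_per_group):
            vals = np.clip(mean_vec + rng.normal(0.0, subject_sd, size=len(mean_vec)),
                           0.0, 1.0)
            m = np.zeros((n, n))
            m[iu] = vals
            out[s] = m + m.T
        return out

    return draw(pop_a), draw(pop)
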