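"""Readers, writers and channel selection for EEG recordings and derived tables.

Recordings travel as either EDF (European Data Format) files or tab-delimited
channel x sample matrices with a JSON sidecar carrying the sampling rate.
Connectivity matrices and montages are tab-delimited so diffs stay readable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Montage",
    "Recording",
    "read_recording",
    "write_recording",
    "select_scalp_channels",
    "read_matrix",
    "write_matrix",
    "read_montage",
    "write_montage",
]

HEMISPHERES = ("left", "right", "midline")


def hemisphere_of(label: str) -> str:
    """Hemisphere from a 10-10 label: odd final digit = left, even = right,
    trailing 'z'/'Z' = midline.  Non-positional labels (EOG, mastoid M1/M2
    style) fall back to the same digit rule."""
    tail = label.rstrip()
    if tail and tail[-1] in "zZ":
        return "midline"
    digits = "".join(c for c in tail if c.isdigit())
    if not digits:
        return "midline"
    return "left" if int(digits[-1]) % 2 == 1 else "right"


@dataclass(frozen=True)
class Montage:
    """Electrode montage: labels with 3-D positions, hemisphere and scalp flag.

    ``positions`` is ``(n, 3)``; scalp positions are unit-norm (sphere model).
    """

    labels: tuple[str, ...]
    positions: np.ndarray
    hemisphere: tuple[str, ...]
    is_scalp: np.ndarray  # bool per channel

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("montage labels must be unique")
        if self.positions.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_channels, 3)")
        for h in self.hemisphere:
            if h not in HEMISPHERES:
                raise ValueError(f"unknown hemisphere {h!r}")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    @property
    def scalp_labels(self) -> list[str]:
        return [l for l, s in zip(self.labels, self.is_scalp) if s]

    def hemisphere_labels(self, side: str, scalp_only: bool = True) -> list[str]:
        if side not in HEMISPHERES:
            raise ValueError(f"side must be one of {HEMISPHERES}, got {side!r}")
        out = []
        for l, h, s in zip(self.labels, self.hemisphere, self.is_scalp):
            if h == side and (s or not scalp_only):
                out.append(l)
        return out

    def subset(self, labels: list[str]) -> "Montage":
        idx = [self.index(l) for l in labels]
        return Montage(
            labels=tuple(self.labels[i] for i in idx),
            positions=self.positions[idx],
            hemisphere=tuple(self.hemisphere[i] for i in idx),
            is_scalp=self.is_scalp[idx],
        )


@dataclass
class Recording:
    """Multichannel recording: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    montage: Montage | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **kw) -> "Recording":
        out = replace(self, **kw) if kw else replace(self)
        out.data = np.array(out.data)
        return out


# ---------------------------------------------------------------------------
# recordings


def write_recording(rec: Recording, path, format: str = "delimited") -> Path:
    """Write a recording as EDF or tab-delimited text (+ JSON sidecar)."""
    path = Path(path)
    if format == "edf":
        from . import _edf

        _edf.write_edf(path, rec.data, rec.fs, rec.channel_labels)
    elif format == "delimited":
        df = pd.DataFrame(rec.data, index=rec.channel_labels)
        df.to_csv(path, sep="\t", header=False, float_format="%.6f")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps({"fs": rec.fs, "channel_labels": rec.channel_labels})
        )
    else:
        raise ValueError(f"unknown recording format {format!r}")
    return path


def read_recording(path, format: str | None = None, montage: Montage | None = None) -> Recording:
    """Read an EDF or delimited recording.

    ``format`` is inferred from the extension when omitted.  Delimited files
    need the JSON sidecar written by :func:`write_recording` (one row per
    channel, first column the label).
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        from . import _edf

        data, fs, labels = _edf.read_edf(path)
    elif format == "delimited":
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"missing sidecar metadata {sidecar}")
        meta = json.loads(sidecar.read_text())
        df = pd.read_csv(path, sep="\t", header=None, index_col=0)
        labels = [str(l) for l in df.index]
        if labels != list(meta["channel_labels"]):
            raise ValueError(
                "channel labels in sidecar do not match data rows "
                f"({meta['channel_labels'][:3]}... vs {labels[:3]}...)"
            )
        data = df.to_numpy(dtype=float)
        fs = float(meta["fs"])
    else:
        raise ValueError(f"unknown recording format {format!r}")
    return Recording(data=data, fs=fs, channel_labels=list(labels), montage=montage)


def select_scalp_channels(rec: Recording, drop_labels: list[str] | None = None,
                          ignore_missing: bool = False) -> Recording:
    """Remove non-scalp channels (EOG, mastoids) ahead of connectivity analysis.

    The surviving channels are re-ordered to montage order when a montage is
    attached, so the channel axis of every downstream matrix is stable
    regardless of input file order.
    """
    drop = list(dict.fromkeys(drop_labels or []))  # de-duplicate, keep order
    missing = [d for d in drop if d not in rec.channel_labels]
    if missing and not ignore_missing:
        raise KeyError(f"drop labels not present: {missing}")
    keep = [l for l in rec.channel_labels if l not in drop]
    if rec.montage is not None:
        order = [l for l in rec.montage.labels if l in keep]
        order += [l for l in keep if l not in order]  # channels absent from montage
        keep = order
    if not keep:
        raise ValueError("channel selection removed every channel")
    idx = [rec.channel_labels.index(l) for l in keep]
    sub_montage = rec.montage
    if sub_montage is not None:
        in_mont = [l for l in keep if l in sub_montage.labels]
        sub_montage = sub_montage.subset(in_mont) if in_mont else None
    return Recording(
        data=rec.data[idx].copy(),
        fs=rec.fs,
        channel_labels=keep,
        montage=sub_montage,
        meta=dict(rec.meta),
    )


# ---------------------------------------------------------------------------
# labeled symmetric matrices


def write_matrix(matrix: np.ndarray, path, labels: list[str] | None = None) -> Path:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"matrix must be square, got shape {matrix.shape}")
    n = matrix.shape[0]
    labels = labels if labels is not None else [f"ch{i}" for i in range(n)]
    if len(labels) != n:
        raise ValueError("label count does not match matrix dimension")
    df = pd.DataFrame(matrix, index=labels, columns=labels)
    df.to_csv(path, sep="\t", float_format="%.17g")
    return Path(path)


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != labels:
        raise ValueError("matrix file row labels differ from column labels")
    return df.to_numpy(dtype=float), labels


# ---------------------------------------------------------------------------
# montage tables


def write_montage(montage: Montage, path) -> Path:
    df = pd.DataFrame(
        {
            "label": montage.labels,
            "x": montage.positions[:, 0],
            "y": montage.positions[:, 1],
            "z": montage.positions[:, 2],
            "hemisphere": montage.hemisphere,
            "is_scalp": montage.is_scalp.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return Path(path)


def read_montage(path) -> Montage:
    df = pd.read_csv(path, sep="\t")
    return Montage(
        labels=tuple(df["label"].astype(str)),
        positions=df[["x", "y", "z"]].to_numpy(dtype=float),
        hemisphere=tuple(df["hemisphere"].astype(str)),
        is_scalp=df["is_scalp"].to_numpy(dtype=bool),
    )
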