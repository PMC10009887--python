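"""Reading and writing multi-channel recordings and R-peak annotations.

A recording on disk is a delimited numeric matrix (one column per channel,
one row per sample, values in microvolts) accompanied by a JSON sidecar
``<name>.json`` holding the sampling rate, per-channel roles and names.
Peak annotations are stored as plain text, one 0-based sample index per line.

All indices are 0-based everywhere in the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

ABDOMINAL = "abdominal"
REFERENCE = "reference"

__all__ = [
    "ABDOMINAL",
    "REFERENCE",
    "FormatError",
    "MultichannelRecording",
    "PeakAnnotations",
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
]


class FormatError(ValueError):
    """Raised when an on-disk recording or annotation file is malformed."""


@dataclass
class MultichannelRecording:
    """A channels x samples matrix in microvolts with per-channel roles.

    Parameters
    ----------
    samples:
        Array of shape ``(n_channels, n_samples)``, in microvolts.
    fs:
        Sampling rate in Hz.
    channel_roles:
        One of ``"abdominal"`` or ``"reference"`` per channel.  Reference
        channels are fetal-free thoracic maternal-ECG leads used as noise
        references by the adaptive extractor.
    """

    samples: np.ndarray
    fs: float
    channel_roles: list[str]
    channel_names: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] < 1:
            raise ValueError("samples must be a (n_channels, n_samples) matrix")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if len(self.channel_roles) != self.n_channels:
            raise ValueError("one role per channel required")
        for role in self.channel_roles:
            if role not in (ABDOMINAL, REFERENCE):
                raise ValueError(f"unknown channel role: {role!r}")
        if self.channel_names is None:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]
        elif len(self.channel_names) != self.n_channels:
            raise ValueError("one name per channel required")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def abdominal_indices(self) -> list[int]:
        return [i for i, r in enumerate(self.channel_roles) if r == ABDOMINAL]

    @property
    def reference_indices(self) -> list[int]:
        return [i for i, r in enumerate(self.channel_roles) if r == REFERENCE]


@dataclass
class PeakAnnotations:
    """Strictly increasing 0-based R-peak sample indices at a given rate."""

    indices: np.ndarray
    fs: float
    label: str = "fetal"

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64).ravel()
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise FormatError("annotation indices must be strictly increasing")
        if self.indices.size and self.indices[0] < 0:
            raise FormatError("annotation indices must be non-negative")

    def __len__(self) -> int:
        return int(self.indices.size)

    def times(self) -> np.ndarray:
        """Peak times in seconds."""
        return self.indices / self.fs


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: MultichannelRecording, path: str | Path) -> Path:
    """Write ``rec`` as ``<path>.csv`` plus a ``<path>.json`` sidecar."""
    path = Path(path)
    csv_path = path.with_suffix(".csv")
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(csv_path, rec.samples.T, delimiter=",", fmt="%.8g")
    sidecar = {
        "fs": rec.fs,
        "roles": list(rec.channel_roles),
        "names": list(rec.channel_names),
        "meta": rec.meta,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return csv_path


def read_recording(
    path: str | Path, role_map: dict[str, str] | None = None
) -> MultichannelRecording:
    """Read a delimited matrix + JSON sidecar recording.

    ``role_map`` optionally overrides the sidecar roles by channel name.
    Channels with no role in either place default to abdominal.
    """
    path = Path(path)
    csv_path = path.with_suffix(".csv")
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    try:
        sidecar = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:  # pragma: no cover - defensive
        raise FormatError(f"unreadable sidecar {sidecar_path}: {exc}") from exc
    if "fs" not in sidecar:
        raise FormatError("sidecar missing required 'fs'")
    try:
        matrix = np.loadtxt(csv_path, delimiter=",", ndmin=2)
    except ValueError as exc:
        raise FormatError(f"ragged or non-numeric matrix in {csv_path}") from exc
    samples = matrix.T  # columns on disk are channels
    n_channels = samples.shape[0]
    names = sidecar.get("names") or [f"ch{i}" for i in range(n_channels)]
    roles = sidecar.get("roles") or [ABDOMINAL] * n_channels
    if len(roles) != n_channels or len(names) != n_channels:
        raise FormatError("sidecar roles/names length does not match matrix")
    if role_map:
        roles = [role_map.get(name, role) for name, role in zip(names, roles)]
    return MultichannelRecording(
        samples=samples,
        fs=float(sidecar["fs"]),
        channel_roles=list(roles),
        channel_names=list(names),
        meta=sidecar.get("meta", {}),
    )


def write_annotations(ann: PeakAnnotations, path: str | Path) -> Path:
    """Write one 0-based integer sample index per line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("".join(f"{i}\n" for i in ann.indices))
    return path


def read_annotations(
    path: str | Path, fs: float, label: str = "fetal"
) -> PeakAnnotations:
    """Read a one-index-per-line annotation file written by this package."""
    text = Path(path).read_text()
    try:
        indices = [int(line) for line in text.split()]
    except ValueError as exc:
        raise FormatError(f"non-integer annotation entry in {path}") from exc
    try:
        return PeakAnnotations(np.asarray(indices, dtype=np.int64), fs, label)
    except FormatError:
        raise
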