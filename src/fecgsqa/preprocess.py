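"""Resampling, causal high-pass filtering and 5-s segmentation.

Two presets are used by the channel-selection pipeline:

* ``TRAIN_PRESET`` — 500 Hz, 1 Hz 4th-order Butterworth high-pass: the
  light preprocessing applied before computing quality features, leaving
  powerline and high-frequency noise in band on purpose (the classifier
  must learn to recognise them).
* ``NINFEA_PRESET`` — 512 Hz, 3 Hz 5th-order Butterworth high-pass: the
  more aggressive variant for recordings with strong baseline wander.

Filtering is causal single-pass (second-order sections), matching a
real-time wearable implementation; no notch filter is ever applied.
Filters are applied to the whole channel before segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy.signal import butter, resample_poly, sosfilt

from .io_formats import MultichannelRecording

__all__ = [
    "FilterSpec",
    "PreprocessPreset",
    "TRAIN_PRESET",
    "NINFEA_PRESET",
    "Segment",
    "SEGMENT_SECONDS",
    "resample_recording",
    "highpass",
    "highpass_array",
    "segment_channel",
    "preprocess_recording",
]

SEGMENT_SECONDS = 5.0


@dataclass(frozen=True)
class FilterSpec:
    """High-pass Butterworth specification."""

    cutoff: float
    order: int
    kind: str = "highpass"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def sos(self, fs: float) -> np.ndarray:
        if self.cutoff >= fs / 2:
            raise ValueError("cutoff must be below the Nyquist frequency")
        return butter(self.order, self.cutoff, self.kind, fs=fs, output="sos")


@dataclass(frozen=True)
class PreprocessPreset:
    target_fs: float
    filter_spec: FilterSpec
    name: str = ""


TRAIN_PRESET = PreprocessPreset(500.0, FilterSpec(1.0, 4), "train")
NINFEA_PRESET = PreprocessPreset(512.0, FilterSpec(3.0, 5), "ninfea")

PRESETS = {"train": TRAIN_PRESET, "ninfea": NINFEA_PRESET}


@dataclass
class Segment:
    """One 5-s window of one channel, length exactly ``round(5 * fs)``."""

    samples: np.ndarray
    fs: float
    source: tuple[str, int, int] = ("", 0, 0)  # (recording id, channel, start)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        expected = int(round(SEGMENT_SECONDS * self.fs))
        if self.samples.size != expected:
            raise ValueError(
                f"segment must have {expected} samples, got {self.samples.size}"
            )


def resample_recording(
    rec: MultichannelRecording, target_fs: float
) -> MultichannelRecording:
    """Polyphase anti-aliased resampling of every channel.

    The rational approximation of ``target_fs / fs`` is exact to better
    than 1e-9 relative; ``target_fs == fs`` returns the recording
    unchanged (same matrix object).
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if target_fs == rec.fs:
        return rec
    frac = Fraction(target_fs / rec.fs).limit_denominator(10**6)
    out = resample_poly(rec.samples, frac.numerator, frac.denominator, axis=1)
    return MultichannelRecording(
        samples=out,
        fs=target_fs,
        channel_roles=list(rec.channel_roles),
        channel_names=list(rec.channel_names),
        meta=dict(rec.meta),
    )


def highpass_array(x: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Causal high-pass of a 1-D or (channels, samples) array."""
    sos = spec.sos(fs)
    return sosfilt(sos, np.asarray(x, dtype=float), axis=-1)


def highpass(obj, spec: FilterSpec, fs: float | None = None):
    """High-pass a recording, segment or plain array (same type out)."""
    if isinstance(obj, MultichannelRecording):
        return MultichannelRecording(
            samples=highpass_array(obj.samples, obj.fs, spec),
            fs=obj.fs,
            channel_roles=list(obj.channel_roles),
            channel_names=list(obj.channel_names),
            meta=dict(obj.meta),
        )
    if isinstance(obj, Segment):
        return replace(obj, samples=highpass_array(obj.samples, obj.fs, spec))
    if fs is None:
        raise ValueError("fs required when filtering a bare array")
    return highpass_array(obj, fs, spec)


def segment_channel(
    channel: np.ndarray,
    fs: float,
    recording_id: str = "",
    channel_index: int = 0,
) -> list[Segment]:
    """Consecutive non-overlapping 5-s windows starting at sample 0.

    A trailing remainder shorter than 5 s is discarded; a channel shorter
    than 5 s yields an empty list.
    """
    channel = np.asarray(channel, dtype=float).ravel()
    seg_len = int(round(SEGMENT_SECONDS * fs))
    n_segments = channel.size // seg_len
    return [
        Segment(
            samples=channel[k * seg_len : (k + 1) * seg_len],
            fs=fs,
            source=(recording_id, channel_index, k * seg_len),
        )
        for k in range(n_segments)
    ]


def preprocess_recording(
    rec: MultichannelRecording, preset: PreprocessPreset
) -> MultichannelRecording:
    """Resample then high-pass a whole recording with one preset."""
    return highpass(resample_recording(rec, preset.target_fs), preset.filter_spec)
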