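"""Informative / non-informative labelling and class balancing.

A channel (or segment) is labelled informative when the fetal ECG it
carries exceeds an SNR threshold (default 5 dB, strict).  For synthetic
data the generator's ground-truth per-channel SNR is the default
labeller; for real recordings a template-based estimator is provided:
beats are aligned in 100-ms windows centred on the annotated fetal
R-peaks, the mean beat is the signal template, and the residual around
the template is the noise.

Because non-informative segments dominate real recordings, the majority
class is randomly downsampled (without replacement, seeded) to the
minority size before training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import PeakAnnotations
from .sqi import FEATURE_NAMES

__all__ = [
    "LabelConfig",
    "LabelledFeatureTable",
    "estimate_fecg_snr",
    "assign_labels",
    "balance_dataset",
]

PROVENANCE_COLUMNS = ("recording", "channel", "start")


@dataclass(frozen=True)
class LabelConfig:
    snr_threshold: float = 5.0  # dB; informative iff SNR strictly above
    balance_seed: int = 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.snr_threshold):
            raise ValueError("snr_threshold must be finite")


@dataclass
class LabelledFeatureTable:
    """SQI rows with binary labels and (recording, channel, start) keys.

    ``data`` holds the 16 feature columns, a boolean ``degenerate``
    column, a boolean ``label`` column (True = informative) and the three
    provenance columns.  Keys must be unique.
    """

    data: pd.DataFrame
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        required = set(self.feature_names) | {"label"} | set(PROVENANCE_COLUMNS)
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"table missing columns: {sorted(missing)}")
        if "degenerate" not in self.data.columns:
            self.data = self.data.assign(degenerate=False)
        keys = self.data[list(PROVENANCE_COLUMNS)]
        if keys.duplicated().any():
            raise ValueError("duplicate (recording, channel, start) keys")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def features(self) -> pd.DataFrame:
        return self.data[list(self.feature_names)]

    @property
    def labels(self) -> np.ndarray:
        return self.data["label"].to_numpy(dtype=bool)

    @property
    def degenerate(self) -> np.ndarray:
        return self.data["degenerate"].to_numpy(dtype=bool)

    def class_counts(self) -> tuple[int, int]:
        """(n_informative, n_non_informative)."""
        y = self.labels
        return int(y.sum()), int((~y).sum())

    def subset(self, row_indices: np.ndarray) -> "LabelledFeatureTable":
        return LabelledFeatureTable(
            self.data.iloc[np.sort(np.asarray(row_indices))].reset_index(drop=True),
            self.feature_names,
        )


def estimate_fecg_snr(
    fecg: np.ndarray, fs: float, peaks: PeakAnnotations
) -> float:
    """Template-based SNR of an extracted fetal ECG trace, in dB.

    100-ms windows centred on the annotated peaks are averaged into a
    template T; SNR = 10 log10(mean(T^2) / mean((beat - T)^2)).  Fewer
    than 3 complete beat windows gives -inf; a perfectly repeating beat
    (zero residual) gives +inf.
    """
    fecg = np.asarray(fecg, dtype=float).ravel()
    half = int(round(0.05 * fs))
    windows = [
        fecg[p - half : p + half + 1]
        for p in peaks.indices
        if p - half >= 0 and p + half + 1 <= fecg.size
    ]
    if len(windows) < 3:
        return -math.inf
    beats = np.asarray(windows)
    template = beats.mean(axis=0)
    p_sig = float(np.mean(template**2))
    p_noise = float(np.mean((beats - template) ** 2))
    if p_sig == 0.0:
        return -math.inf
    # identical beats leave only rounding residue in the mean
    if p_noise <= p_sig * 1e-20:
        return math.inf
    return 10.0 * math.log10(p_sig / p_noise)


def assign_labels(
    snr_per_item: np.ndarray, cfg: LabelConfig = LabelConfig()
) -> np.ndarray:
    """Boolean labels: informative iff SNR strictly above the threshold."""
    snr = np.asarray(snr_per_item, dtype=float)
    return snr > cfg.snr_threshold


def borderline_mask(snr_per_item: np.ndarray, cfg: LabelConfig = LabelConfig(),
                    margin_db: float = 1.0) -> np.ndarray:
    """Items within ``margin_db`` of the threshold, flagged for optional
    manual review."""
    snr = np.asarray(snr_per_item, dtype=float)
    return np.abs(snr - cfg.snr_threshold) < margin_db


def balance_dataset(table: LabelledFeatureTable, seed: int = 0) -> LabelledFeatureTable:
    """Randomly downsample the majority class to the minority size.

    Sampling is without replacement and deterministic given ``seed``;
    surviving rows keep their original order.  Raises if either class is
    empty.
    """
    y = table.labels
    n_pos, n_neg = table.class_counts()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to balance")
    if n_pos == n_neg:
        return table
    rng = np.random.default_rng(seed)
    majority = np.flatnonzero(y) if n_pos > n_neg else np.flatnonzero(~y)
    minority = np.flatnonzero(~y) if n_pos > n_neg else np.flatnonzero(y)
    kept = rng.choice(majority, size=minority.size, replace=False)
    return table.subset(np.concatenate([minority, kept]))
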