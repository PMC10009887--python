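"""Maternal-ECG cancellation (multi-reference QRD-RLS) and fetal R-peak
detection (expected-rate max-search).

The extractor is an exponentially weighted recursive-least-squares
adaptive filter realized through QR-decomposition updates: the upper
triangular square-root factor of the regressor covariance is propagated
with Givens rotations, which is numerically stable at forgetting factors
close to 1.  The regressor at sample ``n`` concatenates the last ``taps``
samples of each thoracic reference lead (default 3 references x 20 taps
= 60 weights, forgetting factor 0.999); the a-priori error — the part of
the abdominal signal the maternal references cannot explain — is the
fetal ECG estimate.  The first ``10 * taps`` samples are an adaptation
transient and flagged so downstream scoring can exclude them.

The detector slides a window sized from an expected fetal rate (default
2.2 Hz ~ 132 bpm) over the polarity-corrected trace and keeps samples
that are the maximum within +/- half a nominal beat; overlapping
candidates are resolved in favour of the larger peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.ndimage import maximum_filter1d

from .io_formats import PeakAnnotations

__all__ = [
    "ExtractorConfig",
    "DetectorConfig",
    "FetalECGEstimate",
    "build_regressors",
    "qrd_rls_extract",
    "maxsearch_detect",
]


@dataclass(frozen=True)
class ExtractorConfig:
    taps_per_reference: int = 20
    forgetting_factor: float = 0.999
    n_references: int = 3
    regularization: float = 0.01

    def __post_init__(self) -> None:
        if self.taps_per_reference < 1:
            raise ValueError("taps_per_reference must be >= 1")
        if not 0 < self.forgetting_factor <= 1:
            raise ValueError("forgetting factor must be in (0, 1]")
        if self.regularization <= 0:
            raise ValueError("regularization must be positive")


@dataclass(frozen=True)
class DetectorConfig:
    expected_rate: float = 2.2  # Hz, ~132 bpm mid-fetal heart rate
    window_factor: float = 0.5
    polarity: str = "auto"  # auto | positive | negative

    def __post_init__(self) -> None:
        if self.expected_rate <= 0:
            raise ValueError("expected_rate must be positive")
        if self.polarity not in ("auto", "positive", "negative"):
            raise ValueError("polarity must be auto, positive or negative")


@dataclass
class FetalECGEstimate:
    samples: np.ndarray
    fs: float
    source_channel: int = -1
    converged_from: int = 0  # end of the adaptation transient


def build_regressors(references: np.ndarray, taps: int) -> np.ndarray:
    """Regressor matrix U (n_samples x n_refs*taps): per reference, the
    current and ``taps - 1`` previous samples (zero pre-padding)."""
    references = np.atleast_2d(np.asarray(references, dtype=float))
    n_refs, n = references.shape
    U = np.zeros((n, n_refs * taps))
    for r in range(n_refs):
        for k in range(taps):
            U[k:, r * taps + k] = references[r, : n - k]
    return U


@njit(cache=True)
def _qrd_rls_core(U, d, lam, delta):  # pragma: no cover - compiled
    n, m = U.shape
    R = np.zeros((m, m))
    z = np.zeros(m)
    w = np.zeros(m)
    e = np.zeros(n)
    for i in range(m):
        R[i, i] = np.sqrt(delta)
    sl = np.sqrt(lam)
    u = np.zeros(m)
    for t in range(n):
        # a-priori error with the weights from the previous update
        acc = d[t]
        for j in range(m):
            acc -= U[t, j] * w[j]
        e[t] = acc
        # exponential forgetting of the square-root factor
        for i in range(m):
            z[i] *= sl
            for j in range(i, m):
                R[i, j] *= sl
        for j in range(m):
            u[j] = U[t, j]
        dd = d[t]
        # annihilate the new regressor row into R with Givens rotations
        for i in range(m):
            b = u[i]
            if b != 0.0:
                a = R[i, i]
                r = np.hypot(a, b)
                c = a / r
                s = b / r
                R[i, i] = r
                for j in range(i + 1, m):
                    tmp = c * R[i, j] + s * u[j]
                    u[j] = -s * R[i, j] + c * u[j]
                    R[i, j] = tmp
                tmpz = c * z[i] + s * dd
                dd = -s * z[i] + c * dd
                z[i] = tmpz
        # back-substitution: R w = z
        for i in range(m - 1, -1, -1):
            acc = z[i]
            for j in range(i + 1, m):
                acc -= R[i, j] * w[j]
            w[i] = acc / R[i, i] if R[i, i] != 0.0 else 0.0
    return e, w


def qrd_rls_extract(
    abdominal: np.ndarray,
    references: np.ndarray,
    cfg: ExtractorConfig = ExtractorConfig(),
    fs: float = float("nan"),
    source_channel: int = -1,
) -> FetalECGEstimate:
    """Cancel the maternal ECG in one abdominal trace.

    ``references`` is ``(n_references, n_samples)``; all sequences must
    share the abdominal trace's length.  Returns the residual (fetal)
    trace plus the extractor's final state metadata.
    """
    d = np.asarray(abdominal, dtype=float).ravel()
    refs = np.atleast_2d(np.asarray(references, dtype=float))
    if refs.shape[0] != cfg.n_references:
        raise ValueError(
            f"expected {cfg.n_references} references, got {refs.shape[0]}"
        )
    if refs.shape[1] != d.size:
        raise ValueError("references and abdominal trace lengths differ")
    if d.size < 10 * cfg.taps_per_reference:
        raise ValueError("trace shorter than 10 taps of adaptation")
    U = build_regressors(refs, cfg.taps_per_reference)
    e, _w = _qrd_rls_core(
        U, d, cfg.forgetting_factor, cfg.regularization
    )
    return FetalECGEstimate(
        samples=e,
        fs=fs,
        source_channel=source_channel,
        converged_from=10 * cfg.taps_per_reference,
    )


def final_weights(
    abdominal: np.ndarray, references: np.ndarray, cfg: ExtractorConfig
) -> np.ndarray:
    """Adaptive-filter weights after the last sample (for diagnostics)."""
    d = np.asarray(abdominal, dtype=float).ravel()
    U = build_regressors(np.atleast_2d(references), cfg.taps_per_reference)
    _e, w = _qrd_rls_core(U, d, cfg.forgetting_factor, cfg.regularization)
    return w


def _window_max_candidates(y: np.ndarray, w: int) -> np.ndarray:
    """Samples that are the maximum of y within +/- w (edges truncated)."""
    filt = maximum_filter1d(y, size=2 * w + 1, mode="constant", cval=-np.inf)
    return np.flatnonzero(y == filt)


def _enforce_distance(candidates: np.ndarray, y: np.ndarray, w: int) -> np.ndarray:
    """Keep the larger peak whenever two candidates are closer than w."""
    if candidates.size == 0:
        return candidates
    order = np.lexsort((candidates, -y[candidates]))  # amplitude desc, index asc
    kept: list[int] = []
    for idx in candidates[order]:
        if all(abs(idx - k) > w for k in kept):
            kept.append(int(idx))
    return np.array(sorted(kept), dtype=np.int64)


def maxsearch_detect(
    fecg: FetalECGEstimate | np.ndarray,
    cfg: DetectorConfig = DetectorConfig(),
    fs: float | None = None,
) -> PeakAnnotations:
    """Expected-rate sliding local-maximum fetal QRS detection.

    Polarity ``auto`` picks the sign whose candidate extrema have the
    larger median magnitude, so an inverted QRS train detects
    identically to an upright one.
    """
    if isinstance(fecg, FetalECGEstimate):
        x, fs = fecg.samples, fecg.fs
    else:
        x = np.asarray(fecg, dtype=float).ravel()
        if fs is None:
            raise ValueError("fs required for a bare array")
    if x.size < 2 * fs:
        raise ValueError("trace shorter than 2 s")
    w = int(round(cfg.window_factor * fs / cfg.expected_rate))
    w = max(w, 1)

    def detect_sign(sign: float) -> tuple[np.ndarray, float]:
        y = sign * x
        cand = _window_max_candidates(y, w)
        cand = cand[y[cand] > 0]
        cand = _enforce_distance(cand, y, w)
        strength = float(np.median(y[cand])) if cand.size else -np.inf
        return cand, strength

    if cfg.polarity == "positive":
        peaks, _ = detect_sign(+1.0)
    elif cfg.polarity == "negative":
        peaks, _ = detect_sign(-1.0)
    else:
        pos, s_pos = detect_sign(+1.0)
        neg, s_neg = detect_sign(-1.0)
        peaks = pos if s_pos >= s_neg else neg
    return PeakAnnotations(indices=peaks, fs=fs, label="fetal")
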