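"""The 16 signal-quality indexes (SQIs) computed on each 5-s segment.

Frequency-domain features use a Welch estimate with 1-s Hann windows and
50% overlap (one-sided density), giving a grid spacing of 1 Hz — fine
enough to resolve the [48-52] Hz powerline band.  "Average power in a
band" is the mean PSD density over the band's bins (closed interval on
both endpoints); the two ratio features pSQI and basSQI instead use
integrated (summed) band power so that unequal band widths cancel
identically in numerator and denominator.

Time-domain features: baseline standard deviation after a centred 1-s
moving average, steepest sample-to-sample slope, extreme amplitudes,
standard deviation, population (non-excess) kurtosis and skewness, and
Hjorth complexity.  Kurtosis is non-excess, so Gaussian noise scores 3
and a sparse ECG-like spike train scores well above 5.

Zero-variance (degenerate) segments never raise: every feature is
recorded as 0 and the vector carries a degenerate marker which the
classifier maps to non-informative by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import welch
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew

from .preprocess import Segment

__all__ = [
    "FEATURE_NAMES",
    "PSDEstimate",
    "SQIVector",
    "estimate_psd",
    "band_power",
    "band_power_integrated",
    "spectral_entropy",
    "baseline_std",
    "steepest_slope",
    "amplitude_stats",
    "moments",
    "power_ratios",
    "hjorth_complexity",
    "compute_sqi_vector",
]

# mRMR-relevance rank order of the features; this is the canonical column
# order used everywhere downstream (tables, rankings, tie-breaks).
FEATURE_NAMES = (
    "pband2", "seSQI", "pband4", "bas_pow", "pband3", "ss", "pband1", "HA",
    "stdSQI", "kSQI", "pband5", "LA", "pSQI", "complexity", "basSQI", "sSQI",
)

_BANDS = {
    "pband1": (0.5, 10.0),
    "pband2": (10.0, 20.0),
    "pband3": (20.0, 48.0),
    "pband4": (48.0, 52.0),
    "pband5": (52.0, 100.0),
}


@dataclass
class PSDEstimate:
    """One-sided Welch PSD: ascending frequency grid and uV^2/Hz bins."""

    freqs: np.ndarray
    power: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have the same length")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


@dataclass
class SQIVector:
    """The 16 quality features of one segment, in relevance-rank order."""

    pband2: float = 0.0
    seSQI: float = 0.0
    pband4: float = 0.0
    bas_pow: float = 0.0
    pband3: float = 0.0
    ss: float = 0.0
    pband1: float = 0.0
    HA: float = 0.0
    stdSQI: float = 0.0
    kSQI: float = 0.0
    pband5: float = 0.0
    LA: float = 0.0
    pSQI: float = 0.0
    complexity: float = 0.0
    basSQI: float = 0.0
    sSQI: float = 0.0
    degenerate: bool = False

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


def estimate_psd(seg: Segment) -> PSDEstimate:
    """Welch PSD, 1-s Hann windows, 50% overlap, one-sided density."""
    x = seg.samples
    nperseg = int(round(seg.fs))
    if x.size < 2 * seg.fs:
        raise ValueError("segment too short for a PSD estimate")
    freqs, power = welch(
        x, fs=seg.fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2,
        detrend=False, scaling="density",
    )
    return PSDEstimate(freqs=freqs, power=power, fs=seg.fs)


def _band_mask(psd: PSDEstimate, f_lo: float, f_hi: float) -> np.ndarray:
    if not 0 <= f_lo < f_hi:
        raise ValueError("need 0 <= f_lo < f_hi")
    mask = (psd.freqs >= f_lo) & (psd.freqs <= f_hi)
    if not np.any(mask):
        raise ValueError(f"no PSD bins in [{f_lo}, {f_hi}] Hz")
    return mask


def band_power(psd: PSDEstimate, f_lo: float, f_hi: float) -> float:
    """Mean PSD density over the closed band [f_lo, f_hi]."""
    return float(np.mean(psd.power[_band_mask(psd, f_lo, f_hi)]))


def band_power_integrated(psd: PSDEstimate, f_lo: float, f_hi: float) -> float:
    """Summed bin power over the closed band (used by the ratio features)."""
    f_hi = min(f_hi, psd.fs / 2)
    return float(np.sum(psd.power[_band_mask(psd, f_lo, f_hi)]))


def spectral_entropy(psd: PSDEstimate) -> float:
    """Normalized Shannon entropy of the PSD, in [0, 1].

    ``H = -sum p_i ln p_i / ln(N)`` with ``p_i`` the bin power fractions;
    zero-power bins contribute nothing and an all-zero PSD scores 0.
    """
    if psd.power.size < 2:
        raise ValueError("need at least 2 PSD bins")
    total = float(np.sum(psd.power))
    if total == 0.0:
        return 0.0
    p = psd.power / total
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)) / np.log(p.size))


def baseline_std(seg: Segment) -> float:
    """Standard deviation of the 1-s moving-average baseline (bas_pow).

    Single-stage centred moving average, window forced odd, reflected
    edges; the returned value is the population std of the baseline.
    """
    window = int(round(seg.fs))
    if window % 2 == 0:
        window += 1
    baseline = uniform_filter1d(seg.samples, size=window, mode="reflect")
    return float(np.std(baseline))


def steepest_slope(seg: Segment) -> float:
    """Largest absolute sample-to-sample slope, in uV/s (ss)."""
    if seg.samples.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.max(np.abs(np.diff(seg.samples))) * seg.fs)


def amplitude_stats(seg: Segment) -> tuple[float, float, float]:
    """(HA, LA, stdSQI): signed max, signed min and population std."""
    x = seg.samples
    return float(np.max(x)), float(np.min(x)), float(np.std(x))


def moments(seg: Segment) -> tuple[float, float, bool]:
    """(kSQI, sSQI, degenerate): population kurtosis and skewness.

    Kurtosis is non-excess (Gaussian -> 3).  A zero-variance segment
    cannot support either moment: both are recorded as 0 and the
    degenerate flag is raised.
    """
    x = seg.samples
    if float(np.std(x)) == 0.0:
        return 0.0, 0.0, True
    k = float(_kurtosis(x, fisher=False, bias=True))
    s = float(_skew(x, bias=True))
    return k, s, False


def power_ratios(psd: PSDEstimate) -> tuple[float, float, bool]:
    """(pSQI, basSQI, degenerate).

    pSQI = integrated power in [5, 15] Hz over [5, 45] Hz (the fetal QRS
    band fraction); basSQI = integrated power in [0, 3] Hz over [0, 100]
    Hz (baseline fraction; denominator truncated at Nyquist when fs/2 is
    below 100 Hz).  A zero denominator yields 0 with the degenerate flag.
    """
    degenerate = False
    num_p = band_power_integrated(psd, 5.0, 15.0)
    den_p = band_power_integrated(psd, 5.0, 45.0)
    if den_p == 0.0:
        psqi, degenerate = 0.0, True
    else:
        psqi = num_p / den_p
    num_b = band_power_integrated(psd, 0.0, 3.0)
    den_b = band_power_integrated(psd, 0.0, 100.0)
    if den_b == 0.0:
        basqi, degenerate = 0.0, True
    else:
        basqi = num_b / den_b
    return float(psqi), float(basqi), degenerate


def hjorth_complexity(seg: Segment) -> tuple[float, bool]:
    """Hjorth complexity: mobility of the first difference over mobility
    of the signal, where mobility(x) = sqrt(var(diff x) / var(x)).

    A pure sinusoid scores ~1 (its derivative is a sinusoid of the same
    frequency); broadband noise scores well above 1.
    """
    x = seg.samples
    dx = np.diff(x)
    ddx = np.diff(dx)
    vx, vdx, vddx = np.var(x), np.var(dx), np.var(ddx)
    if vx == 0.0 or vdx == 0.0:
        return 0.0, True
    mobility_x = np.sqrt(vdx / vx)
    mobility_dx = np.sqrt(vddx / vdx)
    return float(mobility_dx / mobility_x), False


def compute_sqi_vector(seg: Segment) -> SQIVector:
    """All 16 features of one segment, degenerate-safe."""
    x = seg.samples
    if float(np.std(x)) == 0.0 and float(np.mean(x)) == 0.0:
        return SQIVector(degenerate=True)

    psd = estimate_psd(seg)
    bands = {name: band_power(psd, lo, hi) for name, (lo, hi) in _BANDS.items()}
    ha, la, std = amplitude_stats(seg)
    k, s, deg_m = moments(seg)
    psqi, basqi, deg_r = power_ratios(psd)
    complexity, deg_c = hjorth_complexity(seg)
    return SQIVector(
        pband2=bands["pband2"],
        seSQI=spectral_entropy(psd),
        pband4=bands["pband4"],
        bas_pow=baseline_std(seg),
        pband3=bands["pband3"],
        ss=steepest_slope(seg),
        pband1=bands["pband1"],
        HA=ha,
        stdSQI=std,
        kSQI=k,
        pband5=bands["pband5"],
        LA=la,
        pSQI=psqi,
        complexity=complexity,
        basSQI=basqi,
        sSQI=s,
        degenerate=deg_m or deg_r or deg_c,
    )
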