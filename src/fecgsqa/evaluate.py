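"""Tolerance-window peak matching, detection metrics and the statistical
comparison of channel-selection conditions.

Detected and reference fetal R-peaks are matched one-to-one, greedily by
ascending absolute time difference, a pair counting as a true positive
when |dt| <= tolerance (default 50 ms, i.e. a +/- 50 ms window — about
one fetal QRS complex wide).  Unmatched detections are false positives,
unmatched reference peaks false negatives, and the four detection
metrics are

    ACCdet = TP / (TP + FP + FN)        TPRdet = TP / (TP + FN)
    PPVdet = TP / (TP + FP)             F1det  = 2 PPV TPR / (PPV + TPR)

Conditions (all channels vs selected channels) are compared per
recording with a Kruskal-Wallis omnibus test and pairwise Wilcoxon
signed-rank tests, Bonferroni-corrected over the pairwise family.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import PeakAnnotations

__all__ = [
    "MatchConfig",
    "DetectionScore",
    "ComparisonReport",
    "match_peaks",
    "detection_metrics",
    "compare_conditions",
]


@dataclass(frozen=True)
class MatchConfig:
    tolerance_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.tolerance_ms <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class DetectionScore:
    """Match counts and the four detection metrics (NaN when 0/0)."""

    tp: int
    fp: int
    fn: int
    acc_det: float = field(init=False)
    tpr_det: float = field(init=False)
    ppv_det: float = field(init=False)
    f1_det: float = field(init=False)

    def __post_init__(self) -> None:
        def ratio(num: float, den: float) -> float:
            return num / den if den > 0 else float("nan")

        self.acc_det = ratio(self.tp, self.tp + self.fp + self.fn)
        self.tpr_det = ratio(self.tp, self.tp + self.fn)
        self.ppv_det = ratio(self.tp, self.tp + self.fp)
        if (
            math.isnan(self.tpr_det)
            or math.isnan(self.ppv_det)
            or (self.tpr_det + self.ppv_det) == 0
        ):
            self.f1_det = float("nan")
        else:
            self.f1_det = (
                2 * self.ppv_det * self.tpr_det / (self.ppv_det + self.tpr_det)
            )

    def as_dict(self) -> dict[str, float]:
        return {
            "TPdet": self.tp, "FPdet": self.fp, "FNdet": self.fn,
            "ACCdet": self.acc_det, "TPRdet": self.tpr_det,
            "PPVdet": self.ppv_det, "F1det": self.f1_det,
        }


def match_peaks(
    detected: PeakAnnotations,
    reference: PeakAnnotations,
    cfg: MatchConfig = MatchConfig(),
) -> tuple[int, int, int]:
    """One-to-one greedy nearest-first matching; returns (TP, FP, FN).

    All pairs within tolerance are sorted by ascending |dt| (ties broken
    by reference then detected index, for determinism) and taken greedily
    subject to one-to-one use.
    """
    if detected.fs != reference.fs:
        raise ValueError("detected and reference annotations disagree on fs")
    tol = cfg.tolerance_ms / 1000.0 * reference.fs
    det = detected.indices
    ref = reference.indices
    pairs = [
        (abs(int(r) - int(d)), i, j)
        for i, r in enumerate(ref)
        for j, d in enumerate(det)
        if abs(int(r) - int(d)) <= tol
    ]
    pairs.sort()
    used_ref: set[int] = set()
    used_det: set[int] = set()
    tp = 0
    for _delta, i, j in pairs:
        if i not in used_ref and j not in used_det:
            used_ref.add(i)
            used_det.add(j)
            tp += 1
    fp = det.size - tp
    fn = ref.size - tp
    return tp, int(fp), int(fn)


def detection_metrics(counts: tuple[int, int, int]) -> DetectionScore:
    """DetectionScore from a (TP, FP, FN) triple."""
    tp, fp, fn = counts
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    return DetectionScore(tp=tp, fp=fp, fn=fn)


@dataclass
class ComparisonReport:
    """Kruskal-Wallis omnibus + Bonferroni-corrected pairwise Wilcoxon."""

    condition_names: list[str]
    kruskal_statistic: float
    kruskal_p: float
    pairwise_p: dict[tuple[str, str], float]
    pairwise_p_corrected: dict[tuple[str, str], float]
    alpha: float = 0.05

    def significant_pairs(self) -> list[tuple[str, str]]:
        return [k for k, p in self.pairwise_p_corrected.items() if p < self.alpha]


def _wilcoxon_p(a: np.ndarray, b: np.ndarray) -> float:
    diff = a - b
    if np.allclose(diff, 0):
        return 1.0
    try:
        return float(stats.wilcoxon(a, b).pvalue)
    except ValueError:
        return 1.0


def compare_conditions(
    scores_by_condition: dict[str, np.ndarray], alpha: float = 0.05
) -> ComparisonReport:
    """Compare aligned per-recording metric vectors across conditions.

    Vectors must be aligned by recording (paired observations).  Rows with
    NaN in any condition are dropped pairwise-consistently.  At least 6
    recordings are required for the signed-rank test to be able to reach
    significance at all.
    """
    names = list(scores_by_condition)
    mat = np.column_stack([np.asarray(scores_by_condition[n], float) for n in names])
    mat = mat[~np.isnan(mat).any(axis=1)]
    if mat.shape[0] < 6:
        raise ValueError("need at least 6 recordings")
    columns = [mat[:, k] for k in range(len(names))]
    if all(np.allclose(c, columns[0]) for c in columns[1:]):
        kw_stat, kw_p = 0.0, 1.0
    else:
        kw_stat, kw_p = stats.kruskal(*columns)
    pairs = list(itertools.combinations(range(len(names)), 2))
    raw = {
        (names[i], names[j]): _wilcoxon_p(columns[i], columns[j])
        for i, j in pairs
    }
    corrected = {k: min(1.0, p * len(pairs)) for k, p in raw.items()}
    return ComparisonReport(
        condition_names=names,
        kruskal_statistic=float(kw_stat),
        kruskal_p=float(kw_p),
        pairwise_p=raw,
        pairwise_p_corrected=corrected,
        alpha=alpha,
    )
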