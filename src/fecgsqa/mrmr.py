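"""Minimum-redundancy maximum-relevance (mRMR) feature ranking.

The greedy MID (mutual-information difference) variant: the first feature
picked maximizes its mutual information with the label; each subsequent
pick maximizes ``MI(f, y) - mean over already-selected s of MI(f, s)``.
A feature's raw relevance score is the criterion value at the moment it
was selected, floored at 0 so fully redundant features contribute nothing.

Mutual information is the plug-in estimate on equal-frequency-binned
features (10 bins by default), in bits — robust to the heavy-tailed
distributions typical of power and amplitude quality indexes.

Cross-validation partitions each contribute one score vector, min-max
normalized to [0, 1]; vectors are summed across partitions and features
ranked by the aggregated relevance.  The selected subset is the smallest
ranking prefix reaching a target fraction (default 80%) of the total
aggregated relevance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sqi import FEATURE_NAMES

__all__ = [
    "RelevanceRanking",
    "mutual_information",
    "discretize",
    "mrmr_rank",
    "aggregate_relevance",
    "select_features",
]

DEFAULT_BINS = 10


def discretize(x: np.ndarray, n_bins: int = DEFAULT_BINS) -> np.ndarray:
    """Equal-frequency binning to integer codes; constant x -> one code."""
    x = np.asarray(x, dtype=float)
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def _mi_discrete(cx: np.ndarray, cy: np.ndarray) -> float:
    """Plug-in mutual information of two discrete code arrays, in bits."""
    ux, cxi = np.unique(cx, return_inverse=True)
    uy, cyi = np.unique(cy, return_inverse=True)
    joint = np.bincount(
        cxi * uy.size + cyi, minlength=ux.size * uy.size
    ).reshape(ux.size, uy.size).astype(float)
    n = joint.sum()
    if n == 0:
        return 0.0
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log2(pxy[nz] / (px @ py)[nz])))


def mutual_information(
    x: np.ndarray, y: np.ndarray, n_bins: int = DEFAULT_BINS
) -> float:
    """MI in bits between a numeric feature and discrete labels (>= 0)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 10:
        raise ValueError("need at least 10 samples")
    if np.all(x == x[0]):
        return 0.0
    return max(0.0, _mi_discrete(discretize(x, n_bins), y))


def mrmr_rank(
    features: pd.DataFrame,
    labels: np.ndarray,
    n_bins: int = DEFAULT_BINS,
) -> dict[str, float]:
    """Greedy MID ranking; returns each feature's raw score (floored at 0).

    Ties are broken by the canonical column order of ``features``.
    """
    labels = np.asarray(labels)
    if features.shape[1] < 2:
        raise ValueError("need at least 2 features")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")

    names = list(features.columns)
    codes = {name: discretize(features[name].to_numpy(), n_bins) for name in names}
    relevance = {name: max(0.0, _mi_discrete(codes[name], labels)) for name in names}

    scores: dict[str, float] = {}
    selected: list[str] = []
    remaining = list(names)
    # cache pairwise feature MI lazily
    pair_mi: dict[tuple[str, str], float] = {}

    def redundancy(f: str) -> float:
        if not selected:
            return 0.0
        acc = 0.0
        for s in selected:
            key = (f, s) if f < s else (s, f)
            if key not in pair_mi:
                pair_mi[key] = _mi_discrete(codes[key[0]], codes[key[1]])
            acc += pair_mi[key]
        return acc / len(selected)

    while remaining:
        best_name, best_crit = None, -np.inf
        for f in remaining:  # iteration order = tie-break order
            crit = relevance[f] - redundancy(f)
            if crit > best_crit:
                best_name, best_crit = f, crit
        scores[best_name] = max(0.0, best_crit)
        selected.append(best_name)
        remaining.remove(best_name)
    return scores


@dataclass
class RelevanceRanking:
    """Aggregated relevance per feature, sorted descending, with the
    smallest prefix reaching ``relevance_fraction`` of the total marked
    as selected."""

    feature_names: list[str]
    aggregated_scores: np.ndarray
    relevance_fraction: float = 0.8
    selected: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.aggregated_scores = np.asarray(self.aggregated_scores, dtype=float)
        if np.any(np.diff(self.aggregated_scores) > 1e-12):
            raise ValueError("aggregated scores must be sorted descending")
        if self.selected is None:
            self.selected = _prefix_mask(
                self.aggregated_scores, self.relevance_fraction
            )

    @property
    def selected_features(self) -> list[str]:
        return [n for n, s in zip(self.feature_names, self.selected) if s]

    def to_dict(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "aggregated_scores": self.aggregated_scores.tolist(),
            "relevance_fraction": self.relevance_fraction,
            "selected": [bool(s) for s in self.selected],
        }


def _prefix_mask(scores_desc: np.ndarray, fraction: float) -> np.ndarray:
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    total = float(np.sum(scores_desc))
    mask = np.zeros(scores_desc.size, dtype=bool)
    if total == 0.0:
        return mask
    cum = np.cumsum(scores_desc)
    p = int(np.searchsorted(cum, fraction * total - 1e-12)) + 1
    mask[:p] = True
    return mask


def aggregate_relevance(
    per_partition_scores: list[dict[str, float]],
    relevance_fraction: float = 0.8,
    feature_order: tuple[str, ...] = FEATURE_NAMES,
) -> RelevanceRanking:
    """Min-max normalize each partition's scores to [0, 1], sum across
    partitions and rank features by the aggregated relevance.

    A partition with all-equal scores is degenerate under min-max
    normalization and contributes zeros.  Ties in the aggregated score
    are broken by ``feature_order``.
    """
    if not per_partition_scores:
        raise ValueError("need at least one partition")
    order = [n for n in feature_order if n in per_partition_scores[0]]
    missing = set(per_partition_scores[0]) - set(order)
    order += sorted(missing)
    agg = np.zeros(len(order))
    for scores in per_partition_scores:
        v = np.array([scores[n] for n in order], dtype=float)
        lo, hi = v.min(), v.max()
        if hi > lo:
            agg += (v - lo) / (hi - lo)
    rank = sorted(range(len(order)), key=lambda i: (-agg[i], i))
    return RelevanceRanking(
        feature_names=[order[i] for i in rank],
        aggregated_scores=agg[rank],
        relevance_fraction=relevance_fraction,
    )


def select_features(ranking: RelevanceRanking, fraction: float = 0.8) -> list[str]:
    """Smallest ranking prefix whose cumulative score reaches
    ``fraction`` of the total aggregated relevance."""
    mask = _prefix_mask(ranking.aggregated_scores, fraction)
    return [n for n, s in zip(ranking.feature_names, mask) if s]
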