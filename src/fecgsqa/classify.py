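"""Bagged-tree classification of segment quality and channel selection.

The classifier is a bagging ensemble of 100 CART trees (Gini impurity,
best-first growth capped at 10 internal splits each), trained on the 16
quality features — deliberately small, fixed-capacity trees suited to a
low-power implementation, with no hyperparameter tuning.  Evaluation is
a stratified 10-time 10-fold cross-validation; the five usual metrics
(Acc, TPR, TNR, PPV, F1) are computed per partition and summarized by
median and quartiles.

A whole channel is declared informative when a strict majority of its
5-s segments is predicted informative.  Segments flagged degenerate by
the feature stage are forced to non-informative, as is an exact 50/50
ensemble tie (false positives cost downstream compute).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .io_formats import MultichannelRecording
from .labeling import LabelledFeatureTable
from .preprocess import PreprocessPreset, TRAIN_PRESET, preprocess_recording, segment_channel
from .sqi import compute_sqi_vector

__all__ = [
    "EnsembleParams",
    "CVScheme",
    "CVResult",
    "BaggedTreeModel",
    "train",
    "predict",
    "cross_validate",
    "classification_metrics",
    "ChannelSelection",
    "select_channels",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class EnsembleParams:
    n_learners: int = 100
    max_splits_per_tree: int = 10
    bootstrap: bool = True
    features_per_split: str = "sqrt"  # "sqrt" or "all"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_learners < 1 or self.max_splits_per_tree < 1:
            raise ValueError("n_learners and max_splits_per_tree must be >= 1")
        if self.features_per_split not in ("sqrt", "all"):
            raise ValueError("features_per_split must be 'sqrt' or 'all'")


@dataclass(frozen=True)
class CVScheme:
    n_folds: int = 10
    n_repeats: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")


@dataclass
class BaggedTreeModel:
    """A fitted bagging ensemble plus the feature-name contract."""

    ensemble: BaggingClassifier
    feature_names: list[str]
    params: EnsembleParams

    def vote_scores(self, X: np.ndarray) -> np.ndarray:
        """Fraction of trees voting informative, per row (in [0, 1])."""
        votes = np.zeros(X.shape[0])
        for est, feats in zip(
            self.ensemble.estimators_, self.ensemble.estimators_features_
        ):
            votes += est.predict(X[:, feats])
        return votes / len(self.ensemble.estimators_)


def _build_ensemble(params: EnsembleParams, n_features: int) -> BaggingClassifier:
    # <= max_splits internal nodes == <= max_splits + 1 leaves, best-first
    max_features = "sqrt" if params.features_per_split == "sqrt" else None
    tree = DecisionTreeClassifier(
        criterion="gini",
        max_leaf_nodes=params.max_splits_per_tree + 1,
        max_features=max_features,
    )
    return BaggingClassifier(
        estimator=tree,
        n_estimators=params.n_learners,
        bootstrap=params.bootstrap,
        random_state=params.seed % (2**31),
    )


def train(
    table: LabelledFeatureTable,
    params: EnsembleParams = EnsembleParams(),
    feature_subset: list[str] | None = None,
) -> BaggedTreeModel:
    """Fit the bagging ensemble on a labelled feature table."""
    if len(table) == 0:
        raise ValueError("empty training table")
    names = list(feature_subset) if feature_subset else list(table.feature_names)
    unknown = set(names) - set(table.feature_names)
    if unknown:
        raise ValueError(f"unknown features: {sorted(unknown)}")
    y = table.labels
    if y.all() or not y.any():
        raise ValueError("both classes must be present for training")
    X = table.data[names].to_numpy(dtype=float)
    ensemble = _build_ensemble(params, len(names))
    ensemble.fit(X, y.astype(int))
    return BaggedTreeModel(ensemble=ensemble, feature_names=names, params=params)


def predict(
    model: BaggedTreeModel,
    features: pd.DataFrame,
    degenerate: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(labels, scores) per row: score = tree-vote fraction, label =
    score strictly above 0.5; degenerate rows are non-informative with
    score 0 regardless of the trees."""
    missing = set(model.feature_names) - set(features.columns)
    if missing:
        raise ValueError(f"missing features: {sorted(missing)}")
    X = features[model.feature_names].to_numpy(dtype=float)
    scores = model.vote_scores(X)
    if degenerate is not None:
        scores = np.where(np.asarray(degenerate, dtype=bool), 0.0, scores)
    labels = scores > 0.5  # exact tie -> non-informative
    return labels, scores


def classification_metrics(
    tp: int, fp: int, tn: int, fn: int
) -> dict[str, float]:
    """Acc, TPR, TNR, PPV, F1 from confusion counts; undefined ratios
    (zero denominator) are NaN and excluded from downstream medians."""
    total = tp + fp + tn + fn
    if total <= 0:
        raise ValueError("need at least one count")

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else float("nan")

    acc = (tp + tn) / total
    tpr = ratio(tp, tp + fn)
    tnr = ratio(tn, tn + fp)
    ppv = ratio(tp, tp + fp)
    if np.isnan(tpr) or np.isnan(ppv) or (tpr + ppv) == 0:
        f1 = float("nan")
    else:
        f1 = 2 * ppv * tpr / (ppv + tpr)
    return {"Acc": acc, "TPR": tpr, "TNR": tnr, "PPV": ppv, "F1": f1}


@dataclass
class CVResult:
    """Per-partition metrics (n_repeats x n_folds rows) plus summaries."""

    partitions: pd.DataFrame
    scheme: CVScheme

    def summary(self) -> pd.DataFrame:
        """Median and 25th/75th percentiles per metric (NaN-aware)."""
        rows = {}
        for m in ("Acc", "TPR", "TNR", "PPV", "F1"):
            v = self.partitions[m].to_numpy(dtype=float)
            rows[m] = {
                "median": float(np.nanmedian(v)),
                "q25": float(np.nanpercentile(v, 25)),
                "q75": float(np.nanpercentile(v, 75)),
            }
        return pd.DataFrame(rows).T

    def median(self, metric: str) -> float:
        return float(np.nanmedian(self.partitions[metric].to_numpy(dtype=float)))


def cross_validate(
    table: LabelledFeatureTable,
    params: EnsembleParams = EnsembleParams(),
    scheme: CVScheme = CVScheme(),
    feature_subset: list[str] | None = None,
) -> CVResult:
    """Stratified n-repeat n-fold CV; one confusion matrix per partition.

    Each repeat draws a fresh stratified partition (seeded from
    ``scheme.seed``); each partition trains its own ensemble (seeded from
    ``params.seed`` plus the partition index), so fixed seeds give a
    bit-identical result.
    """
    y = table.labels.astype(int)
    n_pos, n_neg = table.class_counts()
    if min(n_pos, n_neg) < scheme.n_folds:
        raise ValueError("need at least n_folds rows per class")
    names = list(feature_subset) if feature_subset else list(table.feature_names)
    X = table.data[names].to_numpy(dtype=float)
    degenerate = table.degenerate

    records = []
    part_idx = 0
    for rep in range(scheme.n_repeats):
        skf = StratifiedKFold(
            n_splits=scheme.n_folds, shuffle=True,
            random_state=(scheme.seed + 10007 * rep) % (2**31),
        )
        for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
            ensemble = _build_ensemble(
                EnsembleParams(
                    n_learners=params.n_learners,
                    max_splits_per_tree=params.max_splits_per_tree,
                    bootstrap=params.bootstrap,
                    features_per_split=params.features_per_split,
                    seed=params.seed + part_idx,
                ),
                len(names),
            )
            ensemble.fit(X[train_idx], y[train_idx])
            model = BaggedTreeModel(ensemble, names, params)
            scores = model.vote_scores(X[test_idx])
            scores = np.where(degenerate[test_idx], 0.0, scores)
            pred = scores > 0.5
            truth = y[test_idx].astype(bool)
            tp = int(np.sum(pred & truth))
            fp = int(np.sum(pred & ~truth))
            tn = int(np.sum(~pred & ~truth))
            fn = int(np.sum(~pred & truth))
            rec = {"repeat": rep, "fold": fold, "tp": tp, "fp": fp,
                   "tn": tn, "fn": fn}
            rec.update(classification_metrics(tp, fp, tn, fn))
            records.append(rec)
            part_idx += 1
    return CVResult(partitions=pd.DataFrame(records), scheme=scheme)


@dataclass
class ChannelSelection:
    """Outcome of channel-level quality screening of one recording."""

    selected: list[int]  # abdominal channel indices, strict-majority vote
    vote_fraction: dict[int, float]  # informative-segment fraction per channel
    n_segments: int


def select_channels(
    model: BaggedTreeModel,
    rec: MultichannelRecording,
    preset: PreprocessPreset = TRAIN_PRESET,
) -> ChannelSelection:
    """Screen every abdominal channel of a raw recording.

    The recording is resampled and high-pass filtered per the preset,
    each channel cut into 5-s segments, each segment scored by the
    ensemble; a channel is selected iff a strict majority of its segments
    is predicted informative.  An empty selection is a valid outcome.
    """
    if rec.duration < 5.0:
        raise ValueError("recording must be at least 5 s long")
    if not rec.abdominal_indices:
        raise ValueError("recording has no abdominal channels")
    pre = preprocess_recording(rec, preset)
    selected = []
    fractions: dict[int, float] = {}
    n_segments = 0
    for ch in pre.abdominal_indices:
        segments = segment_channel(pre.samples[ch], pre.fs, channel_index=ch)
        n_segments = len(segments)
        vectors = [compute_sqi_vector(s) for s in segments]
        feats = pd.DataFrame([v.to_dict() for v in vectors])
        degenerate = np.array([v.degenerate for v in vectors])
        labels, _ = predict(model, feats, degenerate)
        fractions[ch] = float(np.mean(labels))
        if labels.sum() > len(labels) / 2:
            selected.append(ch)
    return ChannelSelection(selected=selected, vote_fraction=fractions,
                            n_segments=n_segments)


def save_model(model: BaggedTreeModel, path: str | Path) -> Path:
    """Versioned binary dump (round-trips to identical predictions)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)
    return path


def load_model(path: str | Path) -> BaggedTreeModel:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError("unsupported model format version")
    return payload["model"]
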