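"""Resampling-based feature scoring and selection.

Each feature (one similarity network) is scored per class by counting the
resampling rounds in which it earns a positive fitted network weight for a
query drawn from that class's training members. Features reaching the
selection threshold (default 9 of 10 rounds) are carried into
classification. A multi-split consistency summary reports, per feature, the
highest score attained in at least a given fraction of train/test splits.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import SimilarityNetwork, validate_labels
from .integration import QuerySpec, fit_network_weights

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSelectionConfig",
    "FeatureScoreTable",
    "resample_query",
    "score_features",
    "select_features",
    "consistency_across_splits",
]


@dataclass
class FeatureSelectionConfig:
    """Resampling parameters for feature scoring.

    ``n_rounds`` queries are run per class, each using a without-replacement
    subsample of ``query_fraction`` of the class's training members; a
    feature is selected when its score reaches ``selection_threshold``.
    """

    n_rounds: int = 10
    query_fraction: float = 0.8
    selection_threshold: int = 9
    rng_seed: int = 0
    ridge_lambda: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.query_fraction < 1):
            raise ValueError("query_fraction must be in (0, 1)")
        if not (1 <= self.selection_threshold <= self.n_rounds):
            raise ValueError("selection_threshold must be in 1..n_rounds")


@dataclass
class FeatureScoreTable:
    """Integer scores (0..n_rounds) per feature and class."""

    scores: pd.DataFrame  # index: feature, columns: class labels
    n_rounds: int

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy()
        if vals.size and (vals.min() < 0 or vals.max() > self.n_rounds):
            raise ValueError("scores must lie in 0..n_rounds")

    def to_frame(self) -> pd.DataFrame:
        """Long form: one (class, feature, score) row per pair."""
        long = self.scores.stack().rename("score").reset_index()
        long.columns = ["feature", "class", "score"]
        return long[["class", "feature", "score"]].sort_values(
            ["class", "feature"], ignore_index=True
        )


def _class_stream_seed(master_seed: int, label: str) -> int:
    """Stable per-class seed so scores do not depend on class iteration order."""
    digest = hashlib.sha256(label.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def resample_query(
    class_train_ids: Sequence[str],
    fraction: float,
    rng: np.random.Generator,
) -> list[str]:
    """Without-replacement subsample of size round(fraction * n), minimum two."""
    ids = list(class_train_ids)
    if len(ids) < 3:
        raise ValueError(f"class has only {len(ids)} training members; need >= 3")
    size = max(2, int(round(fraction * len(ids))))
    size = min(size, len(ids) - 1)  # keep at least one non-query class member
    chosen = rng.choice(len(ids), size=size, replace=False)
    return sorted(ids[i] for i in chosen)


def score_features(
    nets: Sequence[SimilarityNetwork],
    train_ids: Sequence[str],
    labels: Mapping[str, str] | pd.Series,
    cfg: FeatureSelectionConfig,
) -> FeatureScoreTable:
    """Count, per class, the rounds in which each feature gets positive weight.

    Networks are restricted to the training patients before any query is
    run, so held-out patients can never influence feature scores. Rounds in
    which no feature receives positive weight contribute zero everywhere.
    """
    labels = validate_labels(labels)
    train_ids = [str(i) for i in train_ids]
    unlabeled = [i for i in train_ids if i not in labels.index]
    if unlabeled:
        raise ValueError(f"training patients without labels: {unlabeled[:5]}")
    train_nets = [n.subset(train_ids) for n in nets]
    names = [n.name for n in train_nets]
    classes = sorted(labels.loc[train_ids].unique())
    scores = pd.DataFrame(0, index=names, columns=classes, dtype=int)
    for label in classes:
        members = [i for i in train_ids if labels[i] == label]
        rng = np.random.default_rng([cfg.rng_seed, _class_stream_seed(cfg.rng_seed, label)])
        for round_idx in range(cfg.n_rounds):
            query = resample_query(members, cfg.query_fraction, rng)
            spec = QuerySpec(tuple(query), tuple(train_ids))
            fit = fit_network_weights(train_nets, spec, ridge_lambda=cfg.ridge_lambda)
            if not fit.weights:
                logger.info(
                    "class %r round %d: no feature with positive weight", label, round_idx
                )
                continue
            for feat in fit.weights:
                scores.loc[feat, label] += 1
    return FeatureScoreTable(scores, cfg.n_rounds)


def select_features(
    scores: FeatureScoreTable, threshold: int
) -> dict[str, tuple[str, ...]]:
    """Per class, the features scoring at least ``threshold`` (possibly none)."""
    if threshold > scores.n_rounds:
        raise ValueError("threshold exceeds the number of rounds")
    out: dict[str, tuple[str, ...]] = {}
    for label in scores.scores.columns:
        col = scores.scores[label]
        out[label] = tuple(sorted(col.index[col >= threshold]))
    return out


def consistency_across_splits(
    per_split_scores: Sequence[FeatureScoreTable],
    min_fraction: float = 0.7,
    score_floor: int | None = None,
) -> pd.DataFrame:
    """Summarize feature scores across train/test splits.

    For each (class, feature), ``consistency`` is the largest score s such
    that the feature attains >= s in at least ``min_fraction`` of splits;
    ``max_in_all_splits`` flags features attaining the maximum possible
    score in every split. With ``score_floor`` given, ``passes_floor``
    marks consistency >= score_floor.
    """
    if len(per_split_scores) < 2:
        raise ValueError("need at least two splits")
    n_rounds = per_split_scores[0].n_rounds
    if any(t.n_rounds != n_rounds for t in per_split_scores):
        raise ValueError("splits disagree on the number of rounds")
    frames = [t.scores for t in per_split_scores]
    features = sorted(set().union(*(set(f.index) for f in frames)))
    classes = sorted(set().union(*(set(f.columns) for f in frames)))
    rows = []
    n_splits = len(frames)
    for label in classes:
        for feat in features:
            vals = np.array(
                [f.loc[feat, label] if (feat in f.index and label in f.columns) else 0
                 for f in frames]
            )
            consistency = 0
            for s in range(n_rounds, -1, -1):
                if (vals >= s).sum() / n_splits >= min_fraction:
                    consistency = s
                    break
            row = {
                "class": label,
                "feature": feat,
                "consistency": consistency,
                "max_in_all_splits": bool((vals == n_rounds).all()),
            }
            if score_floor is not None:
                row["passes_floor"] = consistency >= score_floor
            rows.append(row)
    return pd.DataFrame(rows)
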