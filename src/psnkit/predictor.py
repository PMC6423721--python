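"""End-to-end supervised workflow.

For each stratified train/test split: optionally impute and lasso-prefilter
within the split (training statistics only, so nothing leaks from the test
partition), build per-feature similarity networks on training patients,
score features by resampled network weighting, select features per class,
rebuild the selected networks over train + test, classify held-out patients
by label propagation rank, and report AUROC / AUPR / accuracy per split and
aggregated.

Classification compares, per test patient, the normalized propagation rank
obtained from each class's integrated network (ranks are comparable across
class databases where raw propagation scores are not); the predicted label
is the class with the highest normalized rank, ties broken by the
lexicographically smallest label.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import average_precision_score, roc_auc_score

from .containers import GeneSetCollection, PatientDataLayer, SimilarityNetwork, validate_labels
from .integration import QuerySpec, combine_networks, label_bias, propagate_labels
from .scoring import FeatureScoreTable, FeatureSelectionConfig, score_features, select_features
from .similarity import (
    SparsifierConfig,
    build_datatype_network,
    build_pathway_networks,
    build_variable_networks,
    sparsify,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PredictorConfig",
    "SplitResult",
    "PredictionReport",
    "stratified_split",
    "impute_missing",
    "lasso_prefilter",
    "build_feature_networks",
    "build_class_database",
    "classify",
    "evaluate",
    "run_predictor",
]


@dataclass
class PredictorConfig:
    """Workflow parameters (defaults follow the standard predictor design)."""

    train_fraction: float = 0.8
    n_splits: int = 20
    feature_mode: str = "datatype"  # datatype | pathway | variable
    prefilter: bool = False
    impute: bool = False
    n_rounds: int = 10
    query_fraction: float = 0.8
    selection_threshold: int = 9
    ridge_lambda: float = 1.0
    prop_lambda: float = 1.0
    sparsifier: SparsifierConfig = field(default_factory=SparsifierConfig)
    pathway_size_bounds: tuple[int, int] = (10, 200)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")
        if self.feature_mode not in ("datatype", "pathway", "variable"):
            raise ValueError(f"unknown feature_mode {self.feature_mode!r}")


def _derived_seed(master: int, *tags: int) -> int:
    """Deterministic child seed below 2**31."""
    return int(np.random.default_rng([int(master), *map(int, tags)]).integers(2**31))


def stratified_split(
    labels: pd.Series,
    train_fraction: float,
    rng: np.random.Generator,
) -> tuple[list[str], list[str]]:
    """Per-class random split preserving class proportions to rounding."""
    labels = validate_labels(labels)
    train: list[str] = []
    test: list[str] = []
    for cls in sorted(labels.unique()):
        members = sorted(labels.index[labels == cls])
        if len(members) < 3:
            raise ValueError(f"class {cls!r} has fewer than three members")
        n_train = int(round(train_fraction * len(members)))
        n_train = min(max(n_train, 2), len(members) - 1)
        perm = rng.permutation(len(members))
        train.extend(members[i] for i in perm[:n_train])
        test.extend(members[i] for i in perm[n_train:])
    return sorted(train), sorted(test)


def impute_missing(
    train: PatientDataLayer, test: PatientDataLayer
) -> tuple[PatientDataLayer, PatientDataLayer]:
    """Median-impute with training-partition statistics only.

    Test entries are filled with training medians, never test medians, so no
    information flows from the held-out partition. Variables fully missing
    in training are dropped from both partitions with a warning.
    """
    medians = train.data.median(axis=0, skipna=True)
    dead = medians.index[medians.isna()]
    if len(dead):
        warnings.warn(
            f"layer {train.name!r}: dropping fully missing variables {list(dead)}"
        )
    keep = [v for v in train.variable_ids if v not in set(dead)]
    tr = train.data[keep].fillna(medians[keep])
    te = test.data[keep].fillna(medians[keep])
    return PatientDataLayer(train.name, tr), PatientDataLayer(test.name, te)


def lasso_prefilter(
    train: PatientDataLayer,
    train_labels: pd.Series,
    seed: int = 0,
    n_penalties: int = 10,
    cv_folds: int = 3,
) -> list[str]:
    """Variables with non-zero coefficient in an L1-penalized logistic model.

    The model is fit on standardized training data with the penalty chosen
    by internal cross-validation on training patients only. Returns the
    retained variable names (possibly empty, in which case the caller omits
    the layer for this split).
    """
    y = validate_labels(train_labels).loc[train.patient_ids]
    classes = sorted(y.unique())
    if len(classes) != 2:
        raise ValueError("lasso prefilter requires binary class labels")
    X = train.data.to_numpy(dtype=float)
    if np.isnan(X).any():
        col_med = np.nanmedian(X, axis=0)
        X = np.where(np.isnan(X), col_med[None, :], X)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    yv = (y == classes[1]).astype(int).to_numpy()
    model = LogisticRegressionCV(
        Cs=np.logspace(-2, 2, n_penalties),
        cv=min(cv_folds, int(np.bincount(yv).min())),
        penalty="l1",
        solver="liblinear",
        random_state=seed,
        max_iter=2000,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        model.fit(Xs, yv)
    coef = model.coef_.ravel()
    return [v for v, c in zip(train.variable_ids, coef) if c != 0.0]


def build_feature_networks(
    layers: Sequence[PatientDataLayer],
    patient_ids: Sequence[str],
    cfg: PredictorConfig,
    gene_sets: GeneSetCollection | None = None,
    pathway_layer: str | None = None,
    feature_names: Iterable[str] | None = None,
) -> list[SimilarityNetwork]:
    """Build (and sparsify) the feature networks over the given patients.

    In pathway mode the designated expression layer (default: the first
    layer) yields one network per surviving gene set while remaining layers
    contribute data-type networks; datatype mode yields one network per
    layer; variable mode one normalized-similarity network per variable.
    ``feature_names`` restricts the result (order follows construction).
    """
    patient_ids = [str(p) for p in patient_ids]
    nets: list[SimilarityNetwork] = []
    if cfg.feature_mode == "pathway":
        if gene_sets is None:
            raise ValueError("pathway mode requires a gene set collection")
        target = pathway_layer or layers[0].name
    for layer in layers:
        sub = layer.subset_patients(patient_ids)
        if cfg.feature_mode == "pathway" and layer.name == target:
            nets.extend(build_pathway_networks(sub, gene_sets, cfg.pathway_size_bounds))
        elif cfg.feature_mode == "variable":
            nets.extend(build_variable_networks(sub))
        else:
            nets.append(build_datatype_network(sub))
    if feature_names is not None:
        wanted = set(feature_names)
        missing = wanted - {n.name for n in nets}
        if missing:
            raise KeyError(f"unknown features requested: {sorted(missing)[:5]}")
        nets = [n for n in nets if n.name in wanted]
    return [sparsify(n, cfg.sparsifier) for n in nets]


def build_class_database(
    selected: Mapping[str, Sequence[str]],
    all_features: Sequence[str],
    builder,
) -> tuple[dict[str, list[SimilarityNetwork]], list[str]]:
    """Per class, the selected networks rebuilt over train + test patients.

    ``builder(feature_names)`` must return sparsified networks over the full
    (train + test) patient set. Classes whose selection is empty fall back
    to all features, loudly. Returns the databases and the fallback classes.
    """
    fallback: list[str] = []
    needed: set[str] = set()
    resolved: dict[str, tuple[str, ...]] = {}
    for cls, feats in selected.items():
        feats = tuple(feats)
        if not feats:
            warnings.warn(
                f"class {cls!r}: no feature passed selection; falling back to all features"
            )
            fallback.append(cls)
            feats = tuple(all_features)
        resolved[cls] = feats
        needed.update(feats)
    built = {n.name: n for n in builder(sorted(needed))}
    databases = {cls: [built[f] for f in feats] for cls, feats in resolved.items()}
    return databases, fallback


def classify(
    test_ids: Sequence[str],
    class_databases: Mapping[str, Sequence[SimilarityNetwork]],
    train_labels: pd.Series,
    prop_lambda: float = 1.0,
) -> pd.DataFrame:
    """Assign each test patient to the class of highest normalized rank.

    For every class the selected networks are combined by uniform averaging
    and a label-propagation query is run from all training members of that
    class; each patient's rank is rescaled to [0, 1]. For binary problems
    the continuous decision score is r_positive - r_negative with the
    lexicographically larger label taken as positive.
    """
    train_labels = validate_labels(train_labels)
    classes = sorted(class_databases)
    norm_ranks: dict[str, dict[str, float]] = {}
    for cls in classes:
        nets = list(class_databases[cls])
        if not nets:
            raise ValueError(f"class {cls!r}: empty network database")
        combined = combine_networks(nets, name=f"class:{cls}")
        members = tuple(sorted(train_labels.index[train_labels == cls]))
        spec = QuerySpec(members, tuple(combined.nodes))
        result = propagate_labels(combined, label_bias(spec), prop_lambda)
        norm_ranks[cls] = result.normalized_ranks()
    rows = []
    for pid in test_ids:
        ranks = {cls: norm_ranks[cls][pid] for cls in classes}
        best = max(ranks.values())
        pred = min(c for c in classes if ranks[c] == best)
        row = {"patient": pid, "predicted": pred}
        row.update({f"rank_{c}": ranks[c] for c in classes})
        if len(classes) == 2:
            row["score"] = ranks[classes[1]] - ranks[classes[0]]
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient")


def evaluate(
    scores: Sequence[float],
    true_labels: Sequence[str],
    pos_label: str,
    predicted: Sequence[str] | None = None,
) -> dict[str, float]:
    """AUROC (ties count 1/2), AUPR (step integration), and accuracy."""
    truth = np.asarray([t == pos_label for t in true_labels])
    if truth.all() or not truth.any():
        raise ValueError("AUROC undefined: test truth contains a single class")
    scores = np.asarray(scores, dtype=float)
    out = {
        "auroc": float(roc_auc_score(truth, scores)),
        "aupr": float(average_precision_score(truth, scores)),
    }
    if predicted is not None:
        out["accuracy"] = float(np.mean(np.asarray(predicted) == np.asarray(true_labels)))
    return out


@dataclass
class SplitResult:
    split_index: int
    train_ids: list[str]
    test_ids: list[str]
    score_table: FeatureScoreTable
    selected: dict[str, tuple[str, ...]]
    fallback_classes: list[str]
    predictions: pd.DataFrame
    metrics: dict[str, float]


@dataclass
class PredictionReport:
    """Per-split results plus aggregate mean/SD metrics."""

    splits: list[SplitResult]
    classes: list[str]
    pos_label: str
    config: PredictorConfig

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"split": s.split_index, **s.metrics} for s in self.splits]
        ).set_index("split")

    def summary(self) -> dict[str, float]:
        frame = self.metrics_frame()
        out: dict[str, float] = {}
        for col in frame.columns:
            out[f"mean_{col}"] = float(frame[col].mean())
            out[f"sd_{col}"] = float(frame[col].std(ddof=1)) if len(frame) > 1 else 0.0
        return out

    def score_tables(self) -> list[FeatureScoreTable]:
        return [s.score_table for s in self.splits]

    def to_text(self) -> str:
        """Canonical serialization (used for reproducibility checks)."""
        parts = []
        for s in self.splits:
            parts.append(f"# split {s.split_index}")
            parts.append("train\t" + ",".join(s.train_ids))
            parts.append("test\t" + ",".join(s.test_ids))
            parts.append(s.score_table.to_frame().to_csv(sep="\t", index=False))
            for cls in sorted(s.selected):
                parts.append(f"selected\t{cls}\t" + ",".join(s.selected[cls]))
            parts.append(s.predictions.round(12).to_csv(sep="\t"))
            parts.append(json.dumps(s.metrics, sort_keys=True))
        parts.append(json.dumps(self.summary(), sort_keys=True))
        return "\n".join(parts)


def run_predictor(
    layers: Sequence[PatientDataLayer],
    labels: pd.Series,
    cfg: PredictorConfig,
    gene_sets: GeneSetCollection | None = None,
    pathway_layer: str | None = None,
) -> PredictionReport:
    """Run the full resampled train/test workflow and aggregate metrics.

    Fully reproducible from ``cfg.master_seed``: the split, every resampling
    round, and the prefilter all draw from seeds derived from it. A failed
    split is reported with a warning and excluded from aggregates.
    """
    labels = validate_labels(labels)
    labeled = set(labels.index)
    for layer in layers:
        missing = labeled - set(layer.patient_ids)
        if missing:
            raise ValueError(
                f"layer {layer.name!r} lacks labeled patients {sorted(missing)[:5]}"
            )
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise NotImplementedError("only binary classification is supported")
    pos_label = classes[1]
    splits: list[SplitResult] = []
    for split_idx in range(cfg.n_splits):
        try:
            splits.append(
                _run_split(layers, labels, cfg, gene_sets, pathway_layer, split_idx, pos_label)
            )
        except Exception as exc:  # noqa: BLE001 - a failed split must not kill the run
            warnings.warn(f"split {split_idx} failed and is excluded: {exc}")
    if not splits:
        raise RuntimeError("all splits failed")
    return PredictionReport(splits, classes, pos_label, cfg)


def _run_split(
    layers: Sequence[PatientDataLayer],
    labels: pd.Series,
    cfg: PredictorConfig,
    gene_sets: GeneSetCollection | None,
    pathway_layer: str | None,
    split_idx: int,
    pos_label: str,
) -> SplitResult:
    rng = np.random.default_rng([cfg.master_seed, 7, split_idx])
    train_ids, test_ids = stratified_split(labels, cfg.train_fraction, rng)
    logger.info("split %d: %d train / %d test", split_idx, len(train_ids), len(test_ids))

    prepared: list[PatientDataLayer] = []
    for layer_idx, layer in enumerate(layers):
        tr = layer.subset_patients(train_ids)
        te = layer.subset_patients(test_ids)
        if cfg.impute:
            tr, te = impute_missing(tr, te)
        if cfg.prefilter:
            retained = lasso_prefilter(
                tr, labels.loc[train_ids], seed=_derived_seed(cfg.master_seed, 13, split_idx, layer_idx)
            )
            if not retained:
                logger.info(
                    "split %d: layer %r empty after prefilter, omitted", split_idx, layer.name
                )
                continue
            tr = tr.subset_variables(retained)
            te = te.subset_variables(retained)
        prepared.append(
            PatientDataLayer(layer.name, pd.concat([tr.data, te.data], axis=0))
        )
    if not prepared:
        raise RuntimeError("no layer survived preparation")

    train_layers = [p.subset_patients(train_ids) for p in prepared]
    train_nets = build_feature_networks(
        train_layers, train_ids, cfg, gene_sets, pathway_layer
    )
    fs_cfg = FeatureSelectionConfig(
        n_rounds=cfg.n_rounds,
        query_fraction=cfg.query_fraction,
        selection_threshold=cfg.selection_threshold,
        rng_seed=_derived_seed(cfg.master_seed, 11, split_idx),
        ridge_lambda=cfg.ridge_lambda,
    )
    score_table = score_features(train_nets, train_ids, labels.loc[train_ids], fs_cfg)
    selected = select_features(score_table, cfg.selection_threshold)

    all_ids = train_ids + test_ids
    databases, fallback = build_class_database(
        selected,
        [n.name for n in train_nets],
        lambda feats: build_feature_networks(
            prepared, all_ids, cfg, gene_sets, pathway_layer, feature_names=feats
        ),
    )
    predictions = classify(test_ids, databases, labels.loc[train_ids], cfg.prop_lambda)
    truth = labels.loc[predictions.index]
    metrics = evaluate(
        predictions["score"], truth, pos_label, predicted=predictions["predicted"]
    )
    return SplitResult(
        split_idx,
        list(train_ids),
        list(test_ids),
        score_table,
        selected,
        fallback,
        predictions,
        metrics,
    )
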