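"""Supervised classification of pathway instances.

The learner is a random forest over the per-season topological feature
vectors.  Positives are pathways known in the target organism; negatives
combine pathways from foreign collections with randomly drawn metabolite
sets (negative sampling), so the forest also sees uncorrelated node groups.
Feature relevance is ranked by information gain after supervised
discretization; validation uses stratified k-fold CV or LOOCV with pooled
out-of-fold predictions, and stability is probed by retraining on repeated
80% subsamples (sensitivity analysis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .catalog import FeatureCatalog
from .graphfeat import FeatureVector, NetworkFeatureCache, featurize
from .netbuild import CorrelationNetwork
from .pathmap import PathwayInstance, generate_random_sets

__all__ = [
    "TrainingSet",
    "ForestConfig",
    "ForestModel",
    "PerformanceReport",
    "PredictionRecord",
    "auto_m_try",
    "assemble_training_set",
    "info_gain_rank",
    "train_forest",
    "evaluate",
    "compute_metrics",
    "rank_auc",
    "predict",
    "sensitivity_analysis",
    "rank_against_random",
    "load_feature_table",
    "save_feature_table",
]

POSITIVE, NEGATIVE = 1, 0


@dataclass
class TrainingSet:
    """Labeled feature matrix; rows align with ``ids`` and ``provenance``."""

    x: np.ndarray
    y: np.ndarray  # 1 = positive, 0 = negative
    ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    provenance: tuple[str, ...]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if not (self.x.shape[0] == len(self.y) == len(self.ids) == len(self.provenance)):
            raise ValueError("rows, labels, ids and provenance must align")
        if self.x.shape[1] != len(self.feature_names):
            raise ValueError("columns must match feature names")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate instance ids")

    @property
    def n_positive(self) -> int:
        return int((self.y == POSITIVE).sum())

    @property
    def n_negative(self) -> int:
        return int((self.y == NEGATIVE).sum())

    def subset_features(self, names: Sequence[str]) -> "TrainingSet":
        index = {n: i for i, n in enumerate(self.feature_names)}
        cols = [index[n] for n in names]
        return TrainingSet(self.x[:, cols], self.y.copy(), self.ids,
                           tuple(names), self.provenance)


@dataclass
class ForestConfig:
    n_trees: int = 100
    m_try: int | None = None  # None = floor(log2(n_features)) + 1
    seed: int = 0
    split_criterion: str = "entropy"  # information gain; "gini" configurable

    def resolve_m_try(self, n_features: int) -> int:
        m = self.m_try if self.m_try is not None else auto_m_try(n_features)
        if not (1 <= m <= n_features):
            raise ValueError(f"m_try {m} outside [1, {n_features}]")
        return m


def auto_m_try(n_features: int) -> int:
    """Default number of candidate features per split: floor(log2(d)) + 1."""
    if n_features < 1:
        raise ValueError("need at least one feature")
    return int(math.floor(math.log2(n_features))) + 1


@dataclass
class ForestModel:
    estimator: RandomForestClassifier
    feature_names: tuple[str, ...]
    config: ForestConfig
    manifest_hash: str | None = None

    def vote_fraction(self, x: np.ndarray) -> np.ndarray:
        """Prediction value: fraction of trees voting for the positive class."""
        x = np.asarray(x, dtype=float)
        votes = np.zeros(x.shape[0])
        for tree in self.estimator.estimators_:
            votes += (tree.predict(x) == POSITIVE)
        return votes / len(self.estimator.estimators_)


@dataclass
class PerformanceReport:
    per_class: dict
    weighted: dict
    counts: dict  # tp, fn, fp, tn
    auc: float
    accuracy: float
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    scores: np.ndarray | None = None
    labels: np.ndarray | None = None

    @property
    def n_correct(self) -> int:
        return self.counts["tp"] + self.counts["tn"]

    @property
    def n_incorrect(self) -> int:
        return self.counts["fp"] + self.counts["fn"]


@dataclass
class PredictionRecord:
    pathway_id: str
    prediction_value: float
    predicted_class: int
    threshold: float = 0.5
    sensitivity_mean: float | None = None
    sensitivity_variance: float | None = None

    @property
    def conform(self) -> bool | None:
        """Does the subsample-average class agree with the original class?"""
        if self.sensitivity_mean is None:
            return None
        return (self.sensitivity_mean >= self.threshold) == \
               (self.prediction_value >= self.threshold)


# ---------------------------------------------------------------------------
# training-set assembly


def assemble_training_set(
    positives: Sequence[FeatureVector],
    candidate_negatives: Sequence[FeatureVector],
    common: set[str],
    networks: Sequence[CorrelationNetwork],
    catalog: FeatureCatalog,
    seed: int = 0,
    size_min: int = 2,
    size_max: int = 18,
    exclude_sets: Iterable[Iterable[str]] | None = None,
    caches: Mapping[str, NetworkFeatureCache] | None = None,
) -> TrainingSet:
    """Balance positives against sampled collection negatives + random sets.

    With n positives, k = ceil(n/2) negatives are sampled without
    replacement from the candidate collection and another k random
    metabolite sets (sizes ``size_min``..``size_max``) are generated and
    featurized on the fly, giving 2k negatives in total.
    """
    if not positives:
        raise ValueError("no positive instances")
    rng = np.random.default_rng(seed)
    k = math.ceil(len(positives) / 2)
    if len(candidate_negatives) < k:
        raise ValueError(f"need at least {k} candidate negatives, got {len(candidate_negatives)}")
    order = rng.permutation(len(candidate_negatives))[:k]
    sampled = [candidate_negatives[i] for i in sorted(order)]
    random_sets = generate_random_sets(common, k, size_min, size_max, seed=rng,
                                       exclude=exclude_sets, id_prefix="NONPATH")
    random_vectors = [featurize(inst, networks, catalog, caches) for inst in random_sets]
    rows = list(positives) + sampled + random_vectors
    labels = [POSITIVE] * len(positives) + [NEGATIVE] * (len(sampled) + len(random_vectors))
    provenance = (["positive_collection"] * len(positives)
                  + ["negative_collection"] * len(sampled)
                  + ["random"] * len(random_vectors))
    names = rows[0].names
    for vec in rows:
        if vec.names != names:
            raise ValueError(f"feature order mismatch for {vec.instance_id}")
    return TrainingSet(np.vstack([v.values for v in rows]), np.array(labels),
                       tuple(v.instance_id for v in rows), names, tuple(provenance))


# ---------------------------------------------------------------------------
# information gain with supervised discretization


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _class_counts(y: np.ndarray) -> np.ndarray:
    return np.array([(y == NEGATIVE).sum(), (y == POSITIVE).sum()], dtype=float)


def _mdl_split(x: np.ndarray, y: np.ndarray, cuts: list[float]) -> None:
    """Fayyad-Irani recursive binary splitting with the MDL stop criterion."""
    n = len(y)
    if n < 2:
        return
    distinct = np.unique(x)
    if len(distinct) < 2:
        return
    base_counts = _class_counts(y)
    base_ent = _entropy(base_counts)
    best_gain, best_cut, best_parts = -1.0, None, None
    for i in range(len(distinct) - 1):
        cut = (distinct[i] + distinct[i + 1]) / 2.0
        left = x <= cut
        ent_l = _entropy(_class_counts(y[left]))
        ent_r = _entropy(_class_counts(y[~left]))
        nl = left.sum()
        gain = base_ent - (nl / n) * ent_l - ((n - nl) / n) * ent_r
        if gain > best_gain:
            best_gain, best_cut, best_parts = gain, cut, (left, ent_l, ent_r)
    if best_cut is None:
        return
    left, ent_l, ent_r = best_parts
    k = int((base_counts > 0).sum())
    k_l = int((_class_counts(y[left]) > 0).sum())
    k_r = int((_class_counts(y[~left]) > 0).sum())
    delta = math.log2(3 ** k - 2) - (k * base_ent - k_l * ent_l - k_r * ent_r)
    threshold = (math.log2(n - 1) + delta) / n
    if best_gain <= threshold:
        return
    cuts.append(float(best_cut))
    _mdl_split(x[left], y[left], cuts)
    _mdl_split(x[~left], y[~left], cuts)


#: Features with at most this many distinct values are treated as already
#: discrete and used as categories directly (no MDL binning).
MAX_CATEGORICAL_VALUES = 5


def information_gain(x: np.ndarray, y: np.ndarray,
                     method: str = "mdl") -> float:
    """Class-entropy reduction (bits) of one feature after discretization."""
    x = np.asarray(x, dtype=float)
    distinct = np.unique(x)
    if len(distinct) <= 1:
        return 0.0
    if len(distinct) <= MAX_CATEGORICAL_VALUES:
        bins = np.searchsorted(distinct, x)
    elif method == "mdl":
        cuts: list[float] = []
        _mdl_split(x, y, cuts)
        if not cuts:
            return 0.0
        bins = np.digitize(x, sorted(cuts))
    elif method == "equal_frequency":
        quantiles = np.quantile(x, np.linspace(0, 1, 11)[1:-1])
        bins = np.digitize(x, np.unique(quantiles))
    else:
        raise ValueError(f"unknown discretization method {method!r}")
    base = _entropy(_class_counts(y))
    cond = 0.0
    n = len(y)
    for b in np.unique(bins):
        sel = bins == b
        cond += (sel.sum() / n) * _entropy(_class_counts(y[sel]))
    return max(0.0, base - cond)


def info_gain_rank(training: TrainingSet, method: str = "mdl") -> list[tuple[str, float]]:
    """All features ranked by information gain, ties broken by catalog order."""
    if training.n_positive < 2 or training.n_negative < 2:
        raise ValueError("need at least 2 instances per class")
    gains = [(name, information_gain(training.x[:, i], training.y, method))
             for i, name in enumerate(training.feature_names)]
    order = sorted(range(len(gains)), key=lambda i: (-gains[i][1], i))
    return [gains[i] for i in order]


def top_features(ranked: Sequence[tuple[str, float]], k: int = 20) -> list[str]:
    return [name for name, _ in ranked[:k]]


# ---------------------------------------------------------------------------
# forest training / evaluation


def _make_estimator(config: ForestConfig, n_features: int, oob: bool = False,
                    seed: int | None = None) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.resolve_m_try(n_features),
        criterion=config.split_criterion,
        oob_score=oob,
        bootstrap=True,
        random_state=config.seed if seed is None else seed,
        n_jobs=1,
    )


def train_forest(training: TrainingSet, config: ForestConfig | None = None,
                 manifest_hash: str | None = None) -> tuple[ForestModel, float]:
    """Fit the forest and report its out-of-bag misclassification rate."""
    config = config or ForestConfig()
    if training.n_positive < 2 or training.n_negative < 2:
        raise ValueError("need at least 2 instances per class")
    est = _make_estimator(config, training.x.shape[1], oob=True)
    est.fit(training.x, training.y)
    oob_error = 1.0 - float(est.oob_score_)
    return ForestModel(est, training.feature_names, config, manifest_hash), oob_error


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the Mann-Whitney rank formulation (ties counted half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == POSITIVE]
    neg = scores[labels == NEGATIVE]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC needs both classes")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def roc_points(scores: np.ndarray, labels: np.ndarray) -> list[tuple[float, float]]:
    """(FPR, TPR) sweep over all score thresholds, descending."""
    order = np.argsort(-np.asarray(scores))
    labels = np.asarray(labels)[order]
    scores = np.asarray(scores)[order]
    p = (labels == POSITIVE).sum()
    n = (labels == NEGATIVE).sum()
    pts = [(0.0, 0.0)]
    tp = fp = 0
    for i in range(len(labels)):
        if labels[i] == POSITIVE:
            tp += 1
        else:
            fp += 1
        if i + 1 == len(labels) or scores[i + 1] != scores[i]:
            pts.append((fp / n, tp / p))
    return pts


def _rates(tp: int, fn: int, fp: int, tn: int) -> dict:
    def safe(num, den):
        return num / den if den > 0 else float("nan")
    tpr = safe(tp, tp + fn)
    fpr = safe(fp, fp + tn)
    precision = safe(tp, tp + fp)
    f = (2 * precision * tpr / (precision + tpr)
         if np.isfinite(precision) and np.isfinite(tpr) and (precision + tpr) > 0
         else float("nan"))
    return {"tpr": tpr, "fpr": fpr, "precision": precision, "f_measure": f}


def compute_metrics(tp: int, fn: int, fp: int, tn: int,
                    scores: np.ndarray | None = None,
                    labels: np.ndarray | None = None) -> PerformanceReport:
    """Per-class rates from confusion counts, each class taken as positive.

    The weighted average is the class-size-weighted mean; AUC (identical
    for both classes of a binary problem) is computed from pooled scores
    when provided.
    """
    if min(tp, fn, fp, tn) < 0:
        raise ValueError("counts must be non-negative")
    n_pos, n_neg = tp + fn, fp + tn
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one instance of each class")
    pos = _rates(tp, fn, fp, tn)
    neg = _rates(tn, fp, fn, tp)  # negative class as "positive"
    total = n_pos + n_neg
    weighted = {key: (n_pos * pos[key] + n_neg * neg[key]) / total for key in pos}
    auc = float("nan")
    pts: list[tuple[float, float]] = []
    if scores is not None and labels is not None:
        auc = rank_auc(scores, labels)
        pts = roc_points(scores, labels)
    return PerformanceReport(
        per_class={"positive": pos, "negative": neg},
        weighted=weighted,
        counts={"tp": tp, "fn": fn, "fp": fp, "tn": tn},
        auc=auc,
        accuracy=(tp + tn) / total,
        roc_points=pts,
        scores=None if scores is None else np.asarray(scores, dtype=float),
        labels=None if labels is None else np.asarray(labels, dtype=int),
    )


def evaluate(training: TrainingSet, config: ForestConfig | None = None,
             scheme: str = "kfold", k: int = 10,
             threshold: float = 0.5) -> PerformanceReport:
    """Cross-validated performance with pooled out-of-fold predictions.

    ``scheme`` is ``"kfold"`` (stratified) or ``"loocv"`` (k = n).  Every
    instance receives exactly one out-of-fold prediction value; the pooled
    values yield the confusion counts at the threshold and the ROC/AUC.
    """
    config = config or ForestConfig()
    n = len(training.y)
    if scheme == "loocv":
        splitter = LeaveOneOut()
    elif scheme == "kfold":
        if k > n:
            raise ValueError(f"k={k} exceeds {n} instances")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    scores = np.zeros(n)
    for fold, (train_idx, test_idx) in enumerate(splitter.split(training.x, training.y)):
        est = _make_estimator(config, training.x.shape[1], seed=config.seed + fold)
        est.fit(training.x[train_idx], training.y[train_idx])
        model = ForestModel(est, training.feature_names, config)
        scores[test_idx] = model.vote_fraction(training.x[test_idx])
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == POSITIVE) & (training.y == POSITIVE)).sum())
    fn = int(((pred == NEGATIVE) & (training.y == POSITIVE)).sum())
    fp = int(((pred == POSITIVE) & (training.y == NEGATIVE)).sum())
    tn = int(((pred == NEGATIVE) & (training.y == NEGATIVE)).sum())
    return compute_metrics(tp, fn, fp, tn, scores, training.y)


# ---------------------------------------------------------------------------
# prediction, sensitivity, random ranking


def predict(model: ForestModel, vectors: Sequence[FeatureVector],
            threshold: float = 0.5) -> list[PredictionRecord]:
    """Classify instances; positive at prediction value >= threshold."""
    records = []
    for vec in vectors:
        if vec.names != model.feature_names:
            raise ValueError(f"feature manifest mismatch for {vec.instance_id}")
        value = float(model.vote_fraction(vec.values[None, :])[0])
        records.append(PredictionRecord(vec.instance_id, value,
                                        POSITIVE if value >= threshold else NEGATIVE,
                                        threshold))
    return records


def _stratified_subsample(y: np.ndarray, fraction: float,
                          rng: np.random.Generator) -> np.ndarray:
    idx = []
    for cls in (NEGATIVE, POSITIVE):
        members = np.flatnonzero(y == cls)
        take = max(1, int(round(fraction * len(members))))
        idx.extend(rng.choice(members, size=take, replace=False))
    return np.sort(np.array(idx))


def sensitivity_analysis(
    training: TrainingSet,
    test_vectors: Sequence[FeatureVector],
    config: ForestConfig | None = None,
    iterations: int = 100,
    fraction: float = 0.8,
    seed: int = 0,
    threshold: float = 0.5,
) -> list[PredictionRecord]:
    """Stability of predictions under repeated 80% retraining.

    Each iteration retrains a forest with identical settings on a
    stratified subsample (without replacement) of the training set and
    re-predicts the test instances; records carry the per-instance mean and
    variance over iterations and the conform flag.
    """
    config = config or ForestConfig()
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    if iterations < 2:
        raise ValueError("need at least 2 iterations")
    base_model, _ = train_forest(training, config)
    records = predict(base_model, test_vectors, threshold)
    x_test = np.vstack([v.values for v in test_vectors]) if test_vectors else None
    if x_test is None:
        return records
    rng = np.random.default_rng(seed)
    all_values = np.zeros((iterations, len(test_vectors)))
    for it in range(iterations):
        while True:
            idx = _stratified_subsample(training.y, fraction, rng)
            if len(np.unique(training.y[idx])) == 2:
                break
        est = _make_estimator(config, training.x.shape[1], seed=config.seed + 1 + it)
        est.fit(training.x[idx], training.y[idx])
        model = ForestModel(est, training.feature_names, config)
        all_values[it] = model.vote_fraction(x_test)
    means = all_values.mean(axis=0)
    variances = all_values.var(axis=0, ddof=1)
    for rec, m, v in zip(records, means, variances):
        rec.sensitivity_mean = float(m)
        rec.sensitivity_variance = float(v)
    return records


def rank_against_random(
    model: ForestModel,
    pathway_vectors: Sequence[FeatureVector],
    networks: Sequence[CorrelationNetwork],
    catalog: FeatureCatalog,
    common: set[str],
    n_random: int = 10_000,
    seed: int = 0,
    size_min: int = 2,
    size_max: int = 18,
    caches: Mapping[str, NetworkFeatureCache] | None = None,
    feature_subset: Sequence[str] | None = None,
) -> dict[str, float]:
    """Percentile of each pathway's prediction among random-set predictions.

    The percentile is the fraction of random-set prediction values greater
    than or equal to the pathway's value (ties count).
    """
    if n_random < 100:
        raise ValueError("need at least 100 random sets")
    random_sets = generate_random_sets(common, n_random, size_min, size_max,
                                      seed=seed, id_prefix="RANK")
    random_scores = []
    for inst in random_sets:
        vec = featurize(inst, networks, catalog, caches)
        if feature_subset is not None:
            vec = subset_vector(vec, feature_subset)
        random_scores.append(model.vote_fraction(vec.values[None, :])[0])
    random_scores = np.array(random_scores)
    out = {}
    for vec in pathway_vectors:
        value = model.vote_fraction(vec.values[None, :])[0]
        out[vec.instance_id] = float((random_scores >= value).mean())
    return out


def subset_vector(vector: FeatureVector, names: Sequence[str]) -> FeatureVector:
    index = {n: i for i, n in enumerate(vector.names)}
    cols = [index[n] for n in names]
    return FeatureVector(vector.instance_id, vector.values[cols],
                         vector.missing_mask[cols], tuple(names))


# ---------------------------------------------------------------------------
# feature-table IO (wide delimited table, first column instance id)


def save_feature_table(vectors: Sequence[FeatureVector], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("instance_id\t" + "\t".join(vectors[0].names) + "\n")
        for vec in vectors:
            fh.write(vec.instance_id + "\t"
                     + "\t".join(repr(float(v)) for v in vec.values) + "\n")


def load_feature_table(path: str | Path) -> list[FeatureVector]:
    vectors = []
    with open(path) as fh:
        names = tuple(fh.readline().rstrip("\n").split("\t")[1:])
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            values = np.array([float(v) for v in parts[1:]])
            vectors.append(FeatureVector(parts[0], values,
                                         np.zeros(len(values), dtype=bool), names))
    return vectors


def training_set_from_vectors(
    positives: Sequence[FeatureVector],
    negatives: Sequence[FeatureVector],
    provenance: Sequence[str] | None = None,
) -> TrainingSet:
    rows = list(positives) + list(negatives)
    names = rows[0].names
    labels = [POSITIVE] * len(positives) + [NEGATIVE] * len(negatives)
    if provenance is None:
        provenance = (["positive_collection"] * len(positives)
                      + ["negative_collection"] * len(negatives))
    return TrainingSet(np.vstack([v.values for v in rows]), np.array(labels),
                       tuple(v.instance_id for v in rows), names, tuple(provenance))
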