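"""Scoring of one chromosome by generation-seeded stratified cross-validation.

Each candidate is evaluated with stratified k-fold CV (k=10 by default); the
fold split is reseeded every generation but shared by all solutions of that
generation, so within-generation comparisons are like for like while the
population cannot overfit a single split.  Per fold, an XGBoost classifier
is trained on the decoded feature subset with early stopping monitored on
the validation-fold AUC (patience 50 of at most 500 rounds) and truncated
to its best iteration.

The objective vector holds ten maximized components in [0,1]: eight
classification metrics (accuracy, weighted geometric mean of sensitivity
and specificity, F1, F2, precision, recall, balanced accuracy, AUC) plus
two simplicity metrics (feature complexity and split complexity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xgboost as xgb
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .genome import Chromosome, DecodedModelSpec, HyperparamBounds, decode_features, decode_hyperparams

OBJECTIVE_NAMES = ("accuracy", "wgm", "f1", "f2", "precision", "recall",
                   "balanced_accuracy", "auc", "feature_complexity",
                   "split_complexity")

#: default cap used to map total split-node counts into the [0,1] score
DEFAULT_SPLIT_CAP = 256.0


@dataclass
class CVPlan:
    """One generation's stratified fold assignment (shared by all solutions)."""

    k: int
    seed: int
    folds: list[np.ndarray]  # validation index sets; disjoint, covering 0..n-1

    def splits(self, n: int):
        all_idx = np.arange(n)
        for val in self.folds:
            train = np.setdiff1d(all_idx, val, assume_unique=True)
            yield train, val


def make_cv_plan(y: np.ndarray, k: int, base_seed: int, generation: int) -> CVPlan:
    """Stratified k-fold plan seeded with ``base_seed + generation``.

    Every solution of a generation is evaluated on the same folds; the next
    generation gets a fresh split.
    """
    y = np.asarray(y)
    counts = np.bincount(y)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members < k={k}; use a smaller k")
    seed = int(base_seed) + int(generation)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [val for _, val in skf.split(np.zeros((len(y), 1)), y)]
    return CVPlan(k=k, seed=seed, folds=folds)


# ---------------------------------------------------------------------------
# metrics


def auc_score(y_true: np.ndarray, y_prob: np.ndarray) -> float:
    """Rank-statistic AUC with midrank tie handling.

    Equals the probability that a random positive outranks a random
    negative, counting ties as half.  Returns 0 when only one class is
    present (the degenerate convention used throughout).
    """
    y_true = np.asarray(y_true)
    n_pos = int(np.sum(y_true == 1))
    n_neg = len(y_true) - n_pos
    if n_pos == 0 or n_neg == 0:
        return 0.0
    ranks = rankdata(y_prob)
    return float((ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def wgm(sensitivity: float, specificity: float, w: float = 0.5) -> float:
    """Weighted geometric mean: sensitivity**w * specificity**(1-w).

    With w set to the majority-class proportion the minority-class recall
    carries the larger exponent, rewarding balanced behaviour on
    imbalanced data.
    """
    if not (0.0 <= w <= 1.0):
        raise ValueError("w must be in [0,1]")
    s, p = float(sensitivity), float(specificity)
    if w == 1.0:
        return s
    if w == 0.0:
        return p
    return s ** w * p ** (1.0 - w)


def feature_complexity(n_active: int, p: int) -> float:
    """Simplicity score 1 - n_active/p: fewer active features score higher."""
    if not 0 <= n_active <= p:
        raise ValueError("need 0 <= n_active <= p")
    return 1.0 - n_active / p


def split_complexity(mean_total_splits: float, cap: float = DEFAULT_SPLIT_CAP) -> float:
    """Simplicity score max(0, 1 - splits/cap): shallower ensembles score higher."""
    if mean_total_splits < 0:
        raise ValueError("split count cannot be negative")
    return max(0.0, 1.0 - mean_total_splits / cap)


def classification_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                           y_prob: np.ndarray | None = None,
                           wgm_weight: float | None = None) -> dict[str, float]:
    """Confusion-matrix metrics plus rank AUC; undefined ratios return 0.

    F2 weights recall four times as heavily as precision.  ``wgm_weight``
    defaults to the majority-class proportion of ``y_true``.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    tp = float(np.sum((y_true == 1) & (y_pred == 1)))
    fn = float(np.sum((y_true == 1) & (y_pred == 0)))
    tn = float(np.sum((y_true == 0) & (y_pred == 0)))
    fp = float(np.sum((y_true == 0) & (y_pred == 1)))
    n = tp + fn + tn + fp

    def ratio(num, den):
        return num / den if den > 0 else 0.0

    precision = ratio(tp, tp + fp)
    recall = ratio(tp, tp + fn)
    specificity = ratio(tn, tn + fp)
    if wgm_weight is None:
        prev = ratio(tp + fn, n)
        wgm_weight = max(prev, 1.0 - prev)
    return {
        "accuracy": ratio(tp + tn, n),
        "wgm": wgm(recall, specificity, wgm_weight),
        "f1": ratio(2 * precision * recall, precision + recall),
        "f2": ratio(5 * precision * recall, 4 * precision + recall),
        "precision": precision,
        "recall": recall,
        "specificity": specificity,
        "balanced_accuracy": (recall + specificity) / 2.0,
        "auc": auc_score(y_true, y_prob) if y_prob is not None else 0.0,
    }


@dataclass
class ObjectiveVector:
    """Ten maximized objectives in [0,1] plus overall scalars."""

    accuracy: float = 0.0
    wgm: float = 0.0
    f1: float = 0.0
    f2: float = 0.0
    precision: float = 0.0
    recall: float = 0.0
    balanced_accuracy: float = 0.0
    auc: float = 0.0
    feature_complexity: float = 0.0
    split_complexity: float = 0.0
    overall: float = field(default=0.0)
    weighted_overall: float = field(default=0.0)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in OBJECTIVE_NAMES])

    def validate(self) -> None:
        arr = self.as_array()
        if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
            raise ValueError(f"objective components outside [0,1]: {arr}")
        if abs(self.overall - arr.mean()) > 1e-12:
            raise ValueError("overall must equal the unweighted component mean")


def overall_scores(components: np.ndarray,
                   weights: np.ndarray | None = None) -> tuple[float, float]:
    """Unweighted and user-weighted means of the ten objective components."""
    components = np.asarray(components, float)
    overall = float(components.mean())
    if weights is None:
        return overall, overall
    weights = np.asarray(weights, float)
    if len(weights) != len(components) or np.any(weights < 0):
        raise ValueError("weights must be non-negative, one per objective")
    total = weights.sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")
    return overall, float(np.dot(weights, components) / total)


def make_objective_vector(metrics: dict[str, float], n_active: int, p: int,
                          mean_splits: float, weights: np.ndarray | None = None,
                          split_cap: float = DEFAULT_SPLIT_CAP) -> ObjectiveVector:
    vec = ObjectiveVector(
        accuracy=metrics.get("accuracy", 0.0), wgm=metrics.get("wgm", 0.0),
        f1=metrics.get("f1", 0.0), f2=metrics.get("f2", 0.0),
        precision=metrics.get("precision", 0.0), recall=metrics.get("recall", 0.0),
        balanced_accuracy=metrics.get("balanced_accuracy", 0.0),
        auc=metrics.get("auc", 0.0),
        feature_complexity=feature_complexity(n_active, p),
        split_complexity=split_complexity(mean_splits, split_cap),
    )
    vec.overall, vec.weighted_overall = overall_scores(vec.as_array(), weights)
    return vec


# ---------------------------------------------------------------------------
# model training


@dataclass
class FoldResult:
    val_index: np.ndarray
    y_prob: np.ndarray
    y_pred: np.ndarray
    best_iteration: int
    total_splits: int
    metrics: dict[str, float]


def _count_splits(booster: xgb.Booster, n_trees: int) -> int:
    """Internal split nodes over the first ``n_trees`` boosted trees."""
    dump = booster.get_dump(dump_format="text")
    return sum(tree.count("yes=") for tree in dump[:n_trees])


def train_fold(X_tr, y_tr, X_val, y_val, spec: DecodedModelSpec,
               seed: int = 0) -> tuple[xgb.Booster, FoldResult]:
    """Train one fold's booster with AUC early stopping.

    Boosting halts once 50 rounds pass without validation-AUC improvement
    (or at 500 rounds); the returned model is truncated to the best
    validation iteration.  Training is single-threaded and seeded so
    repeated evaluations agree bit for bit.
    """
    y_tr = np.asarray(y_tr)
    if len(np.unique(y_tr)) < 2:
        raise ValueError("single-class training split")
    params = dict(spec.classifier_config)
    params.update({"objective": "binary:logistic", "eval_metric": "auc",
                   "nthread": 1, "seed": int(seed), "tree_method": "hist"})
    dtr = xgb.DMatrix(np.asarray(X_tr, float), label=y_tr)
    dval = xgb.DMatrix(np.asarray(X_val, float), label=np.asarray(y_val))
    booster = xgb.train(params, dtr, num_boost_round=spec.max_boosting_rounds,
                        evals=[(dval, "val")],
                        early_stopping_rounds=spec.early_stopping_patience,
                        verbose_eval=False)
    best_it = getattr(booster, "best_iteration", None)
    if best_it is None:
        best_it = booster.num_boosted_rounds() - 1
    y_prob = booster.predict(dval, iteration_range=(0, best_it + 1))
    y_pred = (y_prob >= 0.5).astype(int)
    result = FoldResult(val_index=np.arange(len(y_val)), y_prob=y_prob,
                        y_pred=y_pred, best_iteration=int(best_it),
                        total_splits=_count_splits(booster, best_it + 1),
                        metrics={})
    return booster, result


@dataclass
class EvaluatedSolution:
    """A chromosome together with its fold-averaged objective vector."""

    chromosome: Chromosome
    objectives: ObjectiveVector
    oof_labels: np.ndarray  # pooled out-of-fold predicted labels
    oof_probs: np.ndarray  # pooled out-of-fold positive-class probabilities
    active_features: list[int]
    n_active_features: int
    mean_total_splits: float
    best_iterations: list[int] = field(default_factory=list)
    degenerate: bool = False

    @property
    def overall(self) -> float:
        return self.objectives.overall


def evaluate_solution(chrom: Chromosome, dataset, index, plan: CVPlan,
                      bounds: HyperparamBounds,
                      weights: np.ndarray | None = None,
                      split_cap: float = DEFAULT_SPLIT_CAP,
                      wgm_weight: float | None = None) -> EvaluatedSolution:
    """Run the full CV evaluation of one chromosome.

    Per-fold metrics are averaged arithmetically; pooled out-of-fold
    predictions are kept for the degenerate filter and ensemble voting.
    An empty active set scores zero on every classification metric (the
    simplicity metrics follow their formulas), and a solution whose pooled
    predictions are single-class is flagged degenerate.
    """
    X, y = dataset.X, dataset.y
    n, p = X.shape
    active = decode_features(chrom, index)
    n_active = len(active)
    if wgm_weight is None:
        wgm_weight = max(dataset.n_positive, dataset.n_negative) / n

    if n_active == 0:
        vec = make_objective_vector({}, 0, p, 0.0, weights, split_cap)
        return EvaluatedSolution(chromosome=chrom, objectives=vec,
                                 oof_labels=np.zeros(n, dtype=int),
                                 oof_probs=np.zeros(n), active_features=[],
                                 n_active_features=0, mean_total_splits=0.0,
                                 degenerate=True)

    ratio = dataset.n_negative / dataset.n_positive
    spec = decode_hyperparams(chrom, bounds, neg_pos_ratio=ratio)
    Xa = X[:, active]
    oof_prob = np.zeros(n)
    oof_pred = np.zeros(n, dtype=int)
    fold_metrics: list[dict] = []
    splits_counts: list[int] = []
    best_its: list[int] = []
    for train_idx, val_idx in plan.splits(n):
        if len(np.unique(y[train_idx])) < 2:
            continue  # degenerate fold: skipped
        _, fr = train_fold(Xa[train_idx], y[train_idx], Xa[val_idx], y[val_idx],
                           spec, seed=plan.seed)
        oof_prob[val_idx] = fr.y_prob
        oof_pred[val_idx] = fr.y_pred
        fold_metrics.append(classification_metrics(y[val_idx], fr.y_pred,
                                                   fr.y_prob, wgm_weight))
        splits_counts.append(fr.total_splits)
        best_its.append(fr.best_iteration)

    if fold_metrics:
        keys = fold_metrics[0].keys()
        mean_metrics = {k: float(np.mean([m[k] for m in fold_metrics])) for k in keys}
        mean_splits = float(np.mean(splits_counts))
    else:
        mean_metrics, mean_splits = {}, 0.0
    vec = make_objective_vector(mean_metrics, n_active, p, mean_splits,
                                weights, split_cap)
    degenerate = len(np.unique(oof_pred)) < 2
    return EvaluatedSolution(chromosome=chrom, objectives=vec,
                             oof_labels=oof_pred, oof_probs=oof_prob,
                             active_features=list(active),
                             n_active_features=n_active,
                             mean_total_splits=mean_splits,
                             best_iterations=best_its, degenerate=degenerate)
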