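"""Deployable predictors from the final Pareto front.

The first front holds the mutually nondominated solutions: the one with
the highest overall score is the best single compromise, and the rest are
combined into hard (label-count) and soft (probability-averaging)
majority-voting ensembles.  Members that classified every sample into one
class during cross-validation add no discrimination — they sit on the
front purely through simplicity — and are excluded before voting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np
import xgboost as xgb

from .evaluation import EvaluatedSolution
from .genome import HyperparamBounds, decode_hyperparams


def filter_degenerate(front0: Sequence[EvaluatedSolution]) -> list[EvaluatedSolution]:
    """Drop solutions whose pooled out-of-fold predictions are single-class.

    If everything is degenerate, fall back to the single best-overall
    member with a warning.
    """
    kept = [s for s in front0 if not s.degenerate]
    if not kept and front0:
        warnings.warn("all front-0 solutions are degenerate; "
                      "falling back to the best-overall model")
        kept = [max(front0, key=lambda s: s.overall)]
    return kept


def hard_vote(member_labels: np.ndarray, overall_scores: Sequence[float]) -> np.ndarray:
    """Per-sample majority label over members (rows = members).

    Ties follow the vote of the member with the highest overall score.
    """
    votes = np.asarray(member_labels)
    if votes.ndim != 2 or votes.shape[0] < 1:
        raise ValueError("need a members x samples vote table")
    ones = votes.sum(axis=0)
    m = votes.shape[0]
    out = (ones * 2 > m).astype(int)
    tied = ones * 2 == m
    if np.any(tied):
        best = int(np.argmax(overall_scores))
        out[tied] = votes[best, tied]
    return out


def soft_vote(member_probs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean positive-class probability across members; label 1 iff mean >= 0.5."""
    probs = np.asarray(member_probs, float)
    if probs.ndim != 2 or probs.shape[0] < 1:
        raise ValueError("need a members x samples probability table")
    if np.any(probs < 0) or np.any(probs > 1):
        raise ValueError("probabilities must be in [0,1]")
    pooled = probs.mean(axis=0)
    return (pooled >= 0.5).astype(int), pooled


@dataclass
class FittedMember:
    solution: EvaluatedSolution
    booster: xgb.Booster
    active_features: list[int]
    n_rounds: int

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        d = xgb.DMatrix(np.asarray(X, float)[:, self.active_features])
        return self.booster.predict(d)


@dataclass
class EnsembleModel:
    """Refit front-0 members plus a voting mode."""

    members: list[FittedMember]
    voting_mode: str  # "hard" | "soft"
    member_overalls: list[float] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.voting_mode == "soft":
            labels, _ = soft_vote(np.stack([m.predict_proba(X) for m in self.members]))
            return labels
        votes = np.stack([(m.predict_proba(X) >= 0.5).astype(int)
                          for m in self.members])
        return hard_vote(votes, self.member_overalls)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        _, pooled = soft_vote(np.stack([m.predict_proba(X) for m in self.members]))
        return pooled


def refit_member(solution: EvaluatedSolution, dataset,
                 bounds: HyperparamBounds, seed: int = 0) -> FittedMember:
    """Refit one solution's classifier on the full dataset.

    The boosting budget is the member's median best iteration across CV
    folds, since the early-stopping monitor no longer exists at deploy
    time.
    """
    ratio = dataset.n_negative / dataset.n_positive
    spec = decode_hyperparams(solution.chromosome, bounds, neg_pos_ratio=ratio)
    active = solution.active_features
    rounds = max(1, int(np.median(solution.best_iterations)) + 1
                 if solution.best_iterations else 1)
    params = dict(spec.classifier_config)
    params.update({"objective": "binary:logistic", "eval_metric": "auc",
                   "nthread": 1, "seed": int(seed), "tree_method": "hist"})
    dtr = xgb.DMatrix(dataset.X[:, active], label=dataset.y)
    booster = xgb.train(params, dtr, num_boost_round=rounds)
    return FittedMember(solution=solution, booster=booster,
                        active_features=list(active), n_rounds=rounds)


@dataclass
class FinalizedRun:
    best_model: FittedMember
    hard_ensemble: EnsembleModel
    soft_ensemble: EnsembleModel
    biosignature: list[str]
    front0_size: int
    n_voting_members: int

    def biosignature_table(self) -> list[tuple[str, str]]:
        return [(name, "selected") for name in self.biosignature]


def finalize(result, dataset, bounds: HyperparamBounds | None = None,
             seed: int = 0) -> FinalizedRun:
    """Turn a finished run into deployable predictors.

    Recomputes front 0, refits each surviving member on the full dataset,
    and reports the best-overall model's selected feature names (the
    candidate biosignature).
    """
    bounds = bounds or HyperparamBounds()
    front0 = result.front0
    assert front0, "front 0 is non-empty by construction"
    voters = filter_degenerate(front0)
    fitted = [refit_member(s, dataset, bounds, seed) for s in voters]
    overalls = [s.overall for s in voters]
    best_sol = max(front0, key=lambda s: s.overall)
    best_fitted = next((m for m in fitted if m.solution is best_sol), None)
    if best_fitted is None:
        best_fitted = refit_member(best_sol, dataset, bounds, seed)
    biosignature = [dataset.feature_names[i] for i in best_sol.active_features]
    return FinalizedRun(
        best_model=best_fitted,
        hard_ensemble=EnsembleModel(fitted, "hard", overalls),
        soft_ensemble=EnsembleModel(fitted, "soft", overalls),
        biosignature=biosignature,
        front0_size=len(front0),
        n_voting_members=len(fitted),
    )


def save_bundle(finalized: FinalizedRun, dataset, path) -> None:
    """Write a JSON model bundle loadable by the prediction CLI."""
    bundle = {
        "positive_label": str(dataset.positive_label),
        "feature_names": dataset.feature_names,
        "best": _member_dict(finalized.best_model),
        "members": [_member_dict(m) for m in finalized.soft_ensemble.members],
        "member_overalls": finalized.soft_ensemble.member_overalls,
        "biosignature": finalized.biosignature,
    }
    with open(path, "w") as fh:
        json.dump(bundle, fh)


def _member_dict(m: FittedMember) -> dict:
    return {"chromosome": m.solution.chromosome.to_dict(),
            "active_features": m.active_features, "n_rounds": m.n_rounds,
            "booster": m.booster.save_raw(raw_format="json").decode()}


def load_bundle(path) -> dict:
    with open(path) as fh:
        bundle = json.load(fh)
    for entry in [bundle["best"], *bundle["members"]]:
        booster = xgb.Booster()
        booster.load_model(bytearray(entry.pop("booster").encode()))
        entry["model"] = booster
    return bundle
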