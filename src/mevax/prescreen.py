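"""Filter-method feature rankings referenced by the chromosomes' FS genes.

Four rankings are built once, before generation 0: an ANOVA-F univariate
ranking (SelectKBest style), a Wilcoxon rank-sum ranking, and two greedy
information-theoretic orderings — JMI (joint mutual information) and mRMR
(minimum redundancy, maximum relevance, difference criterion).  A
chromosome whose FS gene names one of these methods restricts its active
feature set to the top-k entries of that method's list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.feature_selection import f_classif

#: finite stand-in for an infinite F statistic (zero within-group variance)
F_CAP = 1e12

FS_METHODS = ("kbest", "wilcoxon", "jmi", "mrmr")


@dataclass
class PrescreenIndex:
    """Per-method ordered feature lists (best first), computed once per dataset."""

    rankings: dict[str, list[int]]
    scores: dict[str, list[float]] = field(default_factory=dict)
    n_bins: int = 5
    dataset_hash: str = ""

    def top(self, method: str, k: int) -> list[int]:
        """Top-k indices of a method's list; k is folded into the list length."""
        lst = self.rankings[method]
        k = ((int(k) - 1) % len(lst)) + 1
        return lst[:k]

    def to_json(self) -> str:
        return json.dumps({"rankings": self.rankings, "scores": self.scores,
                           "n_bins": self.n_bins, "dataset_hash": self.dataset_hash})

    @classmethod
    def from_json(cls, text: str) -> "PrescreenIndex":
        d = json.loads(text)
        return cls(rankings={k: list(map(int, v)) for k, v in d["rankings"].items()},
                   scores=d.get("scores", {}), n_bins=d.get("n_bins", 5),
                   dataset_hash=d.get("dataset_hash", ""))


def score_kbest(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """One-way ANOVA F statistic per feature (two-group case).

    Constant features score 0; infinite statistics (perfect separation with
    zero within-group variance) are capped at a large finite sentinel so
    the ranking stays well defined.
    """
    F, _ = f_classif(np.asarray(X, float), np.asarray(y))
    F = np.nan_to_num(F, nan=0.0, posinf=F_CAP)
    return np.minimum(F, F_CAP)


def score_wilcoxon(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) statistic and p per feature.

    Midranks handle ties; the exact null distribution is used for small
    tie-free groups, the tie-corrected normal approximation otherwise.
    Ranking key is the ascending p-value.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    a, b = X[y == 1], X[y == 0]
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto", axis=0)
    return np.atleast_1d(res.statistic), np.atleast_1d(res.pvalue)


def discretize(X: np.ndarray, n_bins: int | None = None) -> np.ndarray:
    """Equal-frequency binning of each column into integer codes.

    Default bin count is min(5, ceil(sqrt(n))).  Columns that already take
    at most ``n_bins`` distinct values are relabeled 0..m-1 unchanged —
    nominal codes and binary indicators pass through losslessly.
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    if n_bins is None:
        n_bins = min(5, int(np.ceil(np.sqrt(n))))
    out = np.empty(X.shape, dtype=np.int64)
    for j in range(X.shape[1]):
        col = X[:, j]
        uniq = np.unique(col)
        if len(uniq) <= n_bins:
            out[:, j] = np.searchsorted(uniq, col)
        else:
            # quantile edges; duplicate edges collapse bins (heavy ties)
            qs = np.quantile(col, np.linspace(0, 1, n_bins + 1)[1:-1])
            out[:, j] = np.searchsorted(qs, col, side="right")
    return out


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information of two discrete vectors, in bits.

    MI >= 0, with equality iff the empirical joint factorizes.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if len(a) != len(b):
        raise ValueError("vectors must have equal length")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    nb = bi.max() + 1
    joint = np.bincount(ai * nb + bi, minlength=(ai.max() + 1) * nb).astype(float)
    joint = joint.reshape(-1, nb) / len(a)
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log2(joint[nz] / (pa @ pb)[nz])))
    return max(mi, 0.0)


def _pair_codes(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Codes of the paired variable (u, v)."""
    return u * (v.max() + 1) + v


def _mi_codes(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in MI (bits) for vectors already coded 0..m-1; avoids re-coding."""
    na, nb = int(a.max()) + 1, int(b.max()) + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).astype(float).reshape(na, nb)
    joint /= len(a)
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return max(float(np.sum(joint[nz] * np.log2(joint[nz] / (pa @ pb)[nz]))), 0.0)


def select_jmi(X: np.ndarray, y: np.ndarray, k: int,
               n_bins: int | None = None) -> list[int]:
    """Greedy joint-mutual-information forward selection (Yang & Moody).

    The first pick maximizes I(f; y); each later pick maximizes
    sum over selected s of I((f, s); y), the mutual information of the
    paired variable with the label.  Ties break toward the lower index.
    """
    Xd = discretize(X, n_bins)
    y = np.asarray(y)
    p = Xd.shape[1]
    k = min(int(k), p)
    yc = np.searchsorted(np.unique(y), y)
    relevance = np.array([_mi_codes(Xd[:, j], yc) for j in range(p)])
    selected = [int(np.argmax(relevance))]
    remaining = [j for j in range(p) if j != selected[0]]
    acc = np.zeros(p)  # running sum of I((f, s); y) over selected s
    while len(selected) < k:
        s = selected[-1]
        for j in remaining:
            acc[j] += _mi_codes(_pair_codes(Xd[:, j], Xd[:, s]), yc)
        best = max(remaining, key=lambda j: (acc[j], -j))
        selected.append(best)
        remaining.remove(best)
    return selected


def select_mrmr(X: np.ndarray, y: np.ndarray, k: int,
                n_bins: int | None = None) -> list[int]:
    """Greedy mRMR with the MID (difference) criterion.

    Each pick maximizes I(f; y) - (1/|S|) * sum over selected s of I(f; s);
    the first pick is pure relevance.  Ties break toward the lower index.
    """
    Xd = discretize(X, n_bins)
    y = np.asarray(y)
    p = Xd.shape[1]
    k = min(int(k), p)
    yc = np.searchsorted(np.unique(y), y)
    relevance = np.array([_mi_codes(Xd[:, j], yc) for j in range(p)])
    selected = [int(np.argmax(relevance))]
    remaining = [j for j in range(p) if j != selected[0]]
    red = np.zeros(p)  # running sum of I(f; s) over selected s
    while len(selected) < k:
        s = selected[-1]
        for j in remaining:
            red[j] += _mi_codes(Xd[:, j], Xd[:, s])
        m = len(selected)
        best = max(remaining, key=lambda j: (relevance[j] - red[j] / m, -j))
        selected.append(best)
        remaining.remove(best)
    return selected


def build_prescreen_index(dataset, k_max: int = 50,
                          n_bins: int | None = None) -> PrescreenIndex:
    """Compute all four rankings for a dataset.

    Full rankings are stored for the univariate methods (kbest, wilcoxon);
    the greedy JMI/mRMR orderings are cut at ``k_max`` since chromosomes
    never reference deeper entries.
    """
    X, y = dataset.X, dataset.y
    p = X.shape[1]
    k_max = min(int(k_max), p)
    f = score_kbest(X, y)
    kbest_order = np.lexsort((np.arange(p), -f))
    _, pvals = score_wilcoxon(X, y)
    wilcoxon_order = np.lexsort((np.arange(p), pvals))
    if n_bins is None:
        n_bins = min(5, int(np.ceil(np.sqrt(X.shape[0]))))
    rankings = {
        "kbest": [int(i) for i in kbest_order],
        "wilcoxon": [int(i) for i in wilcoxon_order],
        "jmi": select_jmi(X, y, k_max, n_bins),
        "mrmr": select_mrmr(X, y, k_max, n_bins),
    }
    scores = {
        "kbest": [float(f[i]) for i in kbest_order],
        "wilcoxon": [float(pvals[i]) for i in wilcoxon_order],
    }
    return PrescreenIndex(rankings=rankings, scores=scores, n_bins=n_bins,
                          dataset_hash=dataset.content_hash())
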