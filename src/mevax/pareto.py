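"""Nondominated sorting and fitness-sharing niching.

Solutions are ranked into Pareto fronts on their ten maximized objectives
(fast nondominated sorting).  Within a front, similar solutions share
fitness: a dual chromosome distance — half normalized parameter-gene
distance, half Jaccard distance of the active-feature sets — feeds a
triangular sharing kernel, and each solution's overall score is divided by
its niche count.  Crowded regions of the front are thereby penalized,
spreading the population over multiple optima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import Chromosome, HyperparamBounds

DEFAULT_SIGMA_SHARE = 0.2


def dominates(u: np.ndarray, v: np.ndarray) -> bool:
    """True iff u >= v component-wise with at least one strict inequality."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    return bool(np.all(u >= v) and np.any(u > v))


def nondominated_sort(objectives: list[np.ndarray] | np.ndarray) -> list[list[int]]:
    """Fast nondominated sorting into fronts of input indices.

    Front 0 is the dominant set; every member of front f+1 is dominated by
    at least one member of an earlier front.  Within-front order is stable
    by input index.
    """
    O = np.asarray(objectives, float)
    n = len(O)
    if n == 0:
        raise ValueError("empty objective list")
    # pairwise dominance: dom[i, j] = i dominates j
    ge = np.all(O[:, None, :] >= O[None, :, :], axis=2)
    gt = np.any(O[:, None, :] > O[None, :, :], axis=2)
    dom = ge & gt
    n_dominators = dom.sum(axis=0)
    fronts: list[list[int]] = []
    assigned = np.zeros(n, dtype=bool)
    current = np.flatnonzero(n_dominators == 0)
    while current.size:
        fronts.append([int(i) for i in current])
        assigned[current] = True
        n_dominators = n_dominators - dom[current].sum(axis=0)
        current = np.flatnonzero((n_dominators == 0) & ~assigned)
    return fronts


def chromosome_distance(a: Chromosome, b: Chromosome,
                        bounds: HyperparamBounds,
                        mask_weight: float = 0.5) -> float:
    """Dual genotype distance in [0,1].

    The parameter part averages the range-normalized absolute differences
    of the hyperparameter genes together with the FS genes (method:
    0/1 mismatch indicator; depth: difference over k_max).  The mask part
    is the Jaccard distance of the active-bit sets (0 when both masks are
    empty).  The two parts are combined 50/50 by default.
    """
    if a.p != b.p:
        raise ValueError("chromosomes must share the same feature space")
    diffs = [abs(a.hyperparams[g.name] - b.hyperparams[g.name]) / (g.upper - g.lower)
             for g in bounds.genes]
    diffs.append(0.0 if a.fs_method == b.fs_method else 1.0)
    diffs.append(min(abs(a.fs_k - b.fs_k) / bounds.k_max, 1.0))
    d_params = float(np.mean(diffs))
    union = int(np.sum(a.mask | b.mask))
    if union == 0:
        d_mask = 0.0
    else:
        inter = int(np.sum(a.mask & b.mask))
        d_mask = 1.0 - inter / union
    return (1.0 - mask_weight) * d_params + mask_weight * d_mask


def niche_degrade(chromosomes: list[Chromosome], overalls: np.ndarray,
                  bounds: HyperparamBounds,
                  sigma_share: float = DEFAULT_SIGMA_SHARE,
                  mask_weight: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Fitness sharing within one front.

    The triangular kernel sh(d) = 1 - d/sigma for d < sigma (else 0) is
    summed over all front members including self, so niche counts are >= 1;
    the niched score is overall / niche_count.  A lone or distinctive
    solution keeps its score; clustered duplicates split theirs.
    """
    m = len(chromosomes)
    overalls = np.asarray(overalls, float)
    counts = np.ones(m)
    for i in range(m):
        for j in range(i + 1, m):
            d = chromosome_distance(chromosomes[i], chromosomes[j], bounds,
                                    mask_weight)
            if d < sigma_share:
                sh = 1.0 - d / sigma_share
                counts[i] += sh
                counts[j] += sh
    return counts, overalls / counts


@dataclass
class ParetoRanking:
    """Front index, niche count and niche-degraded score per solution."""

    front_index: np.ndarray
    niche_count: np.ndarray
    niched_score: np.ndarray
    fronts: list[list[int]]


def rank_population(solutions, bounds: HyperparamBounds,
                    sigma_share: float = DEFAULT_SIGMA_SHARE,
                    mask_weight: float = 0.5) -> ParetoRanking:
    """Nondominated-sort evaluated solutions and apply per-front sharing."""
    objectives = [s.objectives.as_array() for s in solutions]
    fronts = nondominated_sort(objectives)
    n = len(solutions)
    front_index = np.empty(n, dtype=int)
    niche_count = np.empty(n)
    niched_score = np.empty(n)
    for f, members in enumerate(fronts):
        front_index[members] = f
        chroms = [solutions[i].chromosome for i in members]
        overalls = np.array([solutions[i].overall for i in members])
        counts, scores = niche_degrade(chroms, overalls, bounds, sigma_share,
                                       mask_weight)
        niche_count[members] = counts
        niched_score[members] = scores
    return ParetoRanking(front_index=front_index, niche_count=niche_count,
                         niched_score=niched_score, fronts=fronts)
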