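"""Hybrid chromosome: feature mask + FS genes + classifier hyperparameters.

A candidate solution is a binary feature mask over all p features, a
feature-selection gene (which prescreen ranking, if any, to intersect the
mask with, and how deep), and seven gradient-boosting hyperparameters:
learning rate, tree depth, two pruning parameters (minimum split loss,
minimum child weight), two generalization parameters (L2 and L1
regularization), and a class-balancing weight multiplier.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np

FS_GENE_OPTIONS = ("none", "kbest", "wilcoxon", "jmi", "mrmr")

#: initial feature masks carry fewer than this many active bits
MAX_INITIAL_ACTIVE = 30


@dataclass(frozen=True)
class GeneBound:
    name: str
    lower: float
    upper: float
    integer: bool = False


@dataclass(frozen=True)
class HyperparamBounds:
    """Ranges for the 7 classifier genes (lower < upper for each)."""

    genes: tuple[GeneBound, ...] = (
        GeneBound("learning_rate", 0.01, 0.5),
        GeneBound("max_depth", 1, 10, integer=True),
        GeneBound("min_split_loss", 0.0, 5.0),
        GeneBound("min_child_weight", 1.0, 10.0),
        GeneBound("l2_regularization", 0.0, 10.0),
        GeneBound("l1_regularization", 0.0, 5.0),
        GeneBound("positive_class_weight", 0.1, 10.0),
    )
    k_max: int = 50

    def __post_init__(self):
        for g in self.genes:
            if not g.lower < g.upper:
                raise ValueError(f"gene {g.name}: lower must be < upper")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.genes)

    def clip(self, name: str, value: float) -> float:
        g = next(g for g in self.genes if g.name == name)
        v = float(np.clip(value, g.lower, g.upper))
        return float(int(round(v))) if g.integer else v


@dataclass
class Chromosome:
    """Genotype: feature mask bits + FS method/depth genes + 7 hyperparameters."""

    mask: np.ndarray  # bool, length p
    fs_method: str
    fs_k: int
    hyperparams: dict[str, float]

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        self.fs_k = int(self.fs_k)
        if self.fs_method not in FS_GENE_OPTIONS:
            raise ValueError(f"unknown fs_method {self.fs_method!r}")
        if self.fs_k < 1:
            raise ValueError("fs_k must be >= 1")

    @property
    def p(self) -> int:
        return len(self.mask)

    @property
    def n_active(self) -> int:
        return int(self.mask.sum())

    def validate(self, bounds: HyperparamBounds) -> None:
        for g in bounds.genes:
            v = self.hyperparams[g.name]
            if not (g.lower <= v <= g.upper):
                raise ValueError(f"{g.name}={v} outside [{g.lower}, {g.upper}]")
            if g.integer and v != int(v):
                raise ValueError(f"{g.name}={v} must be integral")

    def stable_hash(self) -> str:
        payload = json.dumps(
            [np.flatnonzero(self.mask).tolist(), self.fs_method, self.fs_k,
             [round(float(self.hyperparams[k]), 12) for k in sorted(self.hyperparams)]]
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_dict(self) -> dict:
        return {"active_indices": np.flatnonzero(self.mask).tolist(), "p": self.p,
                "fs_method": self.fs_method, "fs_k": self.fs_k,
                "hyperparams": {k: float(v) for k, v in self.hyperparams.items()}}

    @classmethod
    def from_dict(cls, d: dict) -> "Chromosome":
        mask = np.zeros(int(d["p"]), dtype=bool)
        mask[np.asarray(d["active_indices"], dtype=int)] = True
        return cls(mask=mask, fs_method=d["fs_method"], fs_k=int(d["fs_k"]),
                   hyperparams={k: float(v) for k, v in d["hyperparams"].items()})

    def copy(self) -> "Chromosome":
        return Chromosome(mask=self.mask.copy(), fs_method=self.fs_method,
                          fs_k=self.fs_k, hyperparams=dict(self.hyperparams))


@dataclass
class DecodedModelSpec:
    """Phenotype: active feature indices + named XGBoost configuration."""

    active_features: list[int]
    classifier_config: dict[str, float]
    max_boosting_rounds: int = 500
    early_stopping_patience: int = 50


@dataclass
class MutationRates:
    """Per-gene mutation probabilities; bit rate defaults to max(1/p, 0.001)."""

    bit: float | None = None
    param: float = 0.2
    fs: float = 0.05

    def bit_rate(self, p: int) -> float:
        return self.bit if self.bit is not None else max(1.0 / p, 0.001)


def _draw_hyperparams(bounds: HyperparamBounds, rng: np.random.Generator) -> dict:
    hp = {}
    for g in bounds.genes:
        if g.integer:
            hp[g.name] = float(rng.integers(int(g.lower), int(g.upper) + 1))
        else:
            hp[g.name] = float(rng.uniform(g.lower, g.upper))
    return hp


def init_population(p: int, size: int, bounds: HyperparamBounds,
                    rng: np.random.Generator | int) -> list[Chromosome]:
    """Pseudorandom initial population.

    Hyperparameters are uniform within bounds; each mask activates m bits,
    m uniform on 1..29 (capped at p), positions uniform without
    replacement; the FS method gene is uniform over its 5 options and the
    FS depth gene uniform on 1..k_max.
    """
    if size < 2:
        raise ValueError("population size must be >= 2")
    if p < 1:
        raise ValueError("need at least one feature")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    m_cap = min(MAX_INITIAL_ACTIVE - 1, p)
    pop = []
    for _ in range(size):
        m = int(rng.integers(1, m_cap + 1))
        mask = np.zeros(p, dtype=bool)
        mask[rng.choice(p, size=m, replace=False)] = True
        pop.append(Chromosome(
            mask=mask,
            fs_method=FS_GENE_OPTIONS[rng.integers(len(FS_GENE_OPTIONS))],
            fs_k=int(rng.integers(1, bounds.k_max + 1)),
            hyperparams=_draw_hyperparams(bounds, rng),
        ))
    return pop


def decode_features(chrom: Chromosome, index) -> list[int]:
    """Resolve the chromosome's active feature set.

    With ``fs_method == "none"`` the set is the mask's set bits; otherwise
    it is the intersection of the mask with the top-``fs_k`` entries of the
    named prescreen ranking, falling back to the raw mask bits when the
    intersection is empty.  An empty mask decodes to an empty list (the
    solution is scored as degenerate).
    """
    bits = np.flatnonzero(chrom.mask).tolist()
    if not bits or chrom.fs_method == "none":
        return bits
    top = set(index.top(chrom.fs_method, chrom.fs_k))
    active = [b for b in bits if b in top]
    return active if active else bits


def decode_hyperparams(chrom: Chromosome, bounds: HyperparamBounds,
                       neg_pos_ratio: float = 1.0) -> DecodedModelSpec:
    """Map the 7 genes onto a named XGBoost configuration.

    The balancing gene multiplies the dataset's negatives/positives ratio,
    so a gene of 1.0 reproduces the standard imbalance correction.
    """
    hp = chrom.hyperparams
    config = {
        "eta": float(hp["learning_rate"]),
        "max_depth": int(hp["max_depth"]),
        "gamma": float(hp["min_split_loss"]),
        "min_child_weight": float(hp["min_child_weight"]),
        "lambda": float(hp["l2_regularization"]),
        "alpha": float(hp["l1_regularization"]),
        "scale_pos_weight": float(hp["positive_class_weight"]) * float(neg_pos_ratio),
    }
    return DecodedModelSpec(active_features=np.flatnonzero(chrom.mask).tolist(),
                            classifier_config=config)


def crossover(a: Chromosome, b: Chromosome,
              rng: np.random.Generator) -> tuple[Chromosome, Chromosome]:
    """Uniform crossover: each mask bit and each gene from parent a w.p. 0.5."""
    if a.p != b.p:
        raise ValueError("parents must share the same feature space")
    take_a = rng.random(a.p) < 0.5
    m1 = np.where(take_a, a.mask, b.mask)
    m2 = np.where(take_a, b.mask, a.mask)
    hp1, hp2 = {}, {}
    for name in a.hyperparams:
        if rng.random() < 0.5:
            hp1[name], hp2[name] = a.hyperparams[name], b.hyperparams[name]
        else:
            hp1[name], hp2[name] = b.hyperparams[name], a.hyperparams[name]
    if rng.random() < 0.5:
        fs1, fs2 = (a.fs_method, a.fs_k), (b.fs_method, b.fs_k)
    else:
        fs1, fs2 = (b.fs_method, b.fs_k), (a.fs_method, a.fs_k)
    c1 = Chromosome(mask=m1, fs_method=fs1[0], fs_k=fs1[1], hyperparams=hp1)
    c2 = Chromosome(mask=m2, fs_method=fs2[0], fs_k=fs2[1], hyperparams=hp2)
    return c1, c2


def mutate(chrom: Chromosome, rates: MutationRates, bounds: HyperparamBounds,
           rng: np.random.Generator) -> Chromosome:
    """Bit-flip + Gaussian-perturbation mutation, clipped to bounds.

    Mask bits flip independently w.p. ``rates.bit`` (default ~1 expected
    flip); each hyperparameter is perturbed w.p. ``rates.param`` by
    Gaussian noise with sigma = 10% of its range; the FS method gene is
    resampled w.p. ``rates.fs`` and the FS depth gene is perturbed on the
    same draw.
    """
    r_bit = rates.bit_rate(chrom.p)
    mask = chrom.mask ^ (rng.random(chrom.p) < r_bit)
    hp = {}
    for g in bounds.genes:
        v = chrom.hyperparams[g.name]
        if rng.random() < rates.param:
            v = v + rng.normal(0.0, 0.1 * (g.upper - g.lower))
        hp[g.name] = bounds.clip(g.name, v)
    fs_method, fs_k = chrom.fs_method, chrom.fs_k
    if rng.random() < rates.fs:
        fs_method = FS_GENE_OPTIONS[rng.integers(len(FS_GENE_OPTIONS))]
        fs_k = int(rng.integers(1, bounds.k_max + 1))
    return Chromosome(mask=mask, fs_method=fs_method, fs_k=fs_k, hyperparams=hp)
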