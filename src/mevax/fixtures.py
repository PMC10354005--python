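"""Synthetic datasets with the structure the method assumes.

The generator emulates the two regimes the algorithm targets: a
high-dimensional, low-sample expression-like matrix (n of order 10^2, p of
order 10^3, moderate class imbalance, a handful of weakly informative
genes plus correlated duplicates) and a questionnaire-like clinical table
(hundreds of samples, tens of mixed numeric/nominal features, strong
imbalance, missing values).  Every module is thereby testable without any
external download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import Dataset, table_from_frame, preprocess


@dataclass
class FixtureSpec:
    """Knobs of the generator.

    ``effect_size`` is the standardized mean shift of each informative
    feature between classes; ``class_balance`` the positive-class
    fraction; duplicates are noisy copies of informative features at
    correlation ``duplicate_correlation``.
    """

    n_samples: int = 100
    n_features: int = 200
    n_informative: int = 5
    effect_size: float = 1.0
    class_balance: float = 0.4
    n_redundant_duplicates: int = 0
    duplicate_correlation: float = 0.9
    missing_rate: float = 0.0
    nominal_fraction: float = 0.0
    seed: int = 0
    positive_name: str = "case"
    negative_name: str = "control"

    def validate(self) -> None:
        if self.n_informative + self.n_redundant_duplicates > self.n_features:
            raise ValueError("informative + duplicate features exceed n_features")
        for name in ("class_balance", "missing_rate", "nominal_fraction",
                     "duplicate_correlation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")


@dataclass
class Fixture:
    """A generated table plus its ground truth."""

    frame: pd.DataFrame  # features + label column; may hold NaN / nominal cells
    informative: list[int]  # informative feature indices (duplicates excluded)
    duplicates: list[int]  # indices of correlated copies
    label_column: str = "label"

    def to_dataset(self, impute: str = "median", norm: str = "minmax") -> Dataset:
        raw = table_from_frame(self.frame, self.label_column)
        ds, _ = preprocess(raw, impute=impute, norm=norm)
        return ds


def generate(spec: FixtureSpec) -> Fixture:
    """Draw one dataset.

    Noise features are standard normal; informative features get a mean
    shift of ``effect_size`` in the positive class; duplicates are
    informative columns mixed with fresh noise at the requested
    correlation.  Missingness is completely at random; nominal columns are
    produced by quantile-binning a trailing block of noise features into
    labeled categories.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_features
    n_pos = int(round(spec.class_balance * n))
    n_pos = min(max(n_pos, 1), n - 1)
    y = np.zeros(n, dtype=int)
    y[rng.choice(n, size=n_pos, replace=False)] = 1

    X = rng.standard_normal((n, p))
    informative = list(range(spec.n_informative))
    for j in informative:
        X[y == 1, j] += spec.effect_size
    duplicates = list(range(spec.n_informative,
                            spec.n_informative + spec.n_redundant_duplicates))
    rho = spec.duplicate_correlation
    for d_pos, j in enumerate(duplicates):
        src = informative[d_pos % max(len(informative), 1)]
        X[:, j] = rho * X[:, src] + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)

    names = [f"F{j:04d}" for j in range(p)]
    df = pd.DataFrame(X, columns=names)

    n_nominal = int(round(spec.nominal_fraction * p))
    protected = spec.n_informative + spec.n_redundant_duplicates
    nominal_cols = names[max(protected, p - n_nominal):]
    levels = np.array(["low", "mid_low", "mid_high", "high"], dtype=object)
    for col in nominal_cols:
        codes = pd.qcut(df[col], q=4, labels=False, duplicates="drop")
        df[col] = levels[codes.to_numpy(dtype=int)]

    if spec.missing_rate > 0:
        holes = rng.random((n, p)) < spec.missing_rate
        holes[:, informative] = False  # keep the planted signal observable
        # never blank out an entire column
        full = holes.all(axis=0)
        holes[0, full] = False
        arr = df.to_numpy(dtype=object)
        arr[holes] = np.nan
        df = pd.DataFrame(arr, columns=names)

    df["label"] = np.where(y == 1, spec.positive_name, spec.negative_name)
    return Fixture(frame=df, informative=informative, duplicates=duplicates)


def make_expression_like(seed: int = 0, p: int = 2000) -> Fixture:
    """Microarray-style preset: 89 samples (35 positive / 54 negative).

    The feature count is scaled to 2000 so a full evolutionary run stays a
    desk-scale computation while keeping the samples-to-features ratio far
    below one, which is the regime of interest.
    """
    return generate(FixtureSpec(
        n_samples=89, n_features=p, n_informative=5, effect_size=1.0,
        class_balance=35 / 89, n_redundant_duplicates=5,
        duplicate_correlation=0.9, seed=seed,
        positive_name="Non_responder", negative_name="Responder"))


def make_questionnaire_like(seed: int = 0) -> Fixture:
    """Clinical-questionnaire preset: 631 samples x 50 mixed features, 1:9 imbalance.

    40% of the columns are nominal and 5% of cells are missing, exercising
    the full preprocessing chain.
    """
    return generate(FixtureSpec(
        n_samples=631, n_features=50, n_informative=6, effect_size=0.8,
        class_balance=0.1, n_redundant_duplicates=2, duplicate_correlation=0.9,
        missing_rate=0.05, nominal_fraction=0.4, seed=seed))
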