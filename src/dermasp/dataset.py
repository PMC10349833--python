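"""Assembly of superpixel records into ML-ready train/test sets.

Records live in a pandas DataFrame with the feature CSV schema
(``image_id, sp_label, area, perimeter, eccentricity, orientation,
convex_area, major_axis_length, class``), class coded nevus=0 / melanoma=1.
Splitting is stratified at the superpixel-record level, normalization is
z-score with moments estimated on the training partition only (population
standard deviation), and five-fold cross-validation indices are balanced
partitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import FEATURE_COLUMNS

__all__ = [
    "FEATURE_COLUMNS",
    "CLASS_TO_INT",
    "SplitSpec",
    "split_dataset",
    "zscore_fit_transform",
    "zscore_apply",
    "zscore_invert",
    "kfold_indices",
]

CLASS_TO_INT = {"nevus": 0, "melanoma": 1}


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.70
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


def encode_classes(df: pd.DataFrame) -> pd.DataFrame:
    """Map string class labels to {nevus: 0, melanoma: 1} in place-safe copy."""
    out = df.copy()
    if out["class"].dtype == object:
        unknown = set(out["class"]) - set(CLASS_TO_INT)
        if unknown:
            raise ValueError(f"unknown class labels: {sorted(unknown)}")
        out["class"] = out["class"].map(CLASS_TO_INT)
    return out


def split_dataset(
    data: pd.DataFrame, spec: SplitSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Record-level random split, stratified by class when requested.

    Per class (or globally when unstratified), ``round(train_fraction * n)``
    records go to training.  Deterministic under ``spec.seed``; train and
    test are disjoint and together exhaust the input.
    """
    df = encode_classes(data)
    counts = df["class"].value_counts()
    if spec.stratified:
        if set(counts.index) != {0, 1} or counts.min() < 2:
            raise ValueError("need >= 2 records of each class for a stratified split")
    rng = np.random.default_rng(spec.seed)
    groups = [g for _, g in df.groupby("class")] if spec.stratified else [df]
    train_parts, test_parts = [], []
    for g in groups:
        perm = rng.permutation(len(g))
        n_train = int(round(spec.train_fraction * len(g)))
        train_parts.append(g.iloc[perm[:n_train]])
        test_parts.append(g.iloc[perm[n_train:]])
    train = pd.concat(train_parts).sort_index()
    test = pd.concat(test_parts).sort_index()
    return train, test


def zscore_fit_transform(
    train: pd.DataFrame, test: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, tuple[float, float]]]:
    """Column-wise z-score, a' = (a - mu(A)) / sigma(A), fitted on train only.

    Returns normalized copies of both partitions and the per-feature
    ``{column: (mu, sigma)}`` parameters (population sigma, ddof=0).  A
    zero-variance training feature is rejected by name.
    """
    if len(train) == 0:
        raise ValueError("training partition is empty")
    params: dict[str, tuple[float, float]] = {}
    for col in FEATURE_COLUMNS:
        mu = float(train[col].to_numpy().mean())
        sd = float(train[col].to_numpy().std(ddof=0))
        if sd == 0:
            raise ValueError(f"feature {col!r} has zero variance on the training set")
        params[col] = (mu, sd)
    return zscore_apply(train, params), zscore_apply(test, params), params


def zscore_apply(
    df: pd.DataFrame, params: dict[str, tuple[float, float]]
) -> pd.DataFrame:
    out = df.copy()
    for col, (mu, sd) in params.items():
        out[col] = (out[col] - mu) / sd
    return out


def zscore_invert(
    df: pd.DataFrame, params: dict[str, tuple[float, float]]
) -> pd.DataFrame:
    out = df.copy()
    for col, (mu, sd) in params.items():
        out[col] = out[col] * sd + mu
    return out


def kfold_indices(
    n: int, k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled k-fold indices: validation folds partition 0..n-1, sizes within 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} records")
    perm = np.random.default_rng(seed).permutation(n)
    folds = np.array_split(perm, k)
    out = []
    for i, val in enumerate(folds):
        train = np.concatenate([f for j, f in enumerate(folds) if j != i])
        out.append((np.sort(train), np.sort(val)))
    return out
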