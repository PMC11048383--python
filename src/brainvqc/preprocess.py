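"""Deterministic feature preprocessing: min-max scaling, PCA, splits.

The modelling input is a 34-column volume table; before any learner sees it,
each feature is min-max scaled to [0, 1] (bounds fitted on the training
partition) and the scaled matrix is reduced to ``k`` principal components
(default 17, one per qubit of the quantum model).  Test-time values falling
outside the training bounds are clipped to [0, 1] after scaling so that the
downstream angle encoding stays within its designed domain.

Splitting is a single shuffled 80/20 partition with floor-based sizes:
``|train| = floor(0.8 N)`` and ``|test| = floor(0.2 N)``, discarding a
remainder subject when ``N`` is not a multiple of 5 (for N = 1157 this gives
the published 925 / 231).  Learning-curve subsamples are ``floor(f * N)`` of
the training ids, reproducing the published sweep sizes
{57, 115, 231, 462, 694, 925} for f in {.05, .10, .20, .40, .60, .80}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .cohort import FEATURE_NAMES, N_FEATURES

__all__ = [
    "PreprocessModel",
    "SplitIndex",
    "PipelineError",
    "fit_preprocess",
    "split",
    "subsample_train",
]


class PipelineError(ValueError):
    pass


def _feature_matrix(table: pd.DataFrame) -> np.ndarray:
    missing = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing:
        raise PipelineError(f"table is missing feature columns: {missing}")
    return table[list(FEATURE_NAMES)].to_numpy(dtype=float)


@dataclass
class PreprocessModel:
    """Fitted min-max bounds plus a PCA basis over the scaled feature space."""

    feat_min: np.ndarray        # (34,)
    feat_max: np.ndarray        # (34,)
    pca_mean: np.ndarray        # (34,) mean of scaled training data
    components: np.ndarray      # (k, 34), rows orthonormal
    explained_variance: np.ndarray  # (k,), non-increasing
    k: int

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        """Scale, clip to [0, 1], and project onto the k components."""
        X = _feature_matrix(table)
        scaled = (X - self.feat_min) / (self.feat_max - self.feat_min)
        np.clip(scaled, 0.0, 1.0, out=scaled)
        return (scaled - self.pca_mean) @ self.components.T

    def scale_only(self, table: pd.DataFrame) -> np.ndarray:
        """Min-max scaling with clipping, without the PCA projection."""
        X = _feature_matrix(table)
        scaled = (X - self.feat_min) / (self.feat_max - self.feat_min)
        np.clip(scaled, 0.0, 1.0, out=scaled)
        return scaled

    def inverse_project(self, scores: np.ndarray) -> np.ndarray:
        """Map component scores back to the scaled feature space."""
        return scores @ self.components + self.pca_mean

    def to_json(self, path=None) -> str:
        doc = {
            "k": self.k,
            "feature_names": list(FEATURE_NAMES),
            "feat_min": self.feat_min.tolist(),
            "feat_max": self.feat_max.tolist(),
            "pca_mean": self.pca_mean.tolist(),
            "components": self.components.tolist(),
            "explained_variance": self.explained_variance.tolist(),
        }
        text = json.dumps(doc)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PreprocessModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source, encoding="utf-8") as fh:
                doc = json.load(fh)
        return cls(
            feat_min=np.asarray(doc["feat_min"]),
            feat_max=np.asarray(doc["feat_max"]),
            pca_mean=np.asarray(doc["pca_mean"]),
            components=np.asarray(doc["components"]),
            explained_variance=np.asarray(doc["explained_variance"]),
            k=int(doc["k"]),
        )


def fit_preprocess(table: pd.DataFrame, k: int = 17) -> PreprocessModel:
    """Fit min-max bounds and a k-component PCA on (training) rows.

    The PCA is fitted on the scaled data.  Component signs follow the
    convention that each row's largest-magnitude loading is positive, so a
    fitted model serialises reproducibly.
    """
    X = _feature_matrix(table)
    if k > N_FEATURES:
        raise PipelineError(f"k={k} exceeds the number of features ({N_FEATURES})")
    if len(X) < k:
        raise PipelineError(f"need at least k={k} rows to fit, got {len(X)}")
    feat_min = X.min(axis=0)
    feat_max = X.max(axis=0)
    const = np.flatnonzero(feat_max <= feat_min)
    if const.size:
        raise PipelineError(f"constant feature column (degenerate min-max scale): {FEATURE_NAMES[const[0]]!r}")
    scaled = (X - feat_min) / (feat_max - feat_min)

    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(scaled)
    components = pca.components_.copy()
    # sign convention: largest-|loading| entry of each component positive
    for row in components:
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            row *= -1.0
    return PreprocessModel(
        feat_min=feat_min,
        feat_max=feat_max,
        pca_mean=pca.mean_.copy(),
        components=components,
        explained_variance=pca.explained_variance_.copy(),
        k=k,
    )


@dataclass(frozen=True)
class SplitIndex:
    """A reproducible 80/20 train/test partition by subject id.

    ``n_source`` is the cohort size before the floor split; up to four
    remainder subjects may belong to neither partition.
    """

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int
    n_source: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise PipelineError("train and test ids overlap")


def split(table: pd.DataFrame, seed: int) -> SplitIndex:
    """Shuffle once and partition into floor(0.8 N) train / floor(0.2 N) test."""
    n = len(table)
    if n < 5:
        raise PipelineError(f"need at least 5 subjects to split, got {n}")
    ids = table["subject_id"].to_numpy()
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(np.floor(0.8 * n))
    n_test = int(np.floor(0.2 * n))
    shuffled = ids[order]
    return SplitIndex(
        train_ids=tuple(shuffled[:n_train]),
        test_ids=tuple(shuffled[n_train:n_train + n_test]),
        seed=seed,
        n_source=n,
    )


def subsample_train(split_index: SplitIndex, fraction: float, seed: int) -> tuple[str, ...]:
    """Draw floor(fraction * N) training ids without replacement.

    ``fraction`` is relative to the full cohort size N (so 0.8 returns the
    whole training partition); subsamples at different fractions need not be
    nested.  Deterministic given ``seed``.
    """
    n = split_index.n_source
    if not (0.0 < fraction <= 0.8):
        raise PipelineError(f"fraction must be in (0, 0.8], got {fraction}")
    size = int(np.floor(fraction * n))
    if size > len(split_index.train_ids):
        raise PipelineError(
            f"requested {size} training subjects but only {len(split_index.train_ids)} available"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(split_index.train_ids), size=size, replace=False)
    return tuple(np.asarray(split_index.train_ids)[np.sort(chosen)])
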