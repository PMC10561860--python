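"""Class-imbalance handling: SMOTE oversampling and NearMiss-1 undersampling.

Both operate on the *training* feature matrix only — synthetic or subsampled
rows must never appear in evaluation data, so callers split first, balance
second. Both are bit-reproducible under a fixed seed.

* :func:`smote` raises the minority class to the majority count by
  interpolating new points between a minority point and one of its k nearest
  minority neighbours: ``x + u * (x' - x)``, u ~ Uniform(0, 1).
* :func:`nearmiss` (version 1) keeps the majority points with the smallest
  mean Euclidean distance to their k nearest minority points, down to the
  minority count. Versions 2 (k farthest minority points) and 3 are not
  implemented here; version selection is exposed for forward compatibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["BalancedDataset", "smote", "nearmiss"]


@dataclass
class BalancedDataset:
    """A balanced training matrix with provenance.

    ``synthetic`` flags rows created by interpolation (always all-False for
    undersampling); ``kept_indices`` maps retained rows back to the input for
    undersampling methods.
    """

    X: np.ndarray
    y: np.ndarray
    method: str  # smote | nearmiss | none
    k_neighbors: int
    seed: int
    counts_before: dict[int, int]
    counts_after: dict[int, int]
    synthetic: np.ndarray  # bool mask aligned to rows of X
    kept_indices: np.ndarray | None = None


def _class_counts(y: np.ndarray) -> dict[int, int]:
    vals, counts = np.unique(y, return_counts=True)
    return {int(v): int(c) for v, c in zip(vals, counts)}


def _check_binary(y: np.ndarray) -> tuple[int, int]:
    """Return (minority_label, majority_label)."""
    counts = _class_counts(y)
    if len(counts) != 2:
        raise ValueError(f"balancing needs exactly 2 classes, got {sorted(counts)}")
    (a, na), (b, nb) = counts.items()
    return (a, b) if na <= nb else (b, a)


def smote(
    X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0
) -> BalancedDataset:
    """Synthetic Minority Over-sampling Technique.

    For each synthetic sample, pick a minority point x (cycled in random
    order), one of its k nearest minority neighbours x' (Euclidean), and emit
    ``x + u * (x' - x)`` with u ~ Uniform(0, 1). The minority count is raised
    to the majority count.
    """
    from sklearn.neighbors import NearestNeighbors

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    minority, majority = _check_binary(y)
    before = _class_counts(y)
    n_needed = before[majority] - before[minority]
    minority_X = X[y == minority]
    if len(minority_X) < k + 1:
        raise ValueError(
            f"minority class has {len(minority_X)} members; SMOTE with k={k} "
            f"needs at least {k + 1} — use a smaller k"
        )
    rng = np.random.default_rng(seed)
    # k+1 neighbours because each point is its own nearest neighbour
    nn = NearestNeighbors(n_neighbors=k + 1).fit(minority_X)
    _, neigh = nn.kneighbors(minority_X)
    neigh = neigh[:, 1:]  # drop self

    synth = np.empty((n_needed, X.shape[1]))
    base = rng.permutation(len(minority_X))
    for s in range(n_needed):
        i = base[s % len(minority_X)]
        j = neigh[i, rng.integers(k)]
        u = rng.random()
        synth[s] = minority_X[i] + u * (minority_X[j] - minority_X[i])

    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    mask = np.zeros(len(X_out), dtype=bool)
    mask[len(X):] = True
    return BalancedDataset(
        X=X_out,
        y=y_out,
        method="smote",
        k_neighbors=k,
        seed=seed,
        counts_before=before,
        counts_after=_class_counts(y_out),
        synthetic=mask,
    )


def nearmiss(
    X: np.ndarray, y: np.ndarray, k: int = 3, seed: int = 0, version: int = 1
) -> BalancedDataset:
    """NearMiss-1 undersampling of the majority class.

    Keeps the majority points with the smallest mean Euclidean distance to
    their k nearest minority points, down to the minority count. Ties broken
    by original row order for determinism. Equal classes return the input
    unchanged with a warning.
    """
    from sklearn.neighbors import NearestNeighbors

    if version != 1:
        raise NotImplementedError("only NearMiss version 1 is implemented")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    minority, majority = _check_binary(y)
    before = _class_counts(y)
    if before[minority] == before[majority]:
        warnings.warn("classes already balanced; NearMiss is a no-op", stacklevel=2)
        return BalancedDataset(
            X=X.copy(),
            y=y.copy(),
            method="nearmiss",
            k_neighbors=k,
            seed=seed,
            counts_before=before,
            counts_after=before,
            synthetic=np.zeros(len(X), dtype=bool),
            kept_indices=np.arange(len(X)),
        )
    minority_X = X[y == minority]
    majority_idx = np.flatnonzero(y == majority)
    k_eff = min(k, len(minority_X))
    nn = NearestNeighbors(n_neighbors=k_eff).fit(minority_X)
    dist, _ = nn.kneighbors(X[majority_idx])
    mean_dist = dist.mean(axis=1)
    order = np.argsort(mean_dist, kind="stable")  # stable => ties by row order
    keep_majority = majority_idx[order[: before[minority]]]
    keep = np.sort(np.concatenate([np.flatnonzero(y == minority), keep_majority]))
    out_y = y[keep]
    return BalancedDataset(
        X=X[keep],
        y=out_y,
        method="nearmiss",
        k_neighbors=k_eff,
        seed=seed,
        counts_before=before,
        counts_after=_class_counts(out_y),
        synthetic=np.zeros(len(keep), dtype=bool),
        kept_indices=keep,
    )
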