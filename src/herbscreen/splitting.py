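"""Stratified Kennard-Stone train/test splitting.

The Kennard-Stone algorithm picks a maximally space-filling training subset:
start from the two mutually most distant points, then repeatedly add the
point whose minimum distance to the already-selected set is largest.  Run
independently within each activity class so that both classes keep the
target train fraction, on standardized features with Euclidean distance.
Deterministic; ties broken by lowest input index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .io import DataError


@dataclass(frozen=True)
class SplitResult:
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    ratio: float


def _kennard_stone_indices(X: np.ndarray, n_train: int) -> list[int]:
    """Indices of the Kennard-Stone selection of size ``n_train`` from X."""
    n = X.shape[0]
    if n_train >= n:
        return list(range(n))
    D = squareform(pdist(X, metric="euclidean"))
    # seed pair: mutually most distant; ties -> first (i, j) in row-major order
    iu = np.triu_indices(n, k=1)
    k = int(np.argmax(D[iu]))
    i, j = int(iu[0][k]), int(iu[1][k])
    selected = [i, j][:n_train]
    if n_train == 1:
        return [selected[0]]
    remaining = [k for k in range(n) if k not in selected]
    mindist = np.minimum(D[selected[0]], D[selected[1]])
    while len(selected) < n_train:
        # max-min criterion over remaining points; first index wins ties
        best = max(remaining, key=lambda k: (mindist[k], -k))
        selected.append(best)
        remaining.remove(best)
        mindist = np.minimum(mindist, D[best])
    return selected


def kennard_stone_split(
    X: np.ndarray,
    labels: np.ndarray,
    ids: list[str] | None = None,
    ratio: float = 0.8,
) -> SplitResult:
    """Split samples into train/test by stratified Kennard-Stone selection.

    Parameters
    ----------
    X : (n, p) feature matrix, no missing values.
    labels : binary class vector of length n.
    ids : sample identifiers; defaults to stringified row indices.
    ratio : target train fraction (per class, rounded to the nearest count).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.ndim == 1:
        X = X[:, None]
    if np.isnan(X).any():
        raise DataError("feature matrix contains NaN")
    if not 0 < ratio < 1:
        raise DataError(f"train fraction must be in (0, 1), got {ratio}")
    if ids is None:
        ids = [str(i) for i in range(X.shape[0])]
    # standardize per column for distance comparability across descriptor scales
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    train_idx: list[int] = []
    for cls in np.unique(labels):
        rows = np.flatnonzero(labels == cls)
        if rows.size < 2:
            raise DataError(f"class {cls!r} has fewer than 2 members")
        n_train = int(round(rows.size * ratio))
        n_train = min(max(n_train, 1), rows.size - 1)
        picked = _kennard_stone_indices(Z[rows], n_train)
        train_idx.extend(int(rows[k]) for k in picked)
    train_set = set(train_idx)
    train_ids = tuple(ids[k] for k in sorted(train_set))
    test_ids = tuple(ids[k] for k in range(X.shape[0]) if k not in train_set)
    return SplitResult(train_ids, test_ids, ratio)
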