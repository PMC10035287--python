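"""Greedy forward stepwise feature selection by the Lawley-Hotelling trace.

The Lawley-Hotelling trace

    V = (n - g) * tr(W^{-1} B)

with W the within-groups sum-of-crossproducts matrix and B the weighted
between-group mean crossproducts, measures how far apart the group centroids
sit relative to the within-group scatter.  The selector starts from an empty
set and, at each step, tries every remaining candidate feature, computes V
of the augmented set, and adds the candidate with the largest V, until the
requested number of features is reached.

With far more candidate features than trials, exact collinearity among
candidates is common; candidates that make W numerically singular at a step
are skipped at that step and recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureID

logger = logging.getLogger(__name__)

_RCOND = 1e-12  # reciprocal-condition threshold below which W counts as singular
_TIE_RTOL = 1e-9  # relative tolerance for V ties (lower catalog index wins)


class SingularWithinMatrixError(np.linalg.LinAlgError):
    """W is singular (or nearly so) for the candidate feature set."""


@dataclass
class GroupedFeatureMatrix:
    """Feature values for ``n`` labeled trials.

    Attributes
    ----------
    X : ndarray, shape (n, p)
        One row per trial, one column per catalog feature.
    labels : ndarray, shape (n,)
        Group label per trial; every group must have >= 2 members.
    catalog : list of FeatureID, length p
        Identity of each column.
    """

    X: np.ndarray
    labels: np.ndarray
    catalog: list[FeatureID]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        n, p = self.X.shape
        if self.labels.shape != (n,):
            raise ValueError("labels must have one entry per trial")
        if len(self.catalog) != p:
            raise ValueError("catalog must have one entry per feature column")
        _, counts = np.unique(self.labels, return_counts=True)
        if counts.min() < 2:
            raise ValueError("every group needs at least 2 trials")
        if np.any(np.all(~np.isfinite(self.X), axis=0)):
            raise ValueError("a feature column is entirely non-finite")


@dataclass
class SelectionResult:
    """Outcome of the greedy selection.

    ``v_trajectory[k]`` is the Lawley-Hotelling V after the ``(k+1)``-th
    addition; it is non-decreasing.  ``skipped`` collects features rejected
    for singularity at any step (they may have been retried later).
    """

    selected: list[FeatureID]
    selected_indices: list[int]
    v_trajectory: list[float]
    skipped: list[FeatureID] = field(default_factory=list)


def _group_split(labels: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(labels == gl) for gl in np.unique(labels)]


def within_groups_sscp(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Within-groups sum-of-crossproducts matrix.

    ``W[i, j] = sum_k sum_{m in group k} (X[m, i] - mean_k[i]) * (X[m, j] - mean_k[j])``

    Symmetric and positive semidefinite by construction.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    W = np.zeros((X.shape[1], X.shape[1]))
    for idx in _group_split(np.asarray(labels)):
        Xc = X[idx] - X[idx].mean(axis=0)
        W += Xc.T @ Xc
    return W


def _between_groups(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    grand = X.mean(axis=0)
    B = np.zeros((X.shape[1], X.shape[1]))
    for idx in _group_split(labels):
        d = X[idx].mean(axis=0) - grand
        B += len(idx) * np.outer(d, d)
    return B


def lawley_hotelling_V(
    X: np.ndarray, labels: np.ndarray, rcond: float = _RCOND
) -> float:
    """Lawley-Hotelling trace ``V = (n - g) * tr(W^{-1} B)`` of a feature subset.

    Parameters
    ----------
    X : ndarray, shape (n, q)
        Feature subset, one column per included feature.
    labels : ndarray, shape (n,)
        Group labels.
    rcond : float
        Reciprocal-condition threshold; W with smaller relative smallest
        singular value raises :class:`SingularWithinMatrixError`.

    Notes
    -----
    The inverse of W is never formed explicitly; the trace is evaluated
    through a linear solve.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    n = X.shape[0]
    g = np.unique(labels).size
    W = within_groups_sscp(X, labels)
    s = np.linalg.svd(W, compute_uv=False)
    if s[0] == 0.0 or s[-1] <= rcond * s[0]:
        raise SingularWithinMatrixError(
            "within-groups crossproducts matrix is singular for this feature set"
        )
    B = _between_groups(X, labels)
    V = (n - g) * float(np.trace(np.linalg.solve(W, B)))
    return V


def stepwise_select(gfm: GroupedFeatureMatrix, n_select: int) -> SelectionResult:
    """Greedy forward selection of ``n_select`` features maximizing V.

    At each step every unselected candidate is evaluated afresh as part of
    the augmented set; the argmax is added.  Ties within relative 1e-9 are
    broken toward the lower catalog index, making the procedure
    deterministic.  If at some step every remaining candidate leaves W
    singular, selection stops early with a logged warning.
    """
    p = gfm.X.shape[1]
    if not 1 <= n_select <= p:
        raise ValueError(f"n_select must be in 1..{p}, got {n_select}")

    selected: list[int] = []
    trajectory: list[float] = []
    skipped: dict[int, FeatureID] = {}
    remaining = list(range(p))

    for step in range(n_select):
        best_v = -np.inf
        best_idx: int | None = None
        for cand in remaining:
            cols = selected + [cand]
            try:
                v = lawley_hotelling_V(gfm.X[:, cols], gfm.labels)
            except SingularWithinMatrixError:
                skipped[cand] = gfm.catalog[cand]
                continue
            # strict improvement beyond the tie band; first (lowest) index wins ties
            if best_idx is None or v > best_v + _TIE_RTOL * max(abs(best_v), 1.0):
                best_v = v
                best_idx = cand
        if best_idx is None:
            logger.warning(
                "stepwise selection stopped at %d features: all remaining "
                "candidates make W singular",
                len(selected),
            )
            break
        if trajectory and best_v - trajectory[-1] < 1e-6:
            logger.info(
                "step %d: V gain %.3g is below 1e-6", step + 1, best_v - trajectory[-1]
            )
        selected.append(best_idx)
        remaining.remove(best_idx)
        trajectory.append(best_v)

    return SelectionResult(
        selected=[gfm.catalog[i] for i in selected],
        selected_indices=selected,
        v_trajectory=trajectory,
        skipped=list(skipped.values()),
    )
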