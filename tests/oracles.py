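"""Independent reference implementations used only to check the package.

Each oracle is written the slow, literal way — explicit level-j filters,
double/triple loops, explicit matrix inverses — deliberately sharing no code
path with the implementation under test.
"""

from __future__ import annotations

import numpy as np


def level_filters(g: np.ndarray, h: np.ndarray, j: int) -> tuple[np.ndarray, np.ndarray]:
    """Explicit level-j MODWT filter pair of width (2**j - 1)*(L - 1) + 1.

    Built by cascading the rescaled base pair: the level-j scaling filter is
    the (j-1)-level scaling filter convolved with the base scaling filter
    upsampled by 2**(j-1); the wavelet filter swaps in the upsampled base
    wavelet filter at the last stage.
    """
    g_t = np.asarray(g, dtype=float) / np.sqrt(2.0)
    h_t = np.asarray(h, dtype=float) / np.sqrt(2.0)

    def upsample(f: np.ndarray, factor: int) -> np.ndarray:
        out = np.zeros((len(f) - 1) * factor + 1)
        out[::factor] = f
        return out

    g_prev = np.array([1.0])
    for level in range(1, j):
        g_prev = np.convolve(g_prev, upsample(g_t, 2 ** (level - 1)))
    step = 2 ** (j - 1)
    return np.convolve(g_prev, upsample(h_t, step)), np.convolve(
        g_prev, upsample(g_t, step)
    )


def direct_modwt_level(x: np.ndarray, g: np.ndarray, h: np.ndarray, j: int):
    """Level-j detail and scaling coefficients by direct circular convolution.

    W_j[t] = sum_l h_j[l] * x[(t - l) mod N], same for V_j with g_j.
    """
    x = np.asarray(x, dtype=float)
    N = x.size
    h_j, g_j = level_filters(g, h, j)
    W = np.zeros(N)
    V = np.zeros(N)
    for t in range(N):
        for l, (hl, gl) in enumerate(zip(h_j, g_j)):
            W[t] += hl * x[(t - l) % N]
            V[t] += gl * x[(t - l) % N]
    return W, V


def brute_within_sscp(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """W by the literal double loop over groups and members."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim == 1:
        X = X[:, None]
    q = X.shape[1]
    groups = np.unique(labels)
    W = np.zeros((q, q))
    for i in range(q):
        for j in range(q):
            for gl in groups:
                rows = X[labels == gl]
                mi, mj = rows[:, i].mean(), rows[:, j].mean()
                for m in range(rows.shape[0]):
                    W[i, j] += (rows[m, i] - mi) * (rows[m, j] - mj)
    return W


def brute_lawley_hotelling(X: np.ndarray, labels: np.ndarray) -> float:
    """V by literal term-by-term evaluation with an explicit inverse."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    n, q = X.shape
    groups = np.unique(labels)
    g = groups.size
    a = np.linalg.inv(brute_within_sscp(X, labels))
    grand = X.mean(axis=0)
    V = 0.0
    for i in range(q):
        for j in range(q):
            term = 0.0
            for gl in groups:
                rows = X[labels == gl]
                term += rows.shape[0] * (rows[:, i].mean() - grand[i]) * (
                    rows[:, j].mean() - grand[j]
                )
            V += a[i, j] * term
    return (n - g) * V


def exhaustive_greedy(X: np.ndarray, labels: np.ndarray, n_select: int) -> list[int]:
    """Forward selection evaluating brute-force V for every candidate per step."""
    p = X.shape[1]
    selected: list[int] = []
    for _ in range(n_select):
        best, best_v = None, -np.inf
        for cand in range(p):
            if cand in selected:
                continue
            cols = selected + [cand]
            try:
                v = brute_lawley_hotelling(X[:, cols], labels)
            except np.linalg.LinAlgError:
                continue
            if v > best_v:
                best, best_v = cand, v
        if best is None:
            break
        selected.append(best)
    return selected
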