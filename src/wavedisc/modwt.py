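"""Wavelet filter bank and the maximal overlap discrete wavelet transform.

The MODWT is a non-decimated variant of the discrete wavelet transform: it
produces ``N`` coefficients at every decomposition level for a series of
length ``N``, is equivariant under circular shifts of the input, and (with
orthonormal filters) partitions the series energy exactly across the detail
levels and the final smooth.  Level ``j`` captures, for a sampling rate
``fs``, approximately the octave band ``[fs / 2**(j+1), fs / 2**j]`` Hz.

Filters follow the DWT orthonormal convention (``sum(g) = sqrt(2)``, unit
energy, quadrature-mirror ``h[l] = (-1)**l * g[L-1-l]``); the MODWT uses the
rescaled pair ``(h / sqrt(2), g / sqrt(2))``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt

logger = logging.getLogger(__name__)

# Public name -> PyWavelets name.  dL = Daubechies extremal-phase filter of
# length L; la6 = least-asymmetric (symlet) of length 6; c6 = Coiflet of
# length 6.  Coefficients come from the PyWavelets tables (standard published
# values); the sign/ordering convention is fixed below by deriving h from g
# through the quadrature-mirror relation.
_PYWT_NAMES = {
    "haar": "haar",
    "d4": "db2",
    "d6": "db3",
    "d8": "db4",
    "la6": "sym3",
    "c6": "coif1",
}

SUPPORTED_FILTERS = tuple(_PYWT_NAMES)


class UnsupportedFilterError(ValueError):
    """Raised for a wavelet filter name outside the supported set."""


@dataclass(frozen=True)
class WaveletFilter:
    """An orthonormal quadrature filter pair in the DWT convention.

    Attributes
    ----------
    name : str
        One of :data:`SUPPORTED_FILTERS`.
    L : int
        Filter length in taps.
    g : numpy.ndarray
        Scaling (low-pass) coefficients, ``sum(g) = sqrt(2)``.
    h : numpy.ndarray
        Wavelet (high-pass) coefficients, ``sum(h) = 0``,
        ``h[l] = (-1)**l * g[L-1-l]``.
    """

    name: str
    L: int
    g: np.ndarray = field(repr=False)
    h: np.ndarray = field(repr=False)


def get_filter(name: str) -> WaveletFilter:
    """Return the named quadrature filter pair in the DWT convention.

    Parameters
    ----------
    name : str
        One of ``haar, d4, d6, d8, la6, c6``.

    Raises
    ------
    UnsupportedFilterError
        If ``name`` is not in the supported set.
    """
    try:
        pywt_name = _PYWT_NAMES[name]
    except KeyError:
        raise UnsupportedFilterError(
            f"unsupported wavelet filter {name!r}; "
            f"valid names are: {', '.join(SUPPORTED_FILTERS)}"
        ) from None
    g = np.asarray(pywt.Wavelet(pywt_name).rec_lo, dtype=float)
    if g.sum() < 0:  # enforce sum(g) = +sqrt(2)
        g = -g
    L = g.size
    h = ((-1.0) ** np.arange(L)) * g[::-1]
    return WaveletFilter(name=name, L=L, g=g, h=h)


def modwt_rescale(f: WaveletFilter) -> tuple[np.ndarray, np.ndarray]:
    """Return the MODWT base filter pair ``(h_tilde, g_tilde) = (h, g) / sqrt(2)``.

    The rescaled pair satisfies ``sum(g_tilde) = 1``, ``sum(h_tilde) = 0`` and
    has energy 1/2 in each filter, which is what makes the non-decimated
    transform energy-preserving.
    """
    return f.h / np.sqrt(2.0), f.g / np.sqrt(2.0)


def level_filter_width(j: int, L: int) -> int:
    """Width ``L_j = (2**j - 1) * (L - 1) + 1`` of the level-``j`` equivalent filter."""
    return (2**j - 1) * (L - 1) + 1


def max_safe_level(N: int, L: int) -> int:
    """Largest decomposition level whose equivalent filter fits in the series.

    Returns the largest integer ``J`` with ``J < log2(N / (L - 1) + 1)``,
    i.e. the deepest level at which the level-``J`` filter width ``L_J`` does
    not exceed ``N`` (so at least one non-boundary coefficient exists).

    Raises
    ------
    ValueError
        If ``N < L``.
    """
    if L < 2:
        raise ValueError(f"filter length must be >= 2, got {L}")
    if N < L:
        raise ValueError(f"series length {N} is shorter than the filter length {L}")
    # integer arithmetic: J < log2(N/(L-1)+1)  <=>  L_J <= N
    J = 1
    while level_filter_width(J + 1, L) <= N:
        J += 1
    return J


@dataclass
class MODWTDecomposition:
    """MODWT of one channel: ``J`` detail levels plus the final smooth.

    Every coefficient array has exactly ``N`` entries (the transform is
    non-decimated).  ``boundary_widths[j-1]`` is ``L_j``, the number of
    leading coefficients at level ``j`` affected by the circular wrap-around;
    variance and correlation estimators discard the first ``L_j - 1`` of them.
    """

    channel: str
    N: int
    J: int
    wavelet_coeffs: list[np.ndarray]
    scaling_coeffs: np.ndarray
    filter_name: str
    boundary_widths: list[int]

    def energy(self) -> float:
        """Total energy ``sum_j ||W_j||^2 + ||V_J||^2`` (equals ``||x||^2``)."""
        return float(
            sum(np.sum(w**2) for w in self.wavelet_coeffs)
            + np.sum(self.scaling_coeffs**2)
        )


def modwt(
    x: np.ndarray,
    f: WaveletFilter,
    J: int,
    channel: str = "",
) -> MODWTDecomposition:
    """MODWT of a series by the pyramid algorithm with circular boundaries.

    At level ``j`` the previous level's scaling coefficients are filtered
    with the base MODWT pair upsampled by ``2**(j-1)``:

    ``W_j[t] = sum_l h_tilde[l] * V_{j-1}[(t - l * 2**(j-1)) mod N]``

    which is numerically identical to direct circular convolution of the
    input with the explicitly built level-``j`` filters of width ``L_j``.

    Parameters
    ----------
    x : array_like
        Input series, length ``N >= 2``, all values finite.
    f : WaveletFilter
        Filter pair in the DWT convention (rescaled internally).
    J : int
        Number of detail levels, ``>= 1``.  Requesting ``J`` beyond
        :func:`max_safe_level` emits a warning rather than failing, since
        deep configurations on short series are sometimes wanted anyway;
        levels past the safe bound have no non-boundary coefficients.
    channel : str
        Optional channel identifier carried into the result.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("input must be a 1-D series with at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite values in input series {channel!r}")
    if J < 1:
        raise ValueError(f"number of levels must be >= 1, got {J}")
    N = x.size
    safe = max_safe_level(N, f.L) if N >= f.L else 0
    if J > safe:
        msg = (
            f"requested J={J} exceeds max_safe_level(N={N}, L={f.L})={safe}; "
            "levels beyond the bound have no non-boundary coefficients"
        )
        warnings.warn(msg)
        logger.warning(msg)

    h_t, g_t = modwt_rescale(f)
    v = x
    details: list[np.ndarray] = []
    for j in range(1, J + 1):
        step = 2 ** (j - 1)
        w_j = np.zeros(N)
        v_j = np.zeros(N)
        for l in range(f.L):
            rolled = np.roll(v, l * step)
            w_j += h_t[l] * rolled
            v_j += g_t[l] * rolled
        details.append(w_j)
        v = v_j

    return MODWTDecomposition(
        channel=channel,
        N=N,
        J=J,
        wavelet_coeffs=details,
        scaling_coeffs=v,
        filter_name=f.name,
        boundary_widths=[level_filter_width(j, f.L) for j in range(1, J + 1)],
    )
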