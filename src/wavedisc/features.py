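"""Per-trial feature extraction: wavelet variances and cross-channel wavelet correlations.

Each channel is z-normalized and decomposed with the MODWT; the candidate
feature set then consists of

* the wavelet variance of every channel at every level — a band-limited
  power estimate, and
* the wavelet correlation of every unordered channel pair at every level —
  band-limited linear coupling between channels.

Both estimators exclude the first ``L_j - 1`` boundary coefficients of each
level, leaving ``M_j = N - L_j + 1`` usable coefficients.  For ``P``
channels and ``J`` levels the catalog holds ``J*P`` variances and
``J*P*(P-1)/2`` correlations (22,176 features at P=63, J=11).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .modwt import MODWTDecomposition, WaveletFilter, get_filter, max_safe_level, modwt

FEATURE_TYPES = ("variance", "correlation")


class ZeroVarianceError(ValueError):
    """A channel is constant, so it cannot be z-normalized."""


class UndefinedCorrelationError(ValueError):
    """A coefficient segment is constant, so its correlation is undefined."""


@dataclass(frozen=True, order=True)
class FeatureID:
    """Identity of one candidate feature: type, level, channel(s).

    For correlation features ``chan_b`` names the second channel of the
    unordered pair (stored once, with ``chan_a`` before ``chan_b`` in the
    dataset's channel order); for variance features it is ``None``.
    """

    ftype: str
    level: int
    chan_a: str
    chan_b: str | None = None

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")
        if (self.chan_b is None) != (self.ftype == "variance"):
            raise ValueError("chan_b must be given iff the feature is a correlation")

    @property
    def name(self) -> str:
        """Serialized name, ``type_level_chanA[_chanB]`` (e.g. ``cor_j3_Cz_T8``)."""
        tag = "var" if self.ftype == "variance" else "cor"
        suffix = f"_{self.chan_b}" if self.chan_b is not None else ""
        return f"{tag}_j{self.level}_{self.chan_a}{suffix}"

    @property
    def channels(self) -> tuple[str, ...]:
        return (self.chan_a,) if self.chan_b is None else (self.chan_a, self.chan_b)


@dataclass
class FeatureVector:
    """Extracted feature values for one trial, in catalog order."""

    trial_id: str
    values: np.ndarray


def zscore_normalize(x: np.ndarray, label: str = "") -> np.ndarray:
    """Standardize a series to mean 0 and (population) standard deviation 1.

    Raises
    ------
    ZeroVarianceError
        If the series is constant; ``label`` (e.g. "trial 3, channel Cz")
        is included in the message.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to standardize")
    sd = x.std()  # population convention (divide by n)
    if sd == 0.0:
        where = f" ({label})" if label else ""
        raise ZeroVarianceError(f"constant series cannot be z-normalized{where}")
    return (x - x.mean()) / sd


def _nonboundary(d: MODWTDecomposition, j: int) -> np.ndarray:
    if not 1 <= j <= d.J:
        raise ValueError(f"level {j} outside 1..{d.J}")
    L_j = d.boundary_widths[j - 1]
    M_j = d.N - L_j + 1
    if M_j < 2:
        raise ValueError(
            f"series too short for level {j}: only {M_j} non-boundary "
            f"coefficients (L_j={L_j}, N={d.N})"
        )
    return d.wavelet_coeffs[j - 1][L_j - 1 :]


def wavelet_variance(d: MODWTDecomposition, j: int) -> float:
    """Wavelet variance at level ``j``: mean squared non-boundary coefficient.

    Returns ``(1/M_j) * sum_{t=L_j-1}^{N-1} W_j[t]**2`` with
    ``M_j = N - L_j + 1``.  Coefficient means are not subtracted: the raw
    second moment of the detail coefficients is the band-power estimate.
    """
    seg = _nonboundary(d, j)
    return float(np.mean(seg**2))


def wavelet_correlation(
    dx: MODWTDecomposition, dy: MODWTDecomposition, j: int
) -> float:
    """Wavelet correlation of two channels at level ``j``.

    Pearson correlation of the non-boundary detail coefficients of the two
    decompositions, guaranteed to lie in ``[-1, 1]``.

    Raises
    ------
    UndefinedCorrelationError
        If either coefficient segment is constant.
    ValueError
        If the decompositions use different filters, lengths or depths.
    """
    if dx.filter_name != dy.filter_name or dx.N != dy.N or dx.J != dy.J:
        raise ValueError(
            "correlation requires decompositions with the same filter, N and J"
        )
    a, b = _nonboundary(dx, j), _nonboundary(dy, j)
    if a.std() == 0.0 or b.std() == 0.0:
        raise UndefinedCorrelationError(
            f"constant coefficient segment at level {j} "
            f"({dx.channel!r} vs {dy.channel!r}): correlation undefined"
        )
    r = float(np.corrcoef(a, b)[0, 1])
    return min(1.0, max(-1.0, r))


def build_catalog(
    channels: int | Sequence[str],
    J: int,
    ftypes: Iterable[str] = FEATURE_TYPES,
) -> list[FeatureID]:
    """Enumerate the candidate feature set in deterministic order.

    Order: all variances (channel-major, level-minor), then all correlations
    (level-major, channel pairs in the order the channels were given).

    Parameters
    ----------
    channels : int or sequence of str
        Channel names, or a count (names default to ``ch00, ch01, ...``).
    J : int
        Number of decomposition levels.
    ftypes : iterable of {"variance", "correlation"}
        Feature families to include; must be nonempty.
    """
    if isinstance(channels, int):
        channels = [f"ch{i:02d}" for i in range(channels)]
    names = list(channels)
    if len(names) < 1 or J < 1:
        raise ValueError("need at least one channel and one level")
    ftypes = tuple(ftypes)
    if not ftypes or any(t not in FEATURE_TYPES for t in ftypes):
        raise ValueError(f"ftypes must be a nonempty subset of {FEATURE_TYPES}")

    catalog: list[FeatureID] = []
    if "variance" in ftypes:
        for ch in names:
            for j in range(1, J + 1):
                catalog.append(FeatureID("variance", j, ch))
    if "correlation" in ftypes:
        for j in range(1, J + 1):
            for a in range(len(names)):
                for b in range(a + 1, len(names)):
                    catalog.append(FeatureID("correlation", j, names[a], names[b]))
    return catalog


def extract_features(
    trial: np.ndarray,
    channel_names: Sequence[str],
    wavelet: str | WaveletFilter = "d4",
    J: int | None = None,
    ftypes: Iterable[str] = FEATURE_TYPES,
    trial_id: str = "",
) -> FeatureVector:
    """Extract the full candidate feature vector for one trial.

    Each channel is z-normalized (so features are invariant to per-channel
    gain) and decomposed once; values are filled in catalog order.

    Parameters
    ----------
    trial : ndarray, shape (P, N)
        One multichannel trial, channels x time samples.
    channel_names : sequence of str, length P
        Channel identifiers, fixing the catalog's channel order.
    wavelet : str or WaveletFilter
        Filter to use.
    J : int, optional
        Decomposition depth; defaults to ``max_safe_level(N, L)``.
    ftypes : iterable
        Feature families to compute.
    trial_id : str
        Carried into the result and into error messages.
    """
    trial = np.asarray(trial, dtype=float)
    if trial.ndim != 2:
        raise ValueError("trial must be a 2-D channels x time matrix")
    P, N = trial.shape
    if P != len(channel_names):
        raise ValueError(
            f"trial has {P} channels but {len(channel_names)} names were given"
        )
    f = wavelet if isinstance(wavelet, WaveletFilter) else get_filter(wavelet)
    if J is None:
        J = max_safe_level(N, f.L)

    decomps: dict[str, MODWTDecomposition] = {}
    for ch, row in zip(channel_names, trial):
        z = zscore_normalize(row, label=f"trial {trial_id!r}, channel {ch!r}")
        decomps[ch] = modwt(z, f, J, channel=ch)

    catalog = build_catalog(list(channel_names), J, ftypes)
    values = np.empty(len(catalog))
    for i, fid in enumerate(catalog):
        if fid.ftype == "variance":
            values[i] = wavelet_variance(decomps[fid.chan_a], fid.level)
        else:
            values[i] = wavelet_correlation(
                decomps[fid.chan_a], decomps[fid.chan_b], fid.level
            )
    return FeatureVector(trial_id=trial_id, values=values)
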