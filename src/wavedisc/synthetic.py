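"""Seeded generator of two-class multichannel trials with band-limited structure.

The generator emulates the statistical structure the classification pipeline
exploits in motor-imagery EEG without any pretense of physiological realism:
each channel of a trial is white Gaussian noise, and class differences are
injected as

* **coupled pairs** — a shared band-limited latent source (band-pass
  filtered white noise, drawn independently per trial) added to both
  channels of a pair with a class-dependent gain, so the pair's wavelet
  correlation at the levels overlapping the band depends on the class; and
* **power effects** — an independent band-limited component added to a
  single channel with a class-dependent gain, shifting that channel's
  wavelet variance in the band.

The default profile mirrors the study conditions the pipeline targets
(200 trials per class, 63 channels, 5500 samples at 1000 Hz); a test-scale
profile (8 channels, 512 samples) keeps simulation-based tests fast.

MODWT level ``j`` covers approximately the octave band
``[fs / 2**(j+1), fs / 2**j]`` Hz; :func:`band_to_levels` maps a configured
band to the levels where its effect lands.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

# Butterworth design for the band-limited latent sources.  Order 4 keeps the
# passband flat with acceptable roll-off for octave-wide bands; zero-phase
# filtering avoids introducing lag between coupled channels.
_FILTER_ORDER = 4

CLASS_LABELS = ("foot", "hand")


@dataclass(frozen=True)
class CoupledPair:
    """Cross-channel coupling: a shared source in ``[f_low, f_high]`` Hz.

    ``coupling_class0`` / ``coupling_class1`` are the target wavelet
    correlations (in [-1, 1]) the shared source induces between the two
    channels at the levels overlapping the band, for each class.
    """

    chan_a: int
    chan_b: int
    f_low: float
    f_high: float
    coupling_class0: float
    coupling_class1: float


@dataclass(frozen=True)
class PowerEffect:
    """Band-limited variance boost on one channel, class-dependent gain."""

    chan: int
    f_low: float
    f_high: float
    gain_class0: float
    gain_class1: float


@dataclass
class SyntheticConfig:
    """Generator configuration; defaults mirror the study-scale conditions."""

    n_trials_per_class: int = 200
    n_channels: int = 63
    n_samples: int = 5500
    fs: float = 1000.0
    coupled_pairs: tuple[CoupledPair, ...] = ()
    power_effects: tuple[PowerEffect, ...] = ()
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for cp in self.coupled_pairs:
            _check_band(cp.f_low, cp.f_high, self.fs)
            for c in (cp.coupling_class0, cp.coupling_class1):
                if not -1.0 <= c <= 1.0:
                    raise ValueError(f"coupling {c} outside [-1, 1]")
        for pe in self.power_effects:
            _check_band(pe.f_low, pe.f_high, self.fs)

    @property
    def channel_names(self) -> list[str]:
        return [f"ch{i:02d}" for i in range(self.n_channels)]


def small_scale_config(**overrides) -> SyntheticConfig:
    """A small profile (8 channels, 512 samples) for fast simulations."""
    cfg = SyntheticConfig(
        n_trials_per_class=20, n_channels=8, n_samples=512, fs=1000.0
    )
    return replace(cfg, **overrides)


def _check_band(f_low: float, f_high: float, fs: float) -> None:
    if not 0.0 < f_low < f_high < fs / 2.0:
        raise ValueError(
            f"band ({f_low}, {f_high}) Hz must satisfy 0 < low < high < fs/2 = {fs / 2}"
        )


def band_to_levels(f_low: float, f_high: float, fs: float, J: int) -> list[int]:
    """Decomposition levels whose octave band overlaps ``(f_low, f_high)``.

    Level ``j`` spans approximately ``[fs / 2**(j+1), fs / 2**j]`` Hz.
    """
    levels = []
    for j in range(1, J + 1):
        lo, hi = fs / 2 ** (j + 1), fs / 2**j
        if f_low < hi and f_high > lo:
            levels.append(j)
    return levels


def _bandlimited_source(
    rng: np.random.Generator, n: int, f_low: float, f_high: float, fs: float
) -> np.ndarray:
    """Unit-variance band-pass-filtered white noise."""
    sos = signal.butter(
        _FILTER_ORDER, [f_low, f_high], btype="bandpass", fs=fs, output="sos"
    )
    s = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return s / s.std()


def _coupling_gain(c: float, noise_sd: float, bw_fraction: float) -> float:
    """Gain giving in-band correlation ~ |c| between two channels sharing a source.

    With channel = noise + gain * s (s unit-variance, band-limited, shared),
    the in-band correlation is gain^2 / (gain^2 + sigma_band^2) where
    sigma_band^2 = noise_sd^2 * bw_fraction is the white-noise power falling
    inside the band; solving for gain gives the expression below.
    """
    c = min(abs(c), 0.999)
    if c == 0.0:
        return 0.0
    return float(np.sqrt(c / (1.0 - c) * noise_sd**2 * bw_fraction))


def generate_dataset(
    cfg: SyntheticConfig,
) -> tuple[list[np.ndarray], np.ndarray, dict]:
    """Generate a labeled two-class dataset of multichannel trials.

    Returns
    -------
    trials : list of ndarray, shape (P, N) each
        ``2 * n_trials_per_class`` trials; class-0 trials first.
    labels : ndarray of str
        ``"foot"`` for class 0, ``"hand"`` for class 1 (balanced exactly).
    ground_truth : dict
        Where the injected class differences live: for each coupled pair and
        power effect, the channels involved and the decomposition levels
        (octave bands) overlapping its configured frequency band, assuming
        the study sampling rate in ``cfg.fs``.

    Identical configurations (including ``seed``) give bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    P, N = cfg.n_channels, cfg.n_samples
    n_per = cfg.n_trials_per_class

    # deep enough to cover any band down to ~0.25 Hz at fs=1000
    J_map = max(1, int(np.log2(N)))

    trials: list[np.ndarray] = []
    labels: list[str] = []
    for cls in (0, 1):
        for _ in range(n_per):
            trial = rng.normal(0.0, cfg.noise_sd, size=(P, N))
            for cp in cfg.coupled_pairs:
                c = cp.coupling_class0 if cls == 0 else cp.coupling_class1
                s = _bandlimited_source(rng, N, cp.f_low, cp.f_high, cfg.fs)
                bw_fraction = (cp.f_high - cp.f_low) / (cfg.fs / 2.0)
                gain = _coupling_gain(c, cfg.noise_sd, bw_fraction)
                trial[cp.chan_a] += gain * s
                trial[cp.chan_b] += np.sign(c) * gain * s if c != 0 else 0.0
            for pe in cfg.power_effects:
                gain = pe.gain_class0 if cls == 0 else pe.gain_class1
                if gain != 0.0:
                    u = _bandlimited_source(rng, N, pe.f_low, pe.f_high, cfg.fs)
                    trial[pe.chan] += cfg.noise_sd * gain * u
            trials.append(trial)
            labels.append(CLASS_LABELS[cls])

    names = cfg.channel_names
    ground_truth = {
        "coupled_pairs": [
            {
                "channels": [names[cp.chan_a], names[cp.chan_b]],
                "band_hz": [cp.f_low, cp.f_high],
                "levels": band_to_levels(cp.f_low, cp.f_high, cfg.fs, J_map),
                "coupling": [cp.coupling_class0, cp.coupling_class1],
            }
            for cp in cfg.coupled_pairs
        ],
        "power_effects": [
            {
                "channel": names[pe.chan],
                "band_hz": [pe.f_low, pe.f_high],
                "levels": band_to_levels(pe.f_low, pe.f_high, cfg.fs, J_map),
                "gain": [pe.gain_class0, pe.gain_class1],
            }
            for pe in cfg.power_effects
        ],
    }
    return trials, np.array(labels), ground_truth
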