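"""Synthetic motor-imagery-like EEG and feature-level fixtures.

``generate_mi_trials`` emulates the statistical structure the pipeline
assumes: multichannel 1/f-colored background noise plus a band-limited
mu-rhythm oscillation (8–12 Hz by default), where the imagined movement
class attenuates the oscillation amplitude on a class-specific electrode
set during the middle of the trial (event-related desynchronization).
The default geometry matches the feature extractor: 15 electrodes at
256 Hz, 1,016 samples per trial, 3 balanced classes.

``generate_feature_patterns`` skips the signal stage and directly produces
a normalized variance-like feature matrix with a known set of informative
(planted) features, used to test the feature-selection search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureMatrix, EEGTrialSet

__all__ = [
    "SimulationConfig",
    "default_erd_electrodes",
    "generate_mi_trials",
    "generate_feature_patterns",
    "make_benchmark_suite",
]


def default_erd_electrodes(n_electrodes: int = 15, n_classes: int = 3) -> dict:
    """Disjoint electrode groups per class (up to 3 electrodes each),
    loosely mimicking lateralized sensorimotor topographies.

    With the default 15 electrodes and 3 classes this yields
    {0: (0,1,2), 1: (5,6,7), 2: (10,11,12)}.
    """
    group = max(1, n_electrodes // n_classes)
    count = min(3, group)
    return {
        c: tuple(range(c * group, c * group + count)) for c in range(n_classes)
    }


@dataclass
class SimulationConfig:
    n_trials_per_class: int = 30
    n_classes: int = 3
    n_electrodes: int = 15
    sampling_rate: float = 256.0
    trial_length_samples: int = 1016
    erd_electrodes_per_class: dict | None = None
    erd_band: tuple[float, float] = (8.0, 12.0)
    erd_depth: float = 0.5
    noise_exponent: float = 1.0
    oscillation_amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.erd_depth <= 1.0):
            raise ValueError("erd_depth must be in [0, 1]")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.erd_electrodes_per_class is None:
            self.erd_electrodes_per_class = default_erd_electrodes(
                self.n_electrodes, self.n_classes
            )
        for c, electrodes in self.erd_electrodes_per_class.items():
            if c >= self.n_classes:
                raise ValueError("class index out of range in erd_electrodes_per_class")
            if any(e >= self.n_electrodes for e in electrodes):
                raise ValueError("electrode index out of range")


def _pink_noise(n_samples: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """1/f^exponent noise by spectral shaping of white noise, unit variance."""
    white = rng.standard_normal(n_samples)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    shaped = np.fft.irfft(spectrum * scale, n=n_samples)
    return shaped / shaped.std()


def _band_oscillation(
    n_samples: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Narrow-band signal: random-phase spectrum restricted to the band."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    spectrum = np.zeros(freqs.size, dtype=complex)
    phases = rng.uniform(0, 2 * np.pi, int(in_band.sum()))
    spectrum[in_band] = np.exp(1j * phases)
    signal = np.fft.irfft(spectrum, n=n_samples)
    return signal / signal.std()


def generate_mi_trials(config: SimulationConfig | None = None) -> EEGTrialSet:
    """Balanced synthetic trials with class-dependent band-power attenuation.

    Every electrode carries 1/f noise plus a mu-band oscillation; for a
    trial of class c, the oscillation on that class's electrodes is scaled
    by (1 - erd_depth) over the middle half of the trial.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    n_trials = config.n_trials_per_class * config.n_classes
    T = config.trial_length_samples
    signals = np.empty((n_trials, config.n_electrodes, T))
    labels = np.repeat(np.arange(config.n_classes), config.n_trials_per_class)
    erd_window = slice(T // 4, 3 * T // 4)  # middle half of the trial
    for trial_idx, label in enumerate(labels):
        attenuated = set(config.erd_electrodes_per_class.get(int(label), ()))
        for e in range(config.n_electrodes):
            noise = _pink_noise(T, config.noise_exponent, rng)
            osc = _band_oscillation(T, config.sampling_rate, config.erd_band, rng)
            envelope = np.full(T, config.oscillation_amplitude)
            if e in attenuated:
                envelope[erd_window] *= 1.0 - config.erd_depth
            signals[trial_idx, e] = noise + envelope * osc
    return EEGTrialSet(signals, labels, config.sampling_rate)


def generate_feature_patterns(
    n_patterns: int = 178,
    n_features: int = 3600,
    n_informative: int = 0,
    effect_size: float = 0.0,
    n_classes: int = 3,
    seed: int = 0,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Variance-like feature matrix with planted class-informative columns.

    Base features are right-skewed positive draws (lognormal).  Each
    informative column receives a class-dependent mean shift of
    ``effect_size`` pooled-SD units between adjacent classes.  Features are
    min-max normalized to [0, 1].  Returns the matrix and the planted
    column indices.
    """
    if n_informative > n_features:
        raise ValueError("n_informative cannot exceed n_features")
    if n_patterns < n_classes or n_classes < 2:
        raise ValueError("invalid sizes")
    rng = np.random.default_rng(seed)
    labels = np.arange(n_patterns) % n_classes
    rng.shuffle(labels)
    base_sigma = 0.5
    values = rng.lognormal(mean=0.0, sigma=base_sigma, size=(n_patterns, n_features))
    informative = rng.choice(n_features, size=n_informative, replace=False)
    informative.sort()
    if n_informative and effect_size != 0.0:
        pooled_sd = values[:, informative].std()
        offsets = (labels - (n_classes - 1) / 2.0) * effect_size * pooled_sd
        values[:, informative] += offsets[:, None]
    lo, hi = values.min(axis=0), values.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    values = (values - lo) / span
    names = [f"f{j:04d}" for j in range(n_features)]
    return FeatureMatrix(values, labels, names), informative


def make_benchmark_suite(seed: int = 0) -> dict:
    """The three named feature-level fixtures used by the acceptance tests.

    * ``null`` — no informative features (chance-level classification);
    * ``strong`` — many moderately informative features (learnable signal);
    * ``planted`` — 5 strongly informative features out of 200, for
      feature-selection recovery.

    Each entry records its generator arguments and planted indices.
    """
    specs = {
        "null": dict(n_patterns=178, n_features=200, n_informative=0, effect_size=0.0),
        "strong": dict(n_patterns=178, n_features=200, n_informative=30, effect_size=0.7),
        "planted": dict(n_patterns=178, n_features=200, n_informative=5, effect_size=2.0),
    }
    suite = {}
    for i, (name, kwargs) in enumerate(specs.items()):
        fixture_seed = seed * 10 + i
        matrix, informative = generate_feature_patterns(seed=fixture_seed, **kwargs)
        suite[name] = {
            "matrix": matrix,
            "informative": informative,
            "config": {**kwargs, "seed": fixture_seed},
        }
    return suite
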