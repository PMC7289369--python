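"""Wavelet-variance feature extraction for motor-imagery EEG trials.

Each electrode signal of a trial is cut into overlapping segments, every
segment is decomposed with a discrete wavelet transform (multiresolution
analysis), and every coefficient set — one approximation and one detail set
per decomposition level — is summarized by its variance.  With the default
geometry (20 segments, 15 electrodes, 6 levels) a trial maps to a
2 * 20 * 15 * 6 = 3,600-dimensional pattern, collapsing 151,200 raw wavelet
coefficients to one variance per set.

Level labeling convention: the first decomposition stage produces the
largest coefficient sets (128 coefficients for a 256-sample segment) and is
labeled level ``n_levels``; the deepest stage (4 coefficients) is level 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.preprocessing import MinMaxScaler

__all__ = [
    "EEGTrialSet",
    "MRAConfig",
    "FeatureMatrix",
    "segment_signal",
    "dwt_mra",
    "extract_pattern",
    "extract_features",
    "normalize_features",
    "WaveletVarianceExtractor",
]


@dataclass
class EEGTrialSet:
    """Raw EEG trials: ``signals`` is (n_trials, n_electrodes, n_samples)."""

    signals: np.ndarray
    labels: np.ndarray
    sampling_rate: float = 256.0

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.signals.ndim != 3:
            raise ValueError("signals must be 3-D (trials, electrodes, samples)")
        if len(self.labels) != self.signals.shape[0]:
            raise ValueError("one label per trial required")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_trials(self) -> int:
        return self.signals.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.signals.shape[1]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[2]


@dataclass
class MRAConfig:
    """Segmentation and wavelet-decomposition geometry.

    Defaults: 20 overlapping one-second segments (256 samples at 256 Hz,
    step 40) over a 1,016-sample trial, 6 decomposition levels, Daubechies-4
    wavelet with periodized boundaries so set sizes halve exactly.
    """

    n_segments: int = 20
    segment_length: int = 256
    segment_step: int = 40
    n_levels: int = 6
    wavelet: str = "db4"
    boundary_mode: str = "periodization"

    def __post_init__(self) -> None:
        if self.n_segments < 1 or self.n_levels < 1:
            raise ValueError("n_segments and n_levels must be >= 1")
        if self.segment_length % (2**self.n_levels) != 0:
            raise ValueError(
                f"segment_length {self.segment_length} not divisible by "
                f"2^{self.n_levels}"
            )

    @property
    def min_signal_length(self) -> int:
        return self.segment_length + (self.n_segments - 1) * self.segment_step

    def level_label(self, stage: int) -> int:
        """Map decomposition stage (1 = first split) to the level label.

        Stage 1 yields the largest sets and carries the highest label.
        """
        return self.n_levels - stage + 1


@dataclass
class FeatureMatrix:
    """Patterns-by-features container with per-pattern integer labels."""

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (patterns, features)")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("one label per pattern required")
        if np.isnan(self.values).any():
            raise ValueError("missing values are not allowed")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(self.values.shape[1])]
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length must match feature count")

    @property
    def n_patterns(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def segment_signal(signal: np.ndarray, config: MRAConfig) -> np.ndarray:
    """Cut a 1-D signal into ``n_segments`` overlapping windows.

    Segment ``i`` starts at ``i * segment_step`` and spans
    ``segment_length`` samples.  Returns an (n_segments, segment_length)
    array.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("signal must be 1-D")
    needed = config.min_signal_length
    if signal.size < needed:
        raise ValueError(
            f"signal of length {signal.size} too short: segmentation needs "
            f"{needed} samples"
        )
    starts = np.arange(config.n_segments) * config.segment_step
    return np.stack([signal[s : s + config.segment_length] for s in starts])


def dwt_mra(
    segment: np.ndarray,
    n_levels: int,
    wavelet: str = "db4",
    boundary_mode: str = "periodization",
) -> list[tuple[int, str, np.ndarray]]:
    """Multiresolution decomposition keeping both coefficient types per level.

    Returns a list of ``(level_label, kind, coefficients)`` with
    ``kind in {"approx", "detail"}``.  The intermediate approximation of each
    stage is retained (not only the final one), so a segment yields
    ``2 * n_levels`` sets.  With periodized boundaries a 256-sample segment
    at 6 levels gives sizes 128, 64, 32, 16, 8, 4 for level labels 6..1.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 1:
        raise ValueError("segment must be 1-D")
    if segment.size % (2**n_levels) != 0:
        raise ValueError(
            f"segment length {segment.size} not divisible by 2^{n_levels}"
        )
    if wavelet not in pywt.wavelist(kind="discrete"):
        raise ValueError(f"unknown wavelet family: {wavelet!r}")

    sets: list[tuple[int, str, np.ndarray]] = []
    current = segment
    for stage in range(1, n_levels + 1):
        approx, detail = pywt.dwt(current, wavelet, mode=boundary_mode)
        label = n_levels - stage + 1
        sets.append((label, "approx", approx))
        sets.append((label, "detail", detail))
        current = approx
    return sets


def feature_name(segment: int, electrode: int, level: int, kind: str) -> str:
    return f"s{segment:02d}_e{electrode:02d}_l{level}_{kind}"


def extract_pattern(trial: np.ndarray, config: MRAConfig) -> np.ndarray:
    """Turn one (electrodes, samples) trial into a variance-feature vector.

    Features are ordered by (segment, electrode, level descending, type)
    with approximation before detail; the vector has length
    ``2 * n_segments * n_electrodes * n_levels``.
    """
    trial = np.asarray(trial, dtype=float)
    if trial.ndim != 2:
        raise ValueError("trial must be 2-D (electrodes, samples)")
    segments = [segment_signal(ch, config) for ch in trial]  # per electrode
    values = []
    for seg_idx in range(config.n_segments):
        for elec in range(trial.shape[0]):
            seg = segments[elec][seg_idx]
            for level, kind, coeffs in _ordered_sets(seg, config):
                values.append(float(np.var(coeffs)))
    return np.asarray(values)


def _ordered_sets(segment, config):
    sets = dwt_mra(segment, config.n_levels, config.wavelet, config.boundary_mode)
    # dwt_mra emits stages shallow->deep i.e. level labels descending already,
    # approx before detail within each level
    return sets


def pattern_feature_names(n_segments: int, n_electrodes: int, n_levels: int) -> list[str]:
    names = []
    for s in range(n_segments):
        for e in range(n_electrodes):
            for level in range(n_levels, 0, -1):
                for kind in ("approx", "detail"):
                    names.append(feature_name(s, e, level, kind))
    return names


def extract_features(trials: EEGTrialSet, config: MRAConfig | None = None) -> FeatureMatrix:
    """Extract the wavelet-variance pattern of every trial (no normalization)."""
    config = config or MRAConfig()
    patterns = np.stack([extract_pattern(t, config) for t in trials.signals])
    names = pattern_feature_names(config.n_segments, trials.n_electrodes, config.n_levels)
    return FeatureMatrix(patterns, trials.labels, names)


def normalize_features(
    train: FeatureMatrix, *others: FeatureMatrix
) -> tuple[list[FeatureMatrix], MinMaxScaler]:
    """Min-max normalize to [0, 1], fitting the ranges on ``train`` only.

    Other matrices are transformed with the training ranges and clipped to
    [0, 1]; constant training columns map to 0.  Returns the normalized
    matrices (train first) and the fitted scaler.
    """
    for m in others:
        if m.n_features != train.n_features:
            raise ValueError("feature-count mismatch between matrices")
    scaler = MinMaxScaler(clip=True)
    out = [
        FeatureMatrix(scaler.fit_transform(train.values), train.labels, train.feature_names)
    ]
    for m in others:
        out.append(FeatureMatrix(scaler.transform(m.values), m.labels, m.feature_names))
    return out, scaler


class WaveletVarianceExtractor(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: raw trials -> normalized variance features.

    ``fit`` learns per-feature min-max ranges on the training trials;
    ``transform`` extracts patterns and rescales them with the fitted
    ranges, clipping to [0, 1].

    Parameters mirror :class:`MRAConfig`.
    """

    def __init__(
        self,
        n_segments: int = 20,
        segment_length: int = 256,
        segment_step: int = 40,
        n_levels: int = 6,
        wavelet: str = "db4",
        boundary_mode: str = "periodization",
    ):
        self.n_segments = n_segments
        self.segment_length = segment_length
        self.segment_step = segment_step
        self.n_levels = n_levels
        self.wavelet = wavelet
        self.boundary_mode = boundary_mode

    def _config(self) -> MRAConfig:
        return MRAConfig(
            n_segments=self.n_segments,
            segment_length=self.segment_length,
            segment_step=self.segment_step,
            n_levels=self.n_levels,
            wavelet=self.wavelet,
            boundary_mode=self.boundary_mode,
        )

    def _extract(self, X: np.ndarray) -> np.ndarray:
        config = self._config()
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be 3-D (trials, electrodes, samples)")
        return np.stack([extract_pattern(t, config) for t in X])

    def fit(self, X, y=None):
        raw = self._extract(X)
        self.scaler_ = MinMaxScaler(clip=True).fit(raw)
        self.feature_names_ = pattern_feature_names(
            self.n_segments, np.asarray(X).shape[1], self.n_levels
        )
        self.n_features_out_ = raw.shape[1]
        return self

    def transform(self, X):
        raw = self._extract(X)
        return self.scaler_.transform(raw)
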