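"""Delimited-text formats for feature matrices, trials, and run configs.

Feature matrices are TSV with a header row of feature names and a final
``label`` column; values must be in [0, 1] with no missing cells.  Raw
trials are stored as per-trial TSV files (electrodes as rows) with a
sidecar ``labels.txt``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import EEGTrialSet, FeatureMatrix

__all__ = [
    "read_feature_matrix",
    "write_feature_matrix",
    "read_trials",
    "write_trials",
    "write_mask",
    "read_mask",
    "stage_seed",
    "RunConfig",
]


def write_feature_matrix(matrix: FeatureMatrix, path) -> None:
    frame = pd.DataFrame(matrix.values, columns=matrix.feature_names)
    frame["label"] = matrix.labels
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_feature_matrix(path, check_range: bool = True) -> FeatureMatrix:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"{path}: empty or missing feature-matrix file")
    try:
        frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed feature matrix ({exc})") from exc
    if "label" not in frame.columns:
        raise ValueError(f"{path}: missing required 'label' column")
    labels = frame.pop("label")
    if frame.empty:
        raise ValueError(f"{path}: no data rows")
    na_rows = frame.isna().any(axis=1)
    if na_rows.any():
        line = int(np.flatnonzero(na_rows)[0]) + 2  # 1-based, after header
        raise ValueError(f"{path}: missing or non-numeric cell at line {line}")
    values = frame.to_numpy(dtype=float)
    if check_range and (values.min() < 0.0 or values.max() > 1.0):
        raise ValueError(f"{path}: feature values outside [0, 1]")
    return FeatureMatrix(values, labels.to_numpy(dtype=int), list(frame.columns))


def write_trials(trials: EEGTrialSet, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, trial in enumerate(trials.signals):
        np.savetxt(directory / f"trial_{i:04d}.tsv", trial, delimiter="\t")
    np.savetxt(directory / "labels.txt", trials.labels, fmt="%d")
    (directory / "meta.json").write_text(
        json.dumps({"sampling_rate": trials.sampling_rate})
    )


def read_trials(directory) -> EEGTrialSet:
    directory = Path(directory)
    files = sorted(directory.glob("trial_*.tsv"))
    if not files:
        raise ValueError(f"{directory}: no trial files found")
    signals = np.stack([np.loadtxt(f, delimiter="\t") for f in files])
    labels = np.loadtxt(directory / "labels.txt", dtype=int)
    meta = json.loads((directory / "meta.json").read_text())
    return EEGTrialSet(signals, labels, meta["sampling_rate"])


def write_mask(mask: np.ndarray, feature_names: list[str], path) -> None:
    """Selected-feature identifiers, one per line."""
    active = [feature_names[i] for i in np.flatnonzero(mask)]
    Path(path).write_text("\n".join(active) + "\n")


def read_mask(path, feature_names: list[str]) -> np.ndarray:
    wanted = {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}
    unknown = wanted - set(feature_names)
    if unknown:
        raise ValueError(f"unknown feature identifiers in mask: {sorted(unknown)[:5]}")
    return np.array([name in wanted for name in feature_names])


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    digest = hashlib.sha256(f"{stage}:{global_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


_RUNCONFIG_KEYS = {
    "seed",
    "families",
    "output_dir",
    "simulation",
    "mra",
    "feature_selection",
    "structure_ga",
    "learning_ga",
    "training",
    "evaluation",
    "stats",
}


class RunConfig(dict):
    """Validated pipeline configuration; round-trips through YAML."""

    def __init__(self, data: dict):
        unknown = set(data) - _RUNCONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        defaults = {
            "seed": 0,
            "families": ["cnn", "ffnn", "rnn"],
            "output_dir": "evomi_run",
            "simulation": {},
            "mra": {},
            "feature_selection": {},
            "structure_ga": {},
            "learning_ga": {},
            "training": {},
            "evaluation": {},
            "stats": {},
        }
        defaults.update(data)
        super().__init__(defaults)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dict(self), sort_keys=True))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(dict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
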