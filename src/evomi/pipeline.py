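"""End-to-end experiment pipeline.

Stages mirror the study design: simulate (or load) trials, extract
wavelet-variance patterns, normalize on the training split, run the GA
wrapper feature selection once (shared by the families that use it — the
CNN trains on the full feature set by default), two-step-optimize each
requested network family, evaluate with repeated runs, and compare the
families statistically.  Every stage derives its own seed from the global
seed so stages are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

from . import io as eio
from .evaluation import repeated_runs
from .features import FeatureMatrix, MRAConfig, extract_features, normalize_features
from .ga import GAConfig
from .hyperopt import two_step_optimize
from .selection import run_feature_selection
from .simulate import SimulationConfig, generate_mi_trials
from .stats import ComparisonReport, compare_methods

__all__ = ["PipelineReport", "run_pipeline"]

# families that train on the GA-selected feature subset; the CNN keeps the
# full feature set (selection tuned for a linear wrapper can starve it)
FS_FAMILIES = ("ffnn", "rnn")


@dataclass
class PipelineReport:
    config: eio.RunConfig
    selected_mask: np.ndarray | None
    model_specs: dict = field(default_factory=dict)
    summaries: dict = field(default_factory=dict)
    comparison: ComparisonReport | None = None

    def results_table(self) -> str:
        lines = ["family\tmean\tsd\tbest"]
        for family, summary in self.summaries.items():
            lines.append(
                f"{family}\t{summary.mean:.4f}\t{summary.sd:.4f}\t{summary.best:.4f}"
            )
        return "\n".join(lines)


def _stage(name: str, config: eio.RunConfig) -> int:
    return eio.stage_seed(int(config["seed"]), name)


def run_pipeline(config: eio.RunConfig, features: FeatureMatrix | None = None) -> PipelineReport:
    """Execute the full experiment described by ``config``.

    If ``features`` is given the simulation/extraction stages are skipped
    and the pipeline starts from that matrix.
    """
    out_dir = Path(config["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "config.yaml")

    try:
        if features is None:
            sim = SimulationConfig(seed=_stage("simulate", config), **config["simulation"])
            trials = generate_mi_trials(sim)
            features = extract_features(trials, MRAConfig(**config["mra"]))
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate/extract' failed: {exc}") from exc

    split_seed = _stage("split", config)
    idx_train, idx_test = train_test_split(
        np.arange(features.n_patterns),
        test_size=0.3,
        stratify=features.labels,
        random_state=split_seed,
    )
    train = FeatureMatrix(
        features.values[idx_train], features.labels[idx_train], features.feature_names
    )
    test = FeatureMatrix(
        features.values[idx_test], features.labels[idx_test], features.feature_names
    )
    (train, test), _ = normalize_features(train, test)

    families = list(config["families"])
    report = PipelineReport(config=config, selected_mask=None)

    if any(f in FS_FAMILIES for f in families):
        try:
            fs_opts = dict(config["feature_selection"])
            max_active = int(fs_opts.pop("max_active", 30))
            fs_config = GAConfig(
                population_size=int(fs_opts.pop("population_size", 1000)),
                generations=int(fs_opts.pop("generations", 100)),
                seed=_stage("feature_selection", config),
                **fs_opts,
            )
            mask, _ = run_feature_selection(
                train.values, train.labels, config=fs_config, max_active=max_active
            )
            report.selected_mask = mask
            eio.write_mask(mask, train.feature_names, out_dir / "selected_features.txt")
        except Exception as exc:
            raise RuntimeError(f"stage 'feature_selection' failed: {exc}") from exc

    kappa_matrix = []
    for family in families:
        try:
            if family in FS_FAMILIES and report.selected_mask is not None:
                cols = np.flatnonzero(report.selected_mask)
            else:
                cols = np.arange(train.n_features)
            Xtr, Xte = train.values[:, cols], test.values[:, cols]
            s_opts = dict(config["structure_ga"])
            l_opts = dict(config["learning_ga"]) or s_opts
            spec = two_step_optimize(
                family,
                Xtr,
                train.labels,
                structure_config=GAConfig(
                    seed=_stage(f"structure:{family}", config),
                    **{"population_size": 40, "generations": 10, **s_opts},
                ),
                learning_config=GAConfig(
                    seed=_stage(f"learning:{family}", config),
                    **{"population_size": 40, "generations": 10, **l_opts},
                ),
            )
            report.model_specs[family] = spec
            n_rep = int(config["evaluation"].get("n_repetitions", 15))
            n_classes = len(np.unique(train.labels))
            summary = repeated_runs(
                lambda seed: spec.build(Xtr.shape[1], n_classes).set_params(
                    random_state=seed
                ),
                Xtr,
                train.labels,
                Xte,
                test.labels,
                n_repetitions=n_rep,
                base_seed=_stage(f"evaluate:{family}", config),
                on_divergence="zero",
            )
            report.summaries[family] = summary
            kappa_matrix.append(summary.per_run_kappa)
        except Exception as exc:
            raise RuntimeError(f"stage 'optimize:{family}' failed: {exc}") from exc

    (out_dir / "results.tsv").write_text(report.results_table() + "\n")

    if len(families) >= 2:
        try:
            stats_opts = dict(config["stats"])
            rope = tuple(stats_opts.get("rope", (-0.01, 0.01)))
            report.comparison = compare_methods(
                np.column_stack(kappa_matrix),
                method_names=families,
                rope=rope,
                n_samples=int(stats_opts.get("n_samples", 2000)),
                rng=_stage("stats", config),
            )
            (out_dir / "comparison.txt").write_text(report.comparison.to_text() + "\n")
        except Exception as exc:
            raise RuntimeError(f"stage 'compare' failed: {exc}") from exc

    return report
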