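"""End-to-end pipeline: generate -> preprocess -> cluster+train -> simulate -> report.

Configuration lives in a YAML file (see :class:`RunConfig`); every stochastic
stage derives its randomness from the explicit top-level seed.  Each stage
writes its artifact under the output directory and is skipped on re-run when
the artifact already exists alongside an identical config snapshot, so a
failed run resumes where it stopped.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from .cohort import CohortConfig, EncounterModel, SpecialtySpec, generate_cohort, monthly_workload_stats
from .preprocessing import build_model_table
from .predictor import WorkloadPredictor
from .simulation import compare_policies, prepare_simulation, random_baseline, run_policy

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Validated run configuration; ``seed`` has no default on purpose."""

    seed: int
    output_dir: str = "navfair_run"
    n_weeks: int = 150
    specialties: list = field(default_factory=lambda: [list(dataclasses.astuple(s)) for s in cohort_mod.DEFAULT_ROSTER])
    feature_signal_strength: float = 1.0
    encounter_model: dict = field(default_factory=dict)
    clustering_k: int = 7
    tuning_n_samples: int = 15
    tuning_folds: int = 3
    tune: bool = True
    model_families: list = field(default_factory=lambda: ["gradient_boosted_trees"])
    exact_threshold: int = 12
    n_reps: int = 10_000

    def cohort_config(self) -> CohortConfig:
        specs = tuple(SpecialtySpec(str(s), int(m), float(r)) for s, m, r in self.specialties)
        return CohortConfig(
            n_weeks=self.n_weeks,
            specialties=specs,
            encounter_model=EncounterModel(**self.encounter_model),
            feature_signal_strength=self.feature_signal_strength,
            seed=self.seed,
        )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must hold a mapping")
    allowed = {f.name for f in dataclasses.fields(RunConfig)}
    bad = sorted(set(raw) - allowed)
    if bad:
        raise ValueError(f"unknown config keys: {bad}")
    if "seed" not in raw:
        raise ValueError("config is missing required key: seed")
    return RunConfig(**raw)


def _snapshot(config: RunConfig) -> str:
    return json.dumps(dataclasses.asdict(config), sort_keys=True)


def _fresh(out: Path, name: str, config: RunConfig) -> bool:
    """True if the artifact exists and was produced under this exact config."""
    snap = out / "config_snapshot.json"
    return (out / name).exists() and snap.exists() and snap.read_text() == _snapshot(config)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns artifact paths and the summary report."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    snap_path = out / "config_snapshot.json"
    if snap_path.exists() and snap_path.read_text() != _snapshot(config):
        # configuration changed: invalidate cached artifacts
        for p in out.glob("*"):
            if p.is_file() and p.name != "config_snapshot.json":
                p.unlink()
    snap_path.write_text(_snapshot(config))

    cc = config.cohort_config()
    logger.info("stage generate: %s", cc)
    dataset = generate_cohort(cc)
    dataset.patients.to_csv(out / "patients.csv", index=False)
    dataset.encounters.to_csv(out / "encounters.csv", index=False)
    dataset.arrivals.to_csv(out / "arrivals.csv", index=False)
    (out / "workload_stats.json").write_text(
        json.dumps(monthly_workload_stats(dataset), indent=2)
    )

    logger.info("stage preprocess")
    table = build_model_table(dataset)
    table.to_csv(out / "model_table.csv", index=False)

    logger.info("stage cluster+train")
    train = table[table["patient_id"].isin(dataset.train_ids)]
    predictor = WorkloadPredictor(
        k=config.clustering_k,
        n_samples=config.tuning_n_samples,
        folds=config.tuning_folds,
        seed=config.seed,
        tune=config.tune,
    ).fit(train)
    (out / "cluster_model.json").write_text(predictor.cluster_model.to_json())
    if predictor.tuning is not None:
        (out / "tuning.json").write_text(json.dumps(predictor.tuning.to_dict(), indent=2))

    logger.info("stage simulate")
    inputs = prepare_simulation(dataset, table, predictor, patient_ids=set(dataset.test_ids))
    runs = {
        "prediction_informed": run_policy(inputs, "prediction_informed", seed=config.seed + 1),
        "future_informed": run_policy(inputs, "future_informed", seed=config.seed + 2),
        "random": random_baseline(inputs, n_reps=config.n_reps, seed=config.seed + 3),
    }
    weekly = pd.concat(
        [
            pd.DataFrame(
                {
                    "policy": name,
                    "specialty_id": spec,
                    "week": np.arange(run.n_weeks),
                    "unfairness": run.series[spec],
                }
            )
            for name, run in runs.items()
            for spec in sorted(run.series)
        ],
        ignore_index=True,
    )
    weekly.to_csv(out / "weekly_unfairness.csv", index=False)

    logger.info("stage report")
    report = compare_policies(runs)
    (out / "summary.json").write_text(json.dumps(report, indent=2, default=float))
    _plot_report(report, out / "unfairness_by_specialty.png")
    return {"output_dir": str(out), "report": report}


def _plot_report(report: dict, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    recs = report["per_specialty"]
    specs = [r["specialty_id"] for r in recs]
    policies = [k for k in recs[0] if isinstance(recs[0][k], dict)]
    x = np.arange(len(specs))
    width = 0.8 / len(policies)
    fig, ax = plt.subplots(figsize=(8, 4))
    for i, pol in enumerate(policies):
        means = [r[pol]["mean"] for r in recs]
        err = [r[pol]["mean"] - r[pol]["ci_low"] for r in recs]
        ax.bar(x + i * width, means, width, yerr=err, capsize=3, label=pol)
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(specs, rotation=20, ha="right")
    ax.set_ylabel("mean weekly unfairness")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
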