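"""Weekly policy-comparison simulation.

Replays a cohort week by week: each Monday, every active patient's
next-week workload is predicted, the week's new patients are assigned to
navigators by a policy, assignments are committed for good, and the
specialty's realized unfairness is computed from the *actual* encounter
counts of each navigator's panel that week.  All policies consume the same
realized encounter streams — a patient's encounters do not depend on who
holds them — so the only thing a policy changes is who carries the load.

Policies:

* ``prediction_informed`` — assign to minimize unfairness of predicted
  (existing + new) workloads;
* ``future_informed`` — oracle: same solver fed realized workloads;
* ``random`` — uniform random assignment; the reported weekly value of the
  random *baseline* is the mean unfairness over many (default 10,000)
  conditional re-draws of that week's assignments around one committed
  random trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distributor import (
    DEFAULT_EXACT_THRESHOLD,
    AssignmentProblem,
    AssignmentState,
    commit,
    optimal_assignment,
    random_assignment,
)
from .metrics import summarize_series, unfairness

__all__ = [
    "SimulationInputs",
    "SimulationRun",
    "prepare_simulation",
    "run_policy",
    "random_baseline",
    "compare_policies",
]

POLICIES = ("prediction_informed", "random", "future_informed")


@dataclass
class SimulationInputs:
    """Per-week, per-specialty view of the cohort used by every policy.

    ``weeks[w][specialty]`` holds (patient_ids, actual, predicted, is_new)
    arrays for the patients active at Monday ``w``.  Built once so that all
    policies replay identical realized workloads.
    """

    n_weeks: int
    roster: dict[str, int]
    weeks: list
    cohort_tag: str

    @property
    def specialties(self) -> list[str]:
        return sorted(self.roster)


def prepare_simulation(
    dataset,
    table: pd.DataFrame,
    predictor=None,
    patient_ids=None,
) -> SimulationInputs:
    """Precompute weekly panels, actual targets, and predictions.

    ``table`` is the weekly modelling table; ``patient_ids`` restricts the
    simulation population (typically the held-out test patients).  If a
    predictor is given it must not have been trained on any simulated
    patient.
    """
    sub = table if patient_ids is None else table[table["patient_id"].isin(patient_ids)]
    sub = sub.sort_values(["week", "patient_id"], kind="stable")

    if predictor is not None:
        overlap = predictor.train_patient_ids & set(sub["patient_id"])
        if overlap:
            raise ValueError(
                f"predictor was trained on {len(overlap)} simulated patients; refusing to run"
            )
        predicted = predictor.predict(sub)
    else:
        predicted = np.zeros(len(sub))
    sub = sub.assign(_pred=predicted)

    first_week = sub.groupby("patient_id")["week"].transform("min")
    sub = sub.assign(_is_new=(sub["week"] == first_week).to_numpy())

    n_weeks = dataset.config.n_weeks
    weeks: list[dict] = [dict() for _ in range(n_weeks)]
    for (week, spec), grp in sub.groupby(["week", "specialty_id"], sort=False):
        if week >= n_weeks:
            continue
        weeks[int(week)][spec] = (
            grp["patient_id"].to_numpy(),
            grp["target"].to_numpy(dtype=float),
            grp["_pred"].to_numpy(dtype=float),
            grp["_is_new"].to_numpy(dtype=bool),
        )
    tag = f"seed={dataset.config.seed},n_weeks={n_weeks},n={sub['patient_id'].nunique()}"
    return SimulationInputs(n_weeks=n_weeks, roster=dataset.roster, weeks=weeks, cohort_tag=tag)


@dataclass
class SimulationRun:
    policy: str
    series: dict  # specialty_id -> np.ndarray of weekly unfairness (actual workloads)
    n_weeks: int
    seed: int | None
    cohort_tag: str
    meta: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {spec: summarize_series(vals) for spec, vals in self.series.items()}

    def pooled(self) -> np.ndarray:
        return np.concatenate([self.series[s] for s in sorted(self.series)])


def _panel_loads(pids, values, state: AssignmentState, m: int) -> np.ndarray:
    loads = np.zeros(m)
    for pid, v in zip(pids, values):
        j = state.navigator_of(pid)
        if j is not None:
            loads[j] += v
    return loads


def run_policy(
    inputs: SimulationInputs,
    policy: str = "prediction_informed",
    seed: int | None = None,
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
) -> SimulationRun:
    """Run one policy over the full horizon and score actual unfairness.

    For the plain ``random`` policy this is a single random trajectory; use
    :func:`random_baseline` for the many-repetition baseline.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}")
    rng = np.random.default_rng(seed)
    state = AssignmentState()
    series = {spec: np.zeros(inputs.n_weeks) for spec in inputs.roster}

    for w in range(inputs.n_weeks):
        for spec, m in inputs.roster.items():
            entry = inputs.weeks[w].get(spec)
            if entry is None:
                series[spec][w] = 0.0
                continue
            pids, actual, pred, is_new = entry
            basis = actual if policy == "future_informed" else pred
            existing = _panel_loads(pids[~is_new], basis[~is_new], state, m)
            problem = AssignmentProblem(
                spec, tuple(existing), tuple(pids[is_new]), tuple(basis[is_new])
            )
            if policy == "random":
                mapping = random_assignment(problem, rng)
            else:
                mapping = optimal_assignment(problem, exact_threshold=exact_threshold)
            state = commit(state, mapping)
            real_loads = _panel_loads(pids, actual, state, m)
            series[spec][w] = unfairness(real_loads)

    return SimulationRun(
        policy=policy,
        series=series,
        n_weeks=inputs.n_weeks,
        seed=seed,
        cohort_tag=inputs.cohort_tag,
    )


def random_baseline(
    inputs: SimulationInputs,
    n_reps: int = 10_000,
    seed: int | None = None,
) -> SimulationRun:
    """Random-distribution baseline with per-week conditional repetitions.

    For each week, conditional on the panel state committed so far, the
    week's new patients are randomly re-assigned ``n_reps`` independent
    times; the mean of those unfairness values is the week's baseline value.
    One additional draw is then committed to evolve the panel trajectory.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    state = AssignmentState()
    series = {spec: np.zeros(inputs.n_weeks) for spec in inputs.roster}

    for w in range(inputs.n_weeks):
        for spec, m in inputs.roster.items():
            entry = inputs.weeks[w].get(spec)
            if entry is None:
                series[spec][w] = 0.0
                continue
            pids, actual, pred, is_new = entry
            existing = _panel_loads(pids[~is_new], actual[~is_new], state, m)
            new_w = actual[is_new]
            n_new = int(is_new.sum())
            if n_new == 0:
                series[spec][w] = unfairness(existing)
                committed = {}
            else:
                draws = rng.integers(0, m, size=(n_reps, n_new))
                loads = np.tile(existing, (n_reps, 1))
                for j in range(n_new):
                    loads[np.arange(n_reps), draws[:, j]] += new_w[j]
                series[spec][w] = float(
                    np.abs(loads - loads.mean(axis=1, keepdims=True)).mean()
                )
                extra = rng.integers(0, m, size=n_new)
                committed = {pid: int(j) for pid, j in zip(pids[is_new], extra)}
            state = commit(state, committed)

    return SimulationRun(
        policy="random",
        series=series,
        n_weeks=inputs.n_weeks,
        seed=seed,
        cohort_tag=inputs.cohort_tag,
        meta={"n_reps": n_reps},
    )


def compare_policies(runs: dict) -> dict:
    """Per-specialty summary table and pooled percent reduction vs random.

    All runs must come from the same cohort.  Returns a dict with
    ``per_specialty`` records (mean, sd, 95% CI per policy, CI-overlap flag
    vs random, percent reduction) and pooled percent reductions.
    """
    tags = {r.cohort_tag for r in runs.values()}
    if len(tags) > 1:
        raise ValueError(f"runs come from different cohorts: {tags}")
    if "random" not in runs:
        raise ValueError("need a random run as the comparison baseline")

    per_spec = []
    specs = sorted(next(iter(runs.values())).series)
    for spec in specs:
        rec = {"specialty_id": spec}
        for name, run in runs.items():
            s = summarize_series(run.series[spec])
            rec[name] = s.to_dict()
        rand = rec["random"]
        for name in runs:
            if name == "random":
                continue
            this = rec[name]
            rec[f"{name}_pct_reduction"] = (
                100.0 * (rand["mean"] - this["mean"]) / rand["mean"] if rand["mean"] else 0.0
            )
            rec[f"{name}_ci_overlaps_random"] = not (
                this["ci_high"] < rand["ci_low"] or rand["ci_high"] < this["ci_low"]
            )
        per_spec.append(rec)

    pooled = {}
    rand_pool = runs["random"].pooled().mean()
    for name, run in runs.items():
        if name == "random":
            continue
        pooled[f"{name}_pct_reduction"] = (
            100.0 * (rand_pool - run.pooled().mean()) / rand_pool if rand_pool else 0.0
        )
    return {"per_specialty": per_spec, "pooled": pooled, "random_pooled_mean": float(rand_pool)}
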