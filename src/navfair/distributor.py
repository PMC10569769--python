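"""Distribution of new patients among same-specialty navigators.

Each week a specialty faces an assignment problem: ``m`` navigators carry
existing predicted loads ``e_j`` and ``n`` new patients bring predicted
workloads ``w_p``.  Assigning patient ``p`` to navigator ``j`` yields final
loads ``L_j = e_j + sum_{p -> j} w_p``; the objective is the unfairness
metric ``(1/m) * sum_j |L_j - F|`` with the fair share ``F = (sum e +
sum w)/m`` constant for the week.  The problem is solved exactly as a
mixed-integer program with the standard absolute-deviation linearization
(minimize ``sum d_j`` s.t. ``d_j >= L_j - F`` and ``d_j >= F - L_j``) for
``n`` up to a configurable threshold, and by a longest-processing-time
greedy heuristic beyond it.

Once assigned, a patient never moves: :class:`AssignmentState` enforces the
patient-stays-with-navigator consistency constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .metrics import unfairness

__all__ = [
    "AssignmentProblem",
    "AssignmentState",
    "optimal_assignment",
    "random_assignment",
    "future_informed_assignment",
    "greedy_assignment",
    "assignment_loads",
    "commit",
    "DEFAULT_EXACT_THRESHOLD",
]

DEFAULT_EXACT_THRESHOLD = 12


@dataclass(frozen=True)
class AssignmentProblem:
    """One specialty-week's new-patient assignment instance."""

    specialty_id: str
    existing_loads: tuple[float, ...]  # length m, per navigator
    new_patient_ids: tuple[str, ...]  # length n
    new_workloads: tuple[float, ...]  # length n

    def __post_init__(self) -> None:
        object.__setattr__(self, "existing_loads", tuple(float(x) for x in self.existing_loads))
        object.__setattr__(self, "new_patient_ids", tuple(self.new_patient_ids))
        object.__setattr__(self, "new_workloads", tuple(float(x) for x in self.new_workloads))
        if len(self.existing_loads) < 2:
            raise ValueError("need >= 2 navigators")
        if len(self.new_patient_ids) != len(self.new_workloads):
            raise ValueError("one workload per new patient required")
        if any(x < 0 for x in self.existing_loads) or any(x < 0 for x in self.new_workloads):
            raise ValueError("workloads cannot be negative")

    @property
    def m(self) -> int:
        return len(self.existing_loads)

    @property
    def n(self) -> int:
        return len(self.new_patient_ids)


def assignment_loads(problem: AssignmentProblem, mapping: dict[str, int]) -> np.ndarray:
    """Final per-navigator loads implied by a new-patient -> navigator map."""
    loads = np.asarray(problem.existing_loads, dtype=float).copy()
    for pid, w in zip(problem.new_patient_ids, problem.new_workloads):
        loads[mapping[pid]] += w
    return loads


def greedy_assignment(problem: AssignmentProblem) -> dict[str, int]:
    """Longest-processing-time heuristic: heaviest patient first, to the
    currently least-loaded navigator (ties -> lowest navigator index)."""
    loads = np.asarray(problem.existing_loads, dtype=float).copy()
    w = np.asarray(problem.new_workloads, dtype=float)
    order = np.argsort(-w, kind="stable")
    mapping: dict[str, int] = {}
    for p in order:
        j = int(loads.argmin())
        mapping[problem.new_patient_ids[p]] = j
        loads[j] += w[p]
    return mapping


def _exact_assignment(problem: AssignmentProblem) -> dict[str, int]:
    m, n = problem.m, problem.n
    e = np.asarray(problem.existing_loads, dtype=float)
    w = np.asarray(problem.new_workloads, dtype=float)
    F = (e.sum() + w.sum()) / m

    # variables: x[p, j] binary (n*m), d[j] continuous (m), z continuous (1).
    # z >= per-navigator count of this week's new patients; its epsilon weight
    # breaks ties among equally fair optima by spreading the week's patients
    # (otherwise patients with zero predicted workload would be placed
    # arbitrarily, and the stay-forever constraint would make pile-ups stick).
    n_x = n * m
    n_var = n_x + m + 1
    eps = 1e-6 * max(1.0, float(w.sum() + e.sum()))
    c = np.concatenate([np.zeros(n_x), np.ones(m), [eps]])

    rows, cols, vals = [], [], []
    # each patient assigned exactly once
    for p in range(n):
        for j in range(m):
            rows.append(p)
            cols.append(p * m + j)
            vals.append(1.0)
    A_assign = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n_var))
    con_assign = LinearConstraint(A_assign, lb=np.ones(n), ub=np.ones(n))

    # d_j - sum_p w_p x_pj >= e_j - F   and   d_j + sum_p w_p x_pj >= F - e_j
    rows, cols, vals = [], [], []
    for j in range(m):
        for p in range(n):
            rows.append(j)
            cols.append(p * m + j)
            vals.append(-w[p])
            rows.append(m + j)
            cols.append(p * m + j)
            vals.append(w[p])
        rows.append(j)
        cols.append(n_x + j)
        vals.append(1.0)
        rows.append(m + j)
        cols.append(n_x + j)
        vals.append(1.0)
    A_dev = sparse.coo_matrix((vals, (rows, cols)), shape=(2 * m, n_var))
    lb_dev = np.concatenate([e - F, F - e])
    con_dev = LinearConstraint(A_dev, lb=lb_dev, ub=np.full(2 * m, np.inf))

    # z >= number of new patients on navigator j
    rows, cols, vals = [], [], []
    for j in range(m):
        for p in range(n):
            rows.append(j)
            cols.append(p * m + j)
            vals.append(-1.0)
        rows.append(j)
        cols.append(n_x + m)
        vals.append(1.0)
    A_count = sparse.coo_matrix((vals, (rows, cols)), shape=(m, n_var))
    con_count = LinearConstraint(A_count, lb=np.zeros(m), ub=np.full(m, np.inf))

    integrality = np.concatenate([np.ones(n_x), np.zeros(m + 1)])
    bounds = Bounds(
        lb=np.zeros(n_var),
        ub=np.concatenate([np.ones(n_x), np.full(m + 1, np.inf)]),
    )
    constraints = [con_assign, con_dev, con_count]
    res = milp(c, constraints=constraints, integrality=integrality, bounds=bounds)
    if not res.success:
        # rare HiGHS presolve edge case; the un-presolved solve is robust
        res = milp(
            c,
            constraints=constraints,
            integrality=integrality,
            bounds=bounds,
            options={"presolve": False},
        )
    if not res.success:  # pragma: no cover
        raise RuntimeError(f"MILP solver failed: {res.message}")
    x = res.x[:n_x].reshape(n, m)
    return {problem.new_patient_ids[p]: int(x[p].argmax()) for p in range(n)}


def optimal_assignment(
    problem: AssignmentProblem, exact_threshold: int = DEFAULT_EXACT_THRESHOLD
) -> dict[str, int]:
    """Minimize the unfairness of (existing + new) loads.

    Exact (branch-and-bound integer program) for ``n <= exact_threshold``;
    greedy longest-processing-time fallback for larger weeks.
    """
    if problem.n == 0:
        return {}
    if problem.n <= exact_threshold:
        return _exact_assignment(problem)
    return greedy_assignment(problem)


def random_assignment(problem: AssignmentProblem, rng: np.random.Generator) -> dict[str, int]:
    """Each new patient goes to a uniformly random navigator, independently."""
    draws = rng.integers(0, problem.m, size=problem.n)
    return {pid: int(j) for pid, j in zip(problem.new_patient_ids, draws)}


def future_informed_assignment(
    problem: AssignmentProblem, exact_threshold: int = DEFAULT_EXACT_THRESHOLD
) -> dict[str, int]:
    """Oracle policy: identical solver, but the problem carries *realized*
    next-week workloads instead of predictions (simulation only)."""
    return optimal_assignment(problem, exact_threshold=exact_threshold)


@dataclass(frozen=True)
class AssignmentState:
    """Immutable patient -> navigator assignment history for one roster.

    ``commit`` returns a new state; re-assigning an already-assigned patient
    raises (the consistency constraint).
    """

    assignments: MappingProxyType = field(default_factory=lambda: MappingProxyType({}))

    def navigator_of(self, patient_id: str):
        return self.assignments.get(patient_id)

    def __contains__(self, patient_id: str) -> bool:
        return patient_id in self.assignments

    def __len__(self) -> int:
        return len(self.assignments)


def commit(state: AssignmentState, mapping: dict[str, int]) -> AssignmentState:
    """Extend the state with this week's assignments (order-independent for
    disjoint mappings; rejects any re-assignment)."""
    clash = [pid for pid in mapping if pid in state]
    if clash:
        raise ValueError(f"consistency violation: patients already assigned: {clash[:5]}")
    merged = dict(state.assignments)
    merged.update(mapping)
    return AssignmentState(MappingProxyType(merged))
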