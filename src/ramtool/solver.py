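"""Dynamic optimization of resource-allocation models.

The dynamic enzyme-cost FBA problem maximizes the time integral of the
objective biomass ``B_o(t) = b_P . p(t)`` subject to

* species dynamics ``d/dt [y; x; c; p] = S v`` with the internal
  metabolites ``x`` held in quasi-steady state (``S_X v = 0``),
* box bounds ``v_min <= v <= v_max``,
* enzyme capacity ``HC v <= HE p``,
* biomass composition (quota) ``HB [c; p] <= 0``,
* maintenance floors ``v_m >= HM [c; p]`` on the maintenance rows,
* fixed initial amounts and nonnegativity of all amounts.

Time is discretized on a uniform grid by collocation: amounts live on the
nodes, fluxes are piecewise constant on the intervals, and the dynamics are
integrated exactly for piecewise-constant fluxes.  The default
``implicit_euler`` scheme enforces the path constraints at the right node
of each interval and integrates the objective with right-endpoint
quadrature; ``trapezoid`` enforces capacity at both interval endpoints and
uses trapezoidal quadrature.  Reversible fluxes are decomposed into
nonnegative forward/backward parts so every constraint stays linear; the
resulting LP is solved with the HiGHS backend behind a thin solve contract.

A balanced-growth (RBA-style) initializer finds the largest growth rate
``mu`` for which exponential growth is feasible at fixed biomass
composition, by bisection on the feasibility LP; its amounts are the
natural initial state for dynamic simulations of precultured cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .core import ConstraintMatrices, ModelPartition, RAMModel, build_constraint_matrices
from .errors import (
    DomainError,
    InfeasibleProblemError,
    SolverError,
    UnboundedProblemError,
)

__all__ = [
    "DiscretizationConfig",
    "Scenario",
    "Trajectory",
    "LPProblem",
    "discretize_to_lp",
    "solve_defba",
    "solve_rba_initial",
    "instantaneous_growth_rate",
]

_HIGHS_OPTIONS = {
    "primal_feasibility_tolerance": 1e-10,
    "dual_feasibility_tolerance": 1e-9,
}


@dataclass
class DiscretizationConfig:
    """Time-discretization settings.

    ``t_end`` is the simulation horizon in hours, ``n_steps`` the number of
    uniform intervals, ``scheme`` one of ``implicit_euler`` (default) or
    ``trapezoid``; ``lp_tolerance`` is the feasibility tolerance requested
    from the LP backend and used when checking returned residuals.
    """

    t_end: float
    n_steps: int
    scheme: str = "implicit_euler"
    lp_tolerance: float = 1e-9

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise DomainError("t_end must be positive")
        if not (isinstance(self.n_steps, (int, np.integer)) and self.n_steps >= 1):
            raise DomainError("n_steps must be a positive integer")
        if self.scheme not in ("implicit_euler", "trapezoid"):
            raise DomainError(f"unknown collocation scheme {self.scheme!r}")
        if self.lp_tolerance <= 0:
            raise DomainError("lp_tolerance must be positive")


@dataclass
class Scenario:
    """Initial amounts for the dynamic problem, in partition order.

    ``y0`` covers the extracellular species, ``c0`` storage, ``p0``
    macromolecules; internal metabolites are in quasi-steady state and need
    no initial values.
    """

    y0: np.ndarray
    c0: np.ndarray
    p0: np.ndarray

    def __post_init__(self) -> None:
        self.y0 = np.asarray(self.y0, dtype=float)
        self.c0 = np.asarray(self.c0, dtype=float)
        self.p0 = np.asarray(self.p0, dtype=float)
        for name, arr in (("y0", self.y0), ("c0", self.c0), ("p0", self.p0)):
            if np.any(arr < 0):
                raise DomainError(f"negative initial amounts in {name}")

    @classmethod
    def from_model(cls, model: RAMModel,
                   partition: Optional[ModelPartition] = None) -> "Scenario":
        """Take initial amounts from the species records."""
        from .core import partition_model

        part = partition or partition_model(model)
        amt = lambda idxs: np.array(
            [model.species[i].initial_amount for i in idxs], dtype=float
        )
        return cls(y0=amt(part.Y), c0=amt(part.C), p0=amt(part.P))

    def check_dimensions(self, partition: ModelPartition) -> None:
        if self.y0.shape != (len(partition.Y),) or \
           self.c0.shape != (len(partition.C),) or \
           self.p0.shape != (len(partition.P),):
            raise DomainError(
                "scenario dimensions do not match the model partition:"
                f" got y0 {self.y0.shape}, c0 {self.c0.shape},"
                f" p0 {self.p0.shape}; expected ({len(partition.Y)},),"
                f" ({len(partition.C)},), ({len(partition.P)},)"
            )


@dataclass
class LPProblem:
    """A fully assembled linear program (maximization form).

    ``A_eq x = b_eq``, ``A_ub x <= b_ub``, ``lo <= x <= hi``; the objective
    ``c_max . x`` is to be maximized.  Row names carry symbolic constraint
    labels (``dyn[...]``, ``qssa[...]``, ``capacity[...]``, ``quota[...]``,
    ``maintenance[...]``) for diagnostics.
    """

    c_max: np.ndarray
    A_eq: sparse.csr_matrix
    b_eq: np.ndarray
    A_ub: sparse.csr_matrix
    b_ub: np.ndarray
    bounds: List[Tuple[float, float]]
    eq_names: List[str]
    ub_names: List[str]
    num_amount_variables: int
    num_flux_variables: int
    meta: dict = field(default_factory=dict)


def _matrix(rows: List[Dict[int, float]], n_vars: int) -> sparse.csr_matrix:
    data, ri, ci = [], [], []
    for r, row in enumerate(rows):
        for c, val in row.items():
            ri.append(r)
            ci.append(c)
            data.append(val)
    return sparse.csr_matrix((data, (ri, ci)), shape=(len(rows), n_vars))


def discretize_to_lp(
    model: RAMModel,
    scenario: Scenario,
    config: DiscretizationConfig,
    matrices: Optional[ConstraintMatrices] = None,
) -> LPProblem:
    """Cast the dynamic optimization into a finite LP.

    Variables are the amounts of all dynamic species (Y, C, P) at every
    node plus the sign-split fluxes on every interval.  See the module
    docstring for which constraint is enforced where.
    """
    mats = matrices or build_constraint_matrices(model)
    part = mats.partition
    scenario.check_dimensions(part)

    N = config.n_steps
    dt = config.t_end / N
    dyn_idx = list(part.Y) + list(part.C) + list(part.P)  # rows of S
    n_a = len(dyn_idx)
    n_f = len(mats.flux_columns)
    n_y, n_c, n_p = len(part.Y), len(part.C), len(part.P)
    n_vars = (N + 1) * n_a + N * n_f

    def a_var(node: int, local: int) -> int:
        return node * n_a + local

    def f_var(interval: int, col: int) -> int:
        return (N + 1) * n_a + interval * n_f + col

    # fixed environment species: boundary (nonlimiting) or constant
    fixed_local = {
        k for k, i in enumerate(dyn_idx)
        if model.species[i].is_boundary or model.species[i].is_constant
    }
    init = np.concatenate([scenario.y0, scenario.c0, scenario.p0])

    bounds: List[Tuple[float, float]] = [(0.0, np.inf)] * n_vars
    for local in range(n_a):
        bounds[a_var(0, local)] = (init[local], init[local])
    for node in range(1, N + 1):
        for local in fixed_local:
            bounds[a_var(node, local)] = (init[local], init[local])

    ridx = model.reaction_index()
    extra_net_rows: List[Tuple[str, Dict[int, float], float]] = []
    for col, (rid, sign) in enumerate(mats.flux_columns):
        rxn = model.reactions[ridx[rid]]
        if not rxn.reversible:
            lo, hi = max(rxn.lower_bound, 0.0), rxn.upper_bound
        elif sign > 0:
            lo, hi = 0.0, max(rxn.upper_bound, 0.0)
        else:
            lo, hi = 0.0, max(-rxn.lower_bound, 0.0)
        for i in range(N):
            bounds[f_var(i, col)] = (lo, hi)
    # reversible reactions with strictly positive lower (or negative upper)
    # net bounds need explicit rows on v+ - v-
    for rid, sign in dict.fromkeys(mats.flux_columns):
        rxn = model.reactions[ridx[rid]]
        if rxn.reversible and sign > 0:
            cols = [c for c, fc in enumerate(mats.flux_columns) if fc[0] == rid]
            if rxn.lower_bound > 0:
                for i in range(N):
                    extra_net_rows.append((
                        f"netlb[{rid},{i}]",
                        {f_var(i, cols[0]): -1.0, f_var(i, cols[1]): 1.0},
                        -rxn.lower_bound,
                    ))
            if rxn.upper_bound < 0:
                for i in range(N):
                    extra_net_rows.append((
                        f"netub[{rid},{i}]",
                        {f_var(i, cols[0]): 1.0, f_var(i, cols[1]): -1.0},
                        rxn.upper_bound,
                    ))

    S_dyn = mats.S_split[dyn_idx, :]  # dynamics rows over split columns
    S_x = mats.S_split[part.X, :]

    eq_rows: List[Dict[int, float]] = []
    eq_b: List[float] = []
    eq_names: List[str] = []
    for i in range(N):
        k = i + 1
        for local in range(n_a):
            if local in fixed_local:
                continue
            row = {a_var(k, local): 1.0, a_var(k - 1, local): -1.0}
            for col in np.nonzero(S_dyn[local])[0]:
                row[f_var(i, col)] = row.get(f_var(i, col), 0.0) \
                    - dt * S_dyn[local, col]
            eq_rows.append(row)
            eq_b.append(0.0)
            eq_names.append(
                f"dyn[{model.species[dyn_idx[local]].id},{i}]"
            )
        for xi, x_local in enumerate(part.X):
            row = {
                f_var(i, col): S_x[xi, col]
                for col in np.nonzero(S_x[xi])[0]
            }
            eq_rows.append(row)
            eq_b.append(0.0)
            eq_names.append(f"qssa[{model.species[x_local].id},{i}]")

    ub_rows: List[Dict[int, float]] = []
    ub_b: List[float] = []
    ub_names: List[str] = []

    def cap_nodes(i: int) -> Sequence[int]:
        if config.scheme == "trapezoid":
            return (i, i + 1)
        return (i + 1,)

    c_off = n_y          # local offset of storage amounts within a node
    p_off = n_y + n_c    # local offset of macromolecule amounts

    for i in range(N):
        for node in cap_nodes(i):
            for r in range(mats.HC.shape[0]):
                row: Dict[int, float] = {}
                for col in np.nonzero(mats.HC[r])[0]:
                    row[f_var(i, col)] = mats.HC[r, col]
                for pj in np.nonzero(mats.HE[r])[0]:
                    row[a_var(node, p_off + pj)] = \
                        row.get(a_var(node, p_off + pj), 0.0) - mats.HE[r, pj]
                ub_rows.append(row)
                ub_b.append(0.0)
                ub_names.append(
                    f"capacity[{mats.enzyme_rows[r]},{i},node{node}]"
                )
        k = i + 1
        for r in range(mats.HM.shape[0]):
            rid = mats.maintenance_rows[r]
            cols = [c for c, fc in enumerate(mats.flux_columns) if fc[0] == rid]
            row = {}
            for cj in range(n_c):
                if mats.HM[r, cj]:
                    row[a_var(k, c_off + cj)] = mats.HM[r, cj]
            for pj in range(n_p):
                if mats.HM[r, n_c + pj]:
                    row[a_var(k, p_off + pj)] = mats.HM[r, n_c + pj]
            for c in cols:
                _, sign = mats.flux_columns[c]
                row[f_var(i, c)] = row.get(f_var(i, c), 0.0) - float(sign)
            ub_rows.append(row)
            ub_b.append(0.0)
            ub_names.append(f"maintenance[{rid},{i}]")

    for k in range(1, N + 1):
        for r in range(mats.HB.shape[0]):
            row = {}
            for cj in range(n_c):
                if mats.HB[r, cj]:
                    row[a_var(k, c_off + cj)] = mats.HB[r, cj]
            for pj in range(n_p):
                if mats.HB[r, n_c + pj]:
                    row[a_var(k, p_off + pj)] = mats.HB[r, n_c + pj]
            ub_rows.append(row)
            ub_b.append(0.0)
            ub_names.append(f"quota[{mats.quota_rows[r]},{k}]")

    for name, row, rhs in extra_net_rows:
        ub_rows.append(row)
        ub_b.append(rhs)
        ub_names.append(name)

    b = np.array([model.species[i].objective_weight for i in part.P])
    c_max = np.zeros(n_vars)
    if config.scheme == "trapezoid":
        weights = np.full(N + 1, dt)
        weights[0] = weights[-1] = dt / 2.0
    else:
        weights = np.concatenate([[0.0], np.full(N, dt)])
    for node in range(N + 1):
        if weights[node] == 0.0:
            continue
        for pj in range(n_p):
            if b[pj]:
                c_max[a_var(node, p_off + pj)] += weights[node] * b[pj]

    return LPProblem(
        c_max=c_max,
        A_eq=_matrix(eq_rows, n_vars),
        b_eq=np.array(eq_b),
        A_ub=_matrix(ub_rows, n_vars),
        b_ub=np.array(ub_b),
        bounds=bounds,
        eq_names=eq_names,
        ub_names=ub_names,
        num_amount_variables=(N + 1) * n_a,
        num_flux_variables=N * n_f,
        meta={
            "n_nodes": N + 1,
            "n_a": n_a,
            "n_f": n_f,
            "dt": dt,
            "dyn_idx": dyn_idx,
            "matrices": mats,
        },
    )


def _run_lp(c_min, A_ub, b_ub, A_eq, b_eq, bounds, context: str):
    res = linprog(
        c=c_min,
        A_ub=A_ub if A_ub is not None and A_ub.shape[0] else None,
        b_ub=b_ub if A_ub is not None and A_ub.shape[0] else None,
        A_eq=A_eq if A_eq is not None and A_eq.shape[0] else None,
        b_eq=b_eq if A_eq is not None and A_eq.shape[0] else None,
        bounds=bounds,
        method="highs",
        options=dict(_HIGHS_OPTIONS),
    )
    if res.status == 2:
        raise InfeasibleProblemError(f"{context}: LP infeasible ({res.message})")
    if res.status == 3:
        raise UnboundedProblemError(f"{context}: LP unbounded ({res.message})")
    if res.status != 0:
        raise SolverError(f"{context}: LP solver failed ({res.message})")
    return res


@dataclass
class Trajectory:
    """Solution of a discretized dynamic optimization.

    Amounts are per node (shape ``(N+1, .)``), net fluxes per interval
    (shape ``(N, r)`` in model reaction order).  ``objective`` is the LP
    optimum of the discretized biomass integral.
    """

    times: np.ndarray
    y: np.ndarray
    c: np.ndarray
    p: np.ndarray
    v: np.ndarray
    v_split: np.ndarray
    objective: float
    status: str
    model: RAMModel
    partition: ModelPartition
    matrices: ConstraintMatrices
    config: DiscretizationConfig

    def objective_biomass_series(self) -> np.ndarray:
        """``B_o(t_k) = b_P . p(t_k)`` per node, in grams."""
        b = np.array(
            [self.model.species[i].objective_weight for i in self.partition.P]
        )
        return self.p @ b

    def total_biomass_series(self) -> np.ndarray:
        """``B_t(t_k) = B_o(t_k) + w_C . c(t_k)`` per node, in grams."""
        w = np.array(
            [self.model.species[i].molecular_weight for i in self.partition.C]
        )
        return self.objective_biomass_series() + self.c @ w

    def growth_rates(self) -> np.ndarray:
        """Instantaneous growth rate on every interval, 1/h."""
        return np.array([
            instantaneous_growth_rate(self, i)
            for i in range(len(self.times) - 1)
        ])

    def residuals(self) -> Dict[str, float]:
        """Worst-case violations of the path constraints.

        Keys: ``qssa`` (max |S_X v|), ``capacity`` (max of HC v - HE p at
        the enforcement nodes), ``quota``, ``maintenance`` and
        ``negativity`` (most negative amount; 0 when all nonnegative).
        """
        mats = self.matrices
        N = len(self.times) - 1
        out = {k: 0.0 for k in
               ("qssa", "capacity", "quota", "maintenance", "negativity")}
        S_x = mats.S_split[self.partition.X, :]
        for i in range(N):
            vi = self.v_split[i]
            if S_x.size:
                out["qssa"] = max(out["qssa"], float(np.max(np.abs(S_x @ vi))))
            nodes = (i, i + 1) if self.config.scheme == "trapezoid" else (i + 1,)
            for k in nodes:
                if mats.HC.size:
                    res = mats.HC @ vi - mats.HE @ self.p[k]
                    out["capacity"] = max(out["capacity"], float(np.max(res)))
            k = i + 1
            cp = np.concatenate([self.c[k], self.p[k]])
            if mats.HB.size:
                out["quota"] = max(out["quota"], float(np.max(mats.HB @ cp)))
            if mats.HM.size:
                ridx = self.model.reaction_index()
                floors = mats.HM @ cp
                for r, rid in enumerate(mats.maintenance_rows):
                    out["maintenance"] = max(
                        out["maintenance"],
                        float(floors[r] - self.v[i, ridx[rid]]),
                    )
        for arr in (self.y, self.c, self.p):
            if arr.size:
                out["negativity"] = max(out["negativity"], float(-np.min(arr)))
        return out


def solve_defba(
    model: RAMModel,
    scenario: Optional[Scenario] = None,
    config: Optional[DiscretizationConfig] = None,
) -> Trajectory:
    """Solve the discretized dynamic optimization.

    ``scenario`` defaults to the initial amounts stored on the model;
    ``config`` must be given.  Infeasible and unbounded problems raise
    (:class:`InfeasibleProblemError` / :class:`UnboundedProblemError`);
    they are never silently clamped.
    """
    if config is None:
        raise DomainError("a DiscretizationConfig is required")
    mats = build_constraint_matrices(model)
    if scenario is None:
        scenario = Scenario.from_model(model, mats.partition)
    lp = discretize_to_lp(model, scenario, config, mats)
    res = _run_lp(-lp.c_max, lp.A_ub, lp.b_ub, lp.A_eq, lp.b_eq, lp.bounds,
                  context="deFBA")

    N = config.n_steps
    n_a, n_f = lp.meta["n_a"], lp.meta["n_f"]
    part = mats.partition
    n_y, n_c = len(part.Y), len(part.C)
    amounts = res.x[: (N + 1) * n_a].reshape(N + 1, n_a)
    v_split = res.x[(N + 1) * n_a:].reshape(N, n_f) if n_f else \
        np.zeros((N, 0))
    v = np.vstack([mats.split_to_net(v_split[i]) for i in range(N)]) \
        if N else np.zeros((0, model.r))
    return Trajectory(
        times=np.linspace(0.0, config.t_end, N + 1),
        y=amounts[:, :n_y],
        c=amounts[:, n_y:n_y + n_c],
        p=amounts[:, n_y + n_c:],
        v=v,
        v_split=v_split,
        objective=float(-res.fun),
        status="optimal",
        model=model,
        partition=part,
        matrices=mats,
        config=config,
    )


def instantaneous_growth_rate(trajectory: Trajectory, interval: int) -> float:
    """Growth rate on one interval: ``ln(B_t(t_{i+1})/B_t(t_i)) / dt``."""
    bt = trajectory.total_biomass_series()
    if interval < 0 or interval >= len(trajectory.times) - 1:
        raise DomainError(f"interval {interval} out of range")
    b0, b1 = bt[interval], bt[interval + 1]
    if b0 <= 0 or b1 <= 0:
        raise DomainError(
            "instantaneous growth rate undefined at zero total biomass"
        )
    dt = trajectory.times[interval + 1] - trajectory.times[interval]
    return float(np.log(b1 / b0) / dt)


# ---------------------------------------------------------------------------
# balanced growth (RBA-style) initializer
# ---------------------------------------------------------------------------


def _rba_feasible(model, mats, mu, blocked_cols):
    part = mats.partition
    n_f = len(mats.flux_columns)
    n_c, n_p = len(part.C), len(part.P)
    n_vars = n_f + n_c + n_p
    ridx = model.reaction_index()

    S_x = mats.S_split[part.X, :]
    S_p = mats.S_split[part.P, :]
    S_c = mats.S_split[part.C, :]

    eq_rows: List[Dict[int, float]] = []
    eq_b: List[float] = []
    for xi in range(S_x.shape[0]):
        eq_rows.append({c: S_x[xi, c] for c in np.nonzero(S_x[xi])[0]})
        eq_b.append(0.0)
    for pj in range(n_p):
        row = {c: S_p[pj, c] for c in np.nonzero(S_p[pj])[0]}
        row[n_f + n_c + pj] = row.get(n_f + n_c + pj, 0.0) - mu
        eq_rows.append(row)
        eq_b.append(0.0)
    for cj in range(n_c):
        row = {c: S_c[cj, c] for c in np.nonzero(S_c[cj])[0]}
        row[n_f + cj] = row.get(n_f + cj, 0.0) - mu
        eq_rows.append(row)
        eq_b.append(0.0)
    # biomass normalization B_t = 1 g
    w_c = [model.species[i].molecular_weight for i in part.C]
    b_p = [model.species[i].objective_weight for i in part.P]
    eq_rows.append({
        **{n_f + cj: w_c[cj] for cj in range(n_c) if w_c[cj]},
        **{n_f + n_c + pj: b_p[pj] for pj in range(n_p) if b_p[pj]},
    })
    eq_b.append(1.0)

    ub_rows: List[Dict[int, float]] = []
    ub_b: List[float] = []
    for r in range(mats.HC.shape[0]):
        row = {c: mats.HC[r, c] for c in np.nonzero(mats.HC[r])[0]}
        for pj in np.nonzero(mats.HE[r])[0]:
            row[n_f + n_c + pj] = row.get(n_f + n_c + pj, 0.0) - mats.HE[r, pj]
        ub_rows.append(row)
        ub_b.append(0.0)
    for r in range(mats.HB.shape[0]):
        row = {}
        for cj in range(n_c):
            if mats.HB[r, cj]:
                row[n_f + cj] = mats.HB[r, cj]
        for pj in range(n_p):
            if mats.HB[r, n_c + pj]:
                row[n_f + n_c + pj] = mats.HB[r, n_c + pj]
        ub_rows.append(row)
        ub_b.append(0.0)
    for r, rid in enumerate(mats.maintenance_rows):
        row = {}
        for cj in range(n_c):
            if mats.HM[r, cj]:
                row[n_f + cj] = mats.HM[r, cj]
        for pj in range(n_p):
            if mats.HM[r, n_c + pj]:
                row[n_f + n_c + pj] = mats.HM[r, n_c + pj]
        for c, (cid, sign) in enumerate(mats.flux_columns):
            if cid == rid:
                row[c] = row.get(c, 0.0) - float(sign)
        ub_rows.append(row)
        ub_b.append(0.0)

    bounds: List[Tuple[float, float]] = []
    for c, (rid, sign) in enumerate(mats.flux_columns):
        rxn = model.reactions[ridx[rid]]
        if not rxn.reversible:
            lo, hi = max(rxn.lower_bound, 0.0), rxn.upper_bound
        elif sign > 0:
            lo, hi = 0.0, max(rxn.upper_bound, 0.0)
        else:
            lo, hi = 0.0, max(-rxn.lower_bound, 0.0)
        if c in blocked_cols:
            lo, hi = 0.0, 0.0
        bounds.append((lo, hi))
    bounds.extend([(0.0, np.inf)] * (n_c + n_p))

    try:
        res = _run_lp(
            np.zeros(n_vars),
            _matrix(ub_rows, n_vars), np.array(ub_b),
            _matrix(eq_rows, n_vars), np.array(eq_b),
            bounds, context="RBA feasibility",
        )
    except InfeasibleProblemError:
        return None
    return res.x[n_f:n_f + n_c].copy(), res.x[n_f + n_c:].copy()


def solve_rba_initial(
    model: RAMModel,
    y0,
    mu_bracket: Optional[Tuple[float, float]] = None,
    tolerance: float = 1e-6,
    biomass: float = 1.0,
) -> Tuple[float, np.ndarray, np.ndarray]:
    """Balanced-growth initializer: maximal growth rate and composition.

    Finds by bisection the largest ``mu`` in ``mu_bracket`` for which
    balanced exponential growth is feasible: ``S_X v = 0``,
    ``S_P v = mu p``, ``S_C v = mu c``, capacity/quota/maintenance
    constraints, total biomass normalized to 1 g.  ``y0`` gives the
    environment (partition order or ``{species_id: amount}``): uptake of an
    extracellular species with zero amount is blocked, positive amounts are
    treated as saturating.

    Returns ``(mu_max, c0, p0)`` with the amounts rescaled to ``biomass``
    grams; raises :class:`InfeasibleProblemError` if the model cannot even
    sustain itself at zero growth.
    """
    mats = build_constraint_matrices(model)
    part = mats.partition
    if isinstance(y0, dict):
        y_arr = np.array(
            [float(y0.get(model.species[i].id, 0.0)) for i in part.Y]
        )
    else:
        y_arr = np.asarray(y0, dtype=float)
        if y_arr.shape != (len(part.Y),):
            raise DomainError(
                f"expected {len(part.Y)} extracellular amounts,"
                f" got {y_arr.shape}"
            )

    ridx = model.reaction_index()
    S = mats.S
    blocked = set()
    for c, (rid, sign) in enumerate(mats.flux_columns):
        j = ridx[rid]
        for yi, row in enumerate(part.Y):
            if y_arr[yi] <= 0.0 and sign * S[row, j] < 0:
                blocked.add(c)
                break

    if mu_bracket is None:
        kcats = [r.kcat_forward for r in model.reactions] + \
                [r.kcat_backward for r in model.reactions]
        hi = max([k for k in kcats if k > 0], default=1.0)
        mu_bracket = (0.0, hi)
    lo, hi = mu_bracket
    if lo < 0 or hi <= lo:
        raise DomainError("invalid growth-rate bracket")

    best = _rba_feasible(model, mats, lo, blocked)
    if best is None:
        raise InfeasibleProblemError(
            "balanced growth infeasible even at the lower bracket edge:"
            " the model cannot sustain itself"
        )
    mu_best = lo
    at_hi = _rba_feasible(model, mats, hi, blocked)
    if at_hi is not None:
        mu_best, best = hi, at_hi
    else:
        while hi - mu_best > tolerance:
            mid = 0.5 * (mu_best + hi)
            sol = _rba_feasible(model, mats, mid, blocked)
            if sol is None:
                hi = mid
            else:
                mu_best, best = mid, sol
    c0, p0 = best
    return mu_best, c0 * biomass, p0 * biomass
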