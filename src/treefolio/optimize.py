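"""Planting-portfolio optimization: scenario-optimal, P-EV and P-RA.

The decision is which cells to plant with which species (binary, at most one
species per cell) plus the level ``z`` of a riskless alternative CDR
technology (MtCO2e/yr at unit cost gamma), subject to the ensemble-mean
sequestration target Q.  Three objectives are supported:

* ``scenario_value`` -- maximize the value under one assumed realization;
* ``expected_value`` -- maximize the probability-weighted mean value (P-EV);
* ``cvar``           -- minimize the conditional value-at-risk of the value
  distribution via the Rockafellar-Uryasev linearization (P-RA).

Two value forms are available: ``V_full`` (NPV including the monetized
carbon value, the headline lens) and ``V_prime`` (timber-minus-farm cost
lens used for least-cost technology comparisons; the carbon value is fixed
by the binding sequestration constraint).

All programs are mixed-integer linear and solved with HiGHS through
``scipy.optimize.milp``.  Solutions are re-validated against the constraint
set and the recomputed objective independently of the solver.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import LinearConstraint, milp

from .config import OptimizationSpec, T_PER_MT
from .evaluate import empirical_cvar
from .valuation import ValuationTables

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"


class InfeasibleTargetError(RuntimeError):
    """Sequestration target unattainable; carries the attainable maximum."""

    def __init__(self, message: str, max_attainable_mt: float, gamma: float | None = None):
        super().__init__(message)
        self.max_attainable_mt = max_attainable_mt
        self.gamma = gamma


@dataclass
class PlantingStrategy:
    """A planting assignment plus the alternative-technology level.

    ``assignment`` maps cell_id -> species name; absent cells are unplanted.
    ``z`` is in MtCO2e/yr.
    """

    assignment: dict = field(default_factory=dict)
    z: float = 0.0
    label: str = ""

    def __post_init__(self):
        if self.z < 0:
            raise ValueError("z must be >= 0")

    @property
    def n_planted(self) -> int:
        return len(self.assignment)


@dataclass
class PortfolioSolution:
    strategy: PlantingStrategy
    objective: str
    objective_value: float               # native sense: value for EV, CVaR for cvar
    per_cer_value: np.ndarray            # (S,) V(x, z | s)
    solver_status: str
    mip_gap: float
    hectares: dict                       # species -> hectares planted
    tree_sequestration_mt: float         # ensemble-mean tree storage, MtCO2e/yr
    alpha: float | None = None           # RU auxiliary variable (cvar only)
    recheck_gap: float = 0.0             # |solver obj - recomputed obj|, tie-eps excluded
    x_fractional: np.ndarray | None = None  # retained-pair levels under relaxation


# ---------------------------------------------------------------------------
# value coefficients

def _pairs(valuation: ValuationTables) -> np.ndarray:
    """Retained (i, j) index pairs, ordered by cell then species; (P, 2)."""
    return np.argwhere(valuation.retained)


def value_coefficients(valuation: ValuationTables, spec: OptimizationSpec):
    """Per-pair and z objective coefficients for every CER.

    Returns ``(coef, zcoef)`` with ``coef`` of shape (P, S) such that
    ``V(x, z | s) = coef[:, s] @ x + zcoef[s] * z``.
    """
    gamma = spec.gamma or 0.0
    pairs = _pairs(valuation)
    ann_h = valuation.annuity_horizon
    if spec.value_form == "V_full":
        coef = valuation.R[pairs[:, 0], pairs[:, 1], :]
        zcoef = T_PER_MT * (valuation.scc_disc - gamma * ann_h)
    else:  # V_prime: timber minus foregone farm, minus the technology cost
        coef = (
            valuation.r_timber[pairs[:, 0], pairs[:, 1], :] * ann_h
            - valuation.farm_npv[pairs[:, 0], pairs[:, 1], :]
        )
        zcoef = np.full(valuation.n_cer, -T_PER_MT * gamma * ann_h)
    return coef, zcoef


def _x_vector(strategy: PlantingStrategy, valuation: ValuationTables) -> np.ndarray:
    """Strategy -> indicator over retained pairs; errors on excluded pairs."""
    pairs = _pairs(valuation)
    index = {
        (int(valuation.cell_ids[i]), valuation.species_names[j]): p
        for p, (i, j) in enumerate(pairs)
    }
    x = np.zeros(len(pairs))
    for cell_id, species in strategy.assignment.items():
        key = (int(cell_id), species)
        if key not in index:
            raise KeyError(
                f"strategy plants excluded or unknown pair {key}; "
                "it is not in the retained valuation tables"
            )
        x[index[key]] = 1.0
    return x


def per_cer_values(
    strategy: PlantingStrategy, valuation: ValuationTables, spec: OptimizationSpec
) -> np.ndarray:
    """V(x, z | s) for every realization s; shape (S,)."""
    coef, zcoef = value_coefficients(valuation, spec)
    x = _x_vector(strategy, valuation)
    return coef.T @ x + zcoef * strategy.z


def portfolio_value(
    strategy: PlantingStrategy,
    valuation: ValuationTables,
    cer_index: int,
    spec: OptimizationSpec,
) -> float:
    """V(x, z | s) under the single realization at position ``cer_index``."""
    return float(per_cer_values(strategy, valuation, spec)[cer_index])


# ---------------------------------------------------------------------------
# constraints

@dataclass
class ConstraintSet:
    pairs: np.ndarray                    # (P, 2) retained (i, j)
    a_cell: sparse.csr_matrix            # (N, P) one row per cell: sum_j x_ij <= 1
    mbar: np.ndarray                     # (P,) ensemble-mean storage, tCO2e/yr
    target_t: float                      # Q in tCO2e/yr
    z_upper: float                       # MtCO2e/yr bound on z (0 when disabled)

    @property
    def n_assignment_constraints(self) -> int:
        return self.a_cell.shape[0]

    @property
    def n_target_constraints(self) -> int:
        return 1

    def max_attainable_mt(self) -> float:
        """Best ensemble-mean sequestration with every cell planted plus z."""
        n = self.a_cell.shape[0]
        best = np.zeros(n)
        for p, (i, _) in enumerate(self.pairs):
            best[i] = max(best[i], self.mbar[p])
        return float(best.sum() / T_PER_MT + self.z_upper)


def build_constraints(valuation: ValuationTables, spec: OptimizationSpec) -> ConstraintSet:
    """Assemble the planting constraints; raise if Q is unattainable."""
    spec.validate()
    pairs = _pairs(valuation)
    n = valuation.n_cells
    p_count = len(pairs)
    a_cell = sparse.csr_matrix(
        (np.ones(p_count), (pairs[:, 0], np.arange(p_count))), shape=(n, p_count)
    )
    mbar = valuation.mean_m[pairs[:, 0], pairs[:, 1]]
    cs = ConstraintSet(
        pairs=pairs,
        a_cell=a_cell,
        mbar=mbar,
        target_t=spec.target_q * T_PER_MT,
        z_upper=spec.z_upper,
    )
    attainable = cs.max_attainable_mt()
    if attainable < spec.target_q - 1e-12:
        raise InfeasibleTargetError(
            f"sequestration target Q={spec.target_q} MtCO2e/yr unattainable; "
            f"maximum attainable ensemble-mean sequestration is {attainable:.6g} MtCO2e/yr",
            max_attainable_mt=attainable,
            gamma=spec.gamma,
        )
    logger.debug("unit conversion: 1 MtCO2e = %.0f tCO2e applied to target and z", T_PER_MT)
    return cs


# ---------------------------------------------------------------------------
# solver core

def _tie_penalty(valuation: ValuationTables, cs: ConstraintSet, spec: OptimizationSpec):
    """Lexicographic epsilon: prefer fewer planted cells, then lower cell_id,
    then the first-listed species."""
    cell_ids = valuation.cell_ids[cs.pairs[:, 0]].astype(float)
    return spec.tie_eps * (cell_ids + 0.5 * cs.pairs[:, 1])


def _extract_strategy(
    x: np.ndarray, z: float, valuation: ValuationTables, cs: ConstraintSet, label: str
) -> PlantingStrategy:
    assignment = {}
    for p, (i, j) in enumerate(cs.pairs):
        if x[p] > 0.5:
            assignment[int(valuation.cell_ids[i])] = valuation.species_names[j]
    return PlantingStrategy(assignment=assignment, z=float(max(z, 0.0)), label=label)


def _recheck_feasibility(
    x: np.ndarray, z: float, cs: ConstraintSet, spec: OptimizationSpec
) -> None:
    """Independent exact re-validation of the returned solution."""
    per_cell = cs.a_cell @ x
    if np.any(per_cell > 1 + 1e-9):
        raise RuntimeError("solver returned a cell planted with more than one species")
    lhs = float(cs.mbar @ x) + T_PER_MT * z
    if lhs < cs.target_t - 1e-6 * max(1.0, abs(cs.target_t)):
        raise RuntimeError(
            f"solver solution violates the sequestration target: {lhs} < {cs.target_t}"
        )
    if z < -1e-9 or z > cs.z_upper + 1e-9:
        raise RuntimeError("z outside its bounds")


def _hectares(strategy: PlantingStrategy, valuation: ValuationTables) -> dict:
    area = {name: 0.0 for name in valuation.species_names}
    by_id = dict(zip(valuation.cell_ids.tolist(), valuation.area_ha.tolist()))
    for cell_id, species in strategy.assignment.items():
        area[species] += by_id[int(cell_id)]
    return area


def _tree_sequestration_mt(x: np.ndarray, cs: ConstraintSet) -> float:
    return float(cs.mbar @ x) / T_PER_MT


def _solve_milp(c, constraints, integrality, bounds, spec: OptimizationSpec):
    res = milp(
        c=c,
        constraints=constraints,
        integrality=integrality,
        bounds=bounds,
        options={"mip_rel_gap": spec.mip_gap, "presolve": True},
    )
    if res.status == 2:
        raise InfeasibleTargetError(
            "optimization problem infeasible", max_attainable_mt=np.nan, gamma=spec.gamma
        )
    if not res.success:
        raise RuntimeError(f"MILP solver failed: status={res.status} {res.message}")
    return res


def _scaled_coefficients(coef: np.ndarray, zcoef: np.ndarray):
    """Normalize money coefficients for solver conditioning.

    The internal technology variable is in tCO2e/yr (``z_t = z * 1e6``), and
    all value coefficients are divided by a common money scale, so the
    constraint matrix stays well within HiGHS's comfortable numeric range.
    """
    zcoef_t = zcoef / T_PER_MT
    scale = float(max(1.0, np.abs(coef).max(initial=0.0), np.abs(zcoef_t).max(initial=0.0)))
    return coef / scale, zcoef_t / scale, scale


def _linear_objective_solution(
    valuation: ValuationTables,
    spec: OptimizationSpec,
    weights: np.ndarray,
    label: str,
) -> PortfolioSolution:
    """Maximize a CER-weighted linear value sum (scenario and P-EV cases)."""
    cs = build_constraints(valuation, spec)
    coef, zcoef = value_coefficients(valuation, spec)
    coef_n, zcoef_tn, scale = _scaled_coefficients(coef, zcoef)
    p_count = len(cs.pairs)

    obj_x = coef_n @ weights
    obj_z = float(zcoef_tn @ weights)
    c = np.concatenate([-obj_x + _tie_penalty(valuation, cs, spec), [-obj_z + spec.tie_eps]])

    a_cell = sparse.hstack([cs.a_cell, sparse.csr_matrix((cs.a_cell.shape[0], 1))])
    a_target = sparse.csr_matrix(np.concatenate([cs.mbar, [1.0]])[None, :])
    constraints = [
        LinearConstraint(a_cell, -np.inf, 1.0),
        LinearConstraint(a_target, cs.target_t, np.inf),
    ]
    integrality = np.zeros(p_count + 1)
    if spec.relaxation == "binary":
        integrality[:p_count] = 1
    from scipy.optimize import Bounds

    lb = np.zeros(p_count + 1)
    ub = np.concatenate([np.ones(p_count), [cs.z_upper * T_PER_MT]])
    res = _solve_milp(c, constraints, integrality, Bounds(lb, ub), spec)

    x_raw = res.x[:p_count]
    z = float(res.x[p_count]) / T_PER_MT
    x = np.round(x_raw) if spec.relaxation == "binary" else x_raw
    if spec.relaxation == "binary":
        _recheck_feasibility(x, z, cs, spec)
    strategy = _extract_strategy(x, z, valuation, cs, label)
    per_cer = coef.T @ x + zcoef * z
    recomputed = float(weights @ per_cer)
    tie_part = float(_tie_penalty(valuation, cs, spec) @ x + spec.tie_eps * z * T_PER_MT)
    solver_obj = (-float(res.fun) + tie_part) * scale if res.fun is not None else np.nan
    return PortfolioSolution(
        strategy=strategy,
        objective=spec.objective,
        objective_value=recomputed,
        per_cer_value=per_cer,
        solver_status=res.message,
        mip_gap=float(getattr(res, "mip_gap", 0.0) or 0.0),
        hectares=_hectares(strategy, valuation),
        tree_sequestration_mt=_tree_sequestration_mt(x, cs),
        recheck_gap=abs(solver_obj - recomputed),
        x_fractional=x_raw if spec.relaxation == "continuous" else None,
    )


def scenario_optimal(
    valuation: ValuationTables, cer_index: int, spec: OptimizationSpec, label: str | None = None
) -> PortfolioSolution:
    """Best strategy assuming the realization at ``cer_index`` is true."""
    spec = _with_objective(spec, "scenario_value")
    weights = np.zeros(valuation.n_cer)
    weights[cer_index] = 1.0
    label = label or f"P-CER{int(valuation.cer_ids[cer_index])}"
    return _linear_objective_solution(valuation, spec, weights, label)


def expected_value_optimal(
    valuation: ValuationTables, spec: OptimizationSpec, label: str = "P-EV"
) -> PortfolioSolution:
    """The risk-neutral optimum: maximize the probability-weighted mean value."""
    spec = _with_objective(spec, "expected_value")
    return _linear_objective_solution(valuation, spec, valuation.probs, label)


def cvar_optimal(
    valuation: ValuationTables, spec: OptimizationSpec, label: str = "P-RA"
) -> PortfolioSolution:
    """The risk-averse optimum: minimize CVaR_beta of the value distribution.

    Solves the Rockafellar-Uryasev program
    ``min_{x,z,alpha,u>=0} alpha + (1/(1-beta)) sum_s p_s u_s`` subject to
    ``u_s >= -V(x,z|s) - alpha`` and the planting constraints.  The reported
    objective value is the empirical CVaR of the solution, recomputed from
    its value distribution.
    """
    spec = _with_objective(spec, "cvar")
    s_count = valuation.n_cer
    tail = (1.0 - spec.beta) * s_count
    if abs(tail - round(tail)) > 1e-9:
        warnings.warn(
            f"(1-beta)*S = {tail:.6g} is not an integer; the RU program then "
            "defines CVaR by interpolation between order statistics",
            stacklevel=2,
        )
    cs = build_constraints(valuation, spec)
    coef, zcoef = value_coefficients(valuation, spec)
    coef_n, zcoef_tn, scale = _scaled_coefficients(coef, zcoef)
    p_count = len(cs.pairs)
    n_var = p_count + 1 + 1 + s_count            # x, z_t, alpha, u_s

    c = np.zeros(n_var)
    c[:p_count] = _tie_penalty(valuation, cs, spec)
    c[p_count] = spec.tie_eps
    c[p_count + 1] = 1.0                          # alpha (in scaled money)
    c[p_count + 2:] = valuation.probs / (1.0 - spec.beta)

    a_cell = sparse.hstack(
        [cs.a_cell, sparse.csr_matrix((cs.a_cell.shape[0], 2 + s_count))]
    )
    a_target = sparse.csr_matrix(
        np.concatenate([cs.mbar, [1.0], np.zeros(1 + s_count)])[None, :]
    )
    # u_s + alpha + V(x,z|s) >= 0 for every s (scaled money units)
    a_ru = sparse.hstack(
        [
            sparse.csr_matrix(coef_n.T),              # (S, P)
            sparse.csr_matrix(zcoef_tn[:, None]),     # z_t column
            sparse.csr_matrix(np.ones((s_count, 1))),  # alpha
            sparse.identity(s_count, format="csr"),    # u
        ]
    )
    constraints = [
        LinearConstraint(a_cell, -np.inf, 1.0),
        LinearConstraint(a_target, cs.target_t, np.inf),
        LinearConstraint(a_ru, 0.0, np.inf),
    ]
    integrality = np.zeros(n_var)
    if spec.relaxation == "binary":
        integrality[:p_count] = 1
    from scipy.optimize import Bounds

    lb = np.concatenate([np.zeros(p_count), [0.0], [-np.inf], np.zeros(s_count)])
    ub = np.concatenate(
        [np.ones(p_count), [cs.z_upper * T_PER_MT], [np.inf], np.full(s_count, np.inf)]
    )
    res = _solve_milp(c, constraints, integrality, Bounds(lb, ub), spec)

    x_raw = res.x[:p_count]
    z = float(res.x[p_count]) / T_PER_MT
    alpha = float(res.x[p_count + 1]) * scale
    x = np.round(x_raw) if spec.relaxation == "binary" else x_raw
    if spec.relaxation == "binary":
        _recheck_feasibility(x, z, cs, spec)
    strategy = _extract_strategy(x, z, valuation, cs, label)
    per_cer = coef.T @ x + zcoef * z
    cvar = empirical_cvar(per_cer, valuation.probs, spec.beta)
    tie_part = float(
        _tie_penalty(valuation, cs, spec) @ x + spec.tie_eps * z * T_PER_MT
    )
    solver_obj = (float(res.fun) - tie_part) * scale
    return PortfolioSolution(
        strategy=strategy,
        objective="cvar",
        objective_value=cvar,
        per_cer_value=per_cer,
        solver_status=res.message,
        mip_gap=float(getattr(res, "mip_gap", 0.0) or 0.0),
        hectares=_hectares(strategy, valuation),
        tree_sequestration_mt=_tree_sequestration_mt(x, cs),
        alpha=alpha,
        recheck_gap=abs(solver_obj - cvar),
        x_fractional=x_raw if spec.relaxation == "continuous" else None,
    )


def _with_objective(spec: OptimizationSpec, objective: str) -> OptimizationSpec:
    import dataclasses

    spec = dataclasses.replace(spec, objective=objective)
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# technology sweep

SWEEP_COLUMNS = [
    "gamma", "objective", "hectares_conifer", "hectares_broadleaf",
    "tree_mean_sequestration_MtCO2e", "z",
    "cost_min", "cost_mean", "cost_p95", "cost_max",
]


def mixed_technology_sweep(
    valuation: ValuationTables,
    spec: OptimizationSpec,
    gamma_grid,
) -> pd.DataFrame:
    """Solve P-EV and P-RA with the alternative technology across a cost grid.

    For each gamma the total-cost distribution ``-V'(x, z | s)`` across CERs
    is summarized (min, mean, 95th percentile, max).  Any infeasible point
    aborts with the gamma at fault.
    """
    import dataclasses

    gamma_grid = list(gamma_grid)
    if not gamma_grid or gamma_grid != sorted(gamma_grid):
        raise ValueError("gamma_grid must be non-empty and ascending")
    rows = []
    for gamma in gamma_grid:
        for objective, solver in (
            ("expected_value", expected_value_optimal),
            ("cvar", cvar_optimal),
        ):
            gspec = dataclasses.replace(spec, gamma=float(gamma), objective=objective)
            try:
                sol = solver(valuation, gspec, label=f"{objective}@gamma={gamma:g}")
            except InfeasibleTargetError as err:
                raise InfeasibleTargetError(
                    f"sweep infeasible at gamma={gamma:g}: {err}",
                    max_attainable_mt=err.max_attainable_mt,
                    gamma=float(gamma),
                ) from err
            cost_spec = dataclasses.replace(gspec, value_form="V_prime")
            cost = -per_cer_values(sol.strategy, valuation, cost_spec)
            by_species = {name: sol.hectares.get(name, 0.0) for name in valuation.species_names}
            rows.append(
                {
                    "gamma": float(gamma),
                    "objective": objective,
                    "hectares_conifer": by_species.get("conifer", 0.0),
                    "hectares_broadleaf": by_species.get("broadleaf", 0.0),
                    "tree_mean_sequestration_MtCO2e": sol.tree_sequestration_mt,
                    "z": sol.strategy.z,
                    "cost_min": float(np.min(cost)),
                    "cost_mean": float(np.mean(cost)),
                    "cost_p95": float(np.percentile(cost, 95)),
                    "cost_max": float(np.max(cost)),
                }
            )
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


# ---------------------------------------------------------------------------
# strategy I/O

def write_strategy(strategy: PlantingStrategy, path, spec: OptimizationSpec | None = None) -> None:
    """Delimited strategy file: header records (as # comments) then cell rows."""
    with open(path, "w") as fh:
        fh.write(f"# label={strategy.label}\n")
        fh.write(f"# z={strategy.z!r}\n")
        if spec is not None:
            fh.write(f"# objective={spec.objective}\n")
            fh.write(f"# beta={spec.beta!r}\n")
            fh.write(f"# gamma={spec.gamma!r}\n")
            fh.write(f"# value_form={spec.value_form}\n")
        fh.write("cell_id,species\n")
        for cell_id in sorted(strategy.assignment):
            fh.write(f"{cell_id},{strategy.assignment[cell_id]}\n")


def read_strategy(path) -> PlantingStrategy:
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value.strip()
            elif line and not line.startswith("cell_id"):
                cell, _, species = line.partition(",")
                rows.append((int(cell), species))
    return PlantingStrategy(
        assignment=dict(rows),
        z=float(meta.get("z", "0") or 0.0),
        label=meta.get("label", ""),
    )
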