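"""Linear-programming core: FBA, FVA, ratio couplings and forced-flux scans.

All problems are of the form

    max / min  c'v    s.t.   S v = 0,  lb <= v <= ub,  extra linear rows,

solved with the HiGHS simplex backend (``scipy.optimize.linprog``), which
returns a basic optimal solution (a vertex of the flux polytope).  Optimal
flux vectors are in general non-unique; uniqueness statements must go
through :func:`flux_variability`, never through the returned vertex.

Reversible reactions are kept as single variables with negative lower
bounds.  Ratio couplings (e.g. "oxygenase >= 3% of carboxylase") are extra
matrix rows rather than bound substitutions, so they compose with FVA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel, stoichiometric_matrix

__all__ = [
    "LinearConstraint",
    "ObjectiveSpec",
    "FluxSolution",
    "FluxRange",
    "solve_fba",
    "flux_variability",
    "add_ratio_constraint",
    "forced_flux_scan",
    "parse_constraint",
]

#: feasibility tolerance passed to the solver
FEASIBILITY_TOL = 1e-9
#: tolerance for comparing reported objective values
COMPARISON_TOL = 1e-6


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class LinearConstraint:
    """A row  sum_i coef_i * v_i  {<=,=,>=}  rhs."""

    coefficients: dict[str, float]
    relation: str  # "<=", "=", ">="
    rhs: float = 0.0

    def __post_init__(self) -> None:
        if self.relation not in ("<=", "=", ">="):
            raise ValueError(f"unknown relation {self.relation!r}")
        if not any(c != 0 for c in self.coefficients.values()):
            raise ValueError("constraint has no nonzero coefficient")


@dataclass(frozen=True)
class ObjectiveSpec:
    coefficients: dict[str, float]
    direction: str = "maximize"

    def __post_init__(self) -> None:
        if self.direction not in ("maximize", "minimize"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not any(c != 0 for c in self.coefficients.values()):
            raise ValueError("objective is empty")

    @classmethod
    def maximize(cls, rxn_id: str) -> "ObjectiveSpec":
        return cls({rxn_id: 1.0}, "maximize")

    @classmethod
    def minimize(cls, rxn_id: str) -> "ObjectiveSpec":
        return cls({rxn_id: 1.0}, "minimize")


@dataclass
class FluxSolution:
    status: str  # "optimal" | "infeasible" | "unbounded"
    objective_value: float
    fluxes: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FluxRange:
    """Per-reaction (min, max) flux at a given objective fraction."""

    ranges: dict[str, tuple[float, float]]
    fraction: float = 1.0

    def __getitem__(self, rxn_id: str) -> tuple[float, float]:
        return self.ranges[rxn_id]


# ---------------------------------------------------------------------------


def _build_arrays(model, objective, extra):
    rxn_pos = {r.id: j for j, r in enumerate(model.reactions)}
    n = len(model.reactions)

    c = np.zeros(n)
    for rid, coef in objective.coefficients.items():
        if rid not in rxn_pos:
            raise KeyError(f"objective references unknown reaction {rid!r}")
        c[rxn_pos[rid]] = coef

    S = stoichiometric_matrix(model).tocsr()
    b_eq = np.zeros(S.shape[0])

    A_ub_rows, b_ub = [], []
    A_eq_rows, b_eq_extra = [], []
    for con in extra:
        row = np.zeros(n)
        for rid, coef in con.coefficients.items():
            if rid not in rxn_pos:
                raise KeyError(f"constraint references unknown reaction {rid!r}")
            row[rxn_pos[rid]] = coef
        if con.relation == "<=":
            A_ub_rows.append(row)
            b_ub.append(con.rhs)
        elif con.relation == ">=":
            A_ub_rows.append(-row)
            b_ub.append(-con.rhs)
        else:
            A_eq_rows.append(row)
            b_eq_extra.append(con.rhs)

    from scipy import sparse

    if A_eq_rows:
        A_eq = sparse.vstack([S, sparse.csr_matrix(np.array(A_eq_rows))])
        b_eq = np.concatenate([b_eq, b_eq_extra])
    else:
        A_eq = S
    A_ub = np.array(A_ub_rows) if A_ub_rows else None
    b_ub = np.array(b_ub) if A_ub_rows else None

    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    return c, A_eq, b_eq, A_ub, b_ub, bounds, rxn_pos


def solve_fba(
    model: MetabolicModel,
    objective: ObjectiveSpec,
    extra: list[LinearConstraint] = (),
) -> FluxSolution:
    """Solve one flux-balance problem and return a basic optimal solution."""
    c, A_eq, b_eq, A_ub, b_ub, bounds, rxn_pos = _build_arrays(
        model, objective, list(extra)
    )
    sign = -1.0 if objective.direction == "maximize" else 1.0
    res = linprog(
        sign * c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": FEASIBILITY_TOL},
    )
    if res.status == 2:
        return FluxSolution(status="infeasible", objective_value=float("nan"))
    if res.status == 3:
        return FluxSolution(status="unbounded", objective_value=float("nan"))
    if res.status != 0:
        raise SolverError(f"LP solver failed: {res.message}")
    fluxes = {r.id: float(x) for r, x in zip(model.reactions, res.x)}
    return FluxSolution(
        status="optimal", objective_value=float(c @ res.x), fluxes=fluxes
    )


def flux_variability(
    model: MetabolicModel,
    objective: ObjectiveSpec,
    fraction: float = 1.0,
    extra: list[LinearConstraint] = (),
    reactions: list[str] | None = None,
) -> FluxRange:
    """Min and max flux per reaction subject to retaining ``fraction`` of the
    optimal objective, plus all base constraints."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    base = solve_fba(model, objective, extra)
    if not base.optimal:
        raise SolverError(f"base problem is {base.status}")
    z = base.objective_value
    if objective.direction == "maximize":
        lock = LinearConstraint(dict(objective.coefficients), ">=",
                               fraction * z if z >= 0 else z / fraction)
    else:
        lock = LinearConstraint(dict(objective.coefficients), "<=",
                               z / fraction if z >= 0 else fraction * z)
    cons = list(extra) + [lock]

    targets = reactions if reactions is not None else [r.id for r in model.reactions]
    ranges: dict[str, tuple[float, float]] = {}
    for rid in targets:
        lo = solve_fba(model, ObjectiveSpec.minimize(rid), cons)
        hi = solve_fba(model, ObjectiveSpec.maximize(rid), cons)
        if not (lo.optimal and hi.optimal):
            raise SolverError(f"FVA subproblem for {rid!r} failed")
        ranges[rid] = (lo.objective_value, hi.objective_value)
    return FluxRange(ranges=ranges, fraction=fraction)


def add_ratio_constraint(
    target_rxn: str,
    reference_rxn: str,
    ratio: float,
    relation: str = ">=",
) -> LinearConstraint:
    """Couple two fluxes:  v_target  {>=,=,<=}  ratio * v_reference.

    Returned as the homogeneous row ``v_target - ratio * v_ref {rel} 0``.
    Both reactions are expected to operate irreversibly in the coupled
    direction; with a reference flux that can go negative the inequality
    changes meaning.
    """
    if not np.isfinite(ratio) or ratio < 0:
        raise ValueError("ratio must be finite and non-negative")
    if target_rxn == reference_rxn:
        raise ValueError("target and reference must differ")
    return LinearConstraint(
        {target_rxn: 1.0, reference_rxn: -float(ratio)}, relation, 0.0
    )


def forced_flux_scan(
    model: MetabolicModel,
    objective: ObjectiveSpec,
    rxn_id: str,
    values,
    extra: list[LinearConstraint] = (),
) -> list[tuple[float, float | None]]:
    """Re-optimize with ``v_rxn >= value`` for each grid value (ascending).

    Returns (forced value, objective) pairs; infeasible points carry None.
    For a maximization the objective sequence is non-increasing.
    """
    values = list(values)
    if any(b < a for a, b in zip(values, values[1:])):
        raise ValueError("grid must be sorted ascending")
    out: list[tuple[float, float | None]] = []
    for val in values:
        con = LinearConstraint({rxn_id: 1.0}, ">=", float(val))
        sol = solve_fba(model, objective, list(extra) + [con])
        out.append((float(val), sol.objective_value if sol.optimal else None))
    return out


# ---------------------------------------------------------------------------
# constraint mini-language:  v_<id> <op> <k>*v_<id> [+ <k>*v_<id> ...]
# ---------------------------------------------------------------------------

import re as _re

_TERM = _re.compile(r"^\s*(?:([+-]?\d*\.?\d+(?:[eE][+-]?\d+)?)\s*\*\s*)?v_(\S+)\s*$")


def parse_constraint(text: str) -> LinearConstraint:
    """Parse e.g. ``"v_oxy >= 0.03*v_carb"`` into a LinearConstraint."""
    m = _re.search(r"(<=|>=|=)", text)
    if m is None:
        raise ValueError(f"no relation in constraint {text!r}")
    relation = m.group(1)
    lhs, rhs = text.split(relation, 1)

    def side(expr: str, sign: float, coeffs: dict[str, float]) -> float:
        const = 0.0
        for term in _re.split(r"\+", expr):
            term = term.strip()
            if not term:
                continue
            tm = _TERM.match(term)
            if tm:
                k = float(tm.group(1)) if tm.group(1) else 1.0
                rid = tm.group(2)
                coeffs[rid] = coeffs.get(rid, 0.0) + sign * k
            else:
                const += sign * float(term)
        return const

    coeffs: dict[str, float] = {}
    const = side(lhs, 1.0, coeffs)
    const += side(rhs, -1.0, coeffs)
    return LinearConstraint(coeffs, relation, -const)
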