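"""Brute-force reference solver for tiny flux polytopes.

Enumerates every vertex of  {v : S v = 0, lb <= v <= ub, extra rows}  by
trying all combinations of active constraints, and derives the optimal
objective and fraction-1.0 flux-variability ranges from the vertex list.
Exponential in the reaction count — intended for fixtures of at most ~8
reactions, where it serves as an exact, solver-independent oracle.

For enumeration, reversible reactions are handled directly via their two
bounds; no variable splitting of the LP engine's kind is involved.
"""

from __future__ import annotations

import itertools

import numpy as np

from .fba import LinearConstraint, ObjectiveSpec
from .model import MetabolicModel, stoichiometric_matrix

__all__ = ["enumerate_vertices", "brute_force_optimum", "brute_force_fva"]

_TOL = 1e-8


def _assemble(model, extra):
    n = len(model.reactions)
    rxn_pos = {r.id: j for j, r in enumerate(model.reactions)}
    S = stoichiometric_matrix(model).toarray()
    eq_rows = [S[i] for i in range(S.shape[0])]
    eq_rhs = [0.0] * S.shape[0]
    ineq_rows, ineq_rhs = [], []  # as row . v <= rhs
    for con in extra or ():
        row = np.zeros(n)
        for rid, coef in con.coefficients.items():
            row[rxn_pos[rid]] = coef
        if con.relation == "=":
            eq_rows.append(row)
            eq_rhs.append(con.rhs)
        elif con.relation == "<=":
            ineq_rows.append(row)
            ineq_rhs.append(con.rhs)
        else:
            ineq_rows.append(-row)
            ineq_rhs.append(-con.rhs)
    return np.array(eq_rows), np.array(eq_rhs), ineq_rows, ineq_rhs, rxn_pos


def enumerate_vertices(
    model: MetabolicModel, extra: list[LinearConstraint] = ()
) -> np.ndarray:
    """All vertices of the flux polytope, one per row (deduplicated)."""
    n = len(model.reactions)
    if n > 12:
        raise ValueError("vertex enumeration is meant for tiny fixtures")
    E, f, ineq_rows, ineq_rhs, _ = _assemble(model, extra)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])

    rank_e = np.linalg.matrix_rank(E) if E.size else 0
    k = n - rank_e

    # candidate active constraints: each bound and each inequality row
    candidates: list[tuple[np.ndarray, float]] = []
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        candidates.append((e, lb[j]))
        if ub[j] != lb[j]:
            candidates.append((e.copy(), ub[j]))
    for row, rhs in zip(ineq_rows, ineq_rhs):
        candidates.append((row, rhs))

    verts: list[np.ndarray] = []
    for combo in itertools.combinations(range(len(candidates)), k):
        rows = np.vstack([E] + [candidates[i][0] for i in combo]) if E.size else \
            np.vstack([candidates[i][0] for i in combo])
        rhs = np.concatenate([f, [candidates[i][1] for i in combo]]) if E.size else \
            np.array([candidates[i][1] for i in combo])
        if np.linalg.matrix_rank(rows) < n:
            continue
        v, *_ = np.linalg.lstsq(rows, rhs, rcond=None)
        if np.max(np.abs(rows @ v - rhs)) > _TOL:
            continue
        if np.any(v < lb - _TOL) or np.any(v > ub + _TOL):
            continue
        if ineq_rows and any(
            row @ v > rhs_i + _TOL for row, rhs_i in zip(ineq_rows, ineq_rhs)
        ):
            continue
        if not any(np.allclose(v, w, atol=1e-7) for w in verts):
            verts.append(v)
    return np.array(verts)


def _objective_vector(model, objective):
    rxn_pos = {r.id: j for j, r in enumerate(model.reactions)}
    c = np.zeros(len(model.reactions))
    for rid, coef in objective.coefficients.items():
        c[rxn_pos[rid]] = coef
    return c


def brute_force_optimum(
    model: MetabolicModel,
    objective: ObjectiveSpec,
    extra: list[LinearConstraint] = (),
) -> float:
    """Best objective over all polytope vertices."""
    verts = enumerate_vertices(model, extra)
    if len(verts) == 0:
        raise ValueError("polytope has no vertex (infeasible or misspecified)")
    vals = verts @ _objective_vector(model, objective)
    return float(vals.max() if objective.direction == "maximize" else vals.min())


def brute_force_fva(
    model: MetabolicModel,
    objective: ObjectiveSpec,
    extra: list[LinearConstraint] = (),
    tol: float = 1e-7,
) -> dict[str, tuple[float, float]]:
    """Fraction-1.0 FVA ranges: per-reaction min/max over optimal vertices.

    The optimal face is the convex hull of the optimal vertices, so the
    coordinate-wise extrema over that set are exact.
    """
    verts = enumerate_vertices(model, extra)
    if len(verts) == 0:
        raise ValueError("polytope has no vertex")
    c = _objective_vector(model, objective)
    vals = verts @ c
    z = vals.max() if objective.direction == "maximize" else vals.min()
    opt = verts[np.abs(vals - z) <= tol * max(1.0, abs(z))]
    return {
        r.id: (float(opt[:, j].min()), float(opt[:, j].max()))
        for j, r in enumerate(model.reactions)
    }
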