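"""Brute-force LP solution by pairwise constraint intersection.

This is the package's independent verification route.  It never touches the
closed-form vertex expressions: it rebuilds the LP from raw constraint
coefficients in the reduced (v2, v3) plane, intersects every pair of
constraint boundary lines with a 2x2 determinant solve, keeps the feasible
intersection points, and takes the maximum of the objective over them.
Agreement with :mod:`warburglp.vertex_solver` is therefore a genuine
cross-check, not a tautology.
"""

from __future__ import annotations

import itertools
import math
from typing import List, NamedTuple, Optional, Tuple

from .model_core import (
    EPS,
    FluxVector,
    InternalConsistencyError,
    ModelSpec,
    OptimalSolution,
    VertexSolution,
    atp_rate_reduced,
    is_feasible,
)
from .vertex_solver import classify_regime, REGIME_DEGENERATE_TIE

__all__ = ["brute_force_solve", "check_optimality_certificate"]

# |det| below this (relative to the coefficient scale) is treated as a
# parallel line pair and the intersection is skipped.
_DET_TOL = 1e-12

# binding-set -> table label, used to name oracle vertices where possible
_LABELS = {
    frozenset({"e", "f"}): "O",
    frozenset({"c", "f"}): "A",
    frozenset({"c", "v2=0"}): "B",
    frozenset({"d", "e"}): "C",
    frozenset({"f", "g"}): "A1",
    frozenset({"c", "g"}): "A2",
    frozenset({"g", "v2=0"}): "A3",
    frozenset({"d", "g"}): "A4",
}


class _Constraint(NamedTuple):
    """Half-plane a*v2 + b*v3 <= rhs (sense +1) or >= rhs (sense -1)."""

    name: str
    a: float
    b: float
    rhs: float
    sense: int

    def satisfied(self, v2: float, v3: float, tol: float) -> bool:
        lhs = self.a * v2 + self.b * v3
        slack = tol * max(1.0, abs(self.rhs), abs(lhs))
        if self.sense > 0:
            return lhs <= self.rhs + slack
        return lhs >= self.rhs - slack


def _constraints(spec: ModelSpec) -> List[_Constraint]:
    c = spec.costs
    cons = [
        _Constraint("c", c.alpha1 + c.alpha2, c.alpha1 + c.alpha3, c.Gamma, +1),
        _Constraint("d", c.alpha1 - c.alpha2_rev, c.alpha1 + c.alpha3, c.Gamma, +1),
        _Constraint("e", 1.0, 1.0, 0.0, -1),
        _Constraint("f", 0.0, 1.0, 0.0, -1),
    ]
    if not spec.limit.is_unlimited:
        cons.append(_Constraint("g", 1.0, 1.0, spec.limit.V1, +1))
    if not spec.fermentation_reversible:
        cons.append(_Constraint("v2=0", 1.0, 0.0, 0.0, -1))
    return cons


def _intersect(p: _Constraint, q: _Constraint) -> Optional[Tuple[float, float]]:
    det = p.a * q.b - p.b * q.a
    scale = max(1.0, abs(p.a), abs(p.b), abs(q.a), abs(q.b))
    if abs(det) <= _DET_TOL * scale:
        return None
    v2 = (p.rhs * q.b - p.b * q.rhs) / det
    v3 = (p.a * q.rhs - p.rhs * q.a) / det
    if not (math.isfinite(v2) and math.isfinite(v3)):
        return None
    return (v2, v3)


def _candidates(spec: ModelSpec, tol: float) -> List[Tuple[float, float, frozenset]]:
    cons = _constraints(spec)
    points: List[Tuple[float, float, frozenset]] = []
    for p, q in itertools.combinations(cons, 2):
        pt = _intersect(p, q)
        if pt is None:
            continue
        v2, v3 = pt
        if all(con.satisfied(v2, v3, tol) for con in cons):
            points.append((v2, v3, frozenset({p.name, q.name})))
    return points


def brute_force_solve(spec: ModelSpec, tol: float = EPS) -> OptimalSolution:
    """Solve the scenario by exhaustive vertex search.

    Every pairwise intersection of constraint boundaries that satisfies all
    constraints is a candidate; the maximum of the reduced objective over the
    candidates is the optimum.  Tied candidates at distinct points are all
    reported.  The origin is always a candidate (constraints e and f
    intersect there), so the result is never empty.
    """
    points = _candidates(spec, tol)
    if not points:
        raise InternalConsistencyError(
            "no feasible candidate point; the origin should always qualify"
        )
    y = spec.yields
    values = [atp_rate_reduced(v2, v3, y) for v2, v3, _ in points]
    phi_star = max(values)
    tie = tol * max(1.0, abs(phi_star))
    optima: List[VertexSolution] = []
    seen: List[Tuple[float, float]] = []
    for (v2, v3, binding), phi in zip(points, values):
        if phi < phi_star - tie:
            continue
        if any(math.hypot(v2 - u2, v3 - u3) <= tie for u2, u3 in seen):
            continue
        seen.append((v2, v3))
        flux = FluxVector.from_reduced(v2, v3)
        yr = phi / flux.v1 if abs(flux.v1) > tol * max(1.0, abs(flux.v1)) else None
        optima.append(
            VertexSolution(
                label=_LABELS.get(binding, "X"),
                flux=flux,
                binding=binding,
                feasible=True,
                atp=phi,
                yield_ratio=yr,
            )
        )
    regimes = {classify_regime(v.flux, tol) for v in optima}
    regime = regimes.pop() if len(regimes) == 1 else REGIME_DEGENERATE_TIE
    return OptimalSolution(optima=optima, phi_star=phi_star, regime=regime)


def check_optimality_certificate(
    spec: ModelSpec, candidate: OptimalSolution, tol: float = EPS
) -> bool:
    """Audit a claimed optimum against the exhaustive candidate set.

    Returns True iff every claimed optimal vertex is feasible and no
    constraint-pair intersection point beats ``candidate.phi_star`` by more
    than ``tol * max(1, phi_star)``.  Usable on third-party solutions: only
    the spec and the claimed solution are consulted.
    """
    for v in candidate.optima:
        if not is_feasible(v.flux, spec, tol):
            return False
    slack = tol * max(1.0, abs(candidate.phi_star))
    y = spec.yields
    for v2, v3, _ in _candidates(spec, tol):
        if atp_rate_reduced(v2, v3, y) > candidate.phi_star + slack:
            return False
    return True
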