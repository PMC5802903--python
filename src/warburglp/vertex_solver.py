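"""Closed-form vertex enumeration and selection of the metabolic optimum.

A bounded two-variable LP attains its maximum at a vertex of the feasible
polygon, so the optimum can be found by evaluating the objective at a short
list of critical points known in closed form.  With unlimited substrate there
are four: the origin O (quiescence), A (pure fermentation at full budget),
B (pure respiration at full budget) and C (respiration fed entirely by
reverse fermentation, zero glucose uptake).  A substrate cap ``V1`` adds up to
four more on the cap line: A1 (pure fermentation at the cap), A2 (the
fermentation/respiration mix that exhausts both the cap and the budget),
A3 (pure respiration at the cap) and A4 (the respiration/reverse-fermentation
mix that exhausts the cap and the reverse-cost budget).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

from .model_core import (
    EPS,
    REGIME_DEGENERATE_TIE,
    REGIME_PURE_FERMENTATION,
    REGIME_PURE_RESPIRATION,
    REGIME_QUIESCENT,
    REGIME_RESPIRO_FERMENTATION,
    REGIME_REVERSE_FERMENTATION,
    DegenerateCostError,
    DegenerateYieldError,
    FluxVector,
    InternalConsistencyError,
    ModelSpec,
    OptimalSolution,
    VertexSolution,
    atp_rate,
    is_feasible,
)

__all__ = [
    "enumerate_vertices",
    "solve",
    "classify_regime",
    "fermentation_favored",
    "substrate_thresholds",
    "CrossoverComparison",
]


def _vertex(label: str, v2: float, v3: float, binding: set, spec: ModelSpec,
            tol: float = EPS) -> VertexSolution:
    flux = FluxVector.from_reduced(v2, v3)
    phi = atp_rate(flux, spec.yields)
    if abs(flux.v1) > tol * max(1.0, abs(flux.v1)):
        yield_ratio: Optional[float] = phi / flux.v1
    else:
        yield_ratio = None
    return VertexSolution(
        label=label,
        flux=flux,
        binding=frozenset(binding),
        feasible=is_feasible(flux, spec, tol),
        atp=phi,
        yield_ratio=yield_ratio,
    )


def enumerate_vertices(spec: ModelSpec, tol: float = EPS) -> List[VertexSolution]:
    """All critical points of the scenario, with feasibility flags.

    Returns O, A, B, C for unlimited substrate and additionally A1–A4 when a
    cap is set.  Infeasible vertices are returned with ``feasible=False``
    rather than dropped, so callers can inspect the full geometry.  A capped
    mix vertex (A2 or A4) whose fermentation flux vanishes within tolerance
    coincides with B/A3 and is omitted to avoid duplicate optima.

    Raises
    ------
    DegenerateCostError
        If ``alpha3 == alpha2`` under a substrate cap (the A2 closed form
        divides by ``alpha3 - alpha2``), or if ``alpha1 + alpha2 == 0`` with
        unlimited substrate and ``m1 > 0`` (vertex A recedes to infinity and
        the LP is unbounded).
    """
    c = spec.costs
    y = spec.yields
    gamma = c.Gamma

    if c.alpha1 + c.alpha2 == 0 and spec.limit.is_unlimited and y.m1 > 0:
        raise DegenerateCostError(
            "alpha1 + alpha2 = 0 with unlimited substrate: pure fermentation "
            "is free and the ATP rate is unbounded"
        )

    vertices: List[VertexSolution] = [
        _vertex("O", 0.0, 0.0, {"e", "f"}, spec, tol),
    ]
    if c.alpha1 + c.alpha2 > 0:
        a_flux = gamma / (c.alpha1 + c.alpha2)
        vertices.append(_vertex("A", a_flux, 0.0, {"c", "f"}, spec, tol))
    b_flux = gamma / (c.alpha1 + c.alpha3)
    vertices.append(_vertex("B", 0.0, b_flux, {"c", "v2=0"}, spec, tol))
    c_flux = gamma / (c.alpha2_rev + c.alpha3)
    vertex_c = _vertex("C", -c_flux, c_flux, {"d", "e"}, spec, tol)
    if not spec.fermentation_reversible:
        vertex_c = VertexSolution(
            label="C", flux=vertex_c.flux, binding=vertex_c.binding,
            feasible=False, atp=vertex_c.atp, yield_ratio=vertex_c.yield_ratio,
        )
    vertices.append(vertex_c)

    if spec.limit.is_unlimited:
        return vertices

    V1 = spec.limit.V1
    if abs(c.alpha3 - c.alpha2) <= tol * max(1.0, c.alpha3):
        raise DegenerateCostError(
            f"alpha3 = alpha2 = {c.alpha3}: the capped mix vertex A2 is "
            "undefined (division by alpha3 - alpha2)"
        )

    vertices.append(_vertex("A1", V1, 0.0, {"f", "g"}, spec, tol))

    a2_v2 = ((c.alpha1 + c.alpha3) * V1 - gamma) / (c.alpha3 - c.alpha2)
    a2_v3 = (gamma - (c.alpha1 + c.alpha2) * V1) / (c.alpha3 - c.alpha2)
    if abs(a2_v2) > tol * max(1.0, V1):
        a2 = _vertex("A2", a2_v2, a2_v3, {"c", "g"}, spec, tol)
        # the capped mix is a genuine vertex only for strictly positive v2
        # and non-negative v3
        if a2_v2 < 0 or a2_v3 < 0:
            a2 = _infeasible(a2)
        vertices.append(a2)

    vertices.append(_vertex("A3", 0.0, V1, {"g", "v2=0"}, spec, tol))

    a4_v2 = ((c.alpha1 + c.alpha3) * V1 - gamma) / (c.alpha3 + c.alpha2_rev)
    a4_v3 = (gamma + (c.alpha2_rev - c.alpha1) * V1) / (c.alpha3 + c.alpha2_rev)
    if abs(a4_v2) > tol * max(1.0, V1):
        a4 = _vertex("A4", a4_v2, a4_v3, {"d", "g"}, spec, tol)
        # A4 requires strictly negative v2 (reverse fermentation in use)
        if a4_v2 > 0 or a4_v3 < 0 or not spec.fermentation_reversible:
            a4 = _infeasible(a4)
        vertices.append(a4)

    return vertices


def _infeasible(v: VertexSolution) -> VertexSolution:
    return VertexSolution(
        label=v.label, flux=v.flux, binding=v.binding,
        feasible=False, atp=v.atp, yield_ratio=v.yield_ratio,
    )


def classify_regime(flux: FluxVector, tol: float = EPS) -> str:
    """Qualitative label for a mass-balanced flux pattern.

    Zero tests use the tolerance ``tol * max(1, |v1|)`` so the decision is
    scale-free for large fluxes but absolute near the origin.
    """
    scale = tol * max(1.0, abs(flux.v1))
    v1_zero = abs(flux.v1) <= scale
    v2_zero = abs(flux.v2) <= scale
    v3_zero = abs(flux.v3) <= scale
    if v1_zero and v3_zero and v2_zero:
        return REGIME_QUIESCENT
    if v3_zero and flux.v2 > 0:
        return REGIME_PURE_FERMENTATION
    if v2_zero and flux.v3 > 0:
        return REGIME_PURE_RESPIRATION
    if flux.v2 > 0 and flux.v3 > 0:
        return REGIME_RESPIRO_FERMENTATION
    if flux.v2 < 0 and flux.v3 > 0:
        return REGIME_REVERSE_FERMENTATION
    # remaining patterns (e.g. v2 < 0, v3 = 0) cannot be feasible optima
    return REGIME_QUIESCENT if (v1_zero and v3_zero) else REGIME_DEGENERATE_TIE


def solve(spec: ModelSpec, tol: float = EPS) -> OptimalSolution:
    """Maximize the ATP rate over the feasible vertices.

    All feasible vertices whose objective lies within ``tol * max(1,
    phi_star)`` of the best are reported as optima; if they disagree on the
    regime the solution is labeled ``degenerate_tie``.
    """
    vertices = enumerate_vertices(spec, tol)
    feasible = [v for v in vertices if v.feasible]
    if not feasible:
        raise InternalConsistencyError("no feasible vertex; the origin should always be feasible")
    phi_star = max(v.atp for v in feasible)
    tie = tol * max(1.0, abs(phi_star))
    optima = [v for v in feasible if v.atp >= phi_star - tie]
    regimes = {classify_regime(v.flux, tol) for v in optima}
    regime = regimes.pop() if len(regimes) == 1 else REGIME_DEGENERATE_TIE
    return OptimalSolution(optima=optima, phi_star=phi_star, regime=regime)


@dataclass(frozen=True)
class CrossoverComparison:
    """Outcome of the fermentation-vs-respiration yield/cost comparison.

    ``yield_ratio`` is ``m1 / (m1 + m3)`` (relative ATP yield of fermentation)
    and ``cost_ratio`` is ``(alpha1 + alpha2) / (alpha1 + alpha3)`` (relative
    enzyme cost of fermentation).  Fermentation is favored when its relative
    yield exceeds its relative cost; equality is the crossover at which the
    pure-fermentation and pure-respiration vertices tie.
    """

    favored: bool
    yield_ratio: float
    cost_ratio: float
    at_crossover: bool


def fermentation_favored(spec: ModelSpec, tol: float = EPS) -> CrossoverComparison:
    """Does pure fermentation beat pure respiration with unlimited substrate?

    Compares ``m1/(m1+m3)`` against ``(alpha1+alpha2)/(alpha1+alpha3)``; the
    two sides are equal exactly when vertices A and B produce ATP at the same
    rate.
    """
    y, c = spec.yields, spec.costs
    if y.m1 + y.m3 == 0:
        raise DegenerateYieldError("m1 + m3 = 0: the yield ratio is undefined")
    lhs = y.m1 / (y.m1 + y.m3)
    rhs = (c.alpha1 + c.alpha2) / (c.alpha1 + c.alpha3)
    at_crossover = abs(lhs - rhs) <= tol * max(1.0, abs(lhs), abs(rhs))
    return CrossoverComparison(
        favored=lhs > rhs and not at_crossover,
        yield_ratio=lhs,
        cost_ratio=rhs,
        at_crossover=at_crossover,
    )


def substrate_thresholds(spec: ModelSpec) -> Tuple[float, float]:
    """The two substrate caps at which the optimal regime changes.

    Returns ``(V_low, V_high) = (Gamma/(alpha1+alpha3), Gamma/(alpha1+alpha2))``.
    Above ``V_high`` the cap is slack and the system behaves as if substrate
    were unlimited; between the two thresholds the budget-limited vertices
    govern; below ``V_low`` the cell has spare enzyme capacity and (if
    allowed) tops up respiration with reverse fermentation.
    ``V_low < V_high`` is guaranteed by ``alpha3 > alpha2``.
    """
    c = spec.costs
    v_low = c.Gamma / (c.alpha1 + c.alpha3)
    v_high = c.Gamma / (c.alpha1 + c.alpha2) if c.alpha1 + c.alpha2 > 0 else math.inf
    return (v_low, v_high)
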