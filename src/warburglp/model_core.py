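"""Core domain types for the minimal enzyme-constrained model of energy metabolism.

The model lumps central carbon metabolism into three reactions competing for a
shared enzyme budget:

* glycolysis (rate ``v1``): glucose -> pyruvate, yielding ``m1`` ATP per mole
  of glucose;
* fermentation (rate ``v2``): pyruvate -> low-energy product such as lactate
  (no ATP yield); ``v2 < 0`` means the reverse reaction, oxidation of the
  fermentation product back to pyruvate;
* respiration (rate ``v3``): pyruvate -> CO2 + water via the TCA cycle and
  oxidative phosphorylation, yielding ``m3`` ATP per mole of
  glucose-equivalent.

Pyruvate is the only internal metabolite, so at steady state ``v1 = v2 + v3``.
Sustaining one unit of flux through reaction *i* costs ``alpha_i`` units of an
abstract "enzyme load"; the total load is bounded by a budget ``Gamma``.  The
cell's objective is to maximize the ATP production rate
``phi = m1*v1 + m3*v3``.  All fluxes and loads are in arbitrary units; only
their relative magnitudes matter.

This module defines the parameter containers, flux vectors and solution
records shared by the solver, the brute-force oracle and the response-curve
analysis, together with the elementary operations on them (objective,
enzyme loads, feasibility, mass-balance elimination).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import FrozenSet, List, Optional, Tuple

#: Single global relative tolerance used for feasibility checks, tie
#: detection and "is this flux zero" decisions throughout the package.
EPS = 1e-9

#: Sentinel for an absent substrate-uptake cap.  When the cap is unlimited
#: the uptake constraint is omitted entirely; this value never enters any
#: constraint arithmetic.
UNLIMITED = math.inf

#: Regime labels for the qualitative pattern of an optimal flux vector.
REGIME_QUIESCENT = "quiescent"
REGIME_PURE_FERMENTATION = "pure_fermentation"
REGIME_PURE_RESPIRATION = "pure_respiration"
REGIME_RESPIRO_FERMENTATION = "respiro_fermentation"
REGIME_REVERSE_FERMENTATION = "respiration_with_reverse_fermentation"
REGIME_DEGENERATE_TIE = "degenerate_tie"

REGIMES = (
    REGIME_QUIESCENT,
    REGIME_PURE_FERMENTATION,
    REGIME_PURE_RESPIRATION,
    REGIME_RESPIRO_FERMENTATION,
    REGIME_REVERSE_FERMENTATION,
    REGIME_DEGENERATE_TIE,
)


class InvalidFluxError(ValueError):
    """A flux vector violates mass balance beyond tolerance."""


class DegenerateCostError(ValueError):
    """Cost parameters make a closed-form vertex undefined or the LP unbounded."""


class DegenerateYieldError(ValueError):
    """ATP yields are degenerate (m1 + m3 = 0)."""


class InvalidRangeError(ValueError):
    """An empty or negative substrate-cap range was requested."""


class InvalidGridError(ValueError):
    """A phase-map grid violates the cost-parameter invariants."""


class UndefinedFractionError(ZeroDivisionError):
    """The zero-substrate fraction is undefined because the maximum is zero."""


class InternalConsistencyError(RuntimeError):
    """An invariant that should hold by construction was violated."""


@dataclass(frozen=True)
class YieldCoefficients:
    """Stoichiometric ATP yields (mol ATP per mol glucose-equivalent).

    ``m1`` is the glycolytic (substrate-level) yield, ``m3`` the respiratory
    yield.  Fermentation itself yields no ATP in this model: the occasional
    ATP-producing fermentation (e.g. acetate overflow) is outside scope, so
    the corresponding coefficient is identically zero.
    """

    m1: float = 2.0
    m3: float = 30.0

    def __post_init__(self) -> None:
        if self.m1 < 0 or self.m3 < 0:
            raise ValueError(f"ATP yields must be non-negative, got m1={self.m1}, m3={self.m3}")


@dataclass(frozen=True)
class CostParameters:
    """Enzyme loads per unit flux and the total load budget.

    ``alpha1``, ``alpha2``, ``alpha2_rev`` and ``alpha3`` are the loads of
    glycolysis, forward fermentation, reverse fermentation and respiration;
    ``Gamma`` is the shared budget.  Respiration is strictly the most costly
    pathway (longer pathway, membrane-bound machinery), hence
    ``alpha3 > alpha1``, ``alpha3 > alpha2`` and ``alpha3 > alpha2_rev``.
    """

    alpha1: float = 1.0
    alpha2: float = 1.0
    alpha2_rev: float = 1.0
    alpha3: float = 10.0
    Gamma: float = 200.0

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "alpha2_rev", "alpha3", "Gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if not math.isfinite(self.Gamma):
            raise ValueError(f"Gamma must be finite, got {self.Gamma}")
        if not (self.alpha3 > self.alpha1):
            raise ValueError(f"respiration must cost more than glycolysis (alpha3={self.alpha3} <= alpha1={self.alpha1})")
        if not (self.alpha3 > self.alpha2):
            raise ValueError(f"respiration must cost more than fermentation (alpha3={self.alpha3} <= alpha2={self.alpha2})")
        if not (self.alpha3 > self.alpha2_rev):
            raise ValueError(f"respiration must cost more than reverse fermentation (alpha3={self.alpha3} <= alpha2_rev={self.alpha2_rev})")


@dataclass(frozen=True)
class SubstrateLimit:
    """Cap ``V1`` on the glucose uptake rate; ``UNLIMITED`` removes the cap."""

    V1: float = UNLIMITED

    def __post_init__(self) -> None:
        if self.V1 < 0:
            raise ValueError(f"V1 must be non-negative or UNLIMITED, got {self.V1}")

    @property
    def is_unlimited(self) -> bool:
        return math.isinf(self.V1)


@dataclass(frozen=True)
class ModelSpec:
    """Complete parameterization of one LP scenario.

    ``fermentation_reversible`` toggles whether ``v2`` may go negative
    (lactate oxidation feeding respiration).  When False the additional sign
    constraint ``v2 >= 0`` is enforced and the reverse-fermentation vertices
    are excluded.
    """

    yields: YieldCoefficients = field(default_factory=YieldCoefficients)
    costs: CostParameters = field(default_factory=CostParameters)
    limit: SubstrateLimit = field(default_factory=SubstrateLimit)
    fermentation_reversible: bool = True

    @classmethod
    def from_values(
        cls,
        m1: float = 2.0,
        m3: float = 30.0,
        alpha1: float = 1.0,
        alpha2: float = 1.0,
        alpha2_rev: float = 1.0,
        alpha3: float = 10.0,
        Gamma: float = 200.0,
        V1: float = UNLIMITED,
        fermentation_reversible: bool = True,
    ) -> "ModelSpec":
        """Build a spec from scalar parameters (the S1-table column set)."""
        return cls(
            yields=YieldCoefficients(m1=m1, m3=m3),
            costs=CostParameters(
                alpha1=alpha1, alpha2=alpha2, alpha2_rev=alpha2_rev,
                alpha3=alpha3, Gamma=Gamma,
            ),
            limit=SubstrateLimit(V1=V1),
            fermentation_reversible=fermentation_reversible,
        )

    def with_limit(self, V1: float) -> "ModelSpec":
        """Same scenario with a different substrate cap."""
        return replace(self, limit=SubstrateLimit(V1=V1))

    def with_reversibility(self, fermentation_reversible: bool) -> "ModelSpec":
        """Same scenario with reversibility toggled."""
        return replace(self, fermentation_reversible=fermentation_reversible)


@dataclass(frozen=True)
class FluxVector:
    """Steady-state rates (v1, v2, v3) in mol glucose-equivalent per time.

    Mass balance ``v1 = v2 + v3`` is checked on construction to the tolerance
    ``EPS * max(1, |v1|)``.  Sign constraints are deliberately *not* enforced
    here: candidate vertices with negative components must be representable so
    that feasibility filtering can reject them.
    """

    v1: float
    v2: float
    v3: float

    def __post_init__(self) -> None:
        _check_mass_balance(self.v1, self.v2, self.v3)

    @classmethod
    def from_reduced(cls, v2: float, v3: float) -> "FluxVector":
        """Lift a reduced point (v2, v3) back to a full flux vector."""
        return cls(v1=v2 + v3, v2=v2, v3=v3)

    def as_tuple(self) -> Tuple[float, float, float]:
        return (self.v1, self.v2, self.v3)


def _check_mass_balance(v1: float, v2: float, v3: float) -> None:
    if abs(v1 - v2 - v3) > EPS * max(1.0, abs(v1)):
        raise InvalidFluxError(
            f"mass balance violated: v1={v1} != v2+v3={v2 + v3}"
        )


@dataclass(frozen=True)
class VertexSolution:
    """One labeled critical point of the LP.

    ``binding`` names the constraints satisfied with equality at the stored
    flux, using the identifiers ``c`` (forward cost), ``d`` (reverse cost),
    ``e`` (v1 >= 0), ``f`` (v3 >= 0), ``g`` (uptake cap) and ``v2=0``.
    ``yield_ratio`` is phi/v1, or None (undefined) when v1 = 0 — the model
    never assigns a glucose yield to a flux that consumes no glucose.
    """

    label: str
    flux: FluxVector
    binding: FrozenSet[str]
    feasible: bool
    atp: float
    yield_ratio: Optional[float]


@dataclass(frozen=True)
class OptimalSolution:
    """The LP optimum: all tied optimal vertices, the value, and the regime."""

    optima: List[VertexSolution]
    phi_star: float
    regime: str

    @property
    def flux(self) -> FluxVector:
        """Flux of the first optimal vertex (unique unless regime is a tie)."""
        return self.optima[0].flux


def atp_rate(flux: FluxVector, yields: YieldCoefficients) -> float:
    """ATP production rate ``phi = m1*v1 + m3*v3``.

    Under mass balance this equals the reduced two-variable form
    ``m1*v2 + (m1 + m3)*v3``.
    """
    return yields.m1 * flux.v1 + yields.m3 * flux.v3


def atp_rate_reduced(v2: float, v3: float, yields: YieldCoefficients) -> float:
    """Reduced objective ``m1*v2 + (m1 + m3)*v3`` on the (v2, v3) plane."""
    return yields.m1 * v2 + (yields.m1 + yields.m3) * v3


def enzyme_loads(flux: FluxVector, costs: CostParameters) -> Tuple[float, float]:
    """Forward and reverse enzyme loads of a flux vector.

    Returns ``(alpha1*v1 + alpha2*v2 + alpha3*v3,
    alpha1*v1 - alpha2_rev*v2 + alpha3*v3)``.  The minus sign in the reverse
    load turns a negative ``v2`` into a positive cost.  Both loads coincide
    whenever ``v2 = 0``; the forward load is the tighter of the two for
    ``v2 > 0`` and the reverse load for ``v2 < 0``.
    """
    forward = costs.alpha1 * flux.v1 + costs.alpha2 * flux.v2 + costs.alpha3 * flux.v3
    reverse = costs.alpha1 * flux.v1 - costs.alpha2_rev * flux.v2 + costs.alpha3 * flux.v3
    return (forward, reverse)


def is_feasible(flux: FluxVector, spec: ModelSpec, tol: float = EPS) -> bool:
    """Check every constraint of the scenario at relative tolerance ``tol``.

    Both cost loads must stay within the budget, v1 and v3 must be
    non-negative, v1 must respect the uptake cap when one is set, and v2 must
    be non-negative when fermentation is irreversible.
    """
    if tol <= 0:
        raise ValueError(f"tol must be positive, got {tol}")
    fwd, rev = enzyme_loads(flux, spec.costs)
    gamma = spec.costs.Gamma
    slack = tol * max(1.0, gamma)
    if fwd > gamma + slack or rev > gamma + slack:
        return False
    v_scale = tol * max(1.0, abs(flux.v1))
    if flux.v1 < -v_scale or flux.v3 < -v_scale:
        return False
    if not spec.limit.is_unlimited:
        cap = spec.limit.V1
        if flux.v1 > cap + tol * max(1.0, cap):
            return False
    if not spec.fermentation_reversible and flux.v2 < -v_scale:
        return False
    return True


def eliminate_v1(flux: FluxVector) -> Tuple[float, float]:
    """Project a mass-balanced flux onto the reduced (v2, v3) plane.

    Raises :class:`InvalidFluxError` if mass balance does not hold (it is
    re-checked here so that tuples built outside :class:`FluxVector` are
    caught too).
    """
    _check_mass_balance(flux.v1, flux.v2, flux.v3)
    return (flux.v2, flux.v3)


def restore_v1(v2: float, v3: float) -> FluxVector:
    """Inverse of :func:`eliminate_v1`: set ``v1 = v2 + v3``."""
    return FluxVector.from_reduced(v2, v3)
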