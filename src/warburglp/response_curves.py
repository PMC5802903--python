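"""Parametric analysis in the substrate cap: response curves and phase maps.

The optimal ATP rate as a function of the uptake cap, ``phi*(V1)``, is the
value function of a parametric LP whose right-hand side moves linearly, so it
is piecewise linear, concave and non-decreasing.  Its kinks sit at the two
regime thresholds ``Gamma/(alpha1+alpha3)`` and ``Gamma/(alpha1+alpha2)``;
beyond the larger one the cap is slack and the curve is flat at the
unlimited-substrate optimum.  Breakpoints are therefore computed analytically
— the solver is evaluated at the candidate thresholds and at interval
midpoints only to verify linearity, never to hunt for kinks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .model_core import (
    EPS,
    REGIME_DEGENERATE_TIE,
    InternalConsistencyError,
    InvalidGridError,
    InvalidRangeError,
    ModelSpec,
    UndefinedFractionError,
)
from .vertex_solver import solve, substrate_thresholds

__all__ = [
    "Segment",
    "ResponseCurve",
    "atp_vs_substrate",
    "zero_substrate_fraction",
    "reversibility_gain",
    "regime_phase_map",
    "plot_response_curve",
    "plot_phase_map",
]


@dataclass(frozen=True)
class Segment:
    """One linear piece of the value function: slope and regime on (v_lo, v_hi)."""

    v_lo: float
    v_hi: float
    slope: float
    regime: str


@dataclass(frozen=True)
class ResponseCurve:
    """Piecewise-linear optimal ATP rate phi*(V1) over a cap range.

    ``breakpoints`` are (V1, phi*) pairs at segment ends, including the left
    endpoint of the requested range and — when the range reaches it — the
    saturation point beyond which the curve is flat.  The curve is concave and
    non-decreasing; the final segment of a saturated curve has slope zero.
    """

    breakpoints: List[Tuple[float, float]]
    segments: List[Segment]
    spec: ModelSpec

    def phi_at(self, V1: float) -> float:
        """Evaluate the curve by linear interpolation (flat extrapolation)."""
        xs = [b[0] for b in self.breakpoints]
        ys = [b[1] for b in self.breakpoints]
        return float(np.interp(V1, xs, ys))

    def to_records(self) -> List[dict]:
        """Breakpoint rows for serialization (V1, phi_star, regime, slope)."""
        rows = []
        for i, (v, phi) in enumerate(self.breakpoints):
            seg = self.segments[min(i, len(self.segments) - 1)] if self.segments else None
            rows.append(
                {
                    "V1": v,
                    "phi_star": phi,
                    "regime": seg.regime if seg else "quiescent",
                    "segment_slope": seg.slope if seg else 0.0,
                }
            )
        return rows


def atp_vs_substrate(
    spec: ModelSpec,
    v1_range: Optional[Tuple[float, float]] = None,
    tol: float = EPS,
) -> ResponseCurve:
    """Compute phi*(V1) over ``v1_range`` (default: zero to past saturation).

    Any cap carried by ``spec`` is ignored; the cap is the swept parameter.
    Candidate breakpoints are the analytic thresholds; the solver is run at
    each and at interval midpoints, the midpoint solve certifying linearity of
    the piece.  Adjacent collinear pieces are merged, so a threshold that is
    not an actual kink (e.g. the upper threshold when respiration is cheap)
    does not appear as a breakpoint.
    """
    v_low, v_high = substrate_thresholds(spec)
    if v1_range is None:
        hi_default = v_high if math.isfinite(v_high) else v_low
        v1_range = (0.0, 1.2 * hi_default if hi_default > 0 else 1.0)
    lo, hi = v1_range
    if lo < 0 or hi < 0 or hi <= lo:
        raise InvalidRangeError(f"invalid substrate-cap range ({lo}, {hi})")

    knots = sorted({lo, hi} | {v for v in (v_low, v_high) if lo < v < hi and math.isfinite(v)})

    def phi(v: float) -> float:
        return solve(spec.with_limit(v), tol).phi_star

    def regime_at(v: float) -> str:
        return solve(spec.with_limit(v), tol).regime

    values = [phi(v) for v in knots]
    segments: List[Segment] = []
    for (va, pa), (vb, pb) in zip(zip(knots, values), zip(knots[1:], values[1:])):
        slope = (pb - pa) / (vb - va)
        mid = 0.5 * (va + vb)
        expected = pa + slope * (mid - va)
        if abs(phi(mid) - expected) > 1e-7 * max(1.0, abs(expected)):
            raise InternalConsistencyError(
                f"value function not linear on ({va}, {vb}); "
                "breakpoint analysis missed a kink"
            )
        segments.append(Segment(va, vb, slope, regime_at(mid)))

    # merge collinear neighbours so only true kinks remain
    merged: List[Segment] = []
    for seg in segments:
        if merged and abs(merged[-1].slope - seg.slope) <= 1e-9 * max(1.0, abs(seg.slope)):
            prev = merged.pop()
            merged.append(Segment(prev.v_lo, seg.v_hi, prev.slope, prev.regime))
        else:
            merged.append(seg)

    breakpoints = [(merged[0].v_lo, phi(merged[0].v_lo))] if merged else [(lo, phi(lo))]
    for seg in merged:
        breakpoints.append((seg.v_hi, phi(seg.v_hi)))
    return ResponseCurve(breakpoints=breakpoints, segments=merged, spec=spec)


def zero_substrate_fraction(spec: ModelSpec, tol: float = EPS) -> float:
    """Fraction of the maximal ATP rate attainable with no glucose at all.

    With reverse fermentation the cell can run respiration entirely on the
    fermentation product, so phi*(V1=0) is positive: the ratio
    ``phi*(0) / phi*(unlimited)`` equals ``m3/(m1+m3)`` when respiration is
    cheap and ``[m3/(alpha2_rev+alpha3)] * [(alpha1+alpha2)/m1]`` when it is
    expensive.
    """
    if not spec.fermentation_reversible:
        raise ValueError("zero-substrate fraction requires reversible fermentation")
    phi_max = solve(spec.with_limit(math.inf), tol).phi_star
    if phi_max <= 0:
        raise UndefinedFractionError("maximal ATP rate is zero; fraction undefined")
    phi_zero = solve(spec.with_limit(0.0), tol).phi_star
    return phi_zero / phi_max


def reversibility_gain(
    spec: ModelSpec, V1: float, tol: float = EPS
) -> Tuple[float, float, float]:
    """ATP rates with and without reverse fermentation at cap ``V1``.

    Returns ``(phi_reversible, phi_irreversible, gain)``.  The gain is always
    non-negative (forbidding reverse flux only adds a constraint) and is zero
    whenever substrate is abundant enough that reverse fermentation is never
    optimal.
    """
    capped = spec.with_limit(V1)
    phi_rev = solve(capped.with_reversibility(True), tol).phi_star
    phi_irr = solve(capped.with_reversibility(False), tol).phi_star
    return (phi_rev, phi_irr, phi_rev - phi_irr)


def regime_phase_map(
    spec: ModelSpec,
    alpha3_grid: Sequence[float],
    v1_grid: Sequence[float],
    tol: float = EPS,
):
    """Optimal-regime label on a grid of respiration costs and uptake caps.

    Entry (i, j) is the regime of the optimum at ``alpha3_grid[i]``,
    ``v1_grid[j]`` with the other parameters taken from ``spec``.  Grid points
    whose optimum is tied between regimes (within tolerance) are labeled
    ``degenerate_tie`` rather than arbitrarily assigned; the label boundaries
    trace the yield/cost crossover and the substrate thresholds.

    Returns a pandas DataFrame indexed by alpha3 with columns V1.
    """
    import pandas as pd

    c = spec.costs
    floor = max(c.alpha1, c.alpha2, c.alpha2_rev)
    for a3 in alpha3_grid:
        if not (a3 > floor):
            raise InvalidGridError(
                f"alpha3 grid value {a3} violates alpha3 > max(alpha1, alpha2, alpha2_rev) = {floor}"
            )
    for v1 in v1_grid:
        if v1 < 0:
            raise InvalidGridError(f"V1 grid value {v1} is negative")

    from dataclasses import replace
    from .model_core import CostParameters, SubstrateLimit

    labels = np.empty((len(alpha3_grid), len(v1_grid)), dtype=object)
    for i, a3 in enumerate(alpha3_grid):
        costs = CostParameters(
            alpha1=c.alpha1, alpha2=c.alpha2, alpha2_rev=c.alpha2_rev,
            alpha3=a3, Gamma=c.Gamma,
        )
        for j, v1 in enumerate(v1_grid):
            cell = replace(spec, costs=costs, limit=SubstrateLimit(V1=v1))
            labels[i, j] = solve(cell, tol).regime
    return pd.DataFrame(labels, index=list(alpha3_grid), columns=list(v1_grid))


def plot_response_curve(curve: ResponseCurve, ax=None):
    """Line plot of phi*(V1); contains no information beyond the breakpoints."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    xs = [b[0] for b in curve.breakpoints]
    ys = [b[1] for b in curve.breakpoints]
    ax.plot(xs, ys, marker="o")
    ax.set_xlabel("substrate uptake cap $V_1$")
    ax.set_ylabel(r"optimal ATP rate $\varphi^*$")
    return ax


def plot_phase_map(phase_df, ax=None):
    """Heatmap of regime labels over the (alpha3, V1) grid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    cats = sorted({str(v) for v in phase_df.values.ravel()})
    codes = np.vectorize({c: k for k, c in enumerate(cats)}.get)(
        phase_df.values.astype(str)
    ).astype(float)
    im = ax.imshow(codes, aspect="auto", origin="lower")
    ax.set_xticks(range(len(phase_df.columns)), [f"{v:g}" for v in phase_df.columns])
    ax.set_yticks(range(len(phase_df.index)), [f"{v:g}" for v in phase_df.index])
    ax.set_xlabel("substrate uptake cap $V_1$")
    ax.set_ylabel(r"respiration cost $\alpha_3$")
    cbar = ax.figure.colorbar(im, ax=ax, ticks=range(len(cats)))
    cbar.ax.set_yticklabels(cats)
    return ax
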