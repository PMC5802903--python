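# Methods

## Model and assumptions

The package implements a deliberately minimal constraint-based model of
energy metabolism.  Three lumped reactions — glycolysis (v₁), fermentation
(v₂, reversible) and respiration (v₃) — share one internal metabolite
(pyruvate) and one resource: an abstract enzyme-load budget Γ.  The cell's
objective is the ATP production rate φ = m₁v₁ + m₃v₃, maximized subject to
steady-state mass balance (v₁ = v₂ + v₃), the two cost constraints (forward
and reverse fermentation may carry different enzyme costs α₂ and α̂₂; only
one of the two constraints can bind for any given sign of v₂), the
irreversibility of glycolysis and respiration, and optionally a cap V₁ on
glucose uptake.

Assumptions worth keeping in mind:

* **Linearity.** Rates are linear in enzyme allocation; saturation kinetics
  and nonlinear rate laws are out of scope.
* **Single currency.** Only ATP is balanced.  NADH/redox bookkeeping, ATP
  yield of fermentation itself (set to zero; acetate-style overflow that
  yields ATP is excluded), and biomass objectives are not modeled.
* **Steady state.** No dynamics; the diauxic shift is the temporal analogue
  of the regime transitions this model captures as comparative statics.
* **Abstract units.** Fluxes, costs and the budget carry arbitrary units;
  only ratios matter, and the solution is homogeneous of degree one in
  (Γ, V₁) — a property the suite tests.

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| m₁ | ATP per glucose via glycolysis | 2 | textbook substrate-level yield |
| m₃ | ATP per glucose-equivalent respired | 30 | textbook oxidative yield |
| α₁, α₂, α̂₂ | enzyme load per flux unit of glycolysis / forward / reverse fermentation | 1 | cheap pathways, equal by convention |
| α₃ | enzyme load per respiration flux unit | 10 or 50 | the two illustrative cost regimes; must exceed α₁, α₂, α̂₂ (respiration is the long, membrane-bound pathway) |
| Γ | total enzyme budget | 200 | sets the scale of all fluxes |
| V₁ | glucose-uptake cap | unlimited | the swept parameter of the response curves |

The built-in scenarios `fig2`–`fig8` enumerate the informative corners of
this parameter space: both cost regimes crossed with unlimited, moderate
(25), tight (3.92) and very tight (2) uptake caps.

## Solution method

With v₁ eliminated the problem is a two-variable LP, so the optimum lies at a
vertex of the feasible polygon.  `vertex_solver` evaluates the closed-form
critical points directly — O (origin), A (forward cost bound, no
respiration), B (forward cost bound, no fermentation), C (reverse cost bound,
no glucose uptake) and, under a cap, A1–A4 on the cap line — filters them by
feasibility, and returns every vertex within tolerance of the best value.
A capped mix vertex (A2/A4) whose fermentation flux vanishes within tolerance
coincides with B/A3 and is reported once, under the pure-respiration label,
to avoid duplicate optima.  Ties are reported as all tied vertices with the
regime `degenerate_tie`; in particular, when the relative yield m₁/(m₁+m₃)
equals the relative cost (α₁+α₂)/(α₁+α₃) (with the shared defaults this
happens at α₃ = 31), vertices A and B tie exactly.

`lp_oracle` is the package's independent verification route: it rebuilds the
LP from raw constraint coefficients, intersects every pair of constraint
boundary lines by a 2×2 determinant solve (pairs with |det| ≤ 10⁻¹² × scale
are treated as parallel and skipped), keeps feasible intersections, and takes
the maximum objective.  It shares no formulas with the closed-form solver, so
their agreement — required to 10⁻⁹ relative over 1000 randomized scenarios in
the suite, and re-audited by `scripts/acceptance.py` on every run — is a
genuine cross-check.  The test suite adds scipy's `linprog` as a third route
on the built-in scenarios.

`response_curves` exploits the structure of the parametric LP: φ*(V₁) is
piecewise linear, concave and non-decreasing, with kinks only at the two
thresholds Γ/(α₁+α₃) and Γ/(α₁+α₂).  Breakpoints are computed analytically by
solving at the thresholds; midpoint solves certify linearity of each piece
and collinear pieces are merged, so a threshold that is not an actual kink
(the upper one, when respiration is cheap) does not surface as a breakpoint.

## Numerical choices

* One global relative tolerance ε = 10⁻⁹ governs feasibility slack, tie
  detection and zero tests; zero tests on fluxes scale it by max(1, |v₁|).
  The published scenario values are printed at 1–2 decimals, so ε is far
  below the comparison scale yet far above double-precision noise.
* An absent uptake cap is a distinguished sentinel; the cap constraint is
  omitted rather than approximated by a large number, avoiding conditioning
  artifacts.
* The yield ratio φ/v₁ is *undefined* (None) at v₁ = 0, not infinite: no
  glucose yield is assigned to a flux that consumes no glucose.
* Degenerate inputs fail loudly: α₃ = α₂ under a cap (the A2 form divides by
  α₃ − α₂) and α₁ + α₂ = 0 with unlimited substrate and m₁ > 0 (pure
  fermentation is free, the LP unbounded) raise a degenerate-cost error.
  Γ = 0 is accepted and collapses every vertex onto the origin.

## Randomized validation scenarios

The cross-validation generator (`random_specs`) draws cheap-pathway costs
uniformly on [0, 5] (flooring α₁ + α₂ at 10⁻³ to keep the LP bounded), the
respiration cost uniformly between the dearest cheap pathway + 0.1 and 100,
the budget on [1, 1000], the cap absent half the time and otherwise uniform
up to twice the value at which it stops binding, and reversibility as a fair
coin; the suite uses seed 42 and 1000 draws.  These scenarios emulate the
admissible parameter space of the model, not any measured organism: passing
them demonstrates internal correctness of the solver over that space, not
predictive accuracy for real cells — the model's biological claims stand or
fall with its structural assumptions above, which no amount of solver
validation tests.

## Design choices and limitations

* Scenario input is a plain CSV (case- and order-insensitive headers) rather
  than SBML: the network is three lumped reactions, and a genome-scale
  exchange format would add machinery without information.
* Vertex A1 (fermentation pinned at the cap) can only be optimal in parameter
  corners of little biological interest, but is enumerated for completeness.
* Phase-map cells whose optimum is tied between regimes are labeled
  `degenerate_tie` rather than arbitrarily assigned, so regime boundaries are
  reported honestly at grid points that land on them.
* The package does not implement a general simplex method, LPs in more than
  two free variables, kinetic rate laws, or flux-mode enumeration.
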