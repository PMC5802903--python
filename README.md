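# warburglp

A minimal enzyme-constrained linear-programming model of cellular energy
metabolism, for systems biologists studying overflow metabolism and the
Warburg effect — the puzzling use of low-yield fermentation alongside
high-yield respiration even when oxygen is plentiful.

## The model

Central carbon metabolism is lumped into three reactions competing for a
shared enzyme budget: glycolysis (rate v₁, yielding m₁ = 2 ATP per glucose),
fermentation of pyruvate to lactate (rate v₂, no ATP; v₂ < 0 means lactate is
oxidized *back* to pyruvate), and respiration (rate v₃, yielding m₃ = 30
ATP).  Pyruvate is the only internal metabolite, so v₁ = v₂ + v₃ at steady
state.  Sustaining one flux unit of reaction *i* costs αᵢ units of "enzyme
load" (α̂₂ for reverse fermentation), with total load bounded by a budget Γ.
The cell maximizes its ATP production rate:

```
max  φ = m₁v₁ + m₃v₃
s.t. v₁ = v₂ + v₃                      (mass balance)
     α₁v₁ + α₂v₂ + α₃v₃ ≤ Γ           (forward enzyme cost)
     α₁v₁ − α̂₂v₂ + α₃v₃ ≤ Γ           (reverse enzyme cost)
     v₁ ≥ 0,  v₃ ≥ 0,  v₁ ≤ V₁        (irreversibility; optional uptake cap)
```

After eliminating v₁ this is a two-variable LP whose optimum sits at one of
at most eight vertices, all known in closed form (O, A, B, C with unlimited
substrate; A1–A4 on the uptake cap).  Depending on the relative yield
m₁/(m₁+m₃) versus the relative cost (α₁+α₂)/(α₁+α₃) and on the cap V₁, the
optimum is pure respiration, pure fermentation, a respiro-fermentation mix,
or — when glucose is scarce — respiration fed by reverse fermentation.  The
package solves the LP via the closed-form vertices, cross-validates against a
brute-force constraint-intersection oracle (and scipy's LP solver in the
tests), classifies the regime, and traces the piecewise-linear, concave
response curve φ*(V₁).

## Worked example

Seven built-in scenarios (`fig2`…`fig8`) share m₁ = 2, m₃ = 30,
α₁ = α₂ = α̂₂ = 1, Γ = 200 and vary the respiration cost α₃ ∈ {10, 50} and
the uptake cap V₁:

```
$ warburglp --quiet solve --all-fixtures
fig2: optimum at B, regime pure_respiration, (v1, v2, v3) = (18.18, 0.00, 18.18), ATP = 581.8, yield = 32.0
fig3: optimum at A, regime pure_fermentation, (v1, v2, v3) = (100.00, 100.00, 0.00), ATP = 200.0, yield = 2.0
fig4: optimum at B, regime pure_respiration, (v1, v2, v3) = (18.18, 0.00, 18.18), ATP = 581.8, yield = 32.0
fig5: optimum at A4, regime respiration_with_reverse_fermentation, (v1, v2, v3) = (3.92, -14.26, 18.18), ATP = 553.3, yield = 141.1
fig6: optimum at A2, regime respiro_fermentation, (v1, v2, v3) = (25.00, 21.94, 3.06), ATP = 141.8, yield = 5.7
fig7: optimum at A4, regime respiration_with_reverse_fermentation, (v1, v2, v3) = (3.92, -0.00, 3.92), ATP = 125.5, yield = 32.0
fig8: optimum at A4, regime respiration_with_reverse_fermentation, (v1, v2, v3) = (2.00, -1.92, 3.92), ATP = 121.6, yield = 60.8
```

Reading this: with cheap respiration (`fig2`, `fig4`) the cell respires
purely, producing 581.8 ATP per time at the full glucose yield of 32 ATP per
glucose.  With expensive respiration and abundant glucose (`fig3`) it ferments
purely — the Warburg regime: a fast but wasteful 2 ATP per glucose.  Under a
moderate cap (`fig6`) it mixes (v₂ = 21.94, v₃ = 3.06).  Under severe glucose
scarcity (`fig5`, `fig8`) v₂ turns negative: the cell *imports and oxidizes
lactate* to keep respiration running at full enzyme capacity, lifting the
apparent yield per glucose far above 32.

The response of the optimum to the uptake cap, with its two turning points:

```
$ warburglp --quiet curve --alpha3 50
V1 = 0.00: ATP = 117.6
V1 = 3.92: ATP = 125.5
V1 = 100.00: ATP = 200.0
V1 = 120.00: ATP = 200.0
```

Even with *no* glucose at all the cell sustains 117.6 ATP per time — 58.8 %
of the unlimited-glucose maximum — by respiring lactate.  The same holds in
the library:

```python
from warburglp import ModelSpec, solve, atp_vs_substrate

spec = ModelSpec.from_values(alpha3=50.0, V1=25.0)
sol = solve(spec)
sol.phi_star          # 141.83673469387753
sol.regime            # 'respiro_fermentation'
sol.optima[0].flux    # FluxVector(v1=25.0, v2=21.938..., v3=3.061...)
```

Other subcommands: `curve` (φ* vs V₁ breakpoints), `phase` (regime map over
an (α₃, V₁) grid), `thresholds` (the regime-boundary caps Γ/(α₁+α₃) and
Γ/(α₁+α₂)), and `check` (randomized audit of the closed-form solver against
the brute-force oracle).  Scenario tables can also be read from CSV; see
`warburglp solve --help`.

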