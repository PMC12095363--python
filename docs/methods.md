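# Methods

## Model structure

The colony is modelled as a "super-organism" with a dynamic energy budget:
all energy accounting happens at the colony level, not per bee.  Four state
variables evolve: nectar reserves `N` (ml) — the colony's energy store;
pollen reserves `P` (g) — its protein store, consumed by brood development;
structural energy `V` (bee-equivalents) — a proxy for the living workforce,
with `αV` foragers and `βV` brood; and the colony count `R`, which changes
only at the annual reproductive impulse.  Landscape state is a per-node pair
of stocks `Fᵢ^N` (ml), `Fᵢ^P` (g) on a regular square lattice with the nest
at (or nearest) the geometric centre.

A year alternates a continuous 150-day growth phase (forward Euler,
`dt = 0.1` d) with one discrete jump standing in for reproduction,
hibernation, and colony establishment.  Within the growth phase `R` is
frozen; at the jump the reserves are zeroed, queens are produced by a
clamped arctangent of the per-colony size `V/R` relative to the threshold
`ε_R`, overwinter mortality removes a fraction `δ_R`, and the new season
starts with `V = ε_V R`.

## Fluxes

- **Ingestion** per node and guild: `uᵢ = aᵢFᵢ/(Fᵢ + aᵢ)` with demand
  `aᵢ = C_X n ρᵢ`.  This smooth saturating form has the two required limits —
  `uᵢ → aᵢ` when stocks are ample, `uᵢ → Fᵢ` per day when stocks are scarce —
  with an implicit unit rate constant of 1/day in the scarce regime.  A
  hard-minimum variant `uᵢ = min(Fᵢ, aᵢ)` is selectable
  (`ingestion_form: hardmin`); it changes per-node intake by at most a factor
  of two and none of the qualitative behaviour.
- **Faeces/assimilation**: fixed fractions (defaults: no faeces, perfect
  assimilation).
- **Maintenance**: linear in foragers and brood
  (`C_M1·αV + C_M2·βV` per resource).
- **Heating**: `C_H·n_max`, where `n_max` is the running seasonal peak of
  `αV` — a nest built large stays expensive even after the workforce
  shrinks.
- **Travel**: `C_C Σᵢ (n^N ρᵢ^N + n^P ρᵢ^P) dᵢ`, paid from nectar.
- **Growth**: `κ · P/(P+√V ε_P) · N/(N+√V ε_N)`, capped at `κ`; scaled by
  `R/E_G` in `dV/dt` (egg-laying by `R` queens).  When `V = 0` the growth
  flux is forced to zero so that extinction is absorbing within a season —
  the raw formula would otherwise let a dead colony resurrect from leftover
  reserves.

## Forager distribution

The guild split `n^N/n^P = λ(P+ε_P)/(N+ε_N)` sends more foragers after the
scarcer reserve, reduces to a λ-controlled bias when reserves are
comparable, and falls back to the ratio `λε_P/ε_N` when both are empty.  The
split is conserved exactly: `n^N + n^P = αV` bit-for-bit (an ulp-level
nudge absorbs the rounding of the share computation).

Each guild's spatial density is Boltzmann, `ρᵢ ∝ exp(gainᵢ/T)`, computed
with a max-gain shift for overflow safety.  Gains use the guild's *total*
count in the crowding denominator (mean-field competition), matching the
partition-function form; nectar gains subtract a travel cost `C_C dᵢ` in
energy units (break-even at `C_X^N/C_C = 3` km with defaults), pollen gains
subtract `C_X^P dᵢ/d_max` so distance alone never excludes a node.  `d_max`
defaults to the grid's largest nest-to-node distance.  An optional hard
nectar-range cutoff exists but is off by default, the ~3 km range being
emergent.

Two consequences worth knowing: (i) at the default `T = 0.1` the weights are
close to winner-take-all, so when stocks are depleted nearly all foragers
sit on the single marginally-best node and intake is capped near one node's
production — sparse-background landscapes therefore starve colonies that a
gain-equalising (ideal-free) allocation would sustain; (ii) because
crowding is mean-field, spreading emerges only through stock depletion
feedback over time, not within a time step.

## Parameters

Defaults (units per day unless noted): collection `C_X^N = 1.2` ml/bee,
`C_X^P = 0.8` g/bee; faeces fractions 0; assimilation 1; maintenance
`C_M1^N = 0.025` ml/bee, `C_M1^P = 0.04` g/bee, `C_M2^N = 0`,
`C_M2^P = 0.01` g/brood; heating `C_H = 0.03` ml/bee; travel `C_C = 0.4`
ml/(bee·km); evaporation `θ = 0.01`/d; growth cap `κ = 1` g/d; growth
half-saturations `ε_N = 0.1` ml, `ε_P = 0.5` g; death `δ₀ = 0.05`/d,
starvation boost `δ_N = 1`/d; pollen per structure `E_G = 1/8.5` g/bee;
guild bias `λ = 5`; `α = 1`, `β = 4`; temperature `T = 0.1`; stock
saturation `γ = 0.001` (1/ml, 1/g); reproduction `C_R = 5` queens/colony,
`ψ = 0.2`, `ε_R = 100` bees, overwinter loss `δ_R = 0.12`; season `L = 150`
d, `dt = 0.1` d.

`ε_V` — structure per overwintered queen — defaults to **1 bee-equivalent**.
This is a deliberate choice: the founding queen must be able to out-collect
the starvation death term `δ₀ + δ_N e^(−N/ε_N) ≈ 1.05`/d while the first
reserves accumulate, and a queen worth much less than one bee-equivalent of
structure (and hence of collection capacity `αε_V C_X`) mathematically
cannot — `V` then decays by 150 orders of magnitude over a season in every
scenario, and multi-year runs die in year 2 regardless of year-1 seeding.
One bee-equivalent is also the natural biological reading: the queen forages
for herself until the first workers emerge.

## Scenarios and season-start stocks

Named scenarios cover: a resource-rich baseline and its nectar- or
pollen-poor variants; sudden total shortages of one resource at day 25
(production zeroed *and* standing stocks removed); a mass-flowering crop
blooming days 65–85 over three background intensities; patch-distance
sweeps on a 10×10, 0.67 km grid; ten-year runs at three uniform production
levels; and wildflower-enhancement experiments.

Season-start stocks default to zero (flowers regrow from production).  The
enhancement scenarios instead declare the unexploited equilibrium
`√(F₀/γ)` as their initial stock: their backgrounds are so sparse
(0.1/day/node) that a founding queen starting from a bare landscape starves
before any stock accrues, which would make every enhancement comparison a
comparison of extinctions.  Seeding spring standing crop is the scenario's
declaration, not a global default.

## Enhancement metrics

*Relative composition* of a producer is `100·(F_N − F_P)/(F_N + F_P)`.
Crop and wildflower patch rates are generated from a target composition
`RC` and relative quantity `RWF` on **reference-normalised shares**: the
crop gets shares `((1+r)/2, (1−r)/2)` of the reference rates (500 ml/day,
100 g/day in the single-season experiments; 5000/1000 in the multi-year
ones), the wildflowers the `RWF`-scaled mirror.  On shares, the crop's
contrast is exactly `RC` and the wildflowers' pollen-minus-nectar contrast
is exactly `RC` too (the mirror identity), which a direct raw-rate scaling
cannot satisfy when the nectar and pollen references differ.

*Pollination services* are measured as bee-days of forager presence on the
crop nodes during the crop bloom — the time integral (trapezoidal, over the
recorded samples) of `Σ_{i∈crop} (n^N ρᵢ^N + n^P ρᵢ^P)`.  Any monotone
visitation functional would preserve orderings; bee-days is the simplest.
The *relative change in services* against a wildflower-free baseline is
reported as a percentage, with an extinct baseline flagged as undefined
(`None`) rather than a number.

## Numerical choices

Forward Euler with post-step clamping of `N`, `P`, `V` and of the per-node
stocks at zero; `n_max` updated after each step; events (stock removals)
applied at the step boundary at or after their scheduled time; season-end
time assigned exactly (`t₀ + L`) to avoid accumulated float drift.  Halving
`dt` moves the 150-day endpoint of `V` in the baseline scenario by ~10⁻⁵
relative — far inside the 2% band the tests require.  Ties in the nest
placement on even grids go to the lowest node index.  All computation is
float64 and deterministic; reruns are bit-identical.

Problem sizes used by the test suite and the acceptance script: 5×5 and
10×10 grids, single 150-day seasons for the worked experiments, and
10-year runs for the demographic ones — the scales at which the scenario
definitions themselves are stated.

## Known limitations

- **Reserve accumulation.** At the default rates a forager collects ~20×
  its share of colony consumption, so in any resource-rich scenario the
  reserve pools grow by hundreds of ml/g per season rather than hovering
  near the growth half-saturations.  Consequences: induced-shortage
  collapses are slow (the banked reserve must drain through maintenance,
  heating, travel, and evaporation — tens of days, not days), post-bloom
  heating stress rarely extinguishes a colony that banked a bloom, and
  within-season starvation thresholds (`ε_N`) are reached only after long
  droughts.  The acceptance suite records these departures honestly rather
  than re-fitting the rates.
- **Winner-take-all foraging at low T** (see above) starves colonies on
  sparse uniform backgrounds that could in principle support them.
- **Multi-year overshoot.** Egg-laying scales with `R` but not with
  available resources, so after a good year the jump map overshoots the
  landscape's carrying capacity; `R` then relaxes downward (or, in sparse
  landscapes, the whole population boom-busts to extinction).  Ten-year
  runs show damped oscillation around the resource-set level rather than a
  clean monotone saturation.
- The generator emulates stylised landscapes: lattice geometry, rectangular
  bloom windows, uniform backgrounds, a single nest site.  Real landscapes
  have irregular patch geometry, stochastic phenology, weather-dependent
  foraging, and multiple colonies at distinct sites; passing tests here
  demonstrates internal consistency of the model, not field realism.
- Environmental temperature, forager memory/site fidelity, wax structural
  energy, and multi-nest spatial competition are out of scope.
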