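# Methods

## Model

The community holds `N` bacterial species, each at a fixed total density
`D` (cells/mL). The state is the pair of vectors `B⁺` (plasmid-carrying)
and `B⁻` (plasmid-free) with `B⁺ᵢ + B⁻ᵢ = D` throughout. Spread of the
plasmid is deterministic once the compatibility matrices are drawn; the
model tracks carrier *fractions*, not individual cells or transfer events,
in keeping with the mass-action tradition for conjugation kinetics.

Each timestep applies two updates in order:

1. **Horizontal transfer** (forward Euler on the mass-action law). The
   gain of recipient species `i` is

       ΔB⁺ᵢ = Δt · B⁻ᵢ · Σ_mech γ_mech Σⱼ α_mech(j, i) · B⁺ⱼ

   with the same amount removed from `B⁻ᵢ`. The four mechanisms are
   additive: each contributes its maximal rate constant γ times its
   donor→recipient compatibility matrix α. Vectors (free DNA, phages,
   vesicles) are not modelled explicitly; their abundances are assumed
   proportional to their source populations and folded into γ and α.

2. **Vertical spread** (selection within species). Carriers have a uniform
   Malthusian fitness advantage `m`, so the carrier fraction
   `f = B⁺/(B⁺+B⁻)` obeys the replicator/logistic law. The update

       f′ = f e^{mΔt} / (1 + f (e^{mΔt} − 1))

   is the *exact* time-Δt solution, not an Euler step: iterating it
   composes exactly (`step(Δt)∘step(Δt) = step(2Δt)`), it preserves
   species totals by construction, and it has fixed points at f = 0 and
   f = 1.

Model assumptions: the system is well mixed (no spatial structure); total
and relative population sizes are constant (a steady-state community); the
plasmid is broad-host-range, carries no fitness cost, is never lost, and
every transfer succeeds subject only to the compatibility matrices (no
restriction/CRISPR barriers). These exclusions define the model's scope,
not oversights.

**Full spread** is declared at the first recorded time every species'
carrier fraction reaches 0.99 (threshold configurable), at recording
resolution without interpolation — at the default 10⁴ steps the induced
error is far below replicate-to-replicate spread.

## Rate-constant calibration

Conjugation is measured directly between donors and recipients; its
optimal constant is taken from the fast end of the published range,
γ_conjugation = 10⁻⁸ mL cell⁻¹ min⁻¹.

The other three mechanisms are assayed by mixing recipients with *vector*.
Under mass action such a batch experiment follows
`dR/dt = dV/dt = −γRV`, `dT/dt = γRV` (one vector consumed per converted
recipient). Integrating between t = 0 and t = Δt gives the closed-form
end-point estimator

    γ = [ln((V₀ − R₀ + R₁)/R₁) − ln(V₀/R₀)] / (Δt (V₀ − R₀)),

which `endpoint_rate` evaluates from (V₀, R₀, R₁, Δt). Numerical notes:

* At the removable singularity V₀ = R₀ the formula is 0/0; the analytic
  limit `γ = (1/R₁ − 1/R₀)/Δt` (from dR/dt = −γR²) is used whenever
  |V₀ − R₀| < 10⁻⁹·max(V₀, R₀). Continuity across the switch is tested.
* V₀ < R₀ is legal and typical for transduction and vesicle assays.
* A non-positive log argument (V₀ − R₀ + R₁ ≤ 0) means the data imply
  vector exhaustion, which the one-hit model cannot produce; this raises
  an "infeasible experiment" error rather than returning a number.
* `ode_oracle`, a fixed-step RK4 integration of the forward kinetics, is
  kept in the package purely as an independent inversion check for tests.

Per-vector rates are converted to the per-donor rates the simulator needs
by an environmental vector:donor ratio, times a recipient-side efficiency
where applicable:

| mechanism      | per-vector source                         | ratio        | efficiency | per-donor | rounded |
|----------------|-------------------------------------------|--------------|-----------|-----------|---------|
| conjugation    | direct measurement                        | —            | —         | 1e-8      | 1e-8    |
| transformation | dataset mean 4.35e-17 (mL fragment⁻¹ min⁻¹)| 333 fragments/cell | competence 0.01 | 1.45e-16 | 1e-16 |
| transduction   | end-point γ of the best assay, 1.01e-16   | 10 phages/cell | 1       | 1.01e-15  | 1e-15   |
| vesicle        | dataset mean 4.76e-22 (mL EV⁻¹ min⁻¹)     | 0.4 EV/cell  | 1         | 1.9e-22   | 1e-22   |

The 333 fragments/cell ratio comes from ocean-water estimates of
0.01 μg/mL free DNA and 10⁶ cells/mL, converting DNA mass to counts with a
30 kb reference fragment of mass 3.0×10⁻¹⁷ g (~600 g/mol per base pair).
That fragment mass is the constant that makes the worked transformation
example (2.5 μg/mL → V₀ = 8.33×10¹⁰ fragments/mL → γ = 4.00×10⁻¹⁷) and
the 333 ratio mutually consistent; it is configurable. The two dataset
means (4.35e-17, 4.76e-22) are accepted as constants because recomputing
them requires the source studies' full measurement tables; the worked
single-point examples above are recomputed from raw numbers. The vesicle
assay's incubation time is not recoverable from the published summary, so
the vesicle constant derives from the dataset mean rather than a
single-point end-point evaluation. Rounding to the nearest power of ten
(half-away-from-zero on the exponent) mirrors how such order-of-magnitude
constants are quoted and used.

## Compatibility-matrix rulesets

Rows index donors, columns recipients (fixed by the convention that
transformable species define matrix *columns*). Diagonals follow the same
rules as off-diagonal entries — intraspecies transfer is included in the
donor sum. All generators take a seed (or a shared NumPy `Generator`) and
are bitwise reproducible.

* **Conjugation.** Exactly `round(0.15·N)` recipient species form the
  super-permissive core (a fixed quota, not a Bernoulli draw): their
  columns are i.i.d. uniform[0, 1]; all other columns i.i.d.
  uniform[0, 1/25].
* **Transformation.** Each species is transformable with probability
  0.01; transformable columns are all 1, others all 0. By default the
  draw repeats until at least one species is transformable — at N = 100
  roughly 37% of raw draws would otherwise silently delete the mechanism.
  The flag is exposed for callers who want the unconditioned law.
* **Transduction.** Module sizes are proportional to 1..M
  (largest-remainder rounding to sum exactly to N, minimum size 1);
  species are assigned to modules, and ranked within each module, by
  uniform random permutations. A module of size s has s phages; the host
  of rank r is infected by phages 1..r, so phage sets are nested with one
  full generalist host and one most-specialist host per module.
  Compatibility is `|phages(d) ∩ phages(r)| / |phages(d)|`
  (= min(k_d, k_r)/k_d under nesting) within a module and 0 across
  modules. The default module count is max(1, round(0.13·N)) — 13 at
  N = 100, giving linear sizes whose smallest modules have one or two
  species, consistent with observed modular-nested phage–host networks.
* **Vesicle transfer.** Donor and recipient efficiencies i.i.d.
  uniform[0, 1]; α is their outer product (rank 1, mean entry 1/4). An
  optional participation fraction zeroes both efficiencies for a random
  subset of species, for sensitivity analyses where vesicle exchange is
  not universal.

## Study conditions and defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| N | 100 | species | bacterial diversity of an ocean-water sample |
| D (per-species density) | 10⁴ | cells/mL | total 10⁶ cells/mL at N = 100, the same ocean estimate used for the vector:donor ratios; not stated for the original runs |
| initial condition | fraction 10⁻⁴ in species 1 | — | "one species carries the plasmid, at a very small fraction"; 10⁻⁴ of 10⁴ is ~1 cell/mL |
| m | 0.02 | per **day** | the published value is unitless; per-day is the only standard unit consistent with the ~6-year non-conjugative spread scale (per-hour would finish in weeks). The unit is explicit in `SimulationConfig` |
| timesteps | 10⁴ | — | Δt = horizon/10⁴, mirroring the original scheme |
| horizon | 60 days (conjugative) / 7 years (non-conjugative) | — | each comfortably beyond the respective spread times |
| threshold | 0.99 | — | full-spread definition |
| replicates | 5 | — | fresh matrices per replicate, seeds base+k |

Because density, initial fraction and the fitness unit are modelling
choices rather than published numbers, the replicated scenario means are
reproduced to within a factor of two of the published 26.8 d / 27.9 d /
5.9 y / 6.0 y (observed here: ~33 d, ~33 d, ~6.6 y, ~6.6 y at these
defaults), with every qualitative conclusion intact: conjugative spread is
one-to-two orders faster than non-conjugative; removing transformation or
transduction barely moves the non-conjugative mean (< 10%); removing
vesicle transfer prevents full spread entirely because phage–host modules
without a transformable member become unreachable.

Replicates are paired across scenarios: replicate k always draws all four
matrices from seed base+k in a fixed order, whether or not a mechanism is
enabled, so knockout comparisons differ only in the toggles.

## Numerical choices

* Forward Euler for the transfer step, with the per-recipient gain capped
  at the available plasmid-free pool. The cap binding is the signature of
  a too-coarse timestep; it is counted, logged, and surfaced by
  `convergence_check`, which doubles `n_steps` until the full-spread time
  is stable (default gate 1%). At the default resolutions the cap never
  binds and refinement moves results by ≪ 1%.
* The selection step is exact (see above), so with transfer disabled the
  trajectory matches the logistic closed form to ~10⁻⁹ over 10⁴ steps —
  this is a regression test, not an approximation statement.
* Species totals are conserved exactly in the selection step (B⁻ is
  computed as total − B⁺) and to floating-point rounding in the transfer
  step; drift over 10⁴ steps stays below 10⁻⁹ relative.
* Runs are bitwise deterministic given config and matrices: all
  stochasticity lives in the seeded matrix generators.

## What the generated matrices do and do not capture

The generators reproduce the *statistical signatures* the rulesets
describe: quota and attenuation of the conjugative core, prevalence of
natural transformability, modular-nested phage–host structure, rank-1
vesicle efficiencies. They do not encode real taxa, phylogenetic
correlation (none is established for these traits), empirical infection
networks, or plasmid host-range limits. Passing the scenario checks
therefore shows the model reproduces the published *community-level
dynamics* under these statistical assumptions — not that it predicts
transfer rates for any particular species pair.

## Problem sizes

The test suite exercises unit behaviour on 2–30-species communities and
runs the full 100-species, 5-replicate scenario panels once (session
fixtures); the whole suite completes in well under a minute.
`scripts/acceptance.py` reruns the calibration worked examples plus four
5-replicate scenario panels (~20 simulations) in a few seconds.

## Known limitations

* No spatial structure, vector persistence/decay, plasmid loss, fitness
  cost, host-range limits, or restriction/CRISPR interference.
* Deterministic fractions cannot represent extinction or jackpot events at
  very low carrier numbers (fractions of 10⁻¹⁰ of a species are
  meaningful to the ODEs but correspond to far less than one cell).
* The end-point estimator assumes exactly one vector consumed per
  conversion and no vector replication — transduction data from lytic
  phage amplification would violate it.
* Module count and the 15% quota interpretation are modelling choices
  where the published rulesets leave freedom; both are configurable.
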