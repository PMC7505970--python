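# Methods

## Model structure

The simulator couples three description levels of microbe-enzyme
decomposition:

1. **Deterministic cdmz model** (`exoevo.deterministic`) — four ODEs for
   SOC `c`, DOC `d`, cell biomass `m` and enzyme `z` of one well-mixed
   microsite, valid in the large-system-size limit.  It supplies initial
   conditions (steady states), the analytic selection gradient, and the
   viability range of the enzyme-allocation trait φ.
2. **Hybrid (piecewise-deterministic) microsite** (`exoevo.microsite`) —
   the pools stay continuous, but cells are individuals: death is a Poisson
   jump at rate `d_M·M`, division fires deterministically when a cell's
   stored reserve reaches `ω_M`, and the per-cell reserve integrates
   `(1−φ)γ_M·u(d)·ω_M` between events, with `u(d) = V_max d/(K_m+d)`.
3. **Lattice** (`exoevo.lattice`) — microsites coupled by explicit-Euler
   DOC diffusion with Neumann boundaries and by newborn dispersal with
   micro-disturbances.  The master loop draws one global death clock
   (`rate = d_M·M_total`), advances all sites by `min(T_death, τ_diff)`,
   applies divisions and placement in a uniformly shuffled order, applies
   one diffusion update over the elapsed time, then the death (if the
   clock fired first).

The cdmz right-hand side reconstructs the biomass dynamics from the pool
equations plus the recycling routes of the event loop (dead biomass:
fraction `l` leached, of the rest `p` to SOC, `1−p` to DOC; deactivated
enzyme carbon to DOC; energetic overheads respired).  The reconstruction is
validated by carbon closure: at equilibrium, inputs balance leaching +
respiration + leached recycling to float tolerance (asserted in tests).
Respiration is tracked explicitly as `u·m·[1 − (1−φ)γ_M − φγ_Z]`.

## Parameters and system-size scaling

All symbols live in `ParameterSet` (mg carbon, hours).  The default table
is interpreted at **unit soil volume** (k = 1, the volume expected to hold
one cell); the four volume-dependent parameters are rescaled to the working
system size k (default 10): inputs `I_C`, `I_D` and half-saturation `K_m`
scale with k, the encounter factor in `θ` scales with 1/k.  This makes
per-unit-volume equilibrium densities k-invariant (a test solves the
steady state at k and 2k) and puts the default microsite equilibrium at
≈ 5.6 cells for φ = 0.5 — the same order as the ~10 cells the parameters
were designed around.  The residual factor (~1.8) comes from
reconstructing the biomass equations rather than copying them; it is
within the tolerance the acceptance criteria assign to this quantity.

Mass-consistency relations tie the per-entity costs to the production
fractions (`γ_M = ω_M/((α+α′)ω_D)`, `γ_Z = ω_Z/((ρ+ρ′)ω_D)`,
`ω_C = β·ω_D`); `validate` checks them to 1% because the published cost
values are printed to 3 significant digits.

Key tunables (defaults in `exoevo/data/defaults.yaml`):

- `φ ∈ [0,1]` — enzyme allocation; evolving trait.  Viable range at the
  defaults ≈ (0.012, 0.998), found numerically by scan + bisection.
- `σ_diff ∈ [1e-7, 5e-5]` — DOC diffusion coefficient; the central
  environmental control.  At 1e-5 the inter-site hop rate (≈ 2/h) exceeds
  the uptake relaxation rate, so DOC is effectively shared lattice-wide; at
  1e-7 it is mostly local.
- `p_disp = 0.3`, `p_open = 0.01` — dispersal and micro-disturbance
  probabilities; together they set the site-turnover rate that drives
  between-site selection.
- `p_mut` — 0 by default (invasion assays run without mutation); the
  single-site evolutionary demonstration uses 0.1.  `σ_mut = 0.05`, the
  midpoint of the plausible 0.01–0.1 range.
- `τ_diff` — diffusion time step.  Chosen automatically as
  `min(1 h, (Vk)^(2/3)/(8 σ_diff))`, i.e. half the explicit-scheme
  stability bound `4f < 1` where `f = σ_diff·τ/(Vk)^(2/3)`;
  `diffuse_doc` raises on an unstable factor.

## Numerical choices

- **Flow integration**: adaptive explicit Euler.  The sub-step is
  `0.05 / J`, where `J` bounds the local linearization rates
  (`l_D + V_max ω_M M K_m/(K_m+d)²`, `l_C + θz`, `d_Z`); fluxes are clipped
  at zero with a counted residual.  Budget terms (inputs, leaching,
  respiration, leached recycling) are accumulated from the same Euler
  fluxes the pools see, so carbon closure holds to roundoff plus the clip
  residual — closure is a bookkeeping test, not a discretization test.
- **Division**: the Methods-style excess split is used — mother and
  daughter each keep `(S+Δ−ω_M)/2` — because it conserves carbon exactly
  (a reset-to-zero would not).
- **Death recycling** routes the fraction `p` to SOC uniformly (death,
  micro-disturbance) and includes the victim's stored reserve, again for
  exact closure; at the default `p = 0.5` the routing direction is
  numerically irrelevant.
- **Diffusion cadence**: the update uses the actually elapsed interval
  `min(T_death, τ_diff)`, never more than `τ_diff`, so death-interrupted
  iterations do not distort the scheme.
- **Determinism**: the compiled kernel seeds its own Mersenne generator
  once per call; a fixed seed yields a bit-identical trajectory.  Replicate
  seeds are derived from a master seed through `numpy.random.SeedSequence`.
- The production event loop is a numba kernel; the identical scheme exists
  as plain-Python operations (`integrate_flows`, `apply_divisions`,
  `diffuse_doc`, `step_lattice`, ...) which are unit-tested directly, and a
  cross-check runs both implementations through the deterministic
  (death-free) limit and asserts agreement to 1e-9 relative.

## Synthetic initial states

There is no external data; all inputs are parameter sets and generated
states.  `make_fixture` produces the standard lattices (equilibrium
monomorphic, empty, DOC spike, two-strain split); contests start from the
resident's deterministic equilibrium in every site (integer cell count =
rounded equilibrium biomass, reserves uniform in `[0, ω_M)`) with mutants
replacing `ceil(5%)` of residents in the five central plus-shaped sites.
What the generator does *not* emulate: real soils' spatial heterogeneity in
abiotic parameters, 3-D pore geometry, nutrient co-limitation, temperature
or moisture dynamics.  Passing tests therefore establish internal
consistency of the model's mechanisms, not calibration against field data.

## Experiment scales

Full-scale experiments (T = 1e6 h, 20 replicates, 10×10 lattice, five-point
trait grid, several diffusion rates) take CPU-days.  The packaged tests use
reduced designs chosen as the smallest scales at which the documented
effects are mechanistically expected to rise above demographic drift:

- **ESS vs diffusion** (`tests/test_acceptance.py`): 5×5 lattice,
  T = 6e5 h, 5 replicates, trait grid {0.05, 0.15, 0.25} with mutant
  offset ±0.1, at σ_diff ∈ {1e-5, 1e-6, 1e-7}.  The coarser trait
  contrast roughly doubles the selection differential per contest,
  compensating for the reduced replicate count; the run asserts only the
  qualitative ordering (ESS bracket midpoint increases monotonically as
  σ_diff drops from 1e-5 to 1e-7), not the full-scale bracket values.
  Invasion at these population sizes (~5-9 cells/site) is strongly
  drift-dominated, so individual contests are noisy by construction — the
  survival factor of the fitness proxy is doing real work.
- **Adaptation feedback**: monomorphic runs at the evolved allocations
  (φ = 0.2 for σ_diff = 1e-7, φ = 0.02 for σ_diff = 1e-5) on a 6×6
  lattice to T = 1e5 h with a 2e4 h burn-in, checking the ≥4-fold
  decomposition increase and the large (~80–90%) SOC drop.  The
  deterministic equilibria already imply a ~24-fold enzyme-activity ratio
  and ~90% SOC contrast between these allocations, so the direction is
  robust to the reduced scale.
- **Large-k convergence**: single-site trajectories at k ∈ {10, 100, 1000}
  over 5e4 h, 10 replicates; the relative deviation of biomass from the
  deterministic equilibrium shrinks with k (≈ 1/√k demographic noise).

## Known limitations

- The exact supplementary biomass equations of the source model family are
  not public in the main text; the reconstruction here matches all printed
  equations and conserves carbon, but the equilibrium cell count retains a
  factor ~1.8 uncertainty (see above).
- No local stability analysis of the cdmz equilibrium, no reduced two- or
  three-pool variants, and no molecule-level (complex-resolving) stochastic
  simulation.
- Single-trait evolution only; no coexistence analysis of distinct
  strains.
- Explicit Euler diffusion limits `τ_diff` at high `σ_diff`; runs at
  `σ_diff = 5e-5` are ~40× more iteration-hungry than at 1e-7.
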