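"""Adaptive-dynamics experiment layer: resident-mutant contests on the
lattice, an invasion-fitness proxy, ESS bracketing, and ecosystem-function
read-outs.

A contest introduces a rare mutant strain (5% of local abundance in the
central microsites, replacing residents one-for-one) into a lattice
equilibrated by the resident, and runs the spatial hybrid model without
mutation.  The invasion-fitness proxy follows adaptive-dynamics theory for
finite populations: the product of the mutant survival probability (fraction
of replicates with a surviving mutant population at T) and the average
long-term growth rate ``(1/T) log(final/initial)`` of surviving mutant
populations, rescaled by T.  An ESS for a given diffusion rate is bracketed
between the largest trait value where a slightly more cooperative mutant
(phi + delta) still has positive fitness and the smallest trait value where
a slightly cheating mutant (phi - delta) has positive fitness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .deterministic import steady_state
from .lattice import LatticeState, simulate_lattice
from .microsite import Cell
from .params import ParameterSet

__all__ = [
    "InvasionResult",
    "ESSEstimate",
    "EcosystemFunction",
    "initialize_contest",
    "run_contest",
    "ess_scan",
    "ecosystem_function",
    "introduction_sites",
    "bracket_ess",
]

RESIDENT_STRAIN = 0
MUTANT_STRAIN = 1


@dataclass(frozen=True)
class InvasionResult:
    """Survival and growth statistics of one resident-mutant contest."""

    phi_res: float
    phi_mut: float
    n_replicates: int
    survival_fraction: float
    mean_growth_rate: float          # 1/h, averaged over surviving replicates
    fitness_proxy: float             # survival * mean growth * T
    T: float
    initial_mutants: int
    final_mutant_counts: tuple[int, ...]
    final_total_counts: tuple[int, ...] = ()


@dataclass(frozen=True)
class ESSEstimate:
    """phi-bracket implied by a grid of pairwise contests at one diffusion
    rate.  ``lower`` is the largest grid value where the cooperator mutant
    invades (0 when none does), ``upper`` the smallest where the cheater
    mutant invades (the grid maximum when none does)."""

    sigma_diff: float
    phi_grid: tuple[float, ...]
    lower: float
    upper: float
    directional: bool                # False when the bracket came out inverted
    contests: tuple[InvasionResult, ...] = field(default=(), repr=False)

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)


@dataclass(frozen=True)
class EcosystemFunction:
    """Lattice-scale function read-outs of a monomorphic run."""

    phi: float
    sigma_diff: float
    decomposition_rate: float        # theta * time-avg total enzyme mass
    mean_soc_per_microsite: float    # mg, time-and-lattice average
    extinct_at: Optional[float]


def _child_seed(master_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, *key])
    return int(ss.generate_state(1)[0]) & 0x7FFFFFFF


def introduction_sites(L: int, n_sites: int = 5) -> list[tuple[int, int]]:
    """The central microsite plus (for n_sites = 5) its 4-neighbour
    plus-shape, clipped to the lattice."""
    ci = L // 2
    cand = [(ci, ci), (ci - 1, ci), (ci + 1, ci), (ci, ci - 1), (ci, ci + 1)]
    out = [t for t in cand if 0 <= t[0] < L and 0 <= t[1] < L]
    return out[:n_sites]


def initialize_contest(params: ParameterSet, phi_res: float, phi_mut: float,
                       rng: np.random.Generator,
                       n_intro_sites: int = 5) -> LatticeState:
    """Lattice at the resident's deterministic steady state everywhere, with
    mutants replacing ceil(5% of local abundance) resident cells in each
    introduction site.  Total initial biomass equals the resident-only
    initialization (replacement, not addition)."""
    ss = steady_state(params, phi_res)
    if not ss.viable:
        raise ValueError(f"non-viable resident phi = {phi_res}")
    lattice = LatticeState.monomorphic_steady(params, phi_res, rng=rng,
                                              strain_id=RESIDENT_STRAIN)
    for (i, j) in introduction_sites(params.L, n_intro_sites):
        site = lattice.grid[i][j]
        n_mut = max(1, math.ceil(0.05 * site.M))
        for cell in site.cells[:n_mut]:
            cell.phi = phi_mut
            cell.strain_id = MUTANT_STRAIN
    return lattice


def run_contest(params: ParameterSet, phi_res: float, phi_mut: float,
                n_replicates: int = 20, T_max: Optional[float] = None,
                seeds: Optional[Sequence[int]] = None,
                master_seed: int = 0, n_intro_sites: int = 5,
                cap: int = 64) -> InvasionResult:
    """Estimate the invasion-fitness proxy of ``phi_mut`` against
    ``phi_res`` from independent replicate lattice runs (no mutation)."""
    if T_max is None:
        T_max = params.T_max
    p = params.with_(p_mut=0.0)
    if seeds is None:
        seeds = [_child_seed(master_seed, round(phi_res * 1e6),
                             round(phi_mut * 1e6), r)
                 for r in range(n_replicates)]
    finals: list[int] = []
    totals: list[int] = []
    initial = None
    for r, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        lattice = initialize_contest(p, phi_res, phi_mut, rng, n_intro_sites)
        if initial is None:
            initial = sum(1 for site in lattice.sites()
                          for cell in site.cells
                          if cell.strain_id == MUTANT_STRAIN)
        run = simulate_lattice(lattice, p, T_max, seed=seed,
                               rec_interval=T_max, cap=cap)
        finals.append(int(run.trajectory["M_mutant"][-1]))
        totals.append(int(run.trajectory["M"][-1]))
    finals_arr = np.array(finals)
    surviving = finals_arr > 0
    survival = float(surviving.mean())
    if surviving.any():
        growth = float(np.mean(np.log(finals_arr[surviving] / initial))
                       / T_max)
    else:
        growth = 0.0
    proxy = survival * growth * T_max
    return InvasionResult(phi_res, phi_mut, len(finals), survival, growth,
                          proxy, T_max, int(initial), tuple(finals),
                          tuple(totals))


def bracket_ess(phi_grid: Sequence[float], coop_positive: Sequence[float],
                cheat_positive: Sequence[float]
                ) -> tuple[float, float, bool]:
    """ESS bracket from the sets of grid traits where the cooperator /
    cheater mutant had positive fitness.

    Returns (lower, upper, directional): the largest cooperator-positive
    trait (0 when none — selection points below the grid) and the smallest
    cheater-positive trait (the grid maximum when none — selection points
    above).  ``directional`` is False when the raw bracket came out
    inverted (the bounds are then swapped and should be read as a
    non-directional fitness pattern, e.g. sampling noise).
    """
    lower = max(coop_positive) if len(coop_positive) else 0.0
    upper = min(cheat_positive) if len(cheat_positive) else max(phi_grid)
    directional = lower <= upper
    if not directional:
        lower, upper = upper, lower
    return lower, upper, directional


def ess_scan(params: ParameterSet, sigma_diff: float,
             phi_grid: Sequence[float] = (0.05, 0.10, 0.15, 0.20, 0.25),
             delta_phi: float = 0.05, n_replicates: int = 20,
             T_max: Optional[float] = None, master_seed: int = 0,
             n_intro_sites: int = 5, cap: int = 64) -> ESSEstimate:
    """Bracket the ESS at one diffusion rate from pairwise contests.

    For each grid value phi the cooperator mutant (phi + delta) and the
    cheater mutant (phi - delta) are each contested against the resident
    phi.  ``delta_phi`` must equal the grid spacing.
    """
    grid = sorted(float(x) for x in phi_grid)
    if len(grid) > 1:
        spacings = np.diff(grid)
        if not np.allclose(spacings, delta_phi, rtol=1e-9, atol=1e-12):
            raise ValueError("delta_phi must equal the grid spacing")
    p = params.with_(sigma_diff=sigma_diff)
    contests: list[InvasionResult] = []
    coop_positive: list[float] = []
    cheat_positive: list[float] = []
    for phi in grid:
        for phi_mut in (phi + delta_phi, phi - delta_phi):
            if not (0.0 <= phi_mut <= 1.0):
                continue
            res = run_contest(p, phi, phi_mut, n_replicates, T_max,
                              master_seed=master_seed,
                              n_intro_sites=n_intro_sites, cap=cap)
            contests.append(res)
            if res.fitness_proxy > 0:
                if phi_mut > phi:
                    coop_positive.append(phi)
                else:
                    cheat_positive.append(phi)
    lower, upper, directional = bracket_ess(grid, coop_positive,
                                            cheat_positive)
    return ESSEstimate(sigma_diff, tuple(grid), lower, upper, directional,
                       tuple(contests))


def ecosystem_function(params: ParameterSet, phi_fixed: float,
                       sigma_diff: Optional[float] = None,
                       T_max: Optional[float] = None,
                       burn_in: float = 2e5, seed: int = 0,
                       cap: int = 64) -> EcosystemFunction:
    """Decomposition rate and mean SOC stock of a monomorphic lattice run.

    The decomposition rate is theta times the time-average of the total
    lattice enzyme mass over [burn_in, T_max]; the SOC read-out is the SOC
    mass per microsite averaged across the lattice and over the same
    window.  Extinction before the burn-in is reported via ``extinct_at``
    (the averages then describe the cell-free lattice)."""
    p = params if sigma_diff is None else params.with_(sigma_diff=sigma_diff)
    p = p.with_(p_mut=0.0)
    if T_max is None:
        T_max = p.T_max
    if burn_in >= T_max:
        raise ValueError("burn_in must be < T_max")
    ss = steady_state(p, phi_fixed)
    if ss.viable:
        lattice = LatticeState.monomorphic_steady(p, phi_fixed, seed=seed)
    else:
        # non-viable trait: seed a nominal population of k cells per site on
        # the cell-free pool equilibrium and let it die out
        from .microsite import MicrositeState
        rng = np.random.default_rng(seed)
        n_cells = max(1, round(p.k))
        grid = [[MicrositeState(ss.state.c, ss.state.d, 0.0,
                                [Cell(phi_fixed,
                                      rng.uniform(0, p.omega_M), 0)
                                 for _ in range(n_cells)])
                 for _ in range(p.L)] for _ in range(p.L)]
        lattice = LatticeState(grid)
    run = simulate_lattice(lattice, p, T_max, seed=seed,
                           acc_start=burn_in, cap=cap)
    z_avg_total = float(run.site_time_avg["z"].sum())
    soc_avg = float(run.site_time_avg["c"].mean())
    return EcosystemFunction(phi_fixed, p.sigma_diff,
                             p.theta * z_avg_total, soc_avg, run.extinct_at)
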