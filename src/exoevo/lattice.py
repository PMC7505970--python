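"""Lattice coupling of microsites: DOC diffusion, newborn dispersal,
micro-disturbances, and the master event loop.

Microsites sit on an L x L square grid.  DOC diffuses between 4-neighbours
by an explicit Euler step of the diffusion equation with update factor
``f = sigma_diff * tau / (Vk)^(2/3)`` (the denominator is the squared
inter-site distance); boundaries are Neumann (reflecting), so total DOC is
conserved.  Newborn cells stay in the maternal site with probability
``1 - p_disp``; a dispersing newborn moves to a uniformly chosen empty
neighbour if one exists, and otherwise a micro-disturbance (probability
``p_open``) may wipe out a uniformly chosen neighbour, recycle its carbon
locally, and hand the site to the newborn.  Dispersal tied to disturbances
is what keeps competing strains segregated at the microsite scale.

:func:`step_lattice` is the plain-Python reference iteration of the master
loop; :func:`simulate_lattice` drives the compiled kernel
(:mod:`exoevo._kernel`) that implements the identical scheme at production
speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernel as K
from .deterministic import steady_state
from .microsite import (Cell, FlowLedger, MicrositeState, SUBSTEP_ETA,
                        draw_death_time, integrate_flows)
from .params import ParameterSet

__all__ = [
    "LatticeState",
    "LatticeRun",
    "DiffusionInstabilityError",
    "diffuse_doc",
    "place_newborn",
    "micro_disturbance",
    "step_lattice",
    "simulate_lattice",
]


class DiffusionInstabilityError(ValueError):
    """Explicit diffusion update factor violates 4*f < 1."""


@dataclass
class LatticeState:
    """L x L grid of microsites plus the simulation clock (h)."""

    grid: list[list[MicrositeState]]
    t: float = 0.0

    @property
    def L(self) -> int:
        return len(self.grid)

    def sites(self):
        for row in self.grid:
            yield from row

    @property
    def M_total(self) -> int:
        return sum(site.M for site in self.sites())

    @property
    def total_doc(self) -> float:
        return sum(site.d for site in self.sites())

    def copy(self) -> "LatticeState":
        return LatticeState([[s.copy() for s in row] for row in self.grid],
                            self.t)

    @classmethod
    def monomorphic_steady(cls, params: ParameterSet, phi: float,
                           seed: int = 0, strain_id: int = 0,
                           rng: Optional[np.random.Generator] = None
                           ) -> "LatticeState":
        """Every site at the deterministic steady state for ``phi``; cell
        count rounded to the nearest integer, reserves uniform in
        [0, omega_M)."""
        ss = steady_state(params, phi)
        if not ss.viable:
            raise ValueError(f"no viable steady state at phi = {phi}")
        n_cells = max(1, round(ss.state.m / params.omega_M))
        if rng is None:
            rng = np.random.default_rng(seed)
        grid = []
        for _ in range(params.L):
            row = []
            for _ in range(params.L):
                cells = [Cell(phi, rng.uniform(0, params.omega_M), strain_id)
                         for _ in range(n_cells)]
                row.append(MicrositeState(ss.state.c, ss.state.d, ss.state.z,
                                          cells))
            grid.append(row)
        return cls(grid)


def _diffusion_factor(tau: float, params: ParameterSet) -> float:
    f = params.sigma_diff * tau / params.site_length_sq
    if 4.0 * f >= 1.0:
        raise DiffusionInstabilityError(
            f"diffusion update factor 4f = {4 * f:.3g} >= 1; "
            f"reduce tau_diff below {params.site_length_sq / (4 * params.sigma_diff):.3g} h")
    return f


def diffuse_doc(lattice: LatticeState, tau: float,
                params: ParameterSet) -> LatticeState:
    """One explicit Euler diffusion update of DOC over ``tau`` hours.

    Neumann boundaries: missing neighbours contribute nothing and the
    Laplacian uses only existing neighbours, so total DOC is conserved.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    f = _diffusion_factor(tau, params)
    L = lattice.L
    d = np.array([[lattice.grid[i][j].d for j in range(L)] for i in range(L)])
    padded = np.pad(d, 1, mode="edge")   # edge-replication => zero edge flux
    lap = (padded[:-2, 1:-1] + padded[2:, 1:-1]
           + padded[1:-1, :-2] + padded[1:-1, 2:] - 4.0 * d)
    d_new = d + f * lap
    for i in range(L):
        for j in range(L):
            lattice.grid[i][j].d = d_new[i, j]
    return lattice


def _neighbours(L: int, i: int, j: int) -> list[tuple[int, int]]:
    out = []
    if i > 0:
        out.append((i - 1, j))
    if i < L - 1:
        out.append((i + 1, j))
    if j > 0:
        out.append((i, j - 1))
    if j < L - 1:
        out.append((i, j + 1))
    return out


def micro_disturbance(lattice: LatticeState, target: tuple[int, int],
                      params: ParameterSet,
                      ledger: Optional[FlowLedger] = None) -> LatticeState:
    """Kill the whole cell population of ``target`` and recycle its carbon
    locally: after leaching fraction ``l``, a fraction ``p`` to SOC and the
    rest to DOC of the same site."""
    i, j = target
    site = lattice.grid[i][j]
    dead_c = sum(params.omega_M + cell.S for cell in site.cells)
    site.c += (1 - params.l) * params.p * dead_c
    site.d += (1 - params.l) * (1 - params.p) * dead_c
    if ledger is not None:
        ledger.leached_recycling += params.l * dead_c
    site.cells.clear()
    return lattice


def place_newborn(lattice: LatticeState, origin: tuple[int, int],
                  newborn: Cell, rng: np.random.Generator,
                  params: ParameterSet,
                  ledger: Optional[FlowLedger] = None) -> str:
    """Place one newborn cell; returns the outcome.

    Outcomes: ``"stayed"`` (no dispersal draw, or unsuccessful dispersal),
    ``"dispersed"`` (moved to an empty neighbour), ``"disturbance"`` (a
    micro-disturbance opened a neighbour which the newborn colonized).
    """
    i, j = origin
    nbs = _neighbours(lattice.L, i, j)
    outcome = "stayed"
    dest = origin
    if rng.random() >= 1 - params.p_disp and nbs:
        empties = [t for t in nbs if lattice.grid[t[0]][t[1]].M == 0]
        if empties:
            dest = empties[int(rng.integers(len(empties)))]
            outcome = "dispersed"
        elif rng.random() >= 1 - params.p_open:
            dest = nbs[int(rng.integers(len(nbs)))]
            micro_disturbance(lattice, dest, params, ledger)
            outcome = "disturbance"
    lattice.grid[dest[0]][dest[1]].cells.append(newborn)
    return outcome


def step_lattice(lattice: LatticeState, params: ParameterSet,
                 rng: np.random.Generator,
                 ledger: Optional[FlowLedger] = None,
                 registry=None) -> LatticeState:
    """One iteration of the master event loop (reference implementation).

    Draw the global death time T at rate ``d_M * M_total``; advance all
    sites' flows over ``min(T, tau_diff)``; apply divisions and newborn
    placement in a uniformly shuffled order; apply one diffusion update over
    the elapsed time; if the death clock fired, remove one uniformly chosen
    cell of the whole lattice.  Advances the clock in place.
    """
    from .microsite import apply_divisions

    tau_diff = params.resolve_tau_diff()
    T_death = draw_death_time(lattice.M_total, params, rng)
    tau = min(T_death, tau_diff)
    died = T_death <= tau_diff

    births: list[tuple[tuple[int, int], Cell]] = []
    L = lattice.L
    for i in range(L):
        for j in range(L):
            site = lattice.grid[i][j]
            deltas = integrate_flows(site, tau, params, ledger=ledger)
            for nb_cell in apply_divisions(site, deltas, rng, params,
                                           registry, lattice.t + tau):
                births.append(((i, j), nb_cell))
    if births:
        order = rng.permutation(len(births))
        for b in order:
            origin, cell = births[b]
            place_newborn(lattice, origin, cell, rng, params, ledger)

    if params.sigma_diff > 0 and L > 1:
        diffuse_doc(lattice, tau, params)

    if died and lattice.M_total > 0:
        v = int(rng.integers(lattice.M_total))
        for site in lattice.sites():
            if v < site.M:
                # remove the globally chosen victim (uniform over cells)
                victim = site.cells.pop(v)
                carbon = params.omega_M + victim.S
                site.c += (1 - params.l) * params.p * carbon
                site.d += (1 - params.l) * (1 - params.p) * carbon
                if ledger is not None:
                    ledger.leached_recycling += params.l * carbon
                break
            v -= site.M

    lattice.t += tau
    return lattice


@dataclass
class LatticeRun:
    """Result of a kernel-driven simulation.

    ``trajectory`` maps column names to numpy arrays sampled at the recorded
    times; ``site_time_avg`` holds per-site time averages of c, d, z over
    the accumulation window (empty when no window elapsed).
    """

    trajectory: dict[str, np.ndarray]
    final: LatticeState
    ledger: FlowLedger
    counters: dict[str, float]
    params: ParameterSet
    seed: int
    extinct_at: Optional[float]
    site_time_avg: dict[str, np.ndarray] = field(default_factory=dict)

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.trajectory)


def _lattice_to_arrays(lattice: LatticeState, cap: int):
    L = lattice.L
    n = L * L
    c = np.empty(n)
    d = np.empty(n)
    z = np.empty(n)
    phi = np.zeros((n, cap))
    S = np.zeros((n, cap))
    strain = np.zeros((n, cap), dtype=np.int64)
    M = np.zeros(n, dtype=np.int64)
    for i in range(L):
        for j in range(L):
            s = i * L + j
            site = lattice.grid[i][j]
            if site.M > cap:
                raise ValueError("cell capacity too small for initial state")
            c[s], d[s], z[s] = site.c, site.d, site.z
            M[s] = site.M
            for ci, cell in enumerate(site.cells):
                phi[s, ci] = cell.phi
                S[s, ci] = cell.S
                strain[s, ci] = cell.strain_id
    return c, d, z, phi, S, strain, M


def _arrays_to_lattice(L, t, c, d, z, phi, S, strain, M) -> LatticeState:
    grid = []
    for i in range(L):
        row = []
        for j in range(L):
            s = i * L + j
            cells = [Cell(phi[s, ci], S[s, ci], int(strain[s, ci]))
                     for ci in range(M[s])]
            row.append(MicrositeState(c[s], d[s], z[s], cells))
        grid.append(row)
    return LatticeState(grid, t)


def simulate_lattice(lattice: LatticeState, params: ParameterSet, T: float,
                     seed: int = 0,
                     rec_interval: Optional[float] = None,
                     acc_start: float = math.inf,
                     cap: int = 64,
                     next_strain: Optional[int] = None) -> LatticeRun:
    """Run the compiled event loop from ``lattice`` for ``T`` hours.

    ``rec_interval`` sets the sampling step of the recorded trajectory
    (default T/400).  ``acc_start`` switches on exact time-integral
    accumulation of per-site c, d, z from that time onward (used by the
    ecosystem-function read-outs).  ``cap`` is the per-site cell capacity;
    the kernel is retried with a doubled capacity if it overflows.
    """
    if T <= 0:
        raise ValueError("T must be > 0")
    tau_diff = params.resolve_tau_diff()
    if lattice.L > 1 and params.sigma_diff > 0:
        _diffusion_factor(tau_diff, params)   # instability guard up front
    if rec_interval is None:
        rec_interval = T / 400.0
    rec_times = np.arange(0.0, T + rec_interval * 0.5, rec_interval)
    if next_strain is None:
        next_strain = 2
        for site in lattice.sites():
            for cell in site.cells:
                next_strain = max(next_strain, cell.strain_id + 1)

    L = lattice.L
    max_m0 = max((site.M for site in lattice.sites()), default=0)
    cap = max(cap, 2 * max_m0)
    while True:
        c, d, z, phi, S, strain, M = _lattice_to_arrays(lattice, cap)
        rec_out = np.zeros((len(rec_times), K.N_REC))
        acc_c = np.zeros(L * L)
        acc_d = np.zeros(L * L)
        acc_z = np.zeros(L * L)
        counters = np.zeros(K.N_CNT)
        status, next_strain_out = K.run_lattice_kernel(
            int(seed) & 0x7FFFFFFF, L, float(T), float(tau_diff),
            c, d, z, phi, S, strain, M,
            params.I_C, params.I_D, params.l_C, params.l_D, params.theta,
            params.K_m, params.V_max, params.gamma_M, params.gamma_Z,
            params.d_M, params.d_Z, params.l, params.p, params.omega_M,
            params.p_disp, params.p_open, params.p_mut, params.sigma_mut,
            params.sigma_diff / params.site_length_sq, SUBSTEP_ETA,
            rec_times, rec_out, float(acc_start),
            acc_c, acc_d, acc_z, counters, next_strain)
        if status == 0:
            break
        cap *= 2
        if cap > 1 << 16:
            raise RuntimeError("cell capacity runaway")

    traj = {
        "t": rec_out[:, K.REC_T],
        "c": rec_out[:, K.REC_C],
        "d": rec_out[:, K.REC_D],
        "z": rec_out[:, K.REC_Z],
        "M": rec_out[:, K.REC_M],
        "M_resident": rec_out[:, K.REC_M0],
        "M_mutant": rec_out[:, K.REC_M1],
        "mean_phi": np.where(rec_out[:, K.REC_M] > 0,
                             rec_out[:, K.REC_PHISUM]
                             / np.maximum(rec_out[:, K.REC_M], 1), np.nan),
        "min_phi": rec_out[:, K.REC_PHIMIN],
        "max_phi": rec_out[:, K.REC_PHIMAX],
        "S_total": rec_out[:, K.REC_STOT],
        "cum_inputs": rec_out[:, K.REC_INPUTS],
        "cum_leaching": rec_out[:, K.REC_LEACH],
        "cum_respiration": rec_out[:, K.REC_RESP],
        "cum_leached_recycling": rec_out[:, K.REC_LEACHREC],
        "clip_residual": rec_out[:, K.REC_CLIP],
    }
    ledger = FlowLedger(
        inputs=float(rec_out[-1, K.REC_INPUTS]),
        leaching=float(rec_out[-1, K.REC_LEACH]),
        respiration=float(rec_out[-1, K.REC_RESP]),
        leached_recycling=float(rec_out[-1, K.REC_LEACHREC]),
        clip_residual=float(rec_out[-1, K.REC_CLIP]),
        n_clips=int(counters[K.CNT_CLIPS]))
    cdict = {
        "births": int(counters[K.CNT_BIRTHS]),
        "deaths": int(counters[K.CNT_DEATHS]),
        "disturbances": int(counters[K.CNT_DISTURB]),
        "dispersal_attempts": int(counters[K.CNT_DISP_ATT]),
        "dispersal_moves": int(counters[K.CNT_DISP_MOVE]),
        "mutations": int(counters[K.CNT_MUT]),
        "n_clips": int(counters[K.CNT_CLIPS]),
        "next_strain": int(next_strain_out),
    }
    extinct_at = counters[K.CNT_EXTINCT_AT]
    extinct = float(extinct_at) if extinct_at >= 0 else None
    acc_dur = counters[K.CNT_ACC_DUR]
    site_avg = {}
    if acc_dur > 0:
        site_avg = {"c": acc_c / acc_dur, "d": acc_d / acc_dur,
                    "z": acc_z / acc_dur, "duration": np.array([acc_dur])}
    final = _arrays_to_lattice(L, float(rec_out[-1, K.REC_T]),
                               c, d, z, phi, S, strain, M)
    return LatticeRun(traj, final, ledger, cdict, params, int(seed),
                      extinct, site_avg)
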