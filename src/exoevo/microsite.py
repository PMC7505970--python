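"""Hybrid stochastic-deterministic dynamics of a single microsite.

A microsite holds three continuous carbon pools — SOC ``c``, DOC ``d`` and
exoenzyme ``z`` — and a finite collection of individual cells.  Between
stochastic cell-death events the pools and the per-cell storage evolve
deterministically (a piecewise deterministic Markov process): cells take up
DOC at the Michaelis-Menten rate, allocate a fraction ``phi`` of assimilable
carbon to exoenzyme production and the rest to an internal reserve ``S``,
and divide deterministically once the reserve reaches one cell mass
``omega_M``.  Cell death is the only remaining jump process, with total rate
``d_M * M``.

The operations here are the plain-Python reference implementation of one
event-loop iteration; production-scale trajectories are generated by the
compiled kernel in :mod:`exoevo._kernel` (driven by
:func:`simulate_single_site` and the lattice module), which implements the
identical scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .evolution import StrainRegistry, mutate_trait
from .params import ParameterSet

__all__ = [
    "Cell",
    "MicrositeState",
    "FlowLedger",
    "draw_death_time",
    "integrate_flows",
    "apply_divisions",
    "apply_death",
    "simulate_single_site",
]


@dataclass
class Cell:
    """One microbial individual."""

    phi: float            # enzyme allocation fraction (heritable trait)
    S: float = 0.0        # stored reserve, mg carbon (division at omega_M)
    strain_id: int = 0


@dataclass
class MicrositeState:
    """Continuous pools plus the finite cell collection of one microsite."""

    c: float
    d: float
    z: float
    cells: list[Cell] = field(default_factory=list)

    @property
    def M(self) -> int:
        return len(self.cells)

    @property
    def phi_sum(self) -> float:
        return sum(cell.phi for cell in self.cells)

    def copy(self) -> "MicrositeState":
        return MicrositeState(self.c, self.d, self.z,
                              [Cell(x.phi, x.S, x.strain_id)
                               for x in self.cells])


@dataclass
class FlowLedger:
    """Cumulative carbon budget terms of a run, mg.

    ``clip_residual`` is the carbon discrepancy introduced by clipping a
    pool at zero (the flux limiter of the explicit Euler scheme); it is zero
    in well-resolved runs and bounds the closure error.
    """

    inputs: float = 0.0
    leaching: float = 0.0
    respiration: float = 0.0
    leached_recycling: float = 0.0
    clip_residual: float = 0.0
    n_clips: int = 0

    def add(self, other: "FlowLedger") -> None:
        self.inputs += other.inputs
        self.leaching += other.leaching
        self.respiration += other.respiration
        self.leached_recycling += other.leached_recycling
        self.clip_residual += other.clip_residual
        self.n_clips += other.n_clips


def draw_death_time(M_total: int, params: ParameterSet,
                    rng: np.random.Generator) -> float:
    """Waiting time (h) to the next death: Exp(d_M * M_total), inf if no
    cells."""
    if M_total < 0:
        raise ValueError("M_total must be >= 0")
    rate = params.d_M * M_total
    if rate <= 0:
        return math.inf
    return rng.exponential(1.0 / rate)


# Fraction of the local linearization timescale covered by one Euler
# sub-step; shared with the compiled kernel.
SUBSTEP_ETA = 0.05


def integrate_flows(site: MicrositeState, dt: float, params: ParameterSet,
                    phi_by_strain: Optional[dict[int, float]] = None,
                    ledger: Optional[FlowLedger] = None
                    ) -> dict[float, float]:
    """Advance c, d, z of ``site`` by ``dt`` hours with the cell count held
    fixed; return the storage increment Delta (mg) per trait value.

    The pools are integrated by an adaptive explicit Euler scheme whose
    sub-step is bounded by ``SUBSTEP_ETA`` times the fastest local
    linearization timescale; fluxes are clipped so no pool goes negative
    (clips are counted in ``ledger``).  Cells of trait phi accrue
    ``Delta(phi) = (1-phi) gamma_M omega_M * integral(u(d) dt)``; the
    increments are returned per distinct trait value but NOT yet applied to
    the cells (see :func:`apply_divisions`).

    ``phi_by_strain`` optionally overrides each cell's trait by its strain
    label (the cells' own phi values are used by default).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    p = params
    if phi_by_strain is None:
        phis = [cell.phi for cell in site.cells]
    else:
        phis = [phi_by_strain[cell.strain_id] for cell in site.cells]
    M = len(phis)
    phi_sum = float(sum(phis))

    c, d, z = site.c, site.d, site.z
    G = 0.0                       # integral of u(d) dt
    led = ledger if ledger is not None else FlowLedger()
    remaining = dt
    while remaining > 0:
        u1 = p.V_max * d / (p.K_m + d)
        dep = p.theta * z * c
        uptake = u1 * p.omega_M * M
        dc = p.I_C - p.l_C * c - dep
        dd = p.I_D - p.l_D * d + dep + (1 - p.l) * p.d_Z * z - uptake
        dz = p.gamma_Z * u1 * p.omega_M * phi_sum - p.d_Z * z
        # stiffness bound of the linearized pool dynamics
        J_d = p.l_D + p.V_max * p.omega_M * M * p.K_m / (p.K_m + d) ** 2
        J_c = p.l_C + p.theta * z
        J = max(J_d, J_c, p.d_Z, 1e-12)
        h = min(remaining, SUBSTEP_ETA / J)
        # budget terms use the same start-of-step rates as the pool update,
        # so carbon closure holds to roundoff (minus any clip residual)
        led.inputs += (p.I_C + p.I_D) * h
        led.leaching += (p.l_C * c + p.l_D * d) * h
        led.leached_recycling += p.l * p.d_Z * z * h
        led.respiration += u1 * p.omega_M * h * (
            M - p.gamma_M * (M - phi_sum) - p.gamma_Z * phi_sum)
        c_new, d_new, z_new = c + dc * h, d + dd * h, z + dz * h
        for v in (c_new, d_new, z_new):
            if v < 0:
                led.clip_residual += -v
                led.n_clips += 1
        c, d, z = max(c_new, 0.0), max(d_new, 0.0), max(z_new, 0.0)
        G += u1 * h
        remaining -= h
    site.c, site.d, site.z = c, d, z
    deltas: dict[float, float] = {}
    for phi in phis:
        deltas[phi] = (1 - phi) * p.gamma_M * p.omega_M * G
    return deltas


def apply_divisions(site: MicrositeState, delta, rng: np.random.Generator,
                    params: ParameterSet,
                    registry: Optional[StrainRegistry] = None,
                    time: float = 0.0) -> list[Cell]:
    """Add the storage increment to every cell and divide those whose
    reserve reaches one cell mass.

    ``delta`` is either a scalar increment (monomorphic site) or a mapping
    trait value -> increment as returned by :func:`integrate_flows`.  A
    dividing cell's excess reserve ``S + Delta - omega_M`` is split evenly
    between mother and newborn, which conserves carbon.  Newborns inherit
    the maternal trait subject to mutation; their placement is delegated to
    the lattice module.  Returns the newborn cells (mothers stay in place).
    """
    newborns: list[Cell] = []
    for cell in site.cells:
        inc = delta[cell.phi] if isinstance(delta, dict) else delta
        if inc < 0:
            raise ValueError("Delta must be >= 0")
        total = cell.S + inc
        if total >= params.omega_M:
            share = (total - params.omega_M) / 2.0
            cell.S = share
            phi_child = mutate_trait(cell.phi, params, rng)
            sid = cell.strain_id
            if phi_child != cell.phi:
                sid = (registry.register(phi_child, cell.strain_id, time)
                       if registry is not None else -1)
            newborns.append(Cell(phi_child, share, sid))
        else:
            cell.S = total
    return newborns


def apply_death(site: MicrositeState, rng: np.random.Generator,
                params: ParameterSet,
                ledger: Optional[FlowLedger] = None) -> Cell:
    """Remove one uniformly chosen cell and recycle its carbon locally.

    Of the victim's total carbon (structural mass plus stored reserve) a
    fraction ``l`` is leached; of the remainder a fraction ``p`` flows to
    SOC and ``1 - p`` to DOC.  Returns the removed cell.
    """
    if site.M == 0:
        raise ValueError("cannot apply death to an empty microsite")
    idx = int(rng.integers(site.M))
    victim = site.cells.pop(idx)
    carbon = params.omega_M + victim.S
    site.c += (1 - params.l) * params.p * carbon
    site.d += (1 - params.l) * (1 - params.p) * carbon
    if ledger is not None:
        ledger.leached_recycling += params.l * carbon
    return victim


def simulate_single_site(params: ParameterSet, phi0: float, T: float,
                         with_mutation: bool = False,
                         seed: int = 0,
                         rec_interval: Optional[float] = None,
                         initial: Optional[MicrositeState] = None):
    """Run the hybrid event loop for one isolated microsite.

    The site starts at the deterministic steady state for ``phi0`` (cell
    count rounded, reserves uniform in [0, omega_M)) unless ``initial`` is
    given.  Returns a :class:`exoevo.lattice.LatticeRun` whose trajectory
    columns record (t, c, d, z, M, mean/min/max phi) and the cumulative
    carbon budget.
    """
    from .lattice import LatticeState, simulate_lattice

    p = params.with_(L=1, phi=phi0,
                     p_mut=params.p_mut if with_mutation else 0.0)
    if with_mutation and p.p_mut <= 0:
        p = p.with_(p_mut=0.1)
    if initial is None:
        lattice = LatticeState.monomorphic_steady(p, phi0, seed=seed)
    else:
        lattice = LatticeState([[initial.copy()]], t=0.0)
    return simulate_lattice(lattice, p, T, seed=seed,
                            rec_interval=rec_interval)
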