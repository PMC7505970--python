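"""Deterministic four-compartment ("cdmz") approximation of a microsite.

In the limit of large system size the hybrid microsite dynamics reduce to a
system of four ODEs for SOC mass ``c``, DOC mass ``d``, cell biomass ``m``
and exoenzyme mass ``z`` (all mg of carbon per microsite):

    c' = I_C - l_C c - theta z c + (1-l) p d_M m
    d' = I_D - l_D d + theta z c + (1-l) d_Z z
         + (1-l)(1-p) d_M m - u(d) m
    m' = (1-phi) gamma_M u(d) m - d_M m
    z' = phi gamma_Z u(d) m - d_Z z

with the Michaelis-Menten uptake rate per unit biomass
``u(d) = V_max d / (K_m + d)``.  Dead biomass is recycled after leaching a
fraction ``l``: a fraction ``p`` to SOC, the rest to DOC; deactivated enzyme
carbon returns to DOC.  The carbon not fixed into biomass or enzyme,
``u m [1 - (1-phi) gamma_M - phi gamma_Z]``, is respired as CO2.

At the non-trivial equilibrium the DOC level has the closed form
``d* = K_m x / (1 - x)`` with ``x = d_M / ((1-phi) gamma_M V_max)``, because
the cell balance pins the per-biomass uptake saturation at ``x``.  Given
``d*``, the enzyme and SOC balances are linear in the remaining unknown
``m``, which is found by a bracketed scalar root find on the DOC balance.

This module also provides the adaptive-dynamics quantities of the well-mixed
(single microsite) system: the growth rate of a rare mutant with trait
``phi'`` in the resident's environment and the analytic selection gradient,
which is negative whenever DOC is present — in a well-mixed system enzyme
production is always selected against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from scipy.optimize import brentq

from .params import ParameterSet

__all__ = [
    "DeterministicState",
    "SteadyState",
    "cdmz_rhs",
    "uptake_rate",
    "steady_state",
    "mutant_growth_rate",
    "selection_gradient",
    "viability_threshold",
    "carbon_balance",
]


class DeterministicState(NamedTuple):
    """Compartment masses of one microsite, mg carbon."""

    c: float   # SOC
    d: float   # DOC
    m: float   # cell biomass
    z: float   # enzyme


@dataclass(frozen=True)
class SteadyState:
    """Equilibrium of the cdmz model.

    ``viable`` is False when no positive-biomass equilibrium exists, in which
    case ``state`` is the extinction equilibrium (m = z = 0).
    """

    state: DeterministicState
    phi: float
    viable: bool

    @property
    def cell_count(self) -> float:
        return self.state.m / self._omega_M

    # set post-construction by steady_state()
    _omega_M: float = 1e-9


def uptake_rate(d: float, params: ParameterSet) -> float:
    """Michaelis-Menten uptake rate per unit cell biomass, 1/h."""
    return params.V_max * d / (params.K_m + d)


def cdmz_rhs(state: DeterministicState, params: ParameterSet,
             phi: Optional[float] = None) -> DeterministicState:
    """Time derivative of the cdmz system at ``state``.

    ``phi`` defaults to ``params.phi``.  Raises ValueError on a negative
    component.
    """
    if phi is None:
        phi = params.phi
    c, d, m, z = state
    if min(c, d, m, z) < 0:
        raise ValueError(f"negative state component: {state}")
    p = params
    u = uptake_rate(d, p)
    dep = p.theta * z * c
    dc = p.I_C - p.l_C * c - dep + (1 - p.l) * p.p * p.d_M * m
    dd = (p.I_D - p.l_D * d + dep + (1 - p.l) * p.d_Z * z
          + (1 - p.l) * (1 - p.p) * p.d_M * m - u * m)
    dm = (1 - phi) * p.gamma_M * u * m - p.d_M * m
    dz = phi * p.gamma_Z * u * m - p.d_Z * z
    return DeterministicState(dc, dd, dm, dz)


def _extinction_equilibrium(params: ParameterSet, phi: float) -> SteadyState:
    c0 = params.I_C / params.l_C if params.l_C > 0 else math.inf
    d0 = params.I_D / params.l_D if params.l_D > 0 else (
        math.inf if params.I_D > 0 else 0.0)
    return SteadyState(DeterministicState(c0, d0, 0.0, 0.0), phi, False,
                       params.omega_M)


def steady_state(params: ParameterSet, phi: Optional[float] = None,
                 rtol: float = 1e-12) -> SteadyState:
    """Non-trivial equilibrium of the cdmz model, or the extinction
    equilibrium flagged ``viable=False`` when none exists.

    The residual of :func:`cdmz_rhs` at a viable equilibrium is below
    ``rtol`` relative to the gross fluxes.
    """
    if phi is None:
        phi = params.phi
    p = params
    denom = (1 - phi) * p.gamma_M * p.V_max
    if denom <= 0:
        return _extinction_equilibrium(p, phi)
    x = p.d_M / denom
    if x >= 1:
        return _extinction_equilibrium(p, phi)
    dstar = p.K_m * x / (1 - x)
    u1 = p.V_max * x                       # uptake per unit biomass at d*
    zeta = phi * p.gamma_Z * u1 / p.d_Z    # z* = zeta * m

    def doc_balance(m: float) -> float:
        z = zeta * m
        c = ((p.I_C + (1 - p.l) * p.p * p.d_M * m)
             / (p.l_C + p.theta * z)) if (p.l_C + p.theta * z) > 0 else 0.0
        return (p.I_D - p.l_D * dstar + p.theta * z * c
                + (1 - p.l) * p.d_Z * z
                + (1 - p.l) * (1 - p.p) * p.d_M * m - u1 * m)

    # The balance can have a spurious near-zero root below the positive
    # equilibrium; take the largest (+ -> -) sign change on a log grid.
    ms = np.logspace(math.log10(p.omega_M) - 8, math.log10(p.omega_M) + 8, 600)
    fs = np.array([doc_balance(m) for m in ms])
    root = None
    for i in range(len(ms) - 1, 0, -1):
        if fs[i - 1] > 0 >= fs[i]:
            # biomass is O(1e-9) mg, so the absolute xtol must be far below
            # the default
            root = brentq(doc_balance, ms[i - 1], ms[i],
                          xtol=1e-30, rtol=8.9e-16)
            break
    if root is None or root <= 0:
        return _extinction_equilibrium(p, phi)
    m = root
    z = zeta * m
    c = (p.I_C + (1 - p.l) * p.p * p.d_M * m) / (p.l_C + p.theta * z)
    st = DeterministicState(c, dstar, m, z)
    resid = cdmz_rhs(st, p, phi)
    scale = max(p.I_C + p.I_D, u1 * m, 1e-300)
    if max(abs(r) for r in resid) > rtol * scale:
        raise RuntimeError(f"steady-state residual too large: {resid}")
    return SteadyState(st, phi, True, p.omega_M)


def mutant_growth_rate(phi_mut: float, d_resident: float,
                       params: ParameterSet) -> float:
    """Growth rate (1/h) of a rare mutant with trait ``phi_mut`` at the
    resident-set DOC level ``d_resident``."""
    if d_resident < 0:
        raise ValueError("d_resident must be >= 0")
    return ((1 - phi_mut) * params.gamma_M
            * uptake_rate(d_resident, params) - params.d_M)


def selection_gradient(phi: float, params: ParameterSet,
                       d: Optional[float] = None) -> float:
    """Derivative of the mutant growth rate in the mutant trait, at the
    resident equilibrium: ``-gamma_M V_max d* / (K_m + d*)``.

    ``d`` overrides the equilibrium DOC level (useful for the limits d -> 0
    and d -> inf); by default it is taken from :func:`steady_state` at the
    resident trait ``phi``.
    """
    if d is None:
        ss = steady_state(params, phi)
        if not ss.viable:
            raise ValueError(f"no resident equilibrium at phi = {phi}")
        d = ss.state.d
    if math.isinf(d):
        return -params.gamma_M * params.V_max
    return -params.gamma_M * uptake_rate(d, params)


def viability_threshold(params: ParameterSet,
                        n_grid: int = 201, tol: float = 1e-6
                        ) -> Optional[tuple[float, float]]:
    """Interval of phi over which a positive equilibrium exists.

    Determined by scanning a phi grid for viability and bisecting each edge.
    Returns ``None`` when no grid point is viable.
    """
    grid = np.linspace(0.0, 1.0, n_grid)
    viable = np.array([steady_state(params, ph).viable for ph in grid])
    if not viable.any():
        return None

    def _is_viable(ph: float) -> bool:
        return steady_state(params, ph).viable

    def _bisect(lo: float, hi: float, lo_viable: bool) -> float:
        # invariant: viability differs between lo and hi
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if _is_viable(mid) == lo_viable:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    idx = np.where(viable)[0]
    i0, i1 = idx[0], idx[-1]
    lower = grid[i0] if i0 == 0 else _bisect(grid[i0 - 1], grid[i0], False)
    upper = grid[i1] if i1 == n_grid - 1 else _bisect(grid[i1], grid[i1 + 1],
                                                      True)
    return (lower, upper)


def carbon_balance(state: DeterministicState, params: ParameterSet,
                   phi: Optional[float] = None) -> dict[str, float]:
    """Instantaneous carbon budget terms (mg/h) at ``state``.

    At a steady state ``inputs`` equals ``leaching + respiration +
    leached_recycling`` to float tolerance (carbon closure).
    """
    if phi is None:
        phi = params.phi
    p = params
    c, d, m, z = state
    u = uptake_rate(d, p) * m
    return {
        "inputs": p.I_C + p.I_D,
        "leaching": p.l_C * c + p.l_D * d,
        "respiration": u * (1 - (1 - phi) * p.gamma_M - phi * p.gamma_Z),
        "leached_recycling": p.l * (p.d_M * m + p.d_Z * z),
    }
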