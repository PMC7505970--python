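"""Model parameters, consistency checks, and system-size rescaling.

All quantities are in mg of carbon and hours.  A *microsite* is a well-mixed
soil volume ``k * V`` where ``V`` is the unit soil volume expected to hold a
single microbial cell; ``k`` (the system size) therefore sets how many cells
share one local pool of SOC, DOC and exoenzymes, and controls how stochastic
the local dynamics are.

Four parameters depend on the microsite volume: the external inputs ``I_C``
and ``I_D`` and the uptake half-saturation ``K_m`` scale proportionally with
``k``, while the encounter-rate factor carried by ``theta`` scales inversely
with ``k``.  The published default table lists these four at unit volume
(k = 1); :meth:`ParameterSet.defaults` rescales them to the requested system
size so that the fields of a :class:`ParameterSet` are always the values that
enter the microsite-level equations at that set's own ``k``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

__all__ = [
    "ParameterSet",
    "ParameterError",
    "validate",
    "rescale_for_system_size",
    "UNIT_VOLUME_DEFAULTS",
]


class ParameterError(ValueError):
    """Raised when a parameter set violates one or more invariants.

    ``errors`` holds one human-readable message per violated invariant.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


#: Default values at unit volume (k = 1).  Volume-dependent entries
#: (I_C, I_D, K_m, theta) are rescaled by ``ParameterSet.defaults``.
UNIT_VOLUME_DEFAULTS: dict[str, float] = {
    "V": 1e-9,           # cm^3, unit soil volume of one cell
    "k": 1.0,            # system size (unit volumes per microsite)
    "L": 10,             # lattice side length, microsites
    "phi": 0.5,          # enzyme allocation fraction (evolving trait)
    "gamma_M": 0.3,      # microbial carbon production fraction (MGE)
    "gamma_Z": 0.4,      # enzyme carbon production fraction
    "omega_M": 1e-9,     # mg, carbon mass of one cell
    "omega_Z": 1e-16,    # mg, carbon mass of one enzyme molecule
    "omega_C": 1e-16,    # mg, carbon mass of one SOC molecule
    "omega_D": 1e-19,    # mg, carbon mass of one DOC molecule
    "alpha": 1e10,       # structural cost of one cell, DOC molecules
    "alpha_prime": 2.33e10,  # energetic cost of one cell, DOC molecules
    "beta": 1e3,         # structural cost of one SOC molecule, DOC molecules
    "rho": 1e3,          # structural cost of one enzyme molecule
    "rho_prime": 1.5e3,  # energetic cost of one enzyme molecule
    "d_M": 2e-4,         # 1/h, cell death rate
    "d_Z": 2e-3,         # 1/h, enzyme deactivation rate
    "V_max": 0.42,       # 1/h, maximum uptake rate
    "theta": 7e5,        # 1/(mg h), encounter probability x decomposition rate
    "K_m": 3e-10,        # mg, uptake half-saturation
    "I_C": 5e-13,        # mg/h, external SOC input
    "I_D": 0.0,          # mg/h, external DOC input
    "l_C": 1e-6,         # 1/h, SOC leaching rate
    "l_D": 1e-6,         # 1/h, DOC leaching rate
    "l": 0.0,            # leached fraction of dead-cell / deactivated-enzyme C
    "p": 0.5,            # fraction of recycled dead-cell carbon going to SOC
    "T_max": 1e6,        # h, simulation horizon
    "p_disp": 0.3,       # newborn dispersal probability
    "p_open": 0.01,      # micro-disturbance probability
    "p_mut": 0.0,        # mutation probability per division
    "sigma_mut": 0.05,   # trait units, mutation-effect standard deviation
    "sigma_diff": 5e-6,  # DOC diffusion coefficient (enters the update rule)
    "tau_diff": None,    # h, diffusion time step; None = auto (stability bound)
}

_FRACTION_FIELDS = ("phi", "l", "p", "p_disp", "p_open", "p_mut")
_NONNEGATIVE_FIELDS = (
    "V", "gamma_M", "gamma_Z", "omega_M", "omega_Z", "omega_C", "omega_D",
    "alpha", "alpha_prime", "beta", "rho", "rho_prime", "d_M", "d_Z",
    "V_max", "theta", "K_m", "I_C", "I_D", "l_C", "l_D", "T_max",
    "sigma_mut", "sigma_diff",
)
# Volume-dependent parameters and their scaling exponent in k.
_K_SCALING = {"I_C": 1, "I_D": 1, "K_m": 1, "theta": -1}


@dataclass(frozen=True)
class ParameterSet:
    """All model symbols, at the microsite level for this set's own ``k``."""

    V: float
    k: float
    L: int
    phi: float
    gamma_M: float
    gamma_Z: float
    omega_M: float
    omega_Z: float
    omega_C: float
    omega_D: float
    alpha: float
    alpha_prime: float
    beta: float
    rho: float
    rho_prime: float
    d_M: float
    d_Z: float
    V_max: float
    theta: float
    K_m: float
    I_C: float
    I_D: float
    l_C: float
    l_D: float
    l: float
    p: float
    T_max: float
    p_disp: float
    p_open: float
    p_mut: float
    sigma_mut: float
    sigma_diff: float
    tau_diff: Optional[float] = None

    @classmethod
    def defaults(cls, k: float = 10.0, **overrides) -> "ParameterSet":
        """Default parameter set rescaled to system size ``k``.

        Keyword overrides are applied *after* rescaling, so e.g.
        ``defaults(k=10, sigma_diff=1e-7)`` gives the standard microsite
        set with a different diffusion coefficient.
        """
        vals = dict(UNIT_VOLUME_DEFAULTS)
        base = cls(**vals)
        scaled = rescale_for_system_size(base, k)
        if overrides:
            scaled = replace(scaled, **overrides)
        return validate(scaled)

    def with_(self, **overrides) -> "ParameterSet":
        """Copy with some fields replaced (no re-validation)."""
        return replace(self, **overrides)

    @property
    def microsite_volume(self) -> float:
        """Volume of one microsite, cm^3."""
        return self.k * self.V

    @property
    def site_length_sq(self) -> float:
        """Squared inter-site distance (Vk)^(2/3) used by the diffusion
        update."""
        return self.microsite_volume ** (2.0 / 3.0)

    def resolve_tau_diff(self) -> float:
        """Diffusion time step actually used.

        When ``tau_diff`` is None an automatic value is chosen: at most 1 h,
        and small enough that the explicit diffusion update factor satisfies
        4 * sigma_diff * tau / (Vk)^(2/3) <= 0.5, half the stability bound.
        """
        if self.tau_diff is not None:
            return float(self.tau_diff)
        if self.sigma_diff <= 0:
            return 1.0
        bound = self.site_length_sq / (8.0 * self.sigma_diff)
        return min(1.0, bound)


def validate(params: ParameterSet) -> ParameterSet:
    """Check every invariant; return ``params`` unchanged if all hold.

    Range violations (a fraction outside [0, 1], a negative rate or mass)
    and mass-consistency failures (the cost/production-fraction relations)
    are reported as distinct errors, one message per violated invariant.
    """
    errors: list[str] = []
    for name in _FRACTION_FIELDS:
        v = getattr(params, name)
        if not (0.0 <= v <= 1.0):
            errors.append(f"range: {name} = {v!r} outside [0, 1]")
    for name in _NONNEGATIVE_FIELDS:
        v = getattr(params, name)
        if v < 0.0:
            errors.append(f"range: {name} = {v!r} must be >= 0")
    if params.k < 1:
        errors.append(f"range: k = {params.k!r} must be >= 1")
    if params.L < 1:
        errors.append(f"range: L = {params.L!r} must be >= 1")
    if params.tau_diff is not None and params.tau_diff <= 0:
        errors.append(f"range: tau_diff = {params.tau_diff!r} must be > 0")

    # Mass-consistency relations between per-entity costs (in DOC molecules)
    # and the production fractions / molecular masses.  The published
    # energetic cell cost is printed to 3 significant digits, so these are
    # checked to 1% relative tolerance.
    def _consistent(lhs, rhs):
        return math.isclose(lhs, rhs, rel_tol=1e-2)

    if not _consistent(params.gamma_M,
                       params.omega_M / ((params.alpha + params.alpha_prime)
                                         * params.omega_D)):
        errors.append(
            "mass-consistency: gamma_M != omega_M / ((alpha + alpha') * omega_D)")
    if not _consistent(params.gamma_Z,
                       params.omega_Z / ((params.rho + params.rho_prime)
                                         * params.omega_D)):
        errors.append(
            "mass-consistency: gamma_Z != omega_Z / ((rho + rho') * omega_D)")
    if not _consistent(params.omega_C, params.beta * params.omega_D):
        errors.append("mass-consistency: omega_C != beta * omega_D")

    if errors:
        raise ParameterError(errors)
    return params


def rescale_for_system_size(params: ParameterSet, k_new: float) -> ParameterSet:
    """Rescale the volume-dependent parameters to a new system size.

    ``I_C``, ``I_D`` and ``K_m`` scale proportionally with ``k`` and the
    encounter factor carried by ``theta`` scales inversely, relative to the
    set's current ``k``; everything else is unchanged.  Round-trip rescaling
    recovers the original set to float tolerance.
    """
    if k_new < 1:
        raise ParameterError([f"range: k_new = {k_new!r} must be >= 1"])
    ratio = float(k_new) / float(params.k)
    changes = {name: getattr(params, name) * ratio ** expo
               for name, expo in _K_SCALING.items()}
    changes["k"] = float(k_new)
    return replace(params, **changes)
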