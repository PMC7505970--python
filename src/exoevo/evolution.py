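"""Trait mutation at cell division and strain bookkeeping.

The evolving trait is the exoenzyme allocation fraction phi.  At each
division the daughter inherits the maternal trait, except with probability
``p_mut`` a mutation draws the new trait from a normal distribution centred
on the maternal value with standard deviation ``sigma_mut``.  Draws outside
[0, 1] are rejected and redrawn rather than clipped, so the boundary values
never acquire probability atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ParameterSet

__all__ = ["mutate_trait", "StrainRegistry", "StrainRecord"]


def mutate_trait(phi_parent: float, params: ParameterSet,
                 rng: np.random.Generator) -> float:
    """Trait value of a daughter cell.

    Returns ``phi_parent`` unchanged with probability ``1 - p_mut``;
    otherwise a Normal(phi_parent, sigma_mut^2) draw resampled until it
    falls inside [0, 1].
    """
    if not (0.0 <= phi_parent <= 1.0):
        raise ValueError(f"phi_parent = {phi_parent!r} outside [0, 1]")
    if params.p_mut <= 0.0 or rng.random() >= params.p_mut:
        return phi_parent
    while True:
        phi = rng.normal(phi_parent, params.sigma_mut)
        if 0.0 <= phi <= 1.0:
            return phi


@dataclass(frozen=True)
class StrainRecord:
    strain_id: int
    phi: float
    parent: int          # -1 for founding strains
    founded_at: float    # h


@dataclass
class StrainRegistry:
    """Maps strain ids to founding trait value, parent strain and time."""

    records: dict[int, StrainRecord] = field(default_factory=dict)

    def register(self, phi: float, parent: int = -1,
                 time: float = 0.0) -> int:
        sid = len(self.records)
        self.records[sid] = StrainRecord(sid, phi, parent, time)
        return sid

    def __contains__(self, sid: int) -> bool:
        return sid in self.records

    def __getitem__(self, sid: int) -> StrainRecord:
        return self.records[sid]

    def __len__(self) -> int:
        return len(self.records)
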