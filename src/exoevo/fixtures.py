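"""Deterministic generators of test lattice states."""

from __future__ import annotations

from typing import Optional

import numpy as np

from .deterministic import steady_state
from .lattice import LatticeState
from .microsite import MicrositeState
from .params import ParameterSet

__all__ = ["make_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("steady-monomorphic", "empty", "doc-spike",
                 "two-strain-split")


def make_fixture(kind: str, params: ParameterSet,
                 rng: Optional[np.random.Generator] = None,
                 phi: Optional[float] = None,
                 doc_total: Optional[float] = None) -> LatticeState:
    """Build one of the standard test lattices.

    - ``steady-monomorphic``: every site at the deterministic equilibrium
      for ``phi`` (default ``params.phi``).
    - ``empty``: no cells, all pools zero.
    - ``doc-spike``: empty lattice with all DOC (``doc_total``, default the
      equilibrium DOC times the site count) in the single central site.
    - ``two-strain-split``: steady-state sites; strain 0 with trait ``phi``
      in the left half of the columns, strain 1 with ``phi`` in the right.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    L = params.L
    if phi is None:
        phi = params.phi

    if kind == "steady-monomorphic":
        return LatticeState.monomorphic_steady(params, phi, rng=rng)

    if kind == "empty":
        grid = [[MicrositeState(0.0, 0.0, 0.0) for _ in range(L)]
                for _ in range(L)]
        return LatticeState(grid)

    if kind == "doc-spike":
        if doc_total is None:
            ss = steady_state(params, phi)
            doc_total = ss.state.d * L * L
        lattice = make_fixture("empty", params, rng)
        lattice.grid[L // 2][L // 2].d = doc_total
        return lattice

    if kind == "two-strain-split":
        lattice = LatticeState.monomorphic_steady(params, phi, rng=rng,
                                                  strain_id=0)
        for i in range(L):
            for j in range(L // 2, L):
                for cell in lattice.grid[i][j].cells:
                    cell.strain_id = 1
        return lattice

    raise ValueError(f"unknown fixture kind {kind!r}; "
                     f"expected one of {FIXTURE_KINDS}")
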