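"""Stepwise (square-well) pair potentials.

A :class:`SquareWellPotential` is a radial potential reduced to a staircase:
an infinite hard core inside the innermost boundary, a constant energy in
each shell between consecutive boundaries, and zero beyond the outermost
boundary. Particles interacting through such potentials move ballistically
between boundary crossings, which is what makes event-driven dynamics exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from ._kernels import WALL

__all__ = ["SquareWellPotential", "discretize_potential"]


@dataclass(frozen=True)
class SquareWellPotential:
    """Hard core + square wells.

    ``boundaries`` are strictly ascending distances (Å); ``well_energies``
    holds one energy (kcal/mol) per shell *between* consecutive boundaries,
    so it has ``len(boundaries) - 1`` entries. The shell beyond the last
    boundary has energy zero and the innermost boundary is a hard core.
    """

    boundaries: tuple[float, ...]
    well_energies: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.size == 0:
            raise ValueError("need at least one boundary (the hard core)")
        if np.any(b <= 0) or np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be positive and strictly ascending")
        if len(self.well_energies) != len(self.boundaries) - 1:
            raise ValueError("need one well energy per inter-boundary shell")
        if not np.all(np.isfinite(self.well_energies)):
            raise ValueError("well energies must be finite")

    def levels(self) -> np.ndarray:
        """Energy per shell, index 0 = inside the hard core (forbidden)."""
        return np.array([WALL, *self.well_energies, 0.0])

    def energy(self, r: float) -> float:
        """Potential energy at separation r (inf inside the hard core)."""
        shell = int(np.searchsorted(self.boundaries, r))
        if shell == 0:
            return np.inf
        lev = self.levels()
        return float(lev[shell])


def discretize_potential(
    potential: Callable[[float], float],
    boundaries: Sequence[float],
) -> SquareWellPotential:
    """Reduce a continuous radial potential to square wells.

    Each inter-boundary shell gets the continuous potential evaluated at the
    shell midpoint; the innermost boundary becomes a hard core and the
    outermost shell is forced to zero.
    """
    b = np.asarray(boundaries, dtype=float)
    if b.size == 0 or np.any(np.diff(b) <= 0):
        raise ValueError("boundaries must be non-empty and strictly ascending")
    mids = 0.5 * (b[:-1] + b[1:])
    energies = np.array([float(potential(m)) for m in mids])
    if not np.all(np.isfinite(energies)):
        raise ValueError("potential is not finite at a shell midpoint")
    return SquareWellPotential(tuple(b), tuple(energies))
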