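"""Event-driven discrete molecular dynamics of coarse backbone chains.

The chain is three beads per residue (N, Cα, C) connected by narrow
square-well bonds; 1-3 (pseudo-angle) wells keep bond angles near standard
backbone geometry, and nonbonded pairs interact through a hard core plus a
single attractive square well whose depth depends on residue identity
(glutamine Cα pairs attract more strongly than the generic backbone). This
deliberately simple force field produces a coil–globule collapse transition
while keeping every part of the analysis pipeline exercisable at desk scale.

Between collisions beads travel ballistically; at a potential boundary the
two colliding beads exchange an impulse along their separation vector, which
conserves linear momentum, angular momentum about the pair midpoint, and
total energy. An Andersen-style thermostat (random ghost collisions that
redraw one bead's velocity from the Maxwell–Boltzmann distribution) holds
the system at the requested temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from ._kernels import WALL
from .constructs import ConstructModel
from .geometry import ANGLE13_DISTANCES, BOND_LENGTHS, extended_backbone
from .potentials import SquareWellPotential

__all__ = [
    "ForceField",
    "ChainSystem",
    "DMDSimulation",
    "Trajectory",
    "run_dmd",
    "radius_of_gyration",
    "next_pair_event",
    "resolve_collision",
    "DEFAULT_EQUILIBRATION_TU",
    "DEFAULT_SAVE_INTERVAL_TU",
]

DEFAULT_EQUILIBRATION_TU = 500.0
DEFAULT_SAVE_INTERVAL_TU = 10.0

#: United-atom backbone masses (amu): N(H), Cα(H + lumped side chain), C(=O).
UNITED_MASSES = (15.0, 13.0, 28.0)


@dataclass(frozen=True)
class ForceField:
    """Parameters of the square-well backbone force field.

    Energies are kcal/mol, distances Å. ``eps_qq`` is the well depth between
    glutamine Cα beads, ``eps_bb`` the generic nonbonded depth; both wells
    span from the hard core to ``well_outer``.
    """

    hardcore: float = 2.0
    well_outer: float = 4.5
    eps_qq: float = 1.5
    eps_bb: float = 0.1
    bond_tol: float = 0.03
    angle_tol: float = 0.10
    thermostat_rate: float = 1.0   # ghost collisions per bead per tu
    uniform_mass: bool = True      # False: united-atom N/Cα/C masses
    box_factor: float = 1.2


@dataclass
class ChainSystem:
    """Topology + interaction tables for one simulated chain."""

    n_residues: int
    sequence: str
    mass: np.ndarray
    box_edge: float
    pair_pot: np.ndarray
    pot_bounds: np.ndarray
    pot_nb: np.ndarray
    pot_levels: np.ndarray
    forcefield: ForceField
    label: str = "chain"

    @property
    def n_beads(self) -> int:
        return 3 * self.n_residues

    @classmethod
    def from_model(cls, model: ConstructModel,
                   forcefield: ForceField | None = None) -> "ChainSystem":
        return cls.from_sequence(model.sequence, forcefield, label=model.name)

    @classmethod
    def from_sequence(cls, sequence: str,
                      forcefield: ForceField | None = None,
                      label: str | None = None) -> "ChainSystem":
        ff = forcefield or ForceField()
        n = len(sequence)
        if n < 1:
            raise ValueError("empty sequence")
        nb = 3 * n

        # Potential table. 0-2: bonds, 3-5: 1-3 wells, 6: generic nonbonded,
        # 7: Gln-Gln Cα attraction. Levels: shell 0 is inside the innermost
        # boundary (forbidden for every type).
        pots: list[tuple[np.ndarray, np.ndarray]] = []
        for d in BOND_LENGTHS:
            pots.append((np.array([d - ff.bond_tol, d + ff.bond_tol]),
                         np.array([WALL, 0.0, WALL])))
        for d in ANGLE13_DISTANCES:
            pots.append((np.array([d - ff.angle_tol, d + ff.angle_tol]),
                         np.array([WALL, 0.0, WALL])))
        pots.append((np.array([ff.hardcore, ff.well_outer]),
                     np.array([WALL, -ff.eps_bb, 0.0])))
        pots.append((np.array([ff.hardcore, ff.well_outer]),
                     np.array([WALL, -ff.eps_qq, 0.0])))

        maxb = max(len(b) for b, _ in pots)
        pot_bounds = np.zeros((len(pots), maxb))
        pot_nb = np.zeros(len(pots), dtype=np.int64)
        pot_levels = np.full((len(pots), maxb + 1), WALL)
        for p, (b, lev) in enumerate(pots):
            pot_bounds[p, : len(b)] = b
            pot_nb[p] = len(b)
            pot_levels[p, : len(lev)] = lev

        is_q_ca = np.zeros(nb, dtype=bool)
        for i, aa in enumerate(sequence):
            if aa == "Q":
                is_q_ca[3 * i + 1] = True

        pair_pot = np.full((nb, nb), 6, dtype=np.int16)
        for i in range(nb):
            for j in range(i + 1, nb):
                sep = j - i
                if sep == 1:
                    p = i % 3
                elif sep == 2:
                    p = 3 + i % 3
                elif is_q_ca[i] and is_q_ca[j]:
                    p = 7
                else:
                    p = 6
                pair_pot[i, j] = p
                pair_pot[j, i] = p

        if ff.uniform_mass:
            mass = np.ones(nb)
        else:
            mass = np.array([UNITED_MASSES[k % 3] for k in range(nb)])

        contour = float(np.sum(BOND_LENGTHS + ff.bond_tol)) * n
        box_edge = max(ff.box_factor * contour, 3.0 * ff.well_outer)
        return cls(n, sequence, mass, box_edge, pair_pot, pot_bounds,
                   pot_nb, pot_levels, ff, label or f"chain{n}")


@dataclass
class Trajectory:
    """Saved conformations and energy series of one constant-T run."""

    times: np.ndarray                 # (F,), tu
    positions: np.ndarray             # (F, n_beads, 3), Å, unwrapped
    potential: np.ndarray             # (F,), kcal/mol
    kinetic: np.ndarray               # (F,), kcal/mol
    rg: np.ndarray                    # (F,), Å
    temperature: float
    label: str = ""
    seed: int | None = None
    equilibration_tu: float = DEFAULT_EQUILIBRATION_TU

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def analysis_mask(self) -> np.ndarray:
        """Frames past the initial equilibration discard."""
        return self.times > self.equilibration_tu

    def analysis_frames(self) -> "Trajectory":
        m = self.analysis_mask
        return replace(self, times=self.times[m], positions=self.positions[m],
                       potential=self.potential[m], kinetic=self.kinetic[m],
                       rg=self.rg[m])


def radius_of_gyration(positions: np.ndarray,
                       masses: np.ndarray | None = None) -> np.ndarray | float:
    """Mass-weighted radius of gyration of a frame or a stack of frames.

    ``positions`` is (n, 3) or (F, n, 3) of unwrapped coordinates.
    """
    pos = np.asarray(positions, dtype=float)
    single = pos.ndim == 2
    if single:
        pos = pos[None]
    if pos.shape[1] == 0:
        raise ValueError("empty frame")
    if masses is None:
        masses = np.ones(pos.shape[1])
    w = masses / masses.sum()
    com = np.einsum("j,fjx->fx", w, pos)
    d2 = np.sum((pos - com[:, None, :]) ** 2, axis=2)
    rg = np.sqrt(np.einsum("j,fj->f", w, d2))
    return float(rg[0]) if single else rg


class DMDSimulation:
    """A persistent event-driven simulation that can be advanced in segments.

    Segment-wise advancement is what replica exchange needs: between swap
    attempts each replica's simulation continues from its exact state, and a
    swap only rescales velocities.
    """

    def __init__(self, system: ChainSystem, temperature: float,
                 seed: int | np.random.SeedSequence = 0,
                 thermostat: bool = True,
                 save_interval: float = DEFAULT_SAVE_INTERVAL_TU,
                 start_positions: np.ndarray | None = None):
        if temperature <= 0:
            raise ValueError("temperature must be positive")
        self.system = system
        self.temperature = float(temperature)
        self.thermostat = thermostat
        self.save_interval = float(save_interval)
        ss = (seed if isinstance(seed, np.random.SeedSequence)
              else np.random.SeedSequence(seed))
        self._seedseq = ss
        self._rng = np.random.default_rng(ss.spawn(1)[0])

        nb = system.n_beads
        if start_positions is None:
            pos = extended_backbone(system.n_residues)
        else:
            pos = np.array(start_positions, dtype=float)
            if pos.shape != (nb, 3):
                raise ValueError("start_positions shape mismatch")
        extent = pos.max(axis=0) - pos.min(axis=0)
        if np.any(extent >= system.box_edge):
            raise ValueError("box smaller than the starting conformation")
        self.pos = pos - pos.mean(axis=0) + system.box_edge / 2.0
        self.vel = self._maxwell_boltzmann()
        self.tlast = np.zeros(nb)
        self.t = 0.0
        self.shell = np.zeros((nb, nb), dtype=np.int8)
        _kernels.init_shells(self.pos, system.box_edge, system.pair_pot,
                             system.pot_bounds, system.pot_nb, self.shell)
        if _kernels.potential_energy(system.pair_pot, system.pot_levels,
                                     self.shell) >= 0.5 * WALL:
            raise ValueError("starting conformation violates a hard wall")
        self._next_sample = self.save_interval
        self.n_collisions = 0
        # frame accumulators
        self._ft: list[np.ndarray] = []
        self._fp: list[np.ndarray] = []
        self._fpe: list[np.ndarray] = []
        self._fke: list[np.ndarray] = []

    def _maxwell_boltzmann(self) -> np.ndarray:
        m = self.system.mass
        v = self._rng.normal(size=(len(m), 3)) * np.sqrt(self.temperature / m)[:, None]
        v -= (m[:, None] * v).sum(axis=0) / m.sum()   # zero total momentum
        return v

    def potential_energy(self) -> float:
        return float(_kernels.potential_energy(
            self.system.pair_pot, self.system.pot_levels, self.shell))

    def kinetic_energy(self) -> float:
        return float(_kernels.kinetic_energy(self.vel, self.system.mass))

    def total_energy(self) -> float:
        return self.potential_energy() + self.kinetic_energy()

    def set_temperature(self, temperature: float, rescale: bool = True) -> None:
        """Swap in a new thermostat temperature, rescaling velocities."""
        if temperature <= 0:
            raise ValueError("temperature must be positive")
        if rescale:
            self.vel *= np.sqrt(temperature / self.temperature)
        self.temperature = float(temperature)

    def advance(self, duration: float, max_events: int = 2_000_000_000) -> None:
        """Advance by ``duration`` tu, accumulating frames every save interval."""
        if duration < 0:
            raise ValueError("duration must be non-negative")
        if duration == 0:
            return
        sys_ = self.system
        t_end = self.t + duration
        n_max = int((t_end - self._next_sample) // self.save_interval) + 2
        n_max = max(n_max, 1)
        fpos = np.empty((n_max, sys_.n_beads, 3))
        ft = np.empty(n_max)
        fpe = np.empty(n_max)
        fke = np.empty(n_max)
        seed = int(self._rng.integers(0, 2**31 - 1))
        rate = sys_.forcefield.thermostat_rate if self.thermostat else 0.0
        ncoll, nframes, next_sample, status = _kernels.run_segment(
            self.pos, self.vel, self.tlast, sys_.mass, self.t, t_end,
            sys_.box_edge, sys_.pair_pot, sys_.pot_bounds, sys_.pot_nb,
            sys_.pot_levels, self.shell,
            self.temperature, rate,
            self.save_interval, self._next_sample,
            fpos, ft, fpe, fke, 0, seed, max_events)
        if status == 1:
            raise RuntimeError("event budget exhausted before segment end")
        if status == 2:
            raise RuntimeError("inconsistent collision state (corrupted run)")
        self.t = t_end
        self._next_sample = next_sample
        self.n_collisions += int(ncoll)
        if nframes:
            self._ft.append(ft[:nframes].copy())
            self._fp.append(fpos[:nframes].copy())
            self._fpe.append(fpe[:nframes].copy())
            self._fke.append(fke[:nframes].copy())

    def trajectory(self, equilibration_tu: float = DEFAULT_EQUILIBRATION_TU,
                   seed: int | None = None) -> Trajectory:
        """Collect all accumulated frames into a :class:`Trajectory`."""
        if self._ft:
            times = np.concatenate(self._ft)
            positions = np.concatenate(self._fp)
            pe = np.concatenate(self._fpe)
            ke = np.concatenate(self._fke)
        else:
            nb = self.system.n_beads
            times = np.empty(0)
            positions = np.empty((0, nb, 3))
            pe = np.empty(0)
            ke = np.empty(0)
        rg = (radius_of_gyration(positions, self.system.mass)
              if len(times) else np.empty(0))
        return Trajectory(times, positions, pe, ke, np.asarray(rg),
                          self.temperature, label=self.system.label,
                          seed=seed, equilibration_tu=equilibration_tu)


def run_dmd(model: ConstructModel | ChainSystem, temperature: float,
            duration: float, save_interval: float = DEFAULT_SAVE_INTERVAL_TU,
            seed: int = 0, forcefield: ForceField | None = None,
            thermostat: bool = True,
            equilibration_tu: float = DEFAULT_EQUILIBRATION_TU) -> Trajectory:
    """Run a single constant-temperature DMD trajectory.

    The chain starts fully extended; frames are saved every
    ``save_interval`` tu and the first ``equilibration_tu`` are flagged as
    equilibration (excluded by ``Trajectory.analysis_frames``).
    """
    system = (model if isinstance(model, ChainSystem)
              else ChainSystem.from_model(model, forcefield))
    sim = DMDSimulation(system, temperature, seed=seed, thermostat=thermostat,
                        save_interval=save_interval)
    sim.advance(duration)
    return sim.trajectory(equilibration_tu=equilibration_tu, seed=seed)


def next_pair_event(r_rel: np.ndarray, v_rel: np.ndarray,
                    potential: SquareWellPotential,
                    box_edge: float = 1.0e6) -> tuple[float, int] | None:
    """Earliest boundary crossing for an isolated pair, or None.

    ``r_rel``/``v_rel`` are the relative position and velocity (Å, Å/tu).
    Returns ``(t, boundary_index)``; raises if the pair starts inside the
    hard core.
    """
    r = np.asarray(r_rel, dtype=float)
    v = np.asarray(v_rel, dtype=float)
    d = float(np.linalg.norm(r))
    if d < potential.boundaries[0]:
        raise ValueError("pair overlaps inside the hard core")
    pos = np.array([r, np.zeros(3)]) + box_edge / 2.0
    vel = np.array([v, np.zeros(3)])
    tlast = np.zeros(2)
    pair_pot = np.zeros((2, 2), dtype=np.int16)
    b = np.asarray(potential.boundaries, dtype=float)
    pot_bounds = b[None, :]
    pot_nb = np.array([len(b)], dtype=np.int64)
    shell = np.zeros((2, 2), dtype=np.int8)
    _kernels.init_shells(pos, box_edge, pair_pot, pot_bounds, pot_nb, shell)
    dt, bidx = _kernels._predict(0, 1, 0.0, pos, vel, tlast, box_edge,
                                 pair_pot, pot_bounds, pot_nb, shell)
    if bidx < 0:
        return None
    return float(dt), int(bidx)


def resolve_collision(v_i: np.ndarray, v_j: np.ndarray, r_hat: np.ndarray,
                      m_i: float, m_j: float,
                      delta_u: float) -> tuple[np.ndarray, np.ndarray]:
    """Velocities after a boundary collision with energy step ``delta_u``.

    ``r_hat`` is the unit separation vector from j to i. ``delta_u`` is the
    potential-energy change if the pair crosses (``numpy.inf`` or
    ``WALL``-scale values force reflection). The impulse acts along
    ``r_hat``, conserving momentum, pair angular momentum and total energy.
    """
    v_i = np.asarray(v_i, dtype=float)
    v_j = np.asarray(v_j, dtype=float)
    r_hat = np.asarray(r_hat, dtype=float)
    r_hat = r_hat / np.linalg.norm(r_hat)
    mu = m_i * m_j / (m_i + m_j)
    v_r = float(np.dot(v_i - v_j, r_hat))
    du = WALL if np.isinf(delta_u) else float(delta_u)
    v_r_new, _ = _kernels.collide_radial(v_r, mu, du)
    imp = mu * (v_r_new - v_r)
    return v_i + imp * r_hat / m_i, v_j - imp * r_hat / m_j
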