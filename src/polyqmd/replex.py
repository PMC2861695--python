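"""Replica-exchange DMD: parallel replicas with Metropolis temperature swaps.

Eight replicas of the same chain run at a ladder of fixed temperatures
(default {0.85, 0.75, 0.68, 0.64, 0.6, 0.57, 0.53, 0.5} kcal/mol/k_B); at a
regular interval (default 500 tu, ~25 ps) neighbouring ladder slots attempt
to exchange temperatures with the detailed-balance acceptance rule

    p = min(1, exp[(1/T_i − 1/T_j)(E_i − E_j)]).

A swap exchanges temperatures (with velocity rescaling by sqrt(T_new/T_old)),
not coordinates, so each replica's trajectory is a contiguous dynamical
history that wanders in temperature. Frames carry the temperature at which
they were recorded, which is what the multi-histogram analysis consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constructs import ConstructModel
from .dmd import (DEFAULT_EQUILIBRATION_TU, DEFAULT_SAVE_INTERVAL_TU,
                  ChainSystem, DMDSimulation, ForceField, Trajectory)

__all__ = ["DEFAULT_TEMPERATURES", "ReplicaSchedule", "ExchangeRecord",
           "ReplexResult", "attempt_swap", "run_replex"]

DEFAULT_TEMPERATURES = (0.85, 0.75, 0.68, 0.64, 0.6, 0.57, 0.53, 0.5)


@dataclass(frozen=True)
class ReplicaSchedule:
    """Temperature ladder and timing of a replica-exchange run."""

    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    swap_interval: float = 500.0
    duration: float = 1.0e6
    save_interval: float = DEFAULT_SAVE_INTERVAL_TU

    def __post_init__(self) -> None:
        t = self.temperatures
        if len(t) < 2:
            raise ValueError("need at least two replicas")
        if len(set(t)) != len(t):
            raise ValueError("replica temperatures must be distinct")
        if any(x <= 0 for x in t):
            raise ValueError("temperatures must be positive")
        if self.swap_interval <= 0 or self.duration <= 0:
            raise ValueError("swap_interval and duration must be positive")
        if self.save_interval <= 0:
            raise ValueError("save_interval must be positive")

    @property
    def n_replicas(self) -> int:
        return len(self.temperatures)

    @property
    def frames_per_replica(self) -> int:
        return int(self.duration // self.save_interval)

    @property
    def total_frames(self) -> int:
        """Saved structures produced by the whole simulation."""
        return self.n_replicas * self.frames_per_replica


@dataclass(frozen=True)
class ExchangeRecord:
    time: float
    ladder_pair: tuple[int, int]     # adjacent slots in the temperature ladder
    replicas: tuple[int, int]
    energies: tuple[float, float]
    accepted: bool


def attempt_swap(e_i: float, e_j: float, t_i: float, t_j: float,
                 u: float) -> bool:
    """Metropolis decision for exchanging temperatures T_i and T_j.

    ``u`` is a uniform draw in [0, 1). Accepts with probability
    min(1, exp[(1/T_i − 1/T_j)(E_i − E_j)]).
    """
    if t_i <= 0 or t_j <= 0:
        raise ValueError("temperatures must be positive")
    if t_i == t_j:
        raise ValueError("degenerate swap between equal temperatures")
    log_p = (1.0 / t_i - 1.0 / t_j) * (e_i - e_j)
    return log_p >= 0.0 or u < math.exp(log_p)


@dataclass
class ReplexResult:
    """Trajectories, per-frame temperatures, and the exchange log."""

    trajectories: list[Trajectory]
    frame_temperatures: list[np.ndarray]
    exchange_records: list[ExchangeRecord]
    schedule: ReplicaSchedule
    label: str = ""

    @property
    def total_frames(self) -> int:
        return sum(t.n_frames for t in self.trajectories)

    def exchange_log(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.time, r.ladder_pair[0], r.ladder_pair[1], r.replicas[0],
              r.replicas[1], r.energies[0], r.energies[1], r.accepted)
             for r in self.exchange_records],
            columns=["time", "slot_i", "slot_j", "replica_i", "replica_j",
                     "E_i", "E_j", "accepted"])

    def acceptance_rate(self) -> float:
        if not self.exchange_records:
            return float("nan")
        return float(np.mean([r.accepted for r in self.exchange_records]))

    def energies_by_temperature(self, equilibrated: bool = True
                                ) -> dict[float, np.ndarray]:
        """Potential-energy samples grouped by recording temperature."""
        out: dict[float, list[np.ndarray]] = {
            t: [] for t in self.schedule.temperatures}
        for traj, temps in zip(self.trajectories, self.frame_temperatures):
            mask = traj.analysis_mask if equilibrated else np.ones(
                traj.n_frames, dtype=bool)
            for t in out:
                sel = mask & np.isclose(temps, t)
                out[t].append(traj.potential[sel])
        return {t: np.concatenate(v) for t, v in out.items()}

    def frames_by_temperature(self, temperature: float,
                              equilibrated: bool = True) -> np.ndarray:
        """Stack of frame coordinates recorded at one ladder temperature."""
        chunks = []
        for traj, temps in zip(self.trajectories, self.frame_temperatures):
            mask = np.isclose(temps, temperature)
            if equilibrated:
                mask &= traj.analysis_mask
            chunks.append(traj.positions[mask])
        return np.concatenate(chunks)


def run_replex(model: ConstructModel | ChainSystem,
               schedule: ReplicaSchedule | None = None,
               seed: int = 0,
               forcefield: ForceField | None = None,
               equilibration_tu: float = DEFAULT_EQUILIBRATION_TU,
               store_positions: bool = True) -> ReplexResult:
    """Run replica-exchange DMD for one polypeptide model.

    All adjacent ladder pairs of alternating parity are attempted at each
    swap epoch (even pairs at even epochs, odd pairs at odd epochs).
    ``store_positions=False`` drops coordinates (keeping energies and Rg)
    to bound memory on long runs.
    """
    schedule = schedule or ReplicaSchedule()
    system = (model if isinstance(model, ChainSystem)
              else ChainSystem.from_model(model, forcefield))
    ss = np.random.SeedSequence(seed)
    sim_seeds = ss.spawn(schedule.n_replicas + 1)
    rng = np.random.default_rng(sim_seeds[-1])

    sims = [DMDSimulation(system, t, seed=sim_seeds[k],
                          save_interval=schedule.save_interval)
            for k, t in enumerate(schedule.temperatures)]
    slot_replica = list(range(schedule.n_replicas))  # ladder slot -> replica
    frame_temps: list[list[tuple[float, int]]] = [[] for _ in sims]
    frames_seen = [0] * len(sims)
    records: list[ExchangeRecord] = []

    n_epochs = int(math.ceil(schedule.duration / schedule.swap_interval))
    for epoch in range(n_epochs):
        t_target = min((epoch + 1) * schedule.swap_interval,
                       schedule.duration)
        for k, sim in enumerate(sims):
            sim.advance(t_target - sim.t)
            new_total = sum(len(a) for a in sim._ft)
            frame_temps[k].append((sim.temperature,
                                   new_total - frames_seen[k]))
            frames_seen[k] = new_total
        if t_target >= schedule.duration:
            break
        parity = epoch % 2
        for slot in range(parity, schedule.n_replicas - 1, 2):
            ri, rj = slot_replica[slot], slot_replica[slot + 1]
            ti = schedule.temperatures[slot]
            tj = schedule.temperatures[slot + 1]
            ei = sims[ri].potential_energy()
            ej = sims[rj].potential_energy()
            acc = attempt_swap(ei, ej, ti, tj, float(rng.random()))
            records.append(ExchangeRecord(t_target, (slot, slot + 1),
                                          (ri, rj), (ei, ej), acc))
            if acc:
                sims[ri].set_temperature(tj)
                sims[rj].set_temperature(ti)
                slot_replica[slot], slot_replica[slot + 1] = rj, ri

    trajectories = []
    temp_arrays = []
    for k, sim in enumerate(sims):
        traj = sim.trajectory(equilibration_tu=equilibration_tu, seed=seed)
        temps = np.concatenate([np.full(n, t) for t, n in frame_temps[k]]
                               or [np.empty(0)])
        assert len(temps) == traj.n_frames
        if not store_positions:
            traj.positions = np.empty((traj.n_frames, 0, 3))
        trajectories.append(traj)
        temp_arrays.append(temps)
    return ReplexResult(trajectories, temp_arrays, records, schedule,
                        label=system.label)
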