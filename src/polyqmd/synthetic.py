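"""Synthetic inputs with known ground truth for every pipeline stage.

These generators stand in for raw simulation output when testing the
analysis stages: ideal-dihedral backbones (for the φ/ψ classifier),
two-state telegraph energy series (for cutoff-crossing statistics),
Boltzmann-weighted energy samples from a prescribed density of states (for
the multi-histogram analysis), and noisy copies of template structures (for
clustering). Identical parameters and seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import build_backbone
from .wham import EnergyHistogramSet, histogram_energies

__all__ = [
    "IDEAL_DIHEDRALS",
    "make_ideal_backbone",
    "TwoStateSeries",
    "make_two_state_energy_series",
    "make_replica_energy_samples",
    "make_cluster_blobs",
]

#: Canonical (φ, ψ) per secondary-structure class, degrees.
IDEAL_DIHEDRALS = {
    "alpha": (-57.0, -47.0),
    "beta": (-120.0, 130.0),
    "ppii": (-75.0, 145.0),
}


def make_ideal_backbone(ss: str | np.ndarray, length: int,
                        noise_sd: float = 0.0, seed: int = 0) -> np.ndarray:
    """Backbone coordinates with prescribed dihedral content.

    ``ss`` is a class name from :data:`IDEAL_DIHEDRALS`, ``"coil"``
    (uniform random φ/ψ), or an explicit (length, 2) array of per-residue
    (φ, ψ) in degrees. Isotropic Gaussian noise of ``noise_sd`` Å is added
    to every bead. Returns a (3·length, 3) array.
    """
    if length < 2:
        raise ValueError("need at least two residues")
    rng = np.random.default_rng(seed)
    if isinstance(ss, str):
        if ss == "coil":
            phi = rng.uniform(-180.0, 180.0, size=length)
            psi = rng.uniform(-180.0, 180.0, size=length)
        elif ss in IDEAL_DIHEDRALS:
            p, s = IDEAL_DIHEDRALS[ss]
            phi = np.full(length, p)
            psi = np.full(length, s)
        else:
            raise ValueError(f"unknown secondary-structure class {ss!r}")
    else:
        arr = np.asarray(ss, dtype=float)
        if arr.shape != (length, 2):
            raise ValueError("per-residue dihedrals must be (length, 2)")
        phi, psi = arr[:, 0], arr[:, 1]
    coords = build_backbone(phi, psi)
    if noise_sd > 0.0:
        coords = coords + rng.normal(0.0, noise_sd, size=coords.shape)
    return coords


@dataclass(frozen=True)
class TwoStateSeries:
    """Telegraph energy series plus its ground truth."""

    times: np.ndarray
    energies: np.ndarray
    states: np.ndarray               # 0 = low level, 1 = high level
    true_transitions: int            # state switches within the series
    e_low: float
    e_high: float


def make_two_state_energy_series(e_low: float, e_high: float,
                                 switch_rate: float, within_state_sd: float,
                                 n: int, dt: float = 1.0,
                                 seed: int = 0) -> TwoStateSeries:
    """Symmetric telegraph process between two energy levels.

    The state flips with probability per unit time ``switch_rate`` (sampled
    at interval ``dt``); Gaussian within-state noise of ``within_state_sd``
    is added on top. The number of true state switches is recorded so
    crossing-count estimators can be checked against ground truth.
    """
    if n < 1:
        raise ValueError("need n >= 1 samples")
    if switch_rate < 0:
        raise ValueError("switch rate must be non-negative")
    rng = np.random.default_rng(seed)
    p_flip = 1.0 - np.exp(-switch_rate * dt)
    flips = rng.random(n - 1) < p_flip if n > 1 else np.empty(0, dtype=bool)
    states = np.empty(n, dtype=int)
    states[0] = 0
    if n > 1:
        states[1:] = np.cumsum(flips) % 2
    levels = np.where(states == 0, e_low, e_high).astype(float)
    energies = levels + rng.normal(0.0, within_state_sd, size=n)
    times = np.arange(n) * dt
    return TwoStateSeries(times, energies, states,
                          int(np.count_nonzero(np.diff(states))),
                          float(e_low), float(e_high))


def make_replica_energy_samples(energy_grid: np.ndarray,
                                log_omega: np.ndarray,
                                temperatures,
                                n_per_replica: int,
                                seed: int = 0,
                                bin_width: float | None = None
                                ) -> tuple[EnergyHistogramSet, dict]:
    """Boltzmann-weighted i.i.d. energy draws per replica temperature.

    Samples E with probability ∝ Ω(E)·exp(−E/T_k) on the given discrete
    grid for each temperature, then bins them on a common grid. Returns the
    histogram set and the raw samples keyed by temperature (the ground
    truth density of states is the caller's ``log_omega``).
    """
    e = np.asarray(energy_grid, dtype=float)
    lw = np.asarray(log_omega, dtype=float)
    if e.shape != lw.shape:
        raise ValueError("energy grid and log_omega must align")
    if n_per_replica < 1:
        raise ValueError("need at least one sample per replica "
                         "(empty histograms are not analysable)")
    rng = np.random.default_rng(seed)
    samples: dict[float, np.ndarray] = {}
    for t in temperatures:
        logp = lw - e / t
        logp -= logp.max()
        p = np.exp(logp)
        total = p.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError("density of states not normalisable at "
                             f"T={t}")
        p /= total
        samples[float(t)] = rng.choice(e, size=n_per_replica, p=p)
    if bin_width is None:
        step = float(np.min(np.diff(np.sort(e)))) if len(e) > 1 else 1.0
        edges = np.concatenate([np.sort(e) - 0.5 * step,
                                [np.sort(e)[-1] + 0.5 * step]])
        counts = np.stack([np.histogram(samples[float(t)], bins=edges)[0]
                           for t in sorted(samples, reverse=True)])
        hists = EnergyHistogramSet(
            edges, np.array(sorted(samples, reverse=True)),
            counts.astype(float))
    else:
        hists = histogram_energies(samples, bin_width=bin_width)
    return hists, samples


def make_cluster_blobs(sizes, templates: np.ndarray, spread: float,
                       seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Noisy copies of template structures, with true labels.

    ``templates`` is (k, n, 3); blob ``b`` contributes ``sizes[b]``
    structures equal to its template plus isotropic Gaussian noise of sd
    ``spread`` Å. Returns (structures (Σsizes, n, 3), labels).
    """
    templates = np.asarray(templates, dtype=float)
    if templates.ndim != 3:
        raise ValueError("templates must be (k, n, 3)")
    if len(sizes) != len(templates):
        raise ValueError("one size per template")
    rng = np.random.default_rng(seed)
    chunks = []
    labels = []
    for b, (size, tmpl) in enumerate(zip(sizes, templates)):
        noise = rng.normal(0.0, spread, size=(size, *tmpl.shape))
        chunks.append(tmpl[None] + noise)
        labels.extend([b] * size)
    return np.concatenate(chunks), np.array(labels, dtype=int)
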