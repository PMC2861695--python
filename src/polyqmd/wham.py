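"""Weighted histogram analysis: density of states and heat capacity.

Energy histograms collected at several temperatures are combined into a
single density of states Ω(E) by iterating the self-consistent equations
(k_B = 1 units)

    Ω(E) = Σ_k h_k(E) / Σ_k N_k exp(f_k − E/T_k)
    exp(−f_k) = Σ_E Ω(E) exp(−E/T_k)

to convergence in the per-replica free-energy shifts f_k (gauge f_1 = 0).
All arithmetic is done in log space. From Ω(E) the canonical moments give
the heat capacity C_V(T) = (⟨E²⟩ − ⟨E⟩²)/T², whose peak marks the
collapse/folding transition of the chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .units import temperature_to_kelvin

__all__ = [
    "EnergyHistogramSet",
    "DensityOfStates",
    "HeatCapacityCurve",
    "TransitionPeak",
    "histogram_energies",
    "solve_wham",
    "heat_capacity",
    "find_transition",
    "average_transition_temperature",
]


@dataclass(frozen=True)
class EnergyHistogramSet:
    """Shared-binning energy histograms from replicas at several temperatures."""

    bin_edges: np.ndarray            # (B+1,)
    temperatures: np.ndarray         # (K,)
    counts: np.ndarray               # (K, B)

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.temperatures),
                                 len(self.bin_edges) - 1):
            raise ValueError("counts must be (n_replicas, n_bins)")
        if np.any(self.counts < 0):
            raise ValueError("negative histogram counts")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def histogram_energies(samples: dict[float, np.ndarray],
                       bin_width: float | None = None,
                       n_bins: int | None = None) -> EnergyHistogramSet:
    """Bin per-temperature energy samples on a common grid.

    Default bin width follows the Freedman–Diaconis rule on the pooled
    samples (the bin width is a nuisance parameter; it is exposed because
    published analyses sometimes state one explicitly).
    """
    temps = np.array(sorted(samples, reverse=True), dtype=float)
    pooled = np.concatenate([np.asarray(samples[t], dtype=float)
                             for t in temps])
    if pooled.size == 0:
        raise ValueError("no energy samples provided")
    lo, hi = pooled.min(), pooled.max()
    if hi == lo:
        hi = lo + 1.0
    if bin_width is None:
        if n_bins is None:
            iqr = np.subtract(*np.percentile(pooled, [75, 25]))
            bin_width = (2 * iqr * pooled.size ** (-1 / 3)) or (hi - lo) / 50
            n_bins = max(int(np.ceil((hi - lo) / bin_width)), 10)
        edges = np.linspace(lo, hi, n_bins + 1)
    else:
        edges = np.arange(lo, hi + bin_width, bin_width)
        if len(edges) < 2:
            edges = np.array([lo, lo + bin_width])
    counts = np.stack([np.histogram(np.asarray(samples[t], dtype=float),
                                    bins=edges)[0] for t in temps])
    return EnergyHistogramSet(edges, temps, counts.astype(float))


@dataclass(frozen=True)
class DensityOfStates:
    """log Ω(E) on histogram bin centers, with WHAM diagnostics."""

    energies: np.ndarray             # bin centers
    log_omega: np.ndarray            # up to an additive constant
    free_energy_shifts: np.ndarray   # f_k, gauge f_1 = 0
    temperatures: np.ndarray
    n_iterations: int
    converged: bool
    max_delta_f: float


def solve_wham(hists: EnergyHistogramSet, tol: float = 1.0e-7,
               max_iter: int = 100_000) -> DensityOfStates:
    """Self-consistent WHAM solution for the density of states.

    Bins with zero pooled counts are excluded (log Ω undefined there).
    Raises if the replicas' energy ranges have no mutual overlap or the
    iteration does not converge.
    """
    counts = hists.counts
    temps = np.asarray(hists.temperatures, dtype=float)
    if len(temps) < 1:
        raise ValueError("need at least one histogram")
    if np.any(counts.sum(axis=1) == 0):
        raise ValueError("a replica histogram is empty")
    pooled = counts.sum(axis=0)
    support = pooled > 0
    if len(temps) > 1:
        # every replica must share support with at least one other
        occupied = counts > 0
        for k in range(len(temps)):
            others = occupied[np.arange(len(temps)) != k].any(axis=0)
            if not np.any(occupied[k] & others):
                raise ValueError(
                    "histograms do not overlap: WHAM has no mutual support")

    e = hists.bin_centers[support]
    h = counts[:, support]
    n_k = counts.sum(axis=1)
    log_h_pool = np.log(h.sum(axis=0))
    log_n = np.log(n_k)

    f = np.zeros(len(temps))
    beta = 1.0 / temps
    it = 0
    max_df = np.inf
    for it in range(1, max_iter + 1):
        # log Ω(E) = log Σ_k h_k − logsumexp_k [log N_k + f_k − β_k E]
        denom = logsumexp(log_n[:, None] + f[:, None]
                          - beta[:, None] * e[None, :], axis=0)
        log_omega = log_h_pool - denom
        f_new = -logsumexp(log_omega[None, :] - beta[:, None] * e[None, :],
                           axis=1)
        f_new = f_new - f_new[0]
        max_df = float(np.max(np.abs(f_new - f)))
        f = f_new
        if max_df < tol:
            break
    converged = max_df < tol
    if not converged:
        raise RuntimeError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(max |Δf| = {max_df:.3e})")
    denom = logsumexp(log_n[:, None] + f[:, None]
                      - beta[:, None] * e[None, :], axis=0)
    log_omega = log_h_pool - denom
    return DensityOfStates(e, log_omega, f, temps, it, converged, max_df)


@dataclass(frozen=True)
class HeatCapacityCurve:
    temperatures: np.ndarray         # simulation units
    c_v: np.ndarray
    mean_energy: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.c_v < -1.0e-9):
            raise ValueError("negative heat capacity")


def heat_capacity(dos: DensityOfStates,
                  t_grid: np.ndarray) -> HeatCapacityCurve:
    """Canonical C_V(T) from the density of states.

    C_V = (⟨E²⟩ − ⟨E⟩²)/T² with Boltzmann moments over Ω(E); computed with
    log-sum-exp weights so large |E|/T never overflows.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(t_grid <= 0):
        raise ValueError("temperature grid must be positive")
    e = dos.energies
    cv = np.empty_like(t_grid)
    mean_e = np.empty_like(t_grid)
    for i, t in enumerate(t_grid):
        logw = dos.log_omega - e / t
        logw -= logsumexp(logw)
        w = np.exp(logw)
        m1 = float(np.dot(w, e))
        var = float(np.dot(w, (e - m1) ** 2))
        mean_e[i] = m1
        cv[i] = var / t**2
    return HeatCapacityCurve(t_grid, np.maximum(cv, 0.0), mean_e)


@dataclass(frozen=True)
class TransitionPeak:
    temperature: float               # simulation units
    height: float
    cooperative: bool
    temperature_kelvin: float

    @property
    def has_peak(self) -> bool:
        return np.isfinite(self.temperature)


NO_PEAK = None


def find_transition(curve: HeatCapacityCurve,
                    width_threshold: float = 1.0
                    ) -> TransitionPeak | None:
    """Locate the C_V peak (transition temperature) on the curve.

    The grid argmax is refined by a local quadratic fit through the three
    surrounding points. Returns None when the curve has no interior maximum.
    A peak whose half-height width exceeds ``width_threshold`` times the
    peak temperature is flagged non-cooperative: a broad, shallow
    coil–globule collapse rather than a sharp folding transition (a
    two-level system with unit degeneracy has relative width ≈ 1.7, one
    with 50-fold degeneracy ≈ 0.8). The grid should bracket the peak well
    beyond its half-height points, else the width is underestimated.
    Ties take the lowest temperature.
    """
    t = curve.temperatures
    c = curve.c_v
    if len(t) < 3:
        raise ValueError("need at least three grid points")
    i = int(np.argmax(c))                 # first occurrence = lowest T
    if i == 0 or i == len(c) - 1:
        return None
    # quadratic refinement through (i-1, i, i+1)
    x0, x1, x2 = t[i - 1], t[i], t[i + 1]
    y0, y1, y2 = c[i - 1], c[i], c[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a < 0:
        t_peak = -b / (2 * a)
        t_peak = float(np.clip(t_peak, x0, x2))
        h_peak = float(y1 + (a * t_peak**2 + b * t_peak)
                       - (a * x1**2 + b * x1))
    else:
        t_peak, h_peak = float(x1), float(y1)
    level = c.min() + 0.5 * (c[i] - c.min())
    lo = i
    while lo > 0 and c[lo - 1] >= level:
        lo -= 1
    hi = i
    while hi < len(c) - 1 and c[hi + 1] >= level:
        hi += 1
    rel_width = (t[hi] - t[lo]) / t_peak
    cooperative = c[i] > c.min() and rel_width <= width_threshold
    return TransitionPeak(t_peak, h_peak, cooperative,
                          temperature_to_kelvin(t_peak))


def average_transition_temperature(peaks_kelvin) -> float:
    """Arithmetic mean of transition temperatures (Kelvin).

    Accepts Kelvin floats or :class:`TransitionPeak` objects (converted via
    the ~503 K per simulation-temperature-unit convention).
    """
    vals = [p.temperature_kelvin if isinstance(p, TransitionPeak) else float(p)
            for p in peaks_kelvin]
    if not vals:
        raise ValueError("no transition temperatures given")
    return float(np.mean(vals))
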