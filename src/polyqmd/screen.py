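"""Compact-ensemble screening: Rg/energy cutoffs and crossing statistics.

Replica-exchange sampling is dominated by extended, high-energy
conformations; the structural analyses only concern the compact, low-energy
sub-ensemble (typically ~13–27% of all saved structures). Membership is the
conjunction Rg ≤ rg_cutoff and E ≤ energy_cutoff, with both cutoffs read
off pooled histograms: the Rg cutoff at the right flank of the modal peak,
the energy cutoff from the low-energy component of a two-Gaussian mixture.
The number of times the energy series crosses the energy cutoff (entering
or leaving the compact domain) serves as the effective number of
independent events for binomial standard errors.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

__all__ = [
    "ScreenVariable",
    "ScreenHistogram",
    "CompactEnsemble",
    "propose_rg_cutoff",
    "propose_energy_cutoff",
    "select_compact",
    "count_crossings",
    "probability_standard_error",
]

DEFAULT_RG_BIN_WIDTH = 1.0   # Å


class ScreenVariable(enum.Enum):
    RG = "rg"
    ENERGY = "energy"


@dataclass(frozen=True)
class ScreenHistogram:
    """Pooled histogram of a screening variable across all replicas."""

    variable: ScreenVariable
    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("counts/edges length mismatch")

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_samples(cls, variable: ScreenVariable, values: np.ndarray,
                     bin_width: float = DEFAULT_RG_BIN_WIDTH
                     ) -> "ScreenHistogram":
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise ValueError("no samples")
        lo = np.floor(values.min() / bin_width) * bin_width
        hi = np.ceil(values.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
        edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
        counts, _ = np.histogram(values, bins=edges)
        return cls(variable, edges, counts.astype(int))


def propose_rg_cutoff(hist: ScreenHistogram,
                      flank_fraction: float = 0.10) -> float:
    """Rg cutoff at the right flank of the histogram's modal peak.

    Rule: the left edge of the first bin above the modal bin whose count
    falls below ``flank_fraction`` of the modal count. Falls back to the
    last edge when the counts never drop that far; a single-bin histogram
    yields its upper edge. Manual override is simply passing your own value
    to :func:`select_compact`.
    """
    counts = hist.counts
    if counts.sum() == 0:
        raise ValueError("empty histogram")
    if len(counts) == 1:
        return float(hist.bin_edges[-1])
    mode = int(np.argmax(counts))
    thresh = flank_fraction * counts[mode]
    for i in range(mode + 1, len(counts)):
        if counts[i] < thresh:
            return float(hist.bin_edges[i])
    return float(hist.bin_edges[-1])


def propose_energy_cutoff(energies: np.ndarray, n_sigma: float = 2.0,
                          seed: int = 0) -> float:
    """Energy cutoff selecting the lowest-energy Gaussian component.

    Fits a 2-component Gaussian mixture to the pooled energies and returns
    μ_low + ``n_sigma``·σ_low of the lower-mean component. If the fit is
    degenerate — the fitted mixture density has no real dip between the two
    component means, i.e. the sample is effectively unimodal — the
    lowest-decile value is returned instead, with a warning.
    """
    x = np.asarray(energies, dtype=float).reshape(-1, 1)
    if x.size < 4:
        raise ValueError("too few energy samples for a mixture fit")
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=3)
    gm.fit(x)
    mu = gm.means_.ravel()
    sd = np.sqrt(gm.covariances_.ravel())
    lo = int(np.argmin(mu))
    grid = np.linspace(mu.min(), mu.max(), 101).reshape(-1, 1)
    dens = np.exp(gm.score_samples(grid))
    peak_floor = min(dens[0], dens[-1])
    if dens.min() >= 0.8 * peak_floor:           # no dip between the modes
        warnings.warn("energy mixture fit degenerate; "
                      "falling back to the lowest-decile cutoff")
        return float(np.percentile(x, 10))
    return float(mu[lo] + n_sigma * sd[lo])


@dataclass(frozen=True)
class CompactEnsemble:
    """Frames passing both screening cutoffs, with crossing-event tally."""

    frame_indices: np.ndarray        # indices into the pooled frame list
    rg_cutoff: float
    energy_cutoff: float
    n_total: int
    n_events: int                    # energy-cutoff crossings, for errors

    @property
    def n_frames(self) -> int:
        return len(self.frame_indices)

    @property
    def fraction(self) -> float:
        return self.n_frames / self.n_total if self.n_total else 0.0


def select_compact(rg: np.ndarray, energy: np.ndarray,
                   rg_cutoff: float, energy_cutoff: float,
                   n_events: int = 0) -> CompactEnsemble:
    """Frames with Rg ≤ rg_cutoff and E ≤ energy_cutoff (inclusive).

    ``rg`` and ``energy`` are per-frame arrays over the pooled trajectory.
    An empty selection is a valid result.
    """
    rg = np.asarray(rg, dtype=float)
    energy = np.asarray(energy, dtype=float)
    if rg.shape != energy.shape:
        raise ValueError("rg and energy must align")
    members = np.nonzero((rg <= rg_cutoff) & (energy <= energy_cutoff))[0]
    return CompactEnsemble(members, float(rg_cutoff), float(energy_cutoff),
                           len(rg), int(n_events))


def count_crossings(energies: np.ndarray, cutoff: float) -> int:
    """Number of times a time-ordered energy series crosses the cutoff.

    Both entries into and exits from the compact (below-cutoff) domain are
    counted. Samples exactly at the cutoff attach to the preceding sign;
    leading at-cutoff samples attach to the first decided side.
    """
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        return 0
    s = np.sign(e - cutoff).astype(int)
    nz = np.nonzero(s)[0]
    if nz.size == 0:
        return 0
    s = s[nz]                        # at-cutoff samples keep previous sign
    return int(np.count_nonzero(np.diff(s)))


def probability_standard_error(p: float, n_events: int) -> float:
    """Binomial standard error sqrt(p(1−p)/n) with n = crossing events."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if n_events < 1:
        raise ValueError("standard error undefined without crossing events")
    return float(np.sqrt(p * (1.0 - p) / n_events))
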