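"""Dihedral-based secondary-structure probabilities.

Each residue of each compact-ensemble conformation is assigned one of four
classes from its backbone (φ, ψ) alone — α-helix, β-strand, turn
(left-handed basin) or random coil — using rectangular Ramachandran-basin
rules. Polyproline-II detection is optional (default off, matching the
4-class scheme); when enabled the PPII rectangle is carved out of the β
basin, so β(off) = β(on) + PPII(on) pointwise.

Per-residue class frequencies over the ensemble give the secondary
structure probability profile; a region's probability is the mean over its
residues. Standard errors use the energy-cutoff crossing count as the
effective number of independent events.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .geometry import compute_phi_psi
from .screen import probability_standard_error

__all__ = ["SSClass", "classify_ss", "classify_ss_array", "DihedralPair",
           "SSProfile", "ss_probability_profile", "region_average",
           "compute_dihedrals"]


class SSClass(enum.Enum):
    ALPHA = "alpha"
    BETA = "beta"
    PPII = "ppii"
    TURN = "turn"
    COIL = "coil"


#: Ramachandran rectangles (degrees), declared defaults of this package.
BASINS = {
    SSClass.ALPHA: ((-100.0, -30.0), (-80.0, -5.0)),
    SSClass.BETA: ((-180.0, -45.0), None),          # ψ handled specially
    SSClass.TURN: ((30.0, 100.0), (-20.0, 80.0)),
    SSClass.PPII: ((-90.0, -55.0), (120.0, 170.0)),
}


@dataclass(frozen=True)
class DihedralPair:
    residue: int
    phi: float
    psi: float


def compute_dihedrals(coords: np.ndarray) -> list[DihedralPair]:
    """Backbone φ/ψ pairs for every residue with both angles defined.

    ``coords`` is the (3n, 3) N/Cα/C bead array of one conformation;
    chain-terminal residues (no φ at the N-terminus, no ψ at the
    C-terminus) are excluded.
    """
    phi, psi = compute_phi_psi(coords)
    return [DihedralPair(i, float(phi[i]), float(psi[i]))
            for i in range(len(phi))
            if np.isfinite(phi[i]) and np.isfinite(psi[i])]


def classify_ss(phi: float, psi: float, ppii_enabled: bool = False) -> SSClass:
    """Assign one secondary-structure class to a (φ, ψ) pair."""
    if not (np.isfinite(phi) and np.isfinite(psi)):
        raise ValueError("undefined dihedral angles")
    out = classify_ss_array(np.array([phi]), np.array([psi]), ppii_enabled)
    return out[0]


def classify_ss_array(phi: np.ndarray, psi: np.ndarray,
                      ppii_enabled: bool = False) -> np.ndarray:
    """Vectorised classification; returns an object array of SSClass."""
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    out = np.full(phi.shape, SSClass.COIL, dtype=object)

    (pa, pb), (sa, sb) = BASINS[SSClass.ALPHA]
    alpha = (phi >= pa) & (phi <= pb) & (psi >= sa) & (psi <= sb)
    out[alpha] = SSClass.ALPHA

    (pa, pb), _ = BASINS[SSClass.BETA]
    beta = ((phi >= pa) & (phi <= pb)
            & (((psi >= 90.0) & (psi <= 180.0))
               | ((psi > -180.0) & (psi <= -160.0))))
    out[beta] = SSClass.BETA

    if ppii_enabled:
        (pa, pb), (sa, sb) = BASINS[SSClass.PPII]
        ppii = (phi >= pa) & (phi <= pb) & (psi >= sa) & (psi <= sb)
        out[ppii] = SSClass.PPII

    (pa, pb), (sa, sb) = BASINS[SSClass.TURN]
    turn = (phi >= pa) & (phi <= pb) & (psi >= sa) & (psi <= sb)
    out[turn] = SSClass.TURN
    return out


@dataclass(frozen=True)
class SSProfile:
    """Per-residue secondary-structure probabilities over an ensemble."""

    classes: tuple[SSClass, ...]
    probabilities: np.ndarray        # (n_residues, n_classes); NaN at termini
    n_frames: int
    n_events: int
    ppii_enabled: bool

    @property
    def n_residues(self) -> int:
        return self.probabilities.shape[0]

    def class_probability(self, cls: SSClass) -> np.ndarray:
        return self.probabilities[:, self.classes.index(cls)]

    def standard_errors(self) -> np.ndarray:
        """Binomial standard error per residue and class."""
        p = self.probabilities
        out = np.full_like(p, np.nan)
        ok = np.isfinite(p)
        out[ok] = [probability_standard_error(v, max(self.n_events, 1))
                   for v in p[ok]]
        return out

    def defined_residues(self) -> np.ndarray:
        return np.nonzero(np.isfinite(self.probabilities[:, 0]))[0]


def ss_probability_profile(frames: np.ndarray, ppii_enabled: bool = False,
                           n_events: int = 0) -> SSProfile:
    """Per-residue class frequencies across an ensemble of conformations.

    ``frames`` is (F, 3n, 3) backbone coordinates (the compact ensemble).
    Terminal residues, whose φ or ψ is undefined, carry NaN probabilities
    and are excluded from region averages.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError("need a non-empty (F, 3n, 3) frame stack")
    n_res = frames.shape[1] // 3
    classes = tuple(c for c in SSClass
                    if ppii_enabled or c is not SSClass.PPII)
    counts = np.zeros((n_res, len(classes)))
    defined = np.zeros(n_res, dtype=bool)
    for f in frames:
        phi, psi = compute_phi_psi(f)
        ok = np.isfinite(phi) & np.isfinite(psi)
        labels = classify_ss_array(phi[ok], psi[ok], ppii_enabled)
        for r, lab in zip(np.nonzero(ok)[0], labels):
            counts[r, classes.index(lab)] += 1
            defined[r] = True
    probs = np.full((n_res, len(classes)), np.nan)
    probs[defined] = counts[defined] / frames.shape[0]
    return SSProfile(classes, probs, frames.shape[0], int(n_events),
                     ppii_enabled)


def region_average(profile: SSProfile, mask: range | np.ndarray
                   ) -> dict[SSClass, tuple[float, float]]:
    """Mean class probability ± standard error over a residue range.

    A β-strand value of 0.3 means an average residue of the region adopts
    β-strand dihedral angles 30% of the time. Residues with undefined
    dihedrals inside the mask are dropped from the average.
    """
    idx = np.asarray(list(mask), dtype=int)
    if idx.size == 0:
        raise ValueError("empty region mask")
    if idx.min() < 0 or idx.max() >= profile.n_residues:
        raise ValueError("mask outside profile")
    sub = profile.probabilities[idx]
    ok = np.isfinite(sub[:, 0])
    if not np.any(ok):
        raise ValueError("no residues with defined dihedrals in region")
    means = sub[ok].mean(axis=0)
    out = {}
    for c, m in zip(profile.classes, means):
        err = (probability_standard_error(min(max(m, 0.0), 1.0),
                                          profile.n_events)
               if profile.n_events >= 1 else float("nan"))
        out[c] = (float(m), err)
    return out
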