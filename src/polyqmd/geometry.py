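"""Backbone geometry: constants, internal→Cartesian building, dihedrals.

A residue is represented by its three backbone beads N, Cα, C, so a chain of
``n`` residues is a linear sequence of ``3n`` beads. The same bond-length and
bond-angle constants drive both the simulation engine's constraint wells and
the synthetic conformation builder, so dihedral round-trips are exact.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "BOND_LENGTHS",
    "BOND_ANGLES",
    "ANGLE13_DISTANCES",
    "build_backbone",
    "extended_backbone",
    "dihedrals_from_coords",
    "compute_phi_psi",
]

# Bond lengths (Å), cycling along the bead chain: N–Cα, Cα–C, C–N(next).
BOND_LENGTHS = np.array([1.46, 1.53, 1.33])

# Bond angles (degrees) at the middle atom of each bead triplet, cycling:
# N–Cα–C (at Cα), Cα–C–N (at C), C–N–Cα (at N).
BOND_ANGLES = np.array([111.0, 116.0, 121.7])


def _angle13(i: int) -> float:
    """1-3 distance implied by bonds i, i+1 and the angle between them."""
    a = BOND_LENGTHS[i % 3]
    b = BOND_LENGTHS[(i + 1) % 3]
    theta = np.deg2rad(BOND_ANGLES[i % 3])
    return float(np.sqrt(a * a + b * b - 2 * a * b * np.cos(theta)))


# Equilibrium 1-3 distances (Å) for bead pairs (k, k+2), cycling with k % 3.
ANGLE13_DISTANCES = np.array([_angle13(0), _angle13(1), _angle13(2)])


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of the next atom.

    Returns the position d with |cd| = bond, angle b-c-d = angle and
    torsion a-b-c-d = torsion (IUPAC sign convention).
    """
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phi: np.ndarray, psi: np.ndarray,
                   omega: np.ndarray | None = None) -> np.ndarray:
    """Build N/Cα/C coordinates for a chain with the given dihedrals.

    ``phi`` and ``psi`` are per-residue arrays in degrees (length n); φ of
    residue 0 and ψ of the last residue are irrelevant to the geometry and
    may hold any value. ``omega`` (peptide-bond torsion, default 180° trans)
    has length n−1. Returns an array of shape (3n, 3) in Å.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    n = len(phi)
    if len(psi) != n:
        raise ValueError("phi and psi must have equal length")
    if n < 1:
        raise ValueError("need at least one residue")
    if omega is None:
        omega = np.full(max(n - 1, 0), 180.0)

    coords = np.empty((3 * n, 3))
    # Seed the first three atoms: N at origin, Cα along x, C in the xy plane.
    coords[0] = [0.0, 0.0, 0.0]
    coords[1] = [BOND_LENGTHS[0], 0.0, 0.0]
    theta = np.deg2rad(BOND_ANGLES[0])
    coords[2] = coords[1] + BOND_LENGTHS[1] * np.array(
        [-np.cos(theta), np.sin(theta), 0.0])

    # Torsion driving atom k (k >= 3): cycles ψ(i), ω(i), φ(i+1) for
    # atoms N(i+1), Cα(i+1), C(i+1) respectively.
    for k in range(3, 3 * n):
        role = k % 3           # 0 = N, 1 = CA, 2 = C
        res = k // 3
        if role == 0:
            torsion = psi[res - 1]
        elif role == 1:
            torsion = omega[res - 1]
        else:
            torsion = phi[res]
        bond = BOND_LENGTHS[(k - 1) % 3]
        angle = BOND_ANGLES[(k - 2) % 3]
        coords[k] = _place_atom(coords[k - 3], coords[k - 2], coords[k - 1],
                                bond, angle, torsion)
    return coords


def extended_backbone(n_residues: int) -> np.ndarray:
    """Fully extended chain (φ = ψ = 180°), the simulations' start state."""
    phi = np.full(n_residues, 180.0)
    psi = np.full(n_residues, 180.0)
    return build_backbone(phi, psi)


def dihedrals_from_coords(p: np.ndarray) -> np.ndarray:
    """Torsion angles (degrees) for each consecutive atom quadruple.

    ``p`` has shape (m, 3); returns m−3 angles in (−180, 180], IUPAC sign
    convention. Raises ``ValueError`` when an inner atom triple is collinear
    (the torsion is then undefined).
    """
    p = np.asarray(p, dtype=float)
    b1 = p[1:-2] - p[:-3]
    b2 = p[2:-1] - p[1:-2]
    b3 = p[3:] - p[2:-1]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm1 = np.linalg.norm(n1, axis=1)
    norm2 = np.linalg.norm(n2, axis=1)
    if np.any(norm1 < 1e-10) or np.any(norm2 < 1e-10):
        raise ValueError("collinear atom triplet: dihedral undefined")
    b2n = b2 / np.linalg.norm(b2, axis=1)[:, None]
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2n)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 -> +180 to keep the (−180, 180] convention
    ang[ang <= -180.0] = 180.0
    return ang


def compute_phi_psi(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue backbone φ/ψ (degrees) from an (3n, 3) bead array.

    φ(i) is the torsion C(i−1)–N(i)–Cα(i)–C(i) and ψ(i) is
    N(i)–Cα(i)–C(i)–N(i+1); the undefined terminal angles (φ of the first
    residue, ψ of the last) are returned as NaN.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] % 3 or coords.shape[1] != 3:
        raise ValueError("coords must have shape (3n, 3)")
    n = coords.shape[0] // 3
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    if n < 2:
        return phi, psi
    all_torsions = dihedrals_from_coords(coords)
    # torsion starting at atom k spans atoms k..k+3; φ(i) starts at C(i-1)
    # which is atom 3i-1; ψ(i) starts at N(i) = atom 3i.
    for i in range(1, n):
        phi[i] = all_torsions[3 * i - 1]
    for i in range(0, n - 1):
        psi[i] = all_torsions[3 * i]
    return phi, psi
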