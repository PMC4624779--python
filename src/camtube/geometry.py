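"""Internal-coordinate geometry: torsions, chain building, site reconstruction.

Chains are grown with the natural-extension reference frame (NeRF) using the
embedded backbone bond lengths and angles, so every preset conformation
satisfies all bond constraints exactly by construction.
"""

from __future__ import annotations

import math

import numpy as np

from . import constants as const
from .topology import CGTopology, Conformation, cbeta_bond_length

_MAX_COIL_ATTEMPTS = 2000


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed torsion angle in degrees, IUPAC convention (cis = 0)."""
    b1 = np.asarray(p1) - np.asarray(p0)
    b2 = np.asarray(p2) - np.asarray(p1)
    b3 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    # IUPAC sign: cis = 0, clockwise positive looking along b2
    return math.degrees(math.atan2(-np.dot(m1, n2), np.dot(n1, n2)))


def bond_angle(p0, p1, p2) -> float:
    """Angle at p1 in degrees."""
    u = _unit(np.asarray(p0) - np.asarray(p1))
    v = _unit(np.asarray(p2) - np.asarray(p1))
    return math.degrees(math.acos(np.clip(np.dot(u, v), -1.0, 1.0)))


def nerf_place(a, b, c, bond: float, theta_deg: float, chi_deg: float) -> np.ndarray:
    """Place atom d with |d-c| = bond, angle(b,c,d) = theta, torsion(a,b,c,d) = chi."""
    theta = math.radians(theta_deg)
    chi = math.radians(chi_deg)
    bc = _unit(np.asarray(c) - np.asarray(b))
    n = _unit(np.cross(np.asarray(b) - np.asarray(a), bc))
    m = np.cross(n, bc)
    d = bond * (-math.cos(theta) * bc
                + math.sin(theta) * math.cos(chi) * m
                + math.sin(theta) * math.sin(chi) * n)
    return np.asarray(c) + d


def place_amide_hydrogen(c_prev: np.ndarray, n: np.ndarray, ca: np.ndarray) -> np.ndarray:
    """Amide H in the peptide plane, opposite the bisector of N's two bonds."""
    u = _unit(c_prev - n) + _unit(ca - n)
    return n - const.BOND_N_H * _unit(u)


def place_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray, length: float) -> np.ndarray:
    """Ideal tetrahedral CB for an L-amino acid given the N, CA, C positions."""
    u1 = _unit(n - ca)
    u2 = _unit(c - ca)
    bisec = _unit(-(u1 + u2))
    # L-chirality: CB sits on the side of the N-CA-C plane given by u1 x u2
    # (improper N-C-CA-CB comes out ~ +122 deg, as in L-protein structures)
    perp = _unit(np.cross(u1, u2))
    target = math.radians(const.ANGLES[("N", "CA", "CB")][0])
    cos_delta = math.cos(target) / np.dot(bisec, u1)
    delta = math.acos(np.clip(cos_delta, -1.0, 1.0))
    return ca + length * (math.cos(delta) * bisec + math.sin(delta) * perp)


def build_from_dihedrals(topo: CGTopology, phi, psi, omega=None) -> Conformation:
    """Grow the full chain from per-residue (phi, psi) and peptide omegas.

    ``phi[0]`` is ignored (undefined); ``psi[-1]`` only orients the terminal
    carbonyl O.  All bonded geometry is ideal, so the result satisfies every
    constraint exactly.
    """
    n_res = topo.n_residues
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (n_res,))
    psi = np.broadcast_to(np.asarray(psi, dtype=float), (n_res,))
    if omega is None:
        omega = np.full(max(n_res - 1, 1), 180.0)
    omega = np.broadcast_to(np.asarray(omega, dtype=float), (max(n_res - 1, 1),))

    coords = np.zeros((topo.n_atoms, 3))
    pos_N = np.zeros((n_res, 3))
    pos_CA = np.zeros((n_res, 3))
    pos_C = np.zeros((n_res, 3))

    pos_N[0] = (0.0, 0.0, 0.0)
    pos_CA[0] = (const.BOND_N_CA, 0.0, 0.0)
    a = math.radians(180.0 - const.ANGLES[("N", "CA", "C")][0])
    pos_C[0] = pos_CA[0] + const.BOND_CA_C * np.array([math.cos(a), math.sin(a), 0.0])

    for i in range(n_res - 1):
        pos_N[i + 1] = nerf_place(pos_N[i], pos_CA[i], pos_C[i],
                                  const.BOND_C_N, const.ANGLES[("CA", "C", "N")][0], psi[i])
        pos_CA[i + 1] = nerf_place(pos_CA[i], pos_C[i], pos_N[i + 1],
                                   const.BOND_N_CA, const.ANGLES[("C", "N", "CA")][0], omega[i])
        pos_C[i + 1] = nerf_place(pos_C[i], pos_N[i + 1], pos_CA[i + 1],
                                  const.BOND_CA_C, const.ANGLES[("N", "CA", "C")][0], phi[i + 1])

    for i in range(n_res):
        coords[topo.atom_id(i, "N")] = pos_N[i]
        coords[topo.atom_id(i, "CA")] = pos_CA[i]
        coords[topo.atom_id(i, "C")] = pos_C[i]
        coords[topo.atom_id(i, "O")] = nerf_place(
            pos_N[i], pos_CA[i], pos_C[i],
            const.BOND_C_O, const.ANGLES[("CA", "C", "O")][0], psi[i] + 180.0)
        if i == 0:
            coords[topo.atom_id(i, "H")] = nerf_place(
                pos_C[0], pos_CA[0], pos_N[0],
                const.BOND_N_H, const.ANGLES[("H", "N", "CA")][0], 180.0)
        else:
            coords[topo.atom_id(i, "H")] = place_amide_hydrogen(
                pos_C[i - 1], pos_N[i], pos_CA[i])
        if topo.has_atom(i, "CB"):
            coords[topo.atom_id(i, "CB")] = place_cbeta(
                pos_N[i], pos_CA[i], pos_C[i],
                cbeta_bond_length(topo.sequence[i]))

    return Conformation(coords)


#: preset backbone dihedrals, degrees
PRESETS = {
    "extended": (-120.0, 120.0),
    "ideal_helix": (-57.0, -47.0),
}


def generate_conformation(topo: CGTopology, preset: str, seed: int | None = None) -> Conformation:
    """Build a preset conformation: extended, ideal_helix or random_coil.

    ``random_coil`` draws per-residue (phi, psi) uniformly from the
    sterically allowed set by rejection against the tube term evaluated on a
    local three-residue fragment; it is deterministic for a given seed.
    """
    n = topo.n_residues
    if preset in PRESETS:
        phi0, psi0 = PRESETS[preset]
        return build_from_dihedrals(topo, np.full(n, phi0), np.full(n, psi0))
    if preset != "random_coil":
        raise ValueError(f"unknown preset {preset!r}")

    from .analysis import steric_energy  # lazy: analysis depends on geometry

    rng = np.random.default_rng(seed)
    phi = np.zeros(n)
    psi = np.zeros(n)
    for i in range(n):
        aa = topo.sequence[i]
        for _attempt in range(_MAX_COIL_ATTEMPTS):
            p, q = rng.uniform(-180.0, 180.0, size=2)
            if steric_energy(aa, p, q) == 0.0:
                phi[i], psi[i] = p, q
                break
        else:
            raise RuntimeError(
                f"rejection sampling failed for residue {i} ({aa}) after "
                f"{_MAX_COIL_ATTEMPTS} attempts")
    return build_from_dihedrals(topo, phi, psi)
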