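"""Deterministic synthetic inputs: homopolymer chains, dipeptide fragments,
a two-particle hydrogen-bond dimer and a synthetic all-atom tripeptide.

Everything is generated programmatically, so tests and examples run without
downloads; equal specifications always produce identical structures.
"""

from __future__ import annotations

import numpy as np

from . import constants as const
from .geometry import build_from_dihedrals, generate_conformation
from .residues import ONE_TO_THREE
from .topology import CGAtom, CGTopology, Conformation, build_topology


def make_polyX(residue: str, n: int, preset: str = "extended",
               seed: int | None = None) -> tuple[CGTopology, Conformation]:
    """Homopolymer chain of ``n`` copies of ``residue`` in a preset state.

    The canonical large fixture is the 60-residue polyvaline random coil.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    topo = build_topology(residue * n)
    conf = generate_conformation(topo, preset, seed=seed)
    return topo, conf


def make_dipeptide(aa: str, phi: float, psi: float) -> tuple[CGTopology, Conformation]:
    """Three-residue homopolymer fragment with all residues at (phi, psi).

    Used by the steric-map machinery; the central residue's angles are
    exactly the requested values and all bonded geometry is ideal.
    """
    topo = build_topology(aa * 3)
    conf = build_from_dihedrals(topo, np.full(3, phi), np.full(3, psi))
    return topo, conf


class ToyDimer:
    """Minimal two-particle system exposing a single O...H pair.

    The two atoms are declared to belong to residues 0 and 4 so the
    hydrogen-bond separation rule |i-j| >= 4 is satisfied; there are no
    bonds, so the pair interacts through the 10-12 potential alone.
    """

    def __init__(self, r: float):
        if r <= 0:
            raise ValueError("separation must be positive")
        seq = ["G", "G", "G", "G", "G"]
        atoms = [CGAtom(0, "O"), CGAtom(4, "H")]
        self.topology = CGTopology(seq, atoms, bonds=[], angles=[],
                                   dihedrals=[], impropers=[])
        self.conformation = Conformation(
            np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]))

    def at(self, r: float) -> Conformation:
        return Conformation(np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]))


def make_toy_dimer(r: float) -> tuple[CGTopology, Conformation]:
    """One O...H pair at separation ``r`` nm with residue separation 4."""
    dimer = ToyDimer(r)
    return dimer.topology, dimer.conformation


#: pseudo side-chain atoms attached beyond CB for the synthetic tripeptide
_FAKE_SIDECHAINS = {
    "A": [],                      # Ala: CB only
    "V": ["CG1", "CG2"],          # Val: two methyls
    "L": ["CG", "CD1", "CD2"],    # Leu
}


def make_all_atom_tripeptide() -> tuple[list[dict], str]:
    """Synthetic Ala-Val-Leu tripeptide with side chains beyond CB.

    Returns ``(atom_records, sequence)`` where each record carries
    ``name``, ``res_name``, ``res_id`` and ``coord`` (nm).  The backbone and
    CB positions are ideal coarse-grained geometry; side-chain atoms beyond
    CB sit at plausible tetrahedral offsets.  This synthetic stand-in
    exercises PDB coarse-graining (side-chain stripping, CB rescaling)
    without any external structure file.
    """
    seq = "AVL"
    topo = build_topology(seq)
    conf = generate_conformation(topo, "extended")
    rng = np.random.default_rng(20150)
    records = []
    for ri, aa in enumerate(seq):
        res_name = ONE_TO_THREE[aa]
        for kind in ("N", "H", "CA", "CB", "C", "O"):
            if not topo.has_atom(ri, kind):
                continue
            records.append({
                "name": kind, "res_name": res_name, "res_id": ri + 1,
                "coord": conf.coordinates[topo.atom_id(ri, kind)].copy(),
            })
        cb = conf.coordinates[topo.atom_id(ri, "CB")]
        ca = conf.coordinates[topo.atom_id(ri, "CA")]
        u = (cb - ca) / np.linalg.norm(cb - ca)
        for k, name in enumerate(_FAKE_SIDECHAINS[aa]):
            perp = np.cross(u, rng.normal(size=3))
            perp /= np.linalg.norm(perp)
            coord = cb + 0.153 * (0.5 * u + 0.87 * perp * (1 if k % 2 else -1))
            records.append({
                "name": name, "res_name": res_name, "res_id": ri + 1,
                "coord": coord,
            })
    return records, seq
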