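"""Build the six-site-per-residue chain topology.

A residue carries the five backbone sites N, H, CA, C, O plus a CB side-chain
site for every residue except glycine.  Atom ordering is residue-major and
deterministic: ``[N, H, CA, (CB), C, O]``.  All covalent bonds are holonomic
constraints during dynamics; angles and a small set of dihedrals/impropers
are flexible bonded terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from . import constants as const
from .residues import AminoAcidSpec, amino_acid_spec

#: canonical atom kinds, in per-residue order
KINDS = ("N", "H", "CA", "CB", "C", "O")
KIND_CODE = {k: i for i, k in enumerate(KINDS)}


def cbeta_bond_length(aa: str) -> float:
    """CA-CB constraint length (nm) for a one-letter residue code.

    The per-residue multiplier scales the base Amber CA-CB bond of
    0.1526 nm.  Glycine has no CB and raises ``ValueError``.
    """
    spec = amino_acid_spec(aa)
    if not spec.has_cbeta:
        raise ValueError("glycine has no CB site")
    return spec.cbeta_scale * const.BOND_CA_CB


@dataclass(frozen=True)
class CGAtom:
    """One coarse-grained site: residue index (0-based) and force-field kind."""

    residue_index: int
    kind: str


@dataclass
class Conformation:
    """Cartesian coordinates (nm) for every atom of a topology, in vacuo."""

    coordinates: np.ndarray  # (n_atoms, 3), nm

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")

    def copy(self) -> "Conformation":
        return Conformation(self.coordinates.copy())


# Nonbonded applicability windows, keyed by term.  |i-j| is the residue
# separation; "inf" means no upper limit.  These rules are what the pair-list
# builder in :mod:`camtube.energy` enforces.
PAIR_RULES = {
    "tube": {"kinds": "threshold table", "sep": "|i-j| > 1, plus O-O and H-H at |i-j| = 1"},
    "hbond": {"kinds": ("O", "H"), "sep": "|i-j| >= 4"},
    "hbond_direction_CH": {"kinds": ("C", "H"), "sep": "|i-j| >= 4"},
    "hbond_direction_ON": {"kinds": ("O", "N"), "sep": "|i-j| >= 4"},
    "curvature": {"kinds": ("C", "H"), "sep": "1 < |i-j| < 4"},
    "hydrophobic": {"kinds": ("CB", "CB"), "sep": "|i-j| > 1"},
}


@dataclass
class CGTopology:
    """The complete bonded description of a coarse-grained chain."""

    sequence: list[str]
    atoms: list[CGAtom]
    bonds: list[tuple[int, int, float]]                      # (i, j, length nm)
    angles: list[tuple[int, int, int, float, float]]         # (i,j,k, theta0 deg, k)
    dihedrals: list[tuple[tuple[int, int, int, int], list[tuple[float, float, int]]]]
    impropers: list[tuple[tuple[int, int, int, int], float]]  # periodic n=2, gamma=180
    pair_exclusions: dict = field(default_factory=lambda: dict(PAIR_RULES))

    # ---- derived arrays --------------------------------------------------
    def __post_init__(self) -> None:
        self.n_atoms = len(self.atoms)
        self.n_residues = len(self.sequence)
        self.kind_codes = np.array([KIND_CODE[a.kind] for a in self.atoms], dtype=np.int64)
        self.residue_index = np.array([a.residue_index for a in self.atoms], dtype=np.int64)
        self._index = {(a.residue_index, a.kind): i for i, a in enumerate(self.atoms)}
        self.masses = np.array([self._mass(a) for a in self.atoms], dtype=np.float64)

    def _mass(self, atom: CGAtom) -> float:
        if atom.kind == "CB":
            return const.SIDECHAIN_MASS[self.sequence[atom.residue_index]]
        return const.ATOM_MASS[atom.kind]

    def atom_id(self, residue: int, kind: str) -> int:
        """Flat atom index of (residue, kind); KeyError if absent (Gly CB)."""
        return self._index[(residue, kind)]

    def has_atom(self, residue: int, kind: str) -> bool:
        return (residue, kind) in self._index

    def spec(self, residue: int) -> AminoAcidSpec:
        return amino_acid_spec(self.sequence[residue])

    # ---- checks ----------------------------------------------------------
    def validate(self) -> None:
        """Raise ``ValueError`` on dangling bonds or malformed terms."""
        n = self.n_atoms
        for i, j, length in self.bonds:
            if not (0 <= i < n and 0 <= j < n and i != j):
                raise ValueError(f"dangling bond ({i}, {j})")
            if length <= 0:
                raise ValueError(f"non-positive bond length for ({i}, {j})")
        for i, j, k, theta0, kf in self.angles:
            if len({i, j, k}) != 3 or max(i, j, k) >= n or min(i, j, k) < 0:
                raise ValueError(f"malformed angle ({i}, {j}, {k})")
            if not (0.0 < theta0 < 180.0) or kf < 0:
                raise ValueError(f"out-of-range angle parameters ({theta0}, {kf})")
        for quad, _terms in self.dihedrals:
            if len(set(quad)) != 4 or max(quad) >= n or min(quad) < 0:
                raise ValueError(f"malformed dihedral {quad}")
        for quad, _k in self.impropers:
            if len(set(quad)) != 4 or max(quad) >= n or min(quad) < 0:
                raise ValueError(f"malformed improper {quad}")

    # ---- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "sequence": "".join(self.sequence),
            "atoms": [{"residue": a.residue_index, "kind": a.kind} for a in self.atoms],
            "bonds": [[i, j, float(l)] for i, j, l in self.bonds],
            "angles": [[i, j, k, float(t), float(f)] for i, j, k, t, f in self.angles],
            "dihedrals": [
                {"atoms": list(q), "terms": [[float(v), float(g), int(m)] for v, g, m in t]}
                for q, t in self.dihedrals
            ],
            "impropers": [{"atoms": list(q), "k": float(k)} for q, k in self.impropers],
            "pair_exclusions": self.pair_exclusions,
        }

    def dump(self, path) -> None:
        """Write the topology as a human-readable YAML file."""
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def build_topology(sequence: str) -> CGTopology:
    """Construct the deterministic topology for a one-letter sequence.

    Bonds: N-H, N-CA, CA-CB (residue-scaled), CA-C, C-O within each residue
    and the C-N peptide bond between neighbours.  Angles come from the
    embedded backbone table; the residue-grouped CB dihedrals and the
    peptide-plane impropers complete the bonded terms.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = list(sequence.upper())
    specs = [amino_acid_spec(aa) for aa in seq]  # validates codes

    atoms: list[CGAtom] = []
    for ri, spec in enumerate(specs):
        for kind in KINDS:
            if kind == "CB" and not spec.has_cbeta:
                continue
            atoms.append(CGAtom(ri, kind))

    index = {(a.residue_index, a.kind): i for i, a in enumerate(atoms)}
    aid = lambda ri, kind: index[(ri, kind)]

    bonds = []
    angles = []
    dihedrals = []
    impropers = []

    from .params import dihedral_group_terms  # deferred: params imports data files

    for ri, spec in enumerate(specs):
        N, H, CA, C, O = (aid(ri, k) for k in ("N", "H", "CA", "C", "O"))
        bonds.append((N, H, const.BOND_N_H))
        bonds.append((N, CA, const.BOND_N_CA))
        bonds.append((CA, C, const.BOND_CA_C))
        bonds.append((C, O, const.BOND_C_O))
        angles.append((N, CA, C, *const.ANGLES[("N", "CA", "C")]))
        angles.append((CA, C, O, *const.ANGLES[("CA", "C", "O")]))
        angles.append((H, N, CA, *const.ANGLES[("H", "N", "CA")]))
        if spec.has_cbeta:
            CB = aid(ri, "CB")
            bonds.append((CA, CB, cbeta_bond_length(spec.code)))
            angles.append((N, CA, CB, *const.ANGLES[("N", "CA", "CB")]))
            angles.append((C, CA, CB, *const.ANGLES[("C", "CA", "CB")]))
            if ri > 0:
                dihedrals.append(
                    ((CB, CA, N, aid(ri - 1, "C")),
                     dihedral_group_terms(spec.dihedral_group_phi))
                )
            if ri < len(seq) - 1:
                dihedrals.append(
                    ((CB, CA, C, aid(ri + 1, "N")),
                     dihedral_group_terms(spec.dihedral_group_psi))
                )
        if ri < len(seq) - 1:
            N1, H1, CA1 = (aid(ri + 1, k) for k in ("N", "H", "CA"))
            bonds.append((C, N1, const.BOND_C_N))
            angles.append((CA, C, N1, *const.ANGLES[("CA", "C", "N")]))
            angles.append((O, C, N1, *const.ANGLES[("O", "C", "N")]))
            angles.append((C, N1, CA1, *const.ANGLES[("C", "N", "CA")]))
            angles.append((H1, N1, C, *const.ANGLES[("H", "N", "C")]))
            impropers.append(((CA, C, N1, CA1), const.K_IMPROPER_OMEGA))
            impropers.append(((CA, N1, C, O), const.K_IMPROPER_O))
            impropers.append(((C, CA1, N1, H1), const.K_IMPROPER_H))

    topo = CGTopology(seq, atoms, bonds, angles, dihedrals, impropers)
    topo.validate()
    return topo
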