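"""PDB and FASTA input/output for the six-site model (biotite-backed).

Coordinates are nm internally and Angstrom on disk; written atom names are
the six force-field kinds (N, H, CA, CB, C, O) on one chain, with
MODEL/ENDMDL framing for trajectories.
"""

from __future__ import annotations

import warnings

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.sequence.io.fasta import FastaFile

from .geometry import place_amide_hydrogen, place_cbeta
from .residues import ONE_TO_THREE, THREE_TO_ONE
from .topology import CGTopology, Conformation, build_topology, cbeta_bond_length

_ELEMENT = {"N": "N", "H": "H", "CA": "C", "CB": "C", "C": "C", "O": "O"}


def read_fasta(path) -> str:
    """First sequence of a FASTA file as a one-letter string."""
    fasta = FastaFile.read(str(path))
    for _header, seq in fasta.items():
        return str(seq)
    raise ValueError(f"no sequences in {path}")


def _to_atom_array(topo: CGTopology, conf: Conformation) -> struc.AtomArray:
    n = topo.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(conf.coordinates) * 10.0  # nm -> A
    arr.chain_id = np.full(n, "A")
    arr.res_id = topo.residue_index + 1
    arr.res_name = np.array([ONE_TO_THREE[topo.sequence[a.residue_index]]
                             for a in topo.atoms])
    arr.atom_name = np.array([a.kind for a in topo.atoms])
    arr.element = np.array([_ELEMENT[a.kind] for a in topo.atoms])
    arr.hetero = np.zeros(n, dtype=bool)
    arr.set_annotation("occupancy", np.ones(n))
    arr.set_annotation("b_factor", np.zeros(n))
    return arr


def write_pdb(path, topo: CGTopology, conformations) -> None:
    """Write one conformation, or a list of them as a multi-model file."""
    if isinstance(conformations, Conformation):
        conformations = [conformations]
    arrays = [_to_atom_array(topo, c) for c in conformations]
    pdb = PDBFile()
    if len(arrays) == 1:
        pdb.set_structure(arrays[0])
    else:
        pdb.set_structure(struc.stack(arrays))
    pdb.write(str(path))


def write_trajectory_pdb(path, topo: CGTopology, trajectory) -> None:
    write_pdb(path, topo,
              [trajectory.conformation(i) for i in range(trajectory.n_frames)])


def _load_models(path) -> struc.AtomArray:
    try:
        pdb = PDBFile.read(str(path))
    except Exception as exc:  # pragma: no cover - biotite error text varies
        raise ValueError(f"malformed PDB file {path}: {exc}") from exc
    if pdb.get_model_count() == 0:
        raise ValueError(f"no coordinate records in {path}")
    if pdb.get_model_count() > 1:
        warnings.warn(f"{path}: {pdb.get_model_count()} models, using the first")
    arr = pdb.get_structure(model=1, extra_fields=["occupancy", "b_factor"])
    n_het = int(arr.hetero.sum())
    if n_het:
        warnings.warn(f"{path}: ignored {n_het} HETATM/water atoms")
        arr = arr[~arr.hetero]
    arr = arr[np.isin(arr.res_name, list(THREE_TO_ONE))]
    if arr.array_length() == 0:
        raise ValueError(f"no standard amino-acid atoms in {path}")
    chains = np.unique(arr.chain_id)
    if len(chains) > 1:
        raise ValueError(f"{path}: multiple chains {list(chains)}; supply one chain")
    return arr


def read_pdb(path) -> tuple[CGTopology, Conformation]:
    """Read a PDB file already in the six-site representation.

    Residues must carry N, CA, C, O (H and CB are reconstructed when
    absent); any atoms outside the six kinds are rejected here — use
    :func:`coarse_grain_structure` for all-atom input.
    """
    arr = _load_models(path)
    extra = set(np.unique(arr.atom_name)) - set(_ELEMENT)
    if extra:
        raise ValueError(
            f"{path} contains non-model atoms {sorted(extra)}; "
            "use coarse_grain_structure for all-atom files")
    return _build_from_atoms(arr)


def coarse_grain_structure(path_or_array) -> tuple[CGTopology, Conformation]:
    """Map an all-atom structure onto the six-site model.

    Keeps N, CA, C, O; keeps H (or reconstructs it from ideal amide
    geometry) and CB (rescaled to the residue-specific bond length along the
    original CA->CB direction, or placed tetrahedrally when missing); every
    other atom is discarded.
    """
    if isinstance(path_or_array, struc.AtomArray):
        arr = path_or_array
    else:
        arr = _load_models(path_or_array)
    return _build_from_atoms(arr)


def _build_from_atoms(arr: struc.AtomArray) -> tuple[CGTopology, Conformation]:
    res_ids = np.unique(arr.res_id)
    seq = []
    per_res = []
    for rid in res_ids:
        sub = arr[arr.res_id == rid]
        aa = THREE_TO_ONE[sub.res_name[0]]
        seq.append(aa)
        names = list(sub.atom_name)
        missing = [k for k in ("N", "CA", "C", "O") if k not in names]
        if missing:
            raise ValueError(f"residue {int(rid)} ({sub.res_name[0]}) is "
                             f"missing backbone atoms {missing}")
        per_res.append(sub)

    topo = build_topology("".join(seq))
    coords = np.zeros((topo.n_atoms, 3))
    for ri, sub in enumerate(per_res):
        get = lambda name: sub.coord[list(sub.atom_name).index(name)] / 10.0
        names = list(sub.atom_name)
        N, CA, C, O = get("N"), get("CA"), get("C"), get("O")
        for kind, xyz in (("N", N), ("CA", CA), ("C", C), ("O", O)):
            coords[topo.atom_id(ri, kind)] = xyz
        # amide H: keep if present, else ideal peptide-plane reconstruction
        h_name = next((nm for nm in ("H", "HN", "H1") if nm in names), None)
        if h_name is not None:
            coords[topo.atom_id(ri, "H")] = get(h_name)
        elif ri > 0:
            c_prev = per_res[ri - 1].coord[
                list(per_res[ri - 1].atom_name).index("C")] / 10.0
            coords[topo.atom_id(ri, "H")] = place_amide_hydrogen(c_prev, N, CA)
        else:
            # N-terminal residue: place H opposite the carbonyl O direction
            coords[topo.atom_id(ri, "H")] = place_amide_hydrogen(O, N, CA)
        if topo.has_atom(ri, "CB"):
            length = cbeta_bond_length(topo.sequence[ri])
            if "CB" in names:
                u = get("CB") - CA
                coords[topo.atom_id(ri, "CB")] = CA + length * u / np.linalg.norm(u)
            else:
                coords[topo.atom_id(ri, "CB")] = place_cbeta(N, CA, C, length)
    topo.validate()
    return topo, Conformation(coords)
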