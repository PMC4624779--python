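"""Structural observables: torsions, compactness, hydrogen bonds, secondary
structure, steric maps, RMSD and CV-space microstate binning.

Secondary-structure fragment counting uses crisp Ramachandran boxes over
6-residue windows; this is a documented stand-in for switching-function
based fragment CVs and is configurable through the box constants.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.spatial.transform import Rotation

from . import energy as E
from .geometry import build_from_dihedrals, dihedral_angle
from .params import ForceFieldParams
from .topology import CGTopology, Conformation, build_topology

#: (phi_lo, phi_hi, psi_lo, psi_hi) in degrees
ALPHA_BOX = (-100.0, -30.0, -80.0, -5.0)
BETA_BOX = (-180.0, -90.0, 90.0, 180.0)
SS_WINDOW = 6


def backbone_dihedrals(conf: Conformation, topo: CGTopology) -> np.ndarray:
    """Per-residue (phi, psi) in degrees, NaN where undefined.

    phi(i) = C'(i-1)-N-CA-C', psi(i) = N-CA-C'-N(i+1); a single-residue
    chain returns an empty array.
    """
    n = topo.n_residues
    if n < 2:
        return np.empty((0, 2))
    pos = conf.coordinates
    out = np.full((n, 2), np.nan)
    for i in range(n):
        N, CA, C = (pos[topo.atom_id(i, k)] for k in ("N", "CA", "C"))
        if i > 0:
            out[i, 0] = dihedral_angle(pos[topo.atom_id(i - 1, "C")], N, CA, C)
        if i < n - 1:
            out[i, 1] = dihedral_angle(N, CA, C, pos[topo.atom_id(i + 1, "N")])
    return out


def radius_of_gyration(conf: Conformation, topo: CGTopology) -> float:
    """Unweighted RMS distance of the CA atoms from their centroid (nm)."""
    ca = conf.coordinates[topo.kind_codes == 2]
    if ca.shape[0] == 0:
        raise ValueError("topology has no CA atoms")
    centred = ca - ca.mean(axis=0)
    return float(np.sqrt((centred ** 2).sum(axis=1).mean()))


def _in_box(phi: float, psi: float, box) -> bool:
    return box[0] <= phi <= box[1] and box[2] <= psi <= box[3]


def count_ss_fragments(dihedrals: np.ndarray, mode: str,
                       window: int = SS_WINDOW) -> int:
    """Number of 6-residue windows fully inside the alpha or beta box.

    NaN angles (chain termini) count as inside, so terminal windows are
    classified by their defined angles only.
    """
    box = {"alpha": ALPHA_BOX, "beta": BETA_BOX}[mode]
    dihedrals = np.asarray(dihedrals, dtype=float)
    n = dihedrals.shape[0]
    if n < window:
        return 0
    ok = np.ones(n, dtype=bool)
    for i in range(n):
        phi, psi = dihedrals[i]
        if not math.isnan(phi) and not (box[0] <= phi <= box[1]):
            ok[i] = False
        if not math.isnan(psi) and not (box[2] <= psi <= box[3]):
            ok[i] = False
    return int(sum(ok[i:i + window].all() for i in range(n - window + 1)))


@lru_cache(maxsize=8)
def _ideal_helix_ca(window: int) -> tuple:
    topo = build_topology("A" * window)
    conf = build_from_dihedrals(topo, np.full(window, -57.0),
                                np.full(window, -47.0))
    ca = np.array([conf.coordinates[topo.atom_id(i, "CA")]
                   for i in range(window)])
    return tuple(map(tuple, ca - ca.mean(axis=0)))


def count_helical_fragments_rmsd(conf: Conformation, topo: CGTopology,
                                 window: int = SS_WINDOW,
                                 threshold: float = 0.10) -> int:
    """Six-residue windows whose CA trace superposes on an ideal helix.

    A window counts when its optimal-superposition CA RMSD to an ideal
    (-57, -47) helical fragment falls below ``threshold`` nm.  This is the
    fragment-RMSD notion of helical content (a crisp-threshold version of
    switching-function helix-counting CVs) and is more tolerant of the
    backbone's thermal scatter than the crisp dihedral boxes of
    :func:`count_ss_fragments`.
    """
    n = topo.n_residues
    if n < window:
        return 0
    ideal = np.asarray(_ideal_helix_ca(window))
    ca = conf.coordinates[topo.kind_codes == 2]
    count = 0
    for s in range(n - window + 1):
        w = ca[s:s + window] - ca[s:s + window].mean(axis=0)
        rot, _ = Rotation.align_vectors(w, ideal)
        r = np.sqrt(((w - rot.apply(ideal)) ** 2).sum(axis=1).mean())
        count += r < threshold
    return int(count)


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric H-bond definition: O...H below ``distance`` with |i-j| >= min_sep."""

    distance: float = 0.25  # nm; ~30% of the 10-12 well depth remains here
    min_sep: int = 4


def detect_hbonds(conf: Conformation, topo: CGTopology,
                  criteria: HBondCriteria = HBondCriteria()) -> list[tuple[int, int]]:
    """Deduplicated (donor residue, acceptor residue) pairs.

    The donor is the residue providing the amide H, the acceptor the one
    providing the carbonyl O.
    """
    pos = conf.coordinates
    n = topo.n_residues
    found = set()
    for acc in range(n):
        o = pos[topo.atom_id(acc, "O")]
        for don in range(n):
            if abs(don - acc) < criteria.min_sep:
                continue
            h = pos[topo.atom_id(don, "H")]
            if np.linalg.norm(o - h) < criteria.distance:
                found.add((don, acc))
    return sorted(found)


def hbonded_fraction(conf, topo, criteria: HBondCriteria = HBondCriteria()) -> float:
    """Fraction of residues participating in at least one hydrogen bond."""
    pairs = detect_hbonds(conf, topo, criteria)
    involved = {r for pair in pairs for r in pair}
    return len(involved) / topo.n_residues


@lru_cache(maxsize=32)
def _fragment_topology(aa: str) -> CGTopology:
    return build_topology(aa * 3)


_DEFAULT_PARAMS = None


def _default_params() -> ForceFieldParams:
    global _DEFAULT_PARAMS
    if _DEFAULT_PARAMS is None:
        _DEFAULT_PARAMS = ForceFieldParams()
    return _DEFAULT_PARAMS


def steric_energy(aa: str, phi: float, psi: float,
                  params: ForceFieldParams | None = None) -> float:
    """Tube energy of a three-residue homopolymer fragment at (phi, psi).

    All three residues share the central residue's angles; the fragment's
    self-avoiding sphere energy is zero exactly on the sterically allowed
    set of the Ramachandran map.
    """
    params = params or _default_params()
    topo = _fragment_topology(aa)
    conf = build_from_dihedrals(topo, np.full(3, phi), np.full(3, psi))
    return E.tube_energy(conf, topo, params)[0]


def steric_map(aa: str = "A", grid_step: float = 2.0,
               params: ForceFieldParams | None = None):
    """Tube-energy map over the (phi, psi) grid.

    Returns ``(phi_grid, psi_grid, energies)``; the boolean allowed map is
    ``energies == 0``.  Grid nodes run from -180 in steps of ``grid_step``.
    """
    params = params or _default_params()
    phis = np.arange(-180.0, 180.0, grid_step)
    psis = np.arange(-180.0, 180.0, grid_step)
    out = np.empty((phis.size, psis.size))
    for i, phi in enumerate(phis):
        for j, psi in enumerate(psis):
            out[i, j] = steric_energy(aa, phi, psi, params)
    return phis, psis, out


def rmsd(conf_a: Conformation, conf_b: Conformation,
         topo: CGTopology | None = None,
         selection: set[str] | None = None) -> float:
    """Optimal-superposition RMSD (nm) over the selected atom kinds.

    Least-squares rotation + translation (no reflection), Kabsch via
    quaternion alignment.  Without a topology all atoms are used.
    """
    a = conf_a.coordinates
    b = conf_b.coordinates
    if selection is not None:
        if topo is None:
            raise ValueError("selection requires a topology")
        mask = np.isin([atom.kind for atom in topo.atoms], sorted(selection))
        a = a[mask]
        b = b[mask]
    if a.shape != b.shape:
        raise ValueError("selected atom counts differ")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    rot, _ = Rotation.align_vectors(a, b)
    diff = a - rot.apply(b)
    return float(np.sqrt((diff ** 2).sum(axis=1).mean()))


# ---------------------------------------------------------------------------
# collective-variable records and microstate binning
# ---------------------------------------------------------------------------

@dataclass
class CVRecord:
    """Per-frame values of the four collective variables."""

    frame_time: float
    dihedral_correlation: float
    rgyr: float
    alpha_count: int
    beta_count: int

    def as_tuple(self):
        return (self.dihedral_correlation, self.rgyr,
                float(self.alpha_count), float(self.beta_count))


def dihedral_correlation(dihedrals: np.ndarray) -> float:
    """Sum over adjacent residues of (1 + cos(delta phi))/2 + (1 + cos(delta psi))/2."""
    d = np.radians(np.asarray(dihedrals, dtype=float))
    s = 0.0
    for col in (0, 1):
        v = d[:, col]
        v = v[~np.isnan(v)]
        if v.size >= 2:
            s += float(np.sum(0.5 * (1.0 + np.cos(np.diff(v)))))
    return s


def cv_record(conf: Conformation, topo: CGTopology, time_ps: float = 0.0) -> CVRecord:
    """Evaluate all four CVs for one frame."""
    dih = backbone_dihedrals(conf, topo)
    return CVRecord(
        frame_time=time_ps,
        dihedral_correlation=dihedral_correlation(dih),
        rgyr=radius_of_gyration(conf, topo),
        alpha_count=count_ss_fragments(dih, "alpha"),
        beta_count=count_ss_fragments(dih, "beta"),
    )


@dataclass
class MicrostateTable:
    """Occupied CV-space hypercubes with populations and member frames."""

    widths: tuple
    anchor: float
    cells: dict = field(default_factory=dict)  # index tuple -> list of frame ids
    skipped: int = 0

    @property
    def populations(self) -> dict:
        return {k: len(v) for k, v in self.cells.items()}

    @property
    def n_microstates(self) -> int:
        return len(self.cells)


def bin_microstates(cv_values, widths, anchor: float = 0.0) -> MicrostateTable:
    """Assign frames to half-open hypercubes ``floor((cv - anchor)/width)``.

    ``cv_values`` is (n_frames, n_cv) or a list of :class:`CVRecord`.
    Frames with non-finite CVs are skipped with a warning count.
    """
    if len(cv_values) and isinstance(cv_values[0], CVRecord):
        arr = np.array([r.as_tuple() for r in cv_values], dtype=float)
    else:
        arr = np.atleast_2d(np.asarray(cv_values, dtype=float))
    widths = np.broadcast_to(np.asarray(widths, dtype=float), (arr.shape[1],))
    if np.any(widths <= 0):
        raise ValueError("grid widths must be positive")
    table = MicrostateTable(widths=tuple(widths), anchor=anchor)
    for fid, row in enumerate(arr):
        if not np.all(np.isfinite(row)):
            table.skipped += 1
            continue
        idx = tuple(int(v) for v in np.floor((row - anchor) / widths))
        table.cells.setdefault(idx, []).append(fid)
    if table.skipped:
        warnings.warn(f"{table.skipped} frames had non-finite CVs and were skipped")
    return table
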