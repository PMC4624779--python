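"""Energy terms of the coarse-grained force field and their analytic forces.

Six nonbonded/bonded contributions build the model:

* ``tube`` — half-harmonic self-avoiding spheres with atom-pair thresholds,
  active for residue separation |i-j| > 1 for every tabulated kind pair and
  additionally for O-O and H-H at |i-j| = 1;
* ``hbond`` — a 10-12 well of depth eps_H at 0.2 nm between O(i) and H(j)
  for |i-j| >= 4, truncated and shifted at 0.8 nm;
* ``hbond_direction`` — stiff avoidance spheres on C'(i)...H(j) and
  O(i)...N(j) (|i-j| >= 4) that force near-linear hydrogen bonds;
* ``hydrophobic`` — a sigmoidal contact potential between CB sites of
  hydrophobic residues, |i-j| > 1;
* ``curvature`` — a soft C'(i)...H(j) repulsion for |i-j| in {2, 3} that
  marginally penalises tight helical turns;
* ``dihedral``/``improper``/``angle`` — the residue-grouped CB torsions,
  peptide-plane restraints and harmonic backbone angles.

Pair lists depend only on the topology (residue separations), so they are
built once per (topology, parameter) pair and cached; distance cutoffs are
applied inside the compiled kernels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .params import ForceFieldParams
from .topology import CGTopology, Conformation

_SEP_TUBE_NN = {("H", "H"), ("O", "O")}  # kind pairs kept at |i-j| = 1


@dataclass
class PairTables:
    """Flat index arrays for every energy term of one topology."""

    tube_i: np.ndarray
    tube_j: np.ndarray
    tube_d: np.ndarray
    ch_i: np.ndarray
    ch_j: np.ndarray
    on_i: np.ndarray
    on_j: np.ndarray
    cu_i: np.ndarray
    cu_j: np.ndarray
    hb_o: np.ndarray
    hb_h: np.ndarray
    ph_i: np.ndarray
    ph_j: np.ndarray
    ph_b: np.ndarray
    di: tuple  # (a, b, c, d, V, gamma_rad, n)
    im: tuple
    an: tuple  # (i, j, k, theta0_rad, k)
    con: tuple  # (i, j, d0)
    stats: np.ndarray = field(default_factory=lambda: np.zeros(4, dtype=np.int64))

    @property
    def d_ch_arr(self):
        return np.full(self.ch_i.shape[0], self._d_ch)

    @property
    def d_on_arr(self):
        return np.full(self.on_i.shape[0], self._d_on)

    @property
    def d_cu_arr(self):
        return np.full(self.cu_i.shape[0], self._d_ch)


def _fingerprint(p: ForceFieldParams):
    return (tuple(sorted(p.sphere_thresholds.items())), p.d_CH, p.d_ON,
            tuple(sorted(p.B.items())))


def build_pair_tables(topo: CGTopology, p: ForceFieldParams) -> PairTables:
    """Enumerate every candidate pair per term (separation windows only)."""
    cache = getattr(topo, "_pair_cache", None)
    if cache is None:
        cache = topo._pair_cache = {}
    key = _fingerprint(p)
    if key in cache:
        return cache[key]

    nres = topo.n_residues
    thr = p.sphere_thresholds
    tube_i, tube_j, tube_d = [], [], []
    ch_i, ch_j, on_i, on_j, cu_i, cu_j = [], [], [], [], [], []
    hb_o, hb_h = [], []
    ph_i, ph_j, ph_b = [], [], []

    atoms_of = [
        [(a.kind, idx) for idx, a in enumerate(topo.atoms) if a.residue_index == r]
        for r in range(nres)
    ]
    for ri in range(nres):
        for rj in range(ri + 1, nres):
            sep = rj - ri
            if sep == 1:
                for ka, ia in atoms_of[ri]:
                    for kb, ib in atoms_of[rj]:
                        if ka == kb and (ka, kb) in _SEP_TUBE_NN:
                            tube_i.append(ia)
                            tube_j.append(ib)
                            tube_d.append(thr[(ka, kb)])
            else:
                for ka, ia in atoms_of[ri]:
                    for kb, ib in atoms_of[rj]:
                        key2 = tuple(sorted((ka, kb)))
                        if key2 in thr:
                            tube_i.append(ia)
                            tube_j.append(ib)
                            tube_d.append(thr[key2])
            if 1 < sep < 4:
                for a, b in ((ri, rj), (rj, ri)):
                    if topo.has_atom(a, "C") and topo.has_atom(b, "H"):
                        cu_i.append(topo.atom_id(a, "C"))
                        cu_j.append(topo.atom_id(b, "H"))
            if sep >= 4:
                for a, b in ((ri, rj), (rj, ri)):
                    if topo.has_atom(a, "O") and topo.has_atom(b, "H"):
                        hb_o.append(topo.atom_id(a, "O"))
                        hb_h.append(topo.atom_id(b, "H"))
                    if topo.has_atom(a, "C") and topo.has_atom(b, "H"):
                        ch_i.append(topo.atom_id(a, "C"))
                        ch_j.append(topo.atom_id(b, "H"))
                    if topo.has_atom(a, "O") and topo.has_atom(b, "N"):
                        on_i.append(topo.atom_id(a, "O"))
                        on_j.append(topo.atom_id(b, "N"))
            if sep > 1 and topo.has_atom(ri, "CB") and topo.has_atom(rj, "CB"):
                bij = p.B.get(tuple(sorted((topo.sequence[ri], topo.sequence[rj]))), 0.0)
                if bij != 0.0:
                    ph_i.append(topo.atom_id(ri, "CB"))
                    ph_j.append(topo.atom_id(rj, "CB"))
                    ph_b.append(bij)

    def ia(x):
        return np.asarray(x, dtype=np.int64)

    def fa(x):
        return np.asarray(x, dtype=np.float64)

    da, db, dc, dd, dv, dg, dn = [], [], [], [], [], [], []
    for (a, b, c, d), terms in topo.dihedrals:
        for v, gamma, mult in terms:
            if v == 0.0:
                continue
            da.append(a)
            db.append(b)
            dc.append(c)
            dd.append(d)
            dv.append(v)
            dg.append(math.radians(gamma))
            dn.append(float(mult))
    ja, jb, jc, jd, jv, jg, jn = [], [], [], [], [], [], []
    for (a, b, c, d), kf in topo.impropers:
        ja.append(a)
        jb.append(b)
        jc.append(c)
        jd.append(d)
        jv.append(kf)
        jg.append(math.pi)
        jn.append(2.0)
    an_i = ia([a[0] for a in topo.angles])
    an_j = ia([a[1] for a in topo.angles])
    an_k = ia([a[2] for a in topo.angles])
    an_t0 = fa([math.radians(a[3]) for a in topo.angles])
    an_kf = fa([a[4] for a in topo.angles])
    con = (ia([b[0] for b in topo.bonds]), ia([b[1] for b in topo.bonds]),
           fa([b[2] for b in topo.bonds]))

    tables = PairTables(
        tube_i=ia(tube_i), tube_j=ia(tube_j), tube_d=fa(tube_d),
        ch_i=ia(ch_i), ch_j=ia(ch_j), on_i=ia(on_i), on_j=ia(on_j),
        cu_i=ia(cu_i), cu_j=ia(cu_j),
        hb_o=ia(hb_o), hb_h=ia(hb_h),
        ph_i=ia(ph_i), ph_j=ia(ph_j), ph_b=fa(ph_b),
        di=(ia(da), ia(db), ia(dc), ia(dd), fa(dv), fa(dg), fa(dn)),
        im=(ia(ja), ia(jb), ia(jc), ia(jd), fa(jv), fa(jg), fa(jn)),
        an=(an_i, an_j, an_k, an_t0, an_kf),
        con=con,
    )
    tables._d_ch = p.d_CH
    tables._d_on = p.d_ON
    cache[key] = tables
    return tables


@dataclass
class EnergyBreakdown:
    """Per-term potential energies (kJ/mol) and per-atom forces."""

    tube: float
    hbond: float
    hbond_direction: float
    hydrophobic: float
    curvature: float
    dihedral: float
    improper: float
    angle: float
    forces: np.ndarray

    @property
    def total(self) -> float:
        return (self.tube + self.hbond + self.hbond_direction + self.hydrophobic
                + self.curvature + self.dihedral + self.improper + self.angle)

    def as_dict(self) -> dict:
        return {
            "tube": self.tube, "hbond": self.hbond,
            "hbond_direction": self.hbond_direction,
            "hydrophobic": self.hydrophobic, "curvature": self.curvature,
            "dihedral": self.dihedral, "improper": self.improper,
            "angle": self.angle, "total": self.total,
        }


def _check(conf: Conformation, topo: CGTopology) -> np.ndarray:
    pos = conf.coordinates
    if pos.shape[0] != topo.n_atoms:
        raise ValueError(
            f"conformation has {pos.shape[0]} atoms, topology {topo.n_atoms}")
    return pos


def tube_energy(conf, topo, p: ForceFieldParams):
    """Self-avoiding sphere energy and forces (Heaviside-gated harmonic)."""
    pos = _check(conf, topo)
    t = build_pair_tables(topo, p)
    F = np.zeros_like(pos)
    e = K.half_harmonic_pairs(pos, F, t.tube_i, t.tube_j, t.tube_d,
                              p.kappa_tube, t.tube_i.shape[0])
    return e, F


def hbond_energy(conf, topo, p: ForceFieldParams):
    """10-12 hydrogen-bond energy over directed O(i)...H(j) pairs, |i-j| >= 4."""
    pos = _check(conf, topo)
    t = build_pair_tables(topo, p)
    F = np.zeros_like(pos)
    e = K.hbond_pairs(pos, F, t.hb_o, t.hb_h, t.hb_o.shape[0], p.eps_H, p.r0,
                      float(p.m), float(p.n), p.hbond_cutoff, t.stats)
    return e, F


def hbond_directionality_energy(conf, topo, p: ForceFieldParams):
    """Stiff C'...H and O...N avoidance spheres enforcing H-bond linearity."""
    pos = _check(conf, topo)
    t = build_pair_tables(topo, p)
    F = np.zeros_like(pos)
    e = K.half_harmonic_pairs(pos, F, t.ch_i, t.ch_j, t.d_ch_arr,
                              p.kappa_tube, t.ch_i.shape[0])
    e += K.half_harmonic_pairs(pos, F, t.on_i, t.on_j, t.d_on_arr,
                               p.kappa_tube, t.on_i.shape[0])
    return e, F


def hydrophobic_energy(conf, topo, p: ForceFieldParams):
    """Residue-specific sigmoidal CB-CB contact energy."""
    pos = _check(conf, topo)
    t = build_pair_tables(topo, p)
    F = np.zeros_like(pos)
    e = K.hydrophobic_pairs(pos, F, t.ph_i, t.ph_j, t.ph_b, t.ph_i.shape[0],
                            p.eps_W, p.nonbonded_cutoff)
    return e, F


def curvature_energy(conf, topo, p: ForceFieldParams):
    """Soft C'...H repulsion for residue separations 2 and 3."""
    pos = _check(conf, topo)
    t = build_pair_tables(topo, p)
    F = np.zeros_like(pos)
    e = K.half_harmonic_pairs(pos, F, t.cu_i, t.cu_j, t.d_cu_arr,
                              p.kappa_c, t.cu_i.shape[0])
    return e, F


def dihedral_energy(conf, topo, p: ForceFieldParams):
    """Residue-grouped CB torsion energy (proper dihedrals only)."""
    pos = _check(conf, topo)
    t = build_pair_tables(topo, p)
    F = np.zeros_like(pos)
    e = K.dihedral_terms(pos, F, *t.di, t.di[0].shape[0])
    return e, F


def improper_energy(conf, topo, p: ForceFieldParams):
    """Peptide-plane (omega, carbonyl O, amide H) periodic restraints."""
    pos = _check(conf, topo)
    t = build_pair_tables(topo, p)
    F = np.zeros_like(pos)
    e = K.dihedral_terms(pos, F, *t.im, t.im[0].shape[0])
    return e, F


def angle_energy(conf, topo, p: ForceFieldParams):
    """Harmonic backbone angle energy."""
    pos = _check(conf, topo)
    t = build_pair_tables(topo, p)
    F = np.zeros_like(pos)
    e = K.angle_terms(pos, F, *t.an, t.an[0].shape[0])
    return e, F


def total_energy(conf, topo, p: ForceFieldParams) -> EnergyBreakdown:
    """All terms in one pass over the shared pair tables."""
    pos = _check(conf, topo)
    t = build_pair_tables(topo, p)
    F = np.zeros_like(pos)
    e_tube = K.half_harmonic_pairs(pos, F, t.tube_i, t.tube_j, t.tube_d,
                                   p.kappa_tube, t.tube_i.shape[0])
    e_dir = K.half_harmonic_pairs(pos, F, t.ch_i, t.ch_j, t.d_ch_arr,
                                  p.kappa_tube, t.ch_i.shape[0])
    e_dir += K.half_harmonic_pairs(pos, F, t.on_i, t.on_j, t.d_on_arr,
                                   p.kappa_tube, t.on_i.shape[0])
    e_hb = K.hbond_pairs(pos, F, t.hb_o, t.hb_h, t.hb_o.shape[0], p.eps_H,
                         p.r0, float(p.m), float(p.n), p.hbond_cutoff, t.stats)
    e_ph = K.hydrophobic_pairs(pos, F, t.ph_i, t.ph_j, t.ph_b,
                               t.ph_i.shape[0], p.eps_W, p.nonbonded_cutoff)
    e_cu = K.half_harmonic_pairs(pos, F, t.cu_i, t.cu_j, t.d_cu_arr,
                                 p.kappa_c, t.cu_i.shape[0])
    e_di = K.dihedral_terms(pos, F, *t.di, t.di[0].shape[0])
    e_im = K.dihedral_terms(pos, F, *t.im, t.im[0].shape[0])
    e_an = K.angle_terms(pos, F, *t.an, t.an[0].shape[0])
    return EnergyBreakdown(e_tube, e_hb, e_dir, e_ph, e_cu, e_di, e_im, e_an, F)


def pair_list(conf, topo, p: ForceFieldParams) -> dict:
    """Candidate pairs per term within the 1.5 nm list radius.

    Returns ``{term: [(atom_i, atom_j, residue_separation), ...]}``; a
    superset of every pair that can contribute nonzero energy (all term
    cutoffs are <= 1.2 nm).
    """
    pos = _check(conf, topo)
    t = build_pair_tables(topo, p)
    rmax = p.pairlist_radius
    sep = topo.residue_index
    out = {}
    for name, (ii, jj) in {
        "tube": (t.tube_i, t.tube_j),
        "hbond": (t.hb_o, t.hb_h),
        "hbond_direction_CH": (t.ch_i, t.ch_j),
        "hbond_direction_ON": (t.on_i, t.on_j),
        "curvature": (t.cu_i, t.cu_j),
        "hydrophobic": (t.ph_i, t.ph_j),
    }.items():
        if ii.shape[0] == 0:
            out[name] = []
            continue
        d = np.linalg.norm(pos[ii] - pos[jj], axis=1)
        keep = d < rmax
        out[name] = [
            (int(a), int(b), int(abs(sep[a] - sep[b])))
            for a, b in zip(ii[keep], jj[keep])
        ]
    return out
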