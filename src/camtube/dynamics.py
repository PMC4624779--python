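"""Constrained Langevin dynamics for the coarse-grained chain.

The integrator is a BAOAB splitting of Langevin dynamics with SHAKE/RATTLE
projection onto the bond-constraint manifold after every drift and kick.
Centre-of-mass translation and, in vacuo, rigid rotation are removed every
step.  All randomness flows from one master seed through separate
``numpy.random`` streams for velocity initialisation and the thermostat, so
trajectories are bit-reproducible for identical inputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .constants import KB
from .energy import EnergyBreakdown, build_pair_tables, total_energy
from .metadynamics import BiasRecord, MetadynamicsConfig
from .params import ForceFieldParams
from .topology import CGTopology, Conformation


@dataclass
class SimulationConfig:
    """Run settings (ps, K, ps^-1 units)."""

    n_steps: int
    dt: float = 0.002
    temperature: float = 298.0
    friction: float = 1.0
    seed: int = 0
    constraint_tol: float = 1e-6
    com_removal: bool = True
    report_interval: int = 1000
    #: geodesic sub-steps per half drift; >1 suppresses the kinetic-energy
    #: bias of discrete constrained drift on fast bond rotors
    n_geodesic: int = 4
    #: tangent-projection tolerance (nm/ps) and sweep cap inside sub-drifts
    rattle_tol_sub: float = 1e-3
    rattle_iter_sub: int = 8

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.temperature < 0 or self.friction < 0:
            raise ValueError("need dt > 0, temperature >= 0, friction >= 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        self.report_interval = min(self.report_interval, self.n_steps)

    #: accepted aliases in run-configuration files (engine-style key names)
    _ALIASES = {
        "ref-t": "temperature", "ref_t": "temperature",
        "nsteps": "n_steps", "tau-t": "tau_t", "tau_t": "tau_t",
    }

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Load run settings from a YAML file.

        Engine-style keys are accepted: ``dt``, ``ref-t`` (temperature, K),
        ``tau-t`` (inverse friction, ps), ``nsteps``, plus every native
        field name.
        """
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        data = {}
        for key, value in raw.items():
            key = cls._ALIASES.get(str(key), str(key).replace("-", "_"))
            data[key] = value
        tau = data.pop("tau_t", None)
        if tau is not None and "friction" not in data:
            data["friction"] = 1.0 / float(tau)
        allowed = set(cls.__dataclass_fields__)
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown run-configuration keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class Trajectory:
    """Reported frames with energies and optional CV/bias records."""

    times: np.ndarray                 # ps
    frames: np.ndarray                # (n_frames, n_atoms, 3) nm
    energies: list                    # EnergyBreakdown per frame
    kinetic_temperatures: np.ndarray  # K, instantaneous at report times
    final_velocities: np.ndarray
    dof: int
    cv_trace: np.ndarray | None = None  # per-step CV values (metadynamics)
    bias: BiasRecord | None = None
    aborted: bool = False
    #: all-step mean kinetic temperature, from leapfrog-style averaging of
    #: half-step and full-step kinetic energies
    mean_kinetic_temperature: float = float("nan")
    #: (T from half-step KE, T from full-step KE) diagnostic pair
    kinetic_temperature_components: tuple = (float("nan"), float("nan"))

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def conformation(self, i: int) -> Conformation:
        return Conformation(self.frames[i].copy())


def initialize_velocities(topo: CGTopology, temperature: float, seed: int) -> np.ndarray:
    """Maxwell-Boltzmann draw at the target temperature, COM velocity removed."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7E51]))
    sig = np.sqrt(KB * max(temperature, 0.0) / topo.masses)
    v = rng.standard_normal((topo.n_atoms, 3)) * sig[:, None]
    mtot = topo.masses.sum()
    v -= (topo.masses[:, None] * v).sum(axis=0) / mtot
    return v


def constrain(positions_before: np.ndarray, positions_after: np.ndarray,
              topo: CGTopology, tol: float = 1e-6) -> np.ndarray:
    """Project trial positions back onto the bond-constraint manifold.

    Iterative mass-weighted projection (SHAKE-style); the pre-move positions
    are accepted for API symmetry but the projection uses the current bond
    directions.  Raises on non-convergence with the worst bond reported.
    """
    del positions_before
    t = build_pair_tables_for_constraints(topo)
    pos = np.array(positions_after, dtype=np.float64)
    invm = 1.0 / topo.masses
    ok = K.shake(pos, t[0], t[1], t[2], invm, tol, 1000)
    if ok < 0:
        d = np.linalg.norm(pos[t[0]] - pos[t[1]], axis=1) - t[2]
        worst = int(np.argmax(np.abs(d)))
        raise RuntimeError(
            f"constraint projection did not converge; worst bond "
            f"({int(t[0][worst])}, {int(t[1][worst])}) deviates {d[worst]:.2e} nm")
    return pos


def build_pair_tables_for_constraints(topo: CGTopology):
    bonds = topo.bonds
    ci = np.array([b[0] for b in bonds], dtype=np.int64)
    cj = np.array([b[1] for b in bonds], dtype=np.int64)
    cd = np.array([b[2] for b in bonds], dtype=np.float64)
    return ci, cj, cd


def minimize_energy(conf: Conformation, topo: CGTopology,
                    params: ForceFieldParams, n_steps: int = 500,
                    max_move: float = 5e-4) -> Conformation:
    """Constraint-respecting steepest descent to relax steric overlaps.

    Each iteration moves along the force with the largest per-atom step
    capped at ``max_move`` nm, then projects back onto the bond constraints;
    used to tame random-coil clashes before dynamics.
    """
    pos = np.array(conf.coordinates, dtype=np.float64)
    ci, cj, cd = build_pair_tables_for_constraints(topo)
    invm = 1.0 / topo.masses
    move = max_move
    e_prev = total_energy(Conformation(pos), topo, params).total
    for _ in range(n_steps):
        eb = total_energy(Conformation(pos), topo, params)
        fmax = np.abs(eb.forces).max()
        if fmax < 10.0:  # kJ/mol/nm; essentially relaxed
            break
        trial = pos + (move / fmax) * eb.forces
        K.shake(trial, ci, cj, cd, invm, 1e-6, 1000)
        e_new = total_energy(Conformation(trial), topo, params).total
        if e_new > e_prev:
            move *= 0.5  # backtrack; count the rejected trial as a step
            if move < 1e-8:
                break
            continue
        pos = trial
        e_prev = e_new
        move = min(move * 1.2, max_move)
    return Conformation(pos)


def kinetic_temperature(vel: np.ndarray, masses: np.ndarray, dof: int) -> float:
    ke = 0.5 * float((masses[:, None] * vel ** 2).sum())
    return 2.0 * ke / (dof * KB)


class _MetaWorkspace:
    """Preallocated arrays for in-kernel CV evaluation and hill storage."""

    def __init__(self, topo: CGTopology, meta: MetadynamicsConfig | None,
                 n_steps: int):
        n = topo.n_atoms
        nres = topo.n_residues
        self.ca_idx = np.array(
            [topo.atom_id(r, "CA") for r in range(nres)
             if topo.has_atom(r, "CA")], dtype=np.int64)
        phi_quads, res_phi = [], []
        psi_quads, res_psi = [], []
        for r in range(nres):
            if (r > 0 and topo.has_atom(r - 1, "C") and topo.has_atom(r, "N")
                    and topo.has_atom(r, "CA") and topo.has_atom(r, "C")):
                phi_quads.append([topo.atom_id(r - 1, "C"), topo.atom_id(r, "N"),
                                  topo.atom_id(r, "CA"), topo.atom_id(r, "C")])
                res_phi.append(r)
            if (r < nres - 1 and topo.has_atom(r, "N") and topo.has_atom(r, "CA")
                    and topo.has_atom(r, "C") and topo.has_atom(r + 1, "N")):
                psi_quads.append([topo.atom_id(r, "N"), topo.atom_id(r, "CA"),
                                  topo.atom_id(r, "C"), topo.atom_id(r + 1, "N")])
                res_psi.append(r)
        self.phi_quads = np.array(phi_quads, dtype=np.int64).reshape(-1, 4)
        self.psi_quads = np.array(psi_quads, dtype=np.int64).reshape(-1, 4)
        self.res_of_phi = np.array(res_phi, dtype=np.int64)
        self.res_of_psi = np.array(res_psi, dtype=np.int64)
        nq = max(self.phi_quads.shape[0], self.psi_quads.shape[0], 1)
        self.ws_vals = np.empty(nq)
        self.ws_tg = np.empty((nq, 4, 3))
        self.cvgrad = np.zeros((n, 3))
        self.mem = np.zeros(nres)
        self.dmp = np.zeros(nres)
        self.dms = np.zeros(nres)
        from .analysis import ALPHA_BOX, BETA_BOX

        if meta is None:
            self.cv_id = -1
            self.box = np.zeros(4)
            self.sigma = 1.0
            self.height = 0.0
            self.stride = 10 ** 9
            self.kb_dT = 0.0
            cap = 1
        else:
            self.cv_id = meta.cv_index
            self.box = np.asarray(
                ALPHA_BOX if meta.cv_id == "alpha_count" else BETA_BOX,
                dtype=float)
            self.sigma = meta.sigma
            self.height = meta.height
            self.stride = meta.stride
            self.kb_dT = KB * meta.well_tempered_dT
            cap = n_steps // meta.stride + 2
        self.box_w = 10.0  # logistic edge width of the smooth SS boxes, degrees
        self.hill_c = np.zeros(cap)
        self.hill_h = np.zeros(cap)
        self.nh = np.zeros(1, dtype=np.int64)


def run_md(conf: Conformation, topo: CGTopology, params: ForceFieldParams,
           config: SimulationConfig,
           velocities: np.ndarray | None = None) -> Trajectory:
    """Unbiased constrained Langevin dynamics."""
    return _run(conf, topo, params, config, meta=None, velocities=velocities)


def run_metadynamics(conf: Conformation, topo: CGTopology,
                     params: ForceFieldParams, config: SimulationConfig,
                     meta: MetadynamicsConfig,
                     velocities: np.ndarray | None = None) -> Trajectory:
    """Single-walker metadynamics along one collective variable."""
    return _run(conf, topo, params, config, meta=meta, velocities=velocities)


def _run(conf, topo, params, config, meta, velocities):
    pos = np.array(conf.coordinates, dtype=np.float64)
    t = build_pair_tables(topo, params)
    ci, cj, cd = t.con
    masses = topo.masses
    invm = 1.0 / masses

    e0 = total_energy(Conformation(pos), topo, params)
    if not math.isfinite(e0.total):
        raise ValueError("non-finite initial energy")

    if velocities is None:
        vel = initialize_velocities(topo, config.temperature, config.seed)
    else:
        vel = np.array(velocities, dtype=np.float64)
    # start exactly on the constraint manifold
    K.rattle_velocities(pos, vel, ci, cj, invm, 1e-12, 100)
    if config.com_removal:
        K.remove_com_motion(pos, vel, masses, True)

    n = topo.n_atoms
    ncon = ci.shape[0]
    dof = 3 * n - ncon - (6 if config.com_removal else 0)
    c1 = math.exp(-config.friction * config.dt)
    sigv = np.sqrt(KB * config.temperature * (1.0 - c1 * c1) / masses)

    ws = _MetaWorkspace(topo, meta, config.n_steps)
    F = np.zeros((n, 3))
    pbuf = np.zeros((n, 3))
    cap = t.tube_i.shape[0]
    act_i = np.zeros(cap, dtype=np.int64)
    act_j = np.zeros(cap, dtype=np.int64)
    act_d = np.zeros(cap)
    act_n = np.zeros(1, dtype=np.int64)
    ref_pos = np.zeros_like(pos)
    skin = 0.2  # nm; Verlet skin for the tube active list

    # initial forces (full tables; the kernel rebuilds its own active list)
    F[:] = e0.forces
    com_mode = 2 if config.com_removal else 0
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x0A0B]))

    chunk = config.report_interval
    n_chunks = (config.n_steps + chunk - 1) // chunk
    times, frames, energies, ktemps = [], [], [], []
    cv_parts = []
    aborted = False
    done = 0
    zero_normals = np.zeros((chunk, n, 3))
    cv_trace = np.zeros(chunk)
    ke_acc = np.zeros(2)
    d_ch_arr = t.d_ch_arr
    d_on_arr = t.d_on_arr
    d_cu_arr = t.d_cu_arr
    for _ in range(n_chunks):
        steps = min(chunk, config.n_steps - done)
        if c1 < 1.0 and config.temperature > 0:
            normals = rng.standard_normal((steps, n, 3))
        else:
            normals = zero_normals[:steps]
        ret = K.md_chunk(
            pos, vel, F, masses, invm, normals, config.dt, c1, sigv, steps,
            done,
            ci, cj, cd, config.constraint_tol, config.n_geodesic,
            config.rattle_tol_sub, config.rattle_iter_sub,
            t.tube_i, t.tube_j, t.tube_d, act_i, act_j, act_d, act_n,
            ref_pos, skin, params.kappa_tube,
            t.ch_i, t.ch_j, d_ch_arr, t.on_i, t.on_j, d_on_arr,
            t.cu_i, t.cu_j, d_cu_arr, params.kappa_c,
            t.hb_o, t.hb_h, params.eps_H, params.r0, float(params.m),
            float(params.n), params.hbond_cutoff, t.stats,
            t.ph_i, t.ph_j, t.ph_b, params.eps_W, params.nonbonded_cutoff,
            *t.di, *t.im, *t.an,
            pbuf, com_mode,
            ws.cv_id, ws.hill_c, ws.hill_h, ws.nh, ws.sigma, ws.height,
            ws.stride, ws.kb_dT,
            ws.ca_idx, ws.phi_quads, ws.psi_quads, ws.res_of_phi,
            ws.res_of_psi, topo.n_residues, ws.box, ws.box_w,
            ws.ws_vals, ws.ws_tg, ws.cvgrad, ws.mem, ws.dmp, ws.dms,
            cv_trace[:steps], ke_acc)
        if ret < 0:
            msg = ("constraint solver failed" if ret == -1
                   else "non-finite coordinates")
            warnings.warn(f"dynamics aborted after {done} steps: {msg}; "
                          "returning the last consistent frames")
            aborted = True
            if not frames:  # keep the last good (initial) state reachable
                times.append(0.0)
                frames.append(np.array(conf.coordinates, dtype=np.float64))
                energies.append(e0)
                ktemps.append(kinetic_temperature(vel, masses, dof))
            break
        done += steps
        times.append(done * config.dt)
        frames.append(pos.copy())
        energies.append(total_energy(Conformation(pos.copy()), topo, params))
        ktemps.append(kinetic_temperature(vel, masses, dof))
        if meta is not None:
            cv_parts.append(cv_trace[:steps].copy())

    bias = None
    trace = None
    if meta is not None:
        bias = BiasRecord(cv_id=meta.cv_id, sigma=meta.sigma,
                          centers=ws.hill_c[:ws.nh[0]].copy(),
                          heights=ws.hill_h[:ws.nh[0]].copy())
        trace = np.concatenate(cv_parts) if cv_parts else np.empty(0)
    mean_t = float("nan")
    comps = (float("nan"), float("nan"))
    if done > 0:
        mean_ke = 0.5 * (ke_acc[0] + ke_acc[1]) / done
        mean_t = 2.0 * mean_ke / (dof * KB)
        comps = (2.0 * ke_acc[0] / done / (dof * KB),
                 2.0 * ke_acc[1] / done / (dof * KB))
    return Trajectory(
        times=np.asarray(times), frames=np.asarray(frames), energies=energies,
        kinetic_temperatures=np.asarray(ktemps),
        final_velocities=vel.copy(), dof=dof,
        cv_trace=trace, bias=bias, aborted=aborted,
        mean_kinetic_temperature=mean_t,
        kinetic_temperature_components=comps)
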