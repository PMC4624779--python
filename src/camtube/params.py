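"""Force-field parameters and their packaged data tables.

All energies are kJ mol^-1, lengths nm.  The defaults reproduce the published
parameterisation: a stiff tube constant of 100,000 kJ mol^-1 nm^-2, a 10-12
hydrogen-bond well of depth 21 kJ mol^-1 at 0.2 nm, hydrophobic scale
eps_W = 10 with the curvature penalty kappa_c = 2000 (centre of the
alpha/beta marginally compact phase).
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from . import constants as const
from .residues import HYDROPHOBIC, ONE_TO_THREE


def _data_lines(name: str):
    text = resources.files("camtube.data").joinpath(name).read_text()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            yield line.split("\t")


def load_sphere_thresholds() -> dict[tuple[str, str], float]:
    """Table of self-avoiding sphere diameters keyed by unordered kind pair."""
    table: dict[tuple[str, str], float] = {}
    for a, b, d in _data_lines("sphere_thresholds.tsv"):
        key = tuple(sorted((a, b)))
        table[key] = float(d)
    if len(table) != 16:
        raise ValueError(f"expected 16 sphere thresholds, got {len(table)}")
    return table


def load_dihedral_table() -> dict[str, list[tuple[float, float, int]]]:
    """Fourier terms (Vn, gamma, n) per dihedral group."""
    table: dict[str, list[tuple[float, float, int]]] = {}
    for group, vn, gamma, n in _data_lines("dihedral_terms.tsv"):
        table.setdefault(group, []).append((float(vn), float(gamma), int(n)))
    return table


def dihedral_group_terms(group: str) -> list[tuple[float, float, int]]:
    return list(load_dihedral_table()[group])


def load_contact_matrix(normalize: bool = True) -> dict[tuple[str, str], float]:
    """Hydrophobic contact energies B_ij keyed by unordered one-letter pair.

    With ``normalize`` the raw contact energies are divided by |B(V,V)| so
    the valine-valine contact is exactly -1 and eps_W directly sets the
    contact energy scale in kJ mol^-1.  Pairs involving polar or charged
    residues are absent (treated as zero).
    """
    raw: dict[tuple[str, str], float] = {}
    for a, b, v in _data_lines("contact_matrix.tsv"):
        raw[tuple(sorted((a, b)))] = float(v)
    if normalize:
        scale = abs(raw[("V", "V")])
        raw = {k: v / scale for k, v in raw.items()}
    return raw


def contact_matrix_array(B: dict[tuple[str, str], float] | None = None) -> tuple[np.ndarray, dict[str, int]]:
    """Dense symmetric 20x20 matrix plus the residue-letter index map."""
    if B is None:
        B = load_contact_matrix()
    letters = sorted(ONE_TO_THREE)
    idx = {aa: i for i, aa in enumerate(letters)}
    M = np.zeros((20, 20))
    for (a, b), v in B.items():
        M[idx[a], idx[b]] = v
        M[idx[b], idx[a]] = v
    return M, idx


@dataclass
class ForceFieldParams:
    """Every tunable constant of the coarse-grained force field."""

    kappa_tube: float = 100_000.0          # kJ mol^-1 nm^-2
    eps_H: float = 21.0                    # H-bond well depth, kJ mol^-1
    m: int = 12                            # repulsive exponent
    n: int = 10                            # attractive exponent
    r0: float = const.HBOND_R0             # ideal O...H length, nm
    eps_W: float = 10.0                    # hydrophobic scale, kJ mol^-1
    kappa_c: float = 2000.0                # curvature constant, kJ mol^-1 nm^-2
    d_CH: float = const.D_CH               # C'...H avoidance radius, nm
    d_ON: float = const.D_ON               # O...N avoidance radius, nm
    hbond_cutoff: float = 0.8              # nm
    nonbonded_cutoff: float = 1.2          # nm
    pairlist_radius: float = 1.5           # nm (candidate list)
    sphere_thresholds: dict = field(default_factory=load_sphere_thresholds)
    B: dict = field(default_factory=load_contact_matrix)
    dihedral_table: dict = field(default_factory=load_dihedral_table)

    def __post_init__(self) -> None:
        if min(self.kappa_tube, self.eps_H, self.eps_W, self.kappa_c) < 0:
            raise ValueError("force constants and well depths must be >= 0")
        if not (self.m > self.n > 0):
            raise ValueError("exponents must satisfy m > n > 0")
        if len(self.sphere_thresholds) != 16:
            raise ValueError(
                f"sphere threshold table needs its 16 kind pairs, got "
                f"{len(self.sphere_thresholds)}")
        for (a, b), d in self.sphere_thresholds.items():
            if (a, b) != tuple(sorted((a, b))):
                raise ValueError("threshold keys must be sorted kind pairs")
            if d <= 0:
                raise ValueError(f"non-positive threshold for {(a, b)}")
        for (a, b), v in self.B.items():
            if a in HYDROPHOBIC and b in HYDROPHOBIC:
                continue
            if v != 0.0:
                raise ValueError(f"nonzero contact energy for non-hydrophobic pair {(a, b)}")

    # ---- pair potentials (scalar forms, used for tables and oracles) -----
    def hbond_pair_energy(self, r, shifted: bool = True):
        """10-12 pair potential; minimum -eps_H at r0, shifted to 0 at cutoff."""
        r = np.asarray(r, dtype=float)
        m, n = self.m, self.n
        x = self.r0 / np.maximum(r, 1e-4)
        e = self.eps_H * (n / (m - n) * x**m - m / (m - n) * x**n)
        if shifted:
            xc = self.r0 / self.hbond_cutoff
            e = e - self.eps_H * (n / (m - n) * xc**m - m / (m - n) * xc**n)
            e = np.where(r < self.hbond_cutoff, e, 0.0)
        return e

    def hydrophobic_pair_energy(self, r, bij: float):
        """Sigmoidal contact potential eps_W * B_ij * [1 - logistic((r-0.8)/0.04)]."""
        r = np.asarray(r, dtype=float)
        e = self.eps_W * bij * (1.0 - 1.0 / (1.0 + np.exp((0.8 - r) / 0.04)))
        return np.where(r < self.nonbonded_cutoff, e, 0.0)

    def half_harmonic(self, r, d: float, kappa: float):
        """kappa (d - r)^2 for r < d, else 0."""
        r = np.asarray(r, dtype=float)
        return np.where(r < d, kappa * (d - r) ** 2, 0.0)

    # ---- overrides -------------------------------------------------------
    def with_overrides(self, **kwargs) -> "ForceFieldParams":
        return replace(self, **kwargs)

    @classmethod
    def from_file(cls, path) -> "ForceFieldParams":
        """Load overrides from a YAML parameter file (missing keys keep defaults)."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        allowed = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**data)

    def save(self, path) -> None:
        scalars = {
            k: getattr(self, k)
            for k in ("kappa_tube", "eps_H", "m", "n", "r0", "eps_W", "kappa_c",
                      "d_CH", "d_ON", "hbond_cutoff", "nonbonded_cutoff",
                      "pairlist_radius")
        }
        with open(path, "w") as fh:
            yaml.safe_dump(scalars, fh, sort_keys=False)
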