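"""Export of the pair potentials as tabulated files (xvg dialect).

One three-column table ``(r, E, -dE/dr)`` per atom-kind pair on a uniform
grid, mirroring a tabulated-potential engine setup.  Each pair's table sums
every long-range term acting between those kinds at residue separation
>= 4: the self-avoiding sphere (when the pair is in the threshold table),
the 10-12 hydrogen bond for O-H, and the stiff avoidance spheres for C-H
and O-N.  The residue-specific hydrophobic CB-CB term has per-pair contact
energies and is exported for a unit contact (B = -1); an engine consuming
these tables scales it per pair.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .params import ForceFieldParams

#: kind pairs receiving a table (energy-group pair list)
TABLE_PAIRS = [
    ("CA", "CA"), ("CB", "CB"), ("CA", "CB"), ("O", "O"), ("H", "H"),
    ("C", "H"), ("O", "H"), ("O", "N"), ("C", "CB"), ("H", "CB"),
    ("N", "CB"), ("O", "CB"), ("C", "CA"), ("H", "CA"), ("N", "CA"),
    ("O", "CA"), ("O", "C"), ("C", "C"), ("N", "N"),
]

#: default grid spacing (nm); fine enough that linear interpolation of the
#: stiffest half-harmonic (kappa_tube = 1e5) stays below 1e-3 kJ/mol error
GRID_STEP = 1e-4
TABLE_EXTENSION = 0.5  # nm beyond the largest cutoff


def pair_potential(params: ForceFieldParams, kind_a: str, kind_b: str, r):
    """Analytic pair energy (kJ/mol) between two atom kinds at |i-j| >= 4."""
    r = np.asarray(r, dtype=float)
    key = tuple(sorted((kind_a, kind_b)))
    e = np.zeros_like(r)
    if key in params.sphere_thresholds:
        e = e + params.half_harmonic(r, params.sphere_thresholds[key],
                                     params.kappa_tube)
    if key == ("H", "O"):
        e = e + params.hbond_pair_energy(r)
    if key == ("C", "H"):
        e = e + params.half_harmonic(r, params.d_CH, params.kappa_tube)
    if key == ("N", "O"):
        e = e + params.half_harmonic(r, params.d_ON, params.kappa_tube)
    if key == ("CB", "CB"):
        e = e + params.hydrophobic_pair_energy(r, -1.0)
    return e


def export_tables(params: ForceFieldParams, out_dir,
                  grid_step: float = GRID_STEP) -> list:
    """Write all pair tables plus a topology include; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    r_max = max(params.hbond_cutoff, params.nonbonded_cutoff) + TABLE_EXTENSION
    r = np.arange(grid_step, r_max + grid_step / 2, grid_step)
    written = []
    for a, b in TABLE_PAIRS:
        e = pair_potential(params, a, b, r)
        force = -np.gradient(e, r)
        path = out / f"table_{a}_{b}.xvg"
        with open(path, "w") as fh:
            fh.write(f"# pair potential {a}-{b}: r (nm), E (kJ/mol), "
                     "-dE/dr (kJ/mol/nm)\n")
            fh.write("@ xaxis label \"r (nm)\"\n@ yaxis label \"E (kJ/mol)\"\n")
            for ri, ei, fi in zip(r, e, force):
                fh.write(f"{ri:.6f} {ei:.10e} {fi:.10e}\n")
        written.append(path)
    include = out / "tables_include.txt"
    with open(include, "w") as fh:
        fh.write("; tabulated-potential pair list\n")
        fh.write("energygrp-table = " +
                 " ".join(f"{a} {b}" for a, b in TABLE_PAIRS) + "\n")
        for a, b in TABLE_PAIRS:
            fh.write(f"; {a}-{b}: table_{a}_{b}.xvg\n")
    written.append(include)
    return written


def read_table(path):
    """Read an exported table back as (r, E, F) arrays."""
    data = np.loadtxt(path, comments=("#", "@"))
    return data[:, 0], data[:, 1], data[:, 2]
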