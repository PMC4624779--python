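"""Shared fixtures: default parameters, small chains, gradient helpers."""

from __future__ import annotations

import numpy as np
import pytest

from camtube.geometry import generate_conformation
from camtube.params import ForceFieldParams
from camtube.topology import Conformation, build_topology


@pytest.fixture(scope="session")
def params():
    return ForceFieldParams()


@pytest.fixture(scope="session")
def val10():
    topo = build_topology("V" * 10)
    return topo, generate_conformation(topo, "extended")


@pytest.fixture(scope="session")
def helix12():
    topo = build_topology("A" * 12)
    return topo, generate_conformation(topo, "ideal_helix")


def squashed_random_chain(sequence: str, seed: int, squeeze: float = 0.62,
                          jitter: float = 0.01) -> tuple:
    """A random coil scaled toward its centroid with coordinate jitter.

    Produces sub-threshold pair distances so every energy term is exercised;
    bonded geometry is irrelevant for gradient checks.
    """
    topo = build_topology(sequence)
    conf = generate_conformation(topo, "random_coil", seed=seed)
    rng = np.random.default_rng(seed)
    pos = conf.coordinates
    pos = (pos - pos.mean(axis=0)) * squeeze + jitter * rng.normal(size=pos.shape)
    return topo, Conformation(pos)


def numerical_forces(energy_fn, conf, topo, p, step: float = 1e-6) -> np.ndarray:
    """Central-difference forces, the independent oracle for analytic ones."""
    pos = conf.coordinates
    out = np.zeros_like(pos)
    for i in range(pos.shape[0]):
        for x in range(3):
            up = pos.copy()
            up[i, x] += step
            dn = pos.copy()
            dn[i, x] -= step
            e_up = energy_fn(Conformation(up), topo, p)[0]
            e_dn = energy_fn(Conformation(dn), topo, p)[0]
            out[i, x] = -(e_up - e_dn) / (2.0 * step)
    return out
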