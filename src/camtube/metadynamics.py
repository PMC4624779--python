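"""Metadynamics configuration, deposited-bias bookkeeping and toy models.

A single-walker scheme: Gaussians of fixed width are deposited along one
collective variable every ``stride`` steps; the accumulated bias is stored
as the list of hill centres/heights and evaluated analytically, so no grid
bounds are needed during sampling (the grid in the configuration is used
for free-energy reconstruction only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import _kernels as K
from .constants import KB

#: CV identifiers and their published Gaussian widths
CV_IDS = ("dihedral_correlation", "rgyr", "alpha_count", "beta_count")
DEFAULT_SIGMA = {
    "dihedral_correlation": 0.1,
    "rgyr": 0.05,
    "alpha_count": 0.5,
    "beta_count": 0.5,
}


@dataclass
class MetadynamicsConfig:
    """Single-CV metadynamics settings.

    ``height`` (kJ/mol) and ``stride`` (steps) are not part of the published
    parameter set and are freely configurable; ``well_tempered_dT`` > 0
    activates the well-tempered height rescaling exp(-V/kB dT).
    """

    cv_id: str
    sigma: float | None = None
    height: float = 0.5
    stride: int = 500
    grid_min: float = 0.0
    grid_max: float = 10.0
    grid_step: float = 0.01
    well_tempered_dT: float = 0.0

    def __post_init__(self) -> None:
        if self.cv_id not in CV_IDS:
            raise ValueError(f"unknown CV {self.cv_id!r}; pick from {CV_IDS}")
        if self.sigma is None:
            self.sigma = DEFAULT_SIGMA[self.cv_id]
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.height < 0:
            raise ValueError("height must be >= 0")

    @property
    def cv_index(self) -> int:
        return CV_IDS.index(self.cv_id)


@dataclass
class BiasRecord:
    """Deposited hills of one metadynamics run."""

    cv_id: str
    sigma: float
    centers: np.ndarray = field(default_factory=lambda: np.empty(0))
    heights: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_hills(self) -> int:
        return int(self.centers.shape[0])

    def value(self, s):
        """Bias potential V(s) summed over all hills."""
        s = np.asarray(s, dtype=float)
        if self.n_hills == 0:
            return np.zeros_like(s)
        z = (s[..., None] - self.centers) / self.sigma
        return (self.heights * np.exp(-0.5 * z * z)).sum(axis=-1)


def estimate_fes(bias: BiasRecord, grid: np.ndarray) -> np.ndarray:
    """Free-energy estimate F(s) = -V_bias(s), shifted so min F = 0."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    f = -bias.value(grid)
    return f - f.min()


# ---------------------------------------------------------------------------
# 1D toy landscapes (validation of the deposition/escape machinery)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuarticPotential:
    """V(x) = c4 x^4 + c2 x^2 + c0 (double well for c4 > 0, c2 < 0)."""

    c4: float
    c2: float
    c0: float = 0.0

    @classmethod
    def double_well(cls, barrier: float, x0: float = 1.0) -> "QuarticPotential":
        """Symmetric double well with minima at +-x0 and the given barrier."""
        a = barrier / x0 ** 4
        return cls(c4=a, c2=-2 * a * x0 ** 2, c0=a * x0 ** 4)

    @classmethod
    def harmonic(cls, k: float) -> "QuarticPotential":
        return cls(c4=0.0, c2=0.5 * k, c0=0.0)

    def energy(self, x):
        return self.c4 * x ** 4 + self.c2 * x ** 2 + self.c0


@njit(cache=True)
def _toy_chunk(x, v, c4, c2, dt, c1, sig, mass, normals, n_steps,
               hill_c, hill_h, nh_io, sigma, height, stride, step0, trace):
    half = 0.5 * dt
    for step in range(n_steps):
        f = -(4.0 * c4 * x * x * x + 2.0 * c2 * x)
        _, dv = K.bias_value_deriv(x, hill_c, hill_h, nh_io[0], sigma)
        f -= dv
        v += half * f / mass
        x += half * v
        v = c1 * v + sig * normals[step]
        x += half * v
        f = -(4.0 * c4 * x * x * x + 2.0 * c2 * x)
        _, dv = K.bias_value_deriv(x, hill_c, hill_h, nh_io[0], sigma)
        f -= dv
        v += half * f / mass
        trace[step] = x
        if height > 0.0 and (step0 + step + 1) % stride == 0:
            hill_c[nh_io[0]] = x
            hill_h[nh_io[0]] = height
            nh_io[0] += 1
    return x, v


def run_toy_langevin(potential: QuarticPotential, n_steps: int, seed: int,
                     x0: float = 0.0, dt: float = 0.002, friction: float = 1.0,
                     temperature: float = 298.0, mass: float = 1.0,
                     meta: MetadynamicsConfig | None = None):
    """BAOAB Langevin dynamics of one particle on a quartic landscape.

    Returns ``(trace, bias)`` where ``trace`` is the per-step position and
    ``bias`` the deposited hills (empty for an unbiased run).  Used to
    validate thermostat statistics and metadynamics escape behaviour on
    closed-form landscapes.
    """
    rng = np.random.default_rng(seed)
    c1 = math.exp(-friction * dt)
    sig = math.sqrt(KB * temperature * (1.0 - c1 * c1) / mass)
    sigma = meta.sigma if meta else 1.0
    height = meta.height if meta else 0.0
    stride = meta.stride if meta else 10 ** 9
    cap = n_steps // stride + 2
    hill_c = np.zeros(cap)
    hill_h = np.zeros(cap)
    nh = np.zeros(1, dtype=np.int64)
    trace = np.empty(n_steps)
    normals = rng.standard_normal(n_steps)
    _toy_chunk(x0, 0.0, potential.c4, potential.c2, dt, c1, sig, mass,
               normals, n_steps, hill_c, hill_h, nh, sigma, height,
               stride, 0, trace)
    bias = BiasRecord(cv_id=meta.cv_id if meta else "rgyr", sigma=sigma,
                      centers=hill_c[:nh[0]].copy(), heights=hill_h[:nh[0]].copy())
    return trace, bias
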