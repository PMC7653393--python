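"""Domain partition, blending functions and mesh bookkeeping.

A hybrid simulation divides the domain ``[a, b]`` into three subintervals
by two interfaces ``I1 < I2``.  In the *blending region* ``[I1, I2]`` two
model representations coexist, and the macroscopic diffusion coefficient
``D`` is split between them by complementary blending functions::

    D1(x) = D            on [a, I1)        D2(x) = 0
    D1(x) = D * beta1(x) on [I1, I2]       D2(x) = D * (1 - beta1(x))
    D1(x) = 0            on (I2, b]        D2(x) = D

``beta1`` decreases monotonically from 1 at ``I1`` to 0 at ``I2`` so that
``D1 + D2 = D`` everywhere and both split diffusivities are continuous.
The coarse model always carries ``D1`` (it owns the left part of the
domain) and the fine model carries ``D2``.

In three dimensions the interfaces are planes of constant ``x`` and the
blending depends on ``x`` only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfigurationError",
    "BlendingGeometry",
    "MeshSpec",
    "build_geometry",
    "build_mesh",
]


class ConfigurationError(ValueError):
    """Raised for inconsistent geometry / mesh configuration."""


@dataclass(frozen=True)
class BlendingGeometry:
    """Blended domain ``[a, b]`` with interfaces ``I1 < I2``.

    Parameters
    ----------
    a, b
        Domain endpoints (the ``x`` extent in 3D).
    I1, I2
        Interface positions, ``a < I1 < I2 < b``.
    D
        Macroscopic diffusion coefficient (length^2 / time).
    blend_kind
        Shape of the blending fraction; only ``"linear"`` ships.
    dimension
        1 or 3.  For 3D the cross-section is ``[0, Ly] x [0, Lz]``.
    Ly, Lz
        Cross-section extent (ignored in 1D; the cross-sectional area
        is then 1 by convention).
    """

    a: float
    b: float
    I1: float
    I2: float
    D: float
    blend_kind: str = "linear"
    dimension: int = 1
    Ly: float = 1.0
    Lz: float = 1.0

    @property
    def area(self) -> float:
        """Cross-sectional area (1 in 1D)."""
        return self.Ly * self.Lz if self.dimension == 3 else 1.0

    @property
    def blend_width(self) -> float:
        return self.I2 - self.I1

    def beta1(self, x):
        """Blending fraction of the coarse model, extended to [a, b]."""
        x = np.asarray(x, dtype=float)
        w = (self.I2 - x) / self.blend_width
        return np.clip(w, 0.0, 1.0)

    def beta2(self, x):
        return 1.0 - self.beta1(x)

    def D1(self, x):
        """Split diffusivity of the coarse model (D on [a, I1), 0 on (I2, b])."""
        return self.D * self.beta1(x)

    def D2(self, x):
        """Split diffusivity of the fine model (0 on [a, I1), D on (I2, b])."""
        return self.D * self.beta2(x)

    def dD2dx(self, x):
        """Spatial derivative of D2, one-sided from inside the blending region.

        The linear blend is non-differentiable at I1 and I2; particles
        governed by D2 live in [I1, b], so at both kinks the derivative
        is taken from inside [I1, I2].  Beyond I2 the slope is zero.
        """
        x = np.asarray(x, dtype=float)
        slope = self.D / self.blend_width
        return np.where((x >= self.I1) & (x <= self.I2), slope, 0.0)


def build_geometry(
    a: float,
    b: float,
    I1: float,
    I2: float,
    D: float,
    blend_kind: str = "linear",
    dimension: int = 1,
    Ly: float = 1.0,
    Lz: float = 1.0,
) -> BlendingGeometry:
    """Validate and construct a :class:`BlendingGeometry`."""
    if not (a < I1 < I2 < b):
        raise ConfigurationError(
            f"interfaces must satisfy a < I1 < I2 < b, got "
            f"a={a}, I1={I1}, I2={I2}, b={b}"
        )
    if D <= 0:
        raise ConfigurationError(f"diffusion coefficient must be positive, got {D}")
    if blend_kind != "linear":
        raise ConfigurationError(f"unknown blend_kind {blend_kind!r}")
    if dimension not in (1, 3):
        raise ConfigurationError(f"dimension must be 1 or 3, got {dimension}")
    return BlendingGeometry(
        a=float(a), b=float(b), I1=float(I1), I2=float(I2), D=float(D),
        blend_kind=blend_kind, dimension=dimension, Ly=float(Ly), Lz=float(Lz),
    )


def _exact_divide(length: float, step: float, what: str) -> int:
    n = length / step
    n_round = round(n)
    if n_round <= 0 or abs(n - n_round) > 1e-9 * max(1.0, abs(n)):
        raise ConfigurationError(
            f"{what} = {length!r} is not a positive integer multiple of {step!r}"
        )
    return int(n_round)


@dataclass(frozen=True)
class MeshSpec:
    """Joint mesh bookkeeping for one coupler.

    ``gamma = h/dx`` PDE voxels fit in each compartment.  The counts are

    * ``n_p``  PDE voxels in the pure-PDE region (PDE-compartment coupler),
    * ``n_1``  PDE voxels in the blending region,
    * ``n_2``  compartments in the blending region,
    * ``n_c``  compartments in the pure-compartment region, which lies on
      ``[I2, b]`` for the PDE-compartment coupler and on ``[a, I1]`` for
      the compartment-Brownian coupler.
    """

    dx: float
    h: float
    gamma: int
    n_p: int
    n_1: int
    n_2: int
    n_c: int
    coupling: str = "pde-compartment"


def build_mesh(
    geom: BlendingGeometry,
    dx: float,
    h: float,
    coupling: str = "pde-compartment",
) -> MeshSpec:
    """Build the mesh for the given coupler, checking all divisibility rules."""
    if coupling not in ("pde-compartment", "compartment-brownian"):
        raise ConfigurationError(f"unknown coupling {coupling!r}")
    gamma = _exact_divide(h, dx, "h/dx (voxels per compartment)")
    n_1 = _exact_divide(geom.I2 - geom.I1, dx, "blending width / dx")
    n_2 = _exact_divide(geom.I2 - geom.I1, h, "blending width / h")
    if n_1 != gamma * n_2:
        raise ConfigurationError(
            f"inconsistent mesh: n_1={n_1} != gamma*n_2={gamma * n_2}"
        )
    n_p = _exact_divide(geom.I1 - geom.a, dx, "pure-PDE length / dx")
    if coupling == "pde-compartment":
        n_c = _exact_divide(geom.b - geom.I2, h, "pure-compartment length / h")
    else:
        n_c = _exact_divide(geom.I1 - geom.a, h, "pure-compartment length / h")
    return MeshSpec(
        dx=float(dx), h=float(h), gamma=gamma,
        n_p=n_p, n_1=n_1, n_2=n_2, n_c=n_c, coupling=coupling,
    )
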