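"""Microscopic off-lattice Brownian engine.

Particles follow the drift-corrected Euler-Maruyama update

    y(t + dt) = y(t) + dt * dD/dx|_y + sqrt(2 D(y) dt) * xi,   xi ~ N(0,1),

whose Fokker-Planck equation is the divergence-form diffusion equation
``dc/dt = d/dx(D(x) dc/dx)``; the drift term is exactly what keeps a
uniform density invariant under spatially varying D.  Boundaries
reflect.  Bimolecular reactions use the lambda-rho rule: each unordered
pair closer than the interaction radius ``rho`` reacts with per-step
probability ``p_lambda``; first-order decay removes each particle with
the exact exponential probability ``1 - exp(-mu dt)``; zeroth-order
production places Poisson-distributed new particles uniformly.

Positions are stored as an ``(N, d)`` array with ``d`` in {1, 3}.  In
3D the diffusivity varies along ``x`` only (planar blending), the
Gaussian displacements are coordinate-wise independent, and reflections
apply per coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .compartment import ReactionSystem
from .geometry import BlendingGeometry

__all__ = [
    "ParticleSet",
    "make_particles",
    "em_step",
    "handle_boundaries",
    "react_pairs",
    "react_scalar",
]


@dataclass
class ParticleSet:
    """Off-lattice particle positions inside ``[x_lo, x_hi]``.

    ``reflect_tally`` counts reflections at the left boundary, which in
    the compartment-Brownian hybrid is the interface ``I1`` that
    particles may only cross as a rare time-discretization artefact.
    """

    pos: np.ndarray                 # shape (N, dim)
    x_lo: float
    x_hi: float
    Ly: float = 1.0
    Lz: float = 1.0
    reflect_tally: int = 0

    @property
    def N(self) -> int:
        return self.pos.shape[0]

    @property
    def dim(self) -> int:
        return self.pos.shape[1]

    @property
    def x(self) -> np.ndarray:
        return self.pos[:, 0]

    def copy(self) -> "ParticleSet":
        return ParticleSet(pos=self.pos.copy(), x_lo=self.x_lo, x_hi=self.x_hi,
                           Ly=self.Ly, Lz=self.Lz,
                           reflect_tally=self.reflect_tally)


def make_particles(geom: BlendingGeometry, x,
                   span: Optional[tuple[float, float]] = None,
                   yz: Optional[np.ndarray] = None) -> ParticleSet:
    """Build a particle set from x positions (y, z optional in 3D)."""
    x_lo, x_hi = span if span is not None else (geom.a, geom.b)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if geom.dimension == 3:
        pos = np.zeros((x.shape[0], 3))
        pos[:, 0] = x
        if yz is not None:
            pos[:, 1:] = yz
        return ParticleSet(pos=pos, x_lo=x_lo, x_hi=x_hi, Ly=geom.Ly, Lz=geom.Lz)
    return ParticleSet(pos=x[:, None], x_lo=x_lo, x_hi=x_hi)


def em_step(particles: ParticleSet, geom: BlendingGeometry, dt_b: float,
            rng: np.random.Generator, diffusivity: str = "D2") -> ParticleSet:
    """One Euler-Maruyama step (no boundary handling).

    ``diffusivity`` selects the engine's coefficient: ``"full"`` for
    the constant ``D`` (zero drift) or ``"D2"`` for the fine-model
    split coefficient, whose derivative at the blend's kinks is taken
    one-sided from inside the blending region.
    """
    if dt_b <= 0:
        raise ValueError(f"dt_b must be positive, got {dt_b}")
    x = particles.pos[:, 0]
    if diffusivity == "full":
        Deff = np.full_like(x, geom.D)
        drift = 0.0
    elif diffusivity == "D2":
        Deff = np.asarray(geom.D2(x), dtype=float)
        drift = dt_b * geom.dD2dx(x)
    else:
        raise ValueError(f"unknown diffusivity {diffusivity!r}")
    sd = np.sqrt(2.0 * Deff * dt_b)
    xi = rng.standard_normal(particles.pos.shape)
    particles.pos += sd[:, None] * xi
    particles.pos[:, 0] += drift
    return particles


def _reflect_into(v: np.ndarray, lo: float, hi: float) -> int:
    """Reflect coordinates into [lo, hi] in place; returns the number of
    values that crossed the lower boundary."""
    n_lo = int(np.count_nonzero(v < lo))
    width = hi - lo
    out = (v < lo) | (v > hi)
    if np.any(out):
        y = np.mod(v[out] - lo, 2.0 * width)
        v[out] = lo + np.minimum(y, 2.0 * width - y)
    return n_lo


def handle_boundaries(particles: ParticleSet,
                      region: Optional[tuple[float, float]] = None) -> ParticleSet:
    """Reflect particles back into the region (``y -> 2w - y``, repeated).

    Left-boundary crossings are added to ``reflect_tally`` so the rarity
    of erroneous interface crossings can be reported.
    """
    lo, hi = region if region is not None else (particles.x_lo, particles.x_hi)
    particles.reflect_tally += _reflect_into(particles.pos[:, 0], lo, hi)
    if particles.dim == 3:
        _reflect_into(particles.pos[:, 1], 0.0, particles.Ly)
        _reflect_into(particles.pos[:, 2], 0.0, particles.Lz)
    return particles


def react_pairs(particles: ParticleSet, reactions: ReactionSystem, dt_b: float,
                rng: np.random.Generator,
                eligible: Optional[np.ndarray] = None) -> tuple[ParticleSet, int]:
    """Apply the lambda-rho bimolecular rule for one step.

    Every unordered pair of eligible particles at Euclidean distance
    below ``rho`` reacts with probability ``p_lambda``; both partners
    are removed, and a particle consumed this step is ineligible for
    further pairs (pairs are processed in randomized order).  Returns
    the updated set and the number of particles removed.
    """
    if reactions.rho <= 0 or reactions.p_lambda <= 0 or particles.N < 2:
        return particles, 0
    if eligible is None:
        eligible = np.arange(particles.N)
    if eligible.shape[0] < 2:
        return particles, 0
    tree = cKDTree(particles.pos[eligible])
    pairs = tree.query_pairs(reactions.rho, output_type="ndarray")
    if pairs.shape[0] == 0:
        return particles, 0
    pairs = eligible[pairs[rng.permutation(pairs.shape[0])]]
    consumed = np.zeros(particles.N, dtype=bool)
    for a, b in pairs:
        if consumed[a] or consumed[b]:
            continue
        if rng.random() < reactions.p_lambda:
            consumed[a] = True
            consumed[b] = True
    n_rm = int(consumed.sum())
    if n_rm:
        particles.pos = particles.pos[~consumed]
    return particles, n_rm


def react_scalar(particles: ParticleSet, reactions: ReactionSystem,
                 region: tuple[float, float], dt_b: float,
                 rng: np.random.Generator) -> ParticleSet:
    """First-order decay and zeroth-order production for one step.

    Each particle is removed with probability ``1 - exp(-mu dt)``;
    ``Poisson(kappa2 * V_region * dt)`` new particles appear uniformly
    in the region (cross-section uniform in 3D).
    """
    lo, hi = region
    if reactions.mu > 0 and particles.N > 0:
        keep = rng.random(particles.N) >= -np.expm1(-reactions.mu * dt_b)
        particles.pos = particles.pos[keep]
    if reactions.kappa2 > 0:
        area = particles.Ly * particles.Lz if particles.dim == 3 else 1.0
        n_new = rng.poisson(reactions.kappa2 * (hi - lo) * area * dt_b)
        if n_new:
            new = np.empty((n_new, particles.dim))
            new[:, 0] = rng.uniform(lo, hi, n_new)
            if particles.dim == 3:
                new[:, 1] = rng.uniform(0.0, particles.Ly, n_new)
                new[:, 2] = rng.uniform(0.0, particles.Lz, n_new)
            particles.pos = np.vstack([particles.pos, new])
    return particles
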