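"""Compartment-Brownian hybrid coupler (particle-level blending).

The compartment engine owns ``[a, I2]`` with the split diffusivity
``D1``; Brownian particles live on ``[I1, b]`` with ``D2``.  In the
blending region every compartment-based particle has a Brownian twin,
and the two representations are synchronized every window ``dt_b``:

1. the SSA advances the chain over the window; every diffusion event in
   the blending region is mirrored *immediately* into the particles —
   a jump displaces a uniformly chosen resident of the source
   compartment by +-h, a leftward exit through ``I1`` deletes a
   uniformly chosen resident, a rightward entry creates a particle
   uniformly in ``[I1, I1+h)``; blending reactions (compartment
   paradigm) create or delete twins the same way;
2. the particles take an Euler-Maruyama step with drift ``dD2/dx``,
   reflect at ``I1`` (rare erroneous crossings, tallied) and at the
   outer boundary, and undergo pure-Brownian-region reactions
   (lambda-rho pairs and scalar channels act only beyond ``I2``);
3. the blending counts are reset to the half-open histogram of the
   Brownian positions (rebinning).

Under diffusion-only dynamics every one of these moves conserves the
total particle number exactly.  The module-level operations implement
the synchronization primitives on a :class:`HybridStateCB` and are the
reference semantics; :func:`run_cb` executes whole runs in a compiled
kernel with identical event logic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _kernels
from .brownian import ParticleSet, em_step, handle_boundaries, react_pairs, react_scalar
from .compartment import (CompartmentField, Event, ReactionSystem,
                          make_compartment_field, ssa_advance_window)
from .geometry import BlendingGeometry, MeshSpec

__all__ = [
    "ConsistencyError",
    "HybridStateCB",
    "make_cb_state",
    "mirror_jump_event",
    "exchange_at_interface",
    "rebin",
    "hybrid_window",
    "run_cb",
]


class ConsistencyError(RuntimeError):
    """The twin representations of the blending region disagreed."""


@dataclass
class HybridStateCB:
    """Joint state of the compartment-Brownian hybrid at time ``t``."""

    comp: CompartmentField      # [a, I2], diffusivity D1
    particles: ParticleSet      # [I1, b], diffusivity D2
    geom: BlendingGeometry
    mesh: MeshSpec
    t: float = 0.0
    dt_b: float = 1e-4
    debug: bool = False

    @property
    def n_c(self) -> int:
        return self.mesh.n_c

    def blending_index(self, i: int) -> int:
        """Blending-region index of absolute compartment ``i`` (or -1)."""
        ib = i - self.n_c
        return ib if 0 <= ib < self.mesh.n_2 else -1

    def residents(self, i: int) -> np.ndarray:
        """Particle indices currently inside absolute compartment ``i``."""
        lo = self.geom.a + i * self.mesh.h
        hi = lo + self.mesh.h
        x = self.particles.x
        return np.flatnonzero((x >= lo) & (x < hi))

    def total_count(self) -> float:
        """Pure-compartment counts + Brownian particles (blending once)."""
        return float(self.comp.C[:self.n_c].sum()) + self.particles.N

    def region_masses(self) -> tuple[float, float, float]:
        """(pure-compartment, blending, pure-Brownian) region masses."""
        nb = int(np.count_nonzero(self.particles.x >= self.geom.I2))
        return (float(self.comp.C[:self.n_c].sum()),
                float(self.comp.C[self.n_c:].sum()),
                float(nb))


def make_cb_state(geom: BlendingGeometry, mesh: MeshSpec, dt_b: float,
                  counts, positions, debug: bool = False) -> HybridStateCB:
    """Assemble the hybrid state.  ``counts`` fills the pure-compartment
    region [a, I1]; the blending counts are derived from the particle
    positions (the finer representation is authoritative)."""
    comp = make_compartment_field(geom, mesh.h, span=(geom.a, geom.I2),
                                  diffusivity="D1", counts=0.0)
    counts = np.atleast_1d(np.asarray(counts, dtype=float))
    comp.C[:mesh.n_c] = counts
    if isinstance(positions, ParticleSet):
        particles = positions
    else:
        from .brownian import make_particles
        particles = make_particles(geom, positions, span=(geom.I1, geom.b))
    state = HybridStateCB(comp=comp, particles=particles, geom=geom,
                          mesh=mesh, dt_b=dt_b, debug=debug)
    rebin(state)
    return state


def _pick_resident(state: HybridStateCB, i: int, rng: np.random.Generator) -> int:
    members = state.residents(i)
    if members.shape[0] == 0:
        raise ConsistencyError(
            f"compartment {i} holds no Brownian particle but count "
            f"{state.comp.C[i]}")
    return int(members[rng.integers(members.shape[0])])


def mirror_jump_event(state: HybridStateCB, i: int, direction: int,
                      rng: np.random.Generator) -> HybridStateCB:
    """Mirror an SSA jump from blending compartment ``i`` to ``i +
    direction`` (both blending): displace a uniformly chosen resident
    by ``direction * h``.  Counts were already updated by the engine."""
    k = _pick_resident(state, i, rng)
    state.particles.pos[k, 0] += direction * state.mesh.h
    return state


def exchange_at_interface(state: HybridStateCB, direction: int,
                          rng: np.random.Generator) -> HybridStateCB:
    """Mirror an SSA jump across the interface compartment boundary
    ``n_c-1 <-> n_c``: a leftward exit (direction=-1) deletes a
    uniformly chosen resident of the first blending compartment, a
    rightward entry (direction=+1) creates a particle uniformly in
    ``[I1, I1 + h)`` (cross-section uniform in 3D)."""
    p = state.particles
    if direction < 0:
        k = _pick_resident(state, state.n_c, rng)
        p.pos = np.delete(p.pos, k, axis=0)
    else:
        new = np.empty((1, p.dim))
        new[0, 0] = rng.uniform(state.geom.I1, state.geom.I1 + state.mesh.h)
        if p.dim == 3:
            new[0, 1] = rng.uniform(0.0, p.Ly)
            new[0, 2] = rng.uniform(0.0, p.Lz)
        p.pos = np.vstack([p.pos, new])
    return state


def rebin(state: HybridStateCB) -> HybridStateCB:
    """Set each blending count to the half-open histogram
    ``[I1 + (i-1)h, I1 + ih)`` of the Brownian positions."""
    geom, mesh = state.geom, state.mesh
    x = state.particles.x
    in_blend = x < geom.I2
    idx = np.floor((x[in_blend] - geom.I1) / mesh.h).astype(int)
    np.clip(idx, 0, mesh.n_2 - 1, out=idx)
    state.comp.C[state.n_c:] = np.bincount(idx, minlength=mesh.n_2)
    return state


def _check_invariant(state: HybridStateCB):
    geom, mesh = state.geom, state.mesh
    x = state.particles.x
    in_blend = x < geom.I2
    idx = np.floor((x[in_blend] - geom.I1) / mesh.h).astype(int)
    np.clip(idx, 0, mesh.n_2 - 1, out=idx)
    hist = np.bincount(idx, minlength=mesh.n_2)
    if not np.array_equal(hist, state.comp.C[state.n_c:].astype(int)):
        raise ConsistencyError(
            f"window invariant violated: counts {state.comp.C[state.n_c:]} "
            f"vs histogram {hist}")


def hybrid_window(state: HybridStateCB, reactions: ReactionSystem,
                  rng: np.random.Generator) -> HybridStateCB:
    """Advance the hybrid by one window ``dt_b`` (SSA first, Brownian
    second, then rebinning).  Pure-Python reference path."""
    n_c, n2 = state.n_c, state.mesh.n_2
    geom = state.geom

    def hook(ev: Event):
        ib = state.blending_index(ev.i)
        if ev.kind == "jump":
            j = ev.i + ev.direction
            jb = state.blending_index(j)
            if ib >= 0 and jb >= 0:
                mirror_jump_event(state, ev.i, ev.direction, rng)
            elif ib >= 0 and jb < 0:
                exchange_at_interface(state, -1, rng)
            elif ib < 0 and jb >= 0:
                exchange_at_interface(state, +1, rng)
        elif ib >= 0:
            p = state.particles
            lo = geom.a + ev.i * state.mesh.h
            if ev.kind == "production":
                new = np.empty((1, p.dim))
                new[0, 0] = rng.uniform(lo, lo + state.mesh.h)
                if p.dim == 3:
                    new[0, 1] = rng.uniform(0.0, p.Ly)
                    new[0, 2] = rng.uniform(0.0, p.Lz)
                p.pos = np.vstack([p.pos, new])
            elif ev.kind == "decay":
                k = _pick_resident(state, ev.i, rng)
                p.pos = np.delete(p.pos, k, axis=0)
            elif ev.kind == "annihilation":
                for _ in range(2):
                    k = _pick_resident(state, ev.i, rng)
                    p.pos = np.delete(p.pos, k, axis=0)

    ssa_advance_window(state.comp, reactions, state.t, state.t + state.dt_b,
                       rng, event_hook=hook)

    p = state.particles
    em_step(p, geom, state.dt_b, rng, diffusivity="D2")
    handle_boundaries(p, (geom.I1, geom.b))
    # reactions beyond I2 follow the Brownian paradigm; a pair straddling
    # the interface belongs to the blending compartment's channel
    beyond = np.flatnonzero(p.x > geom.I2)
    if reactions.kappa1 > 0 and beyond.shape[0] >= 2:
        react_pairs(p, reactions, state.dt_b, rng, eligible=beyond)
        beyond = np.flatnonzero(p.x > geom.I2)
    if reactions.mu > 0 and beyond.shape[0] > 0:
        rm_p = -np.expm1(-reactions.mu * state.dt_b)
        doomed = beyond[rng.random(beyond.shape[0]) < rm_p]
        if doomed.shape[0]:
            p.pos = np.delete(p.pos, doomed, axis=0)
    if reactions.kappa2 > 0:
        area = p.Ly * p.Lz if p.dim == 3 else 1.0
        n_new = rng.poisson(reactions.kappa2 * (geom.b - geom.I2) * area
                            * state.dt_b)
        if n_new:
            new = np.empty((n_new, p.dim))
            new[:, 0] = rng.uniform(geom.I2, geom.b, n_new)
            if p.dim == 3:
                new[:, 1] = rng.uniform(0.0, p.Ly, n_new)
                new[:, 2] = rng.uniform(0.0, p.Lz, n_new)
            p.pos = np.vstack([p.pos, new])

    rebin(state)
    state.t += state.dt_b
    if state.debug:
        _check_invariant(state)
    return state


def run_cb(geom: BlendingGeometry, mesh: MeshSpec, dt_b: float,
           counts, positions: np.ndarray, reactions: ReactionSystem,
           output_times, seed: int, cap: Optional[int] = None):
    """Full hybrid run via the compiled kernel.

    ``counts`` fills the pure-compartment region, ``positions`` is an
    ``(N, 3)`` array of initial Brownian positions (y, z ignored in
    1D).  Records compartment counts, the width-h histogram of Brownian
    positions on ``[I1, b]``, the conserved total and the pure-Brownian
    count at each output time (multiples of ``dt_b``).
    """
    output_times = np.asarray(output_times, dtype=float)
    out_steps = np.round(output_times / dt_b).astype(np.int64)
    if not np.allclose(out_steps * dt_b, output_times, rtol=1e-9, atol=1e-12):
        raise ValueError("output times must be multiples of dt_b")
    n_windows = int(out_steps[-1])

    C0 = np.zeros(mesh.n_c + mesh.n_2)
    C0[:mesh.n_c] = counts
    pos0 = np.zeros((max(len(positions), 1), 3))
    if len(positions):
        pos_arr = np.asarray(positions, dtype=float)
        if pos_arr.ndim == 1:
            pos_arr = pos_arr[:, None]
        pos0[:len(positions), :pos_arr.shape[1]] = pos_arr
    n0 = len(positions)
    if cap is None:
        cap = max(4 * int(C0.sum() + n0) + 1000, 2000)

    dim = geom.dimension
    comp = make_compartment_field(geom, mesh.h, span=(geom.a, geom.I2),
                                  diffusivity="D1")
    comp_out, bhist, total, nbrow, reflects, status = _kernels.cb_hybrid_run(
        C0, pos0, n0,
        mesh.n_c, mesh.n_2, geom.a, geom.I1, geom.I2, geom.b, mesh.h,
        comp.volume, comp.rate_left, comp.rate_right,
        geom.D, dim, geom.Ly, geom.Lz, dt_b,
        reactions.mu, reactions.kappa2, reactions.kappa1,
        reactions.influx_left, reactions.rho, reactions.p_lambda,
        out_steps, n_windows, cap, seed % (2**31 - 1))
    if status == _kernels.FAULT_EMPTY_COMPARTMENT:
        raise ConsistencyError("blending compartment emptied of twins")
    if status == _kernels.FAULT_CAPACITY:
        raise RuntimeError("particle capacity exceeded; increase cap")
    blend = comp_out[:, mesh.n_c:].sum(axis=1)
    brow = nbrow.astype(float)
    return {"times": output_times, "comp_C": comp_out, "brow_hist": bhist,
            "total": total,
            "region_masses": np.column_stack(
                [comp_out[:, :mesh.n_c].sum(axis=1), blend, brow]),
            "reflections": int(reflects)}
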