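"""PDE-compartment hybrid coupler (operator-split blending).

The macroscopic PDE solver owns ``[a, I2]`` with the split diffusivity
``D1`` (no condition is needed at ``I2`` because ``D1(I2) = 0``); the
compartment engine owns ``[I1, b]`` with ``D2`` (its left outer face at
``I1`` has zero rate because ``D2(I1) = 0``).  In the blending region
``[I1, I2]`` both representations describe the same mass and are kept
synchronized every window ``dt_p``:

1. the PDE is advanced one step (reaction terms act only on the
   pure-PDE voxels — blending reactions follow the compartment
   paradigm, which avoids double counting);
2. each blending compartment count is overwritten with the integral of
   the PDE concentration over its ``gamma`` voxels (counts may be
   fractional);
3. the compartment engine is advanced over the window, reactions active
   everywhere on ``[I1, b]``;
4. the net count change of each blending compartment is mirrored back
   into the PDE by adding ``delta / (gamma dx)`` concentration to each
   of its voxels.

Mirroring per accumulated window and per event are algebraically
identical (the update is linear); the window form is used by default
and the per-event form is available through the engine's event hook.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Callable, Optional

import numpy as np

from .compartment import (CompartmentField, ReactionSystem, make_compartment_field,
                          ssa_advance_window)
from .geometry import BlendingGeometry, MeshSpec
from .pde import PDEField, make_pde_field, pde_mass, pde_step

__all__ = [
    "HybridStatePC",
    "make_pc_state",
    "sync_pde_to_compartments",
    "push_compartment_delta",
    "hybrid_window",
    "run_pc",
]


@dataclass
class HybridStatePC:
    """Joint state of the PDE-compartment hybrid at time ``t``."""

    pde: PDEField
    comp: CompartmentField
    geom: BlendingGeometry
    mesh: MeshSpec
    t: float = 0.0
    dt_p: float = 1e-4
    reaction_term: Optional[Callable[[np.ndarray], np.ndarray]] = None
    debug: bool = False
    _delta: np.ndarray = dataclass_field(default=None, repr=False)

    def __post_init__(self):
        if self._delta is None:
            self._delta = np.zeros(self.comp.n, np.int64)

    def blending_compartment_mass(self, i: int) -> float:
        """PDE mass over the gamma voxels of blending compartment ``i``."""
        g, dx = self.mesh.gamma, self.mesh.dx
        j0 = self.mesh.n_p + g * i
        return float(self.pde.q[j0:j0 + g].sum() * dx * self.pde.area)

    def total_mass(self) -> float:
        """Pure-PDE mass + all compartment counts (blending counted once)."""
        return pde_mass(self.pde, self.geom.a, self.geom.I1) + float(self.comp.C.sum())

    def region_masses(self) -> tuple[float, float, float]:
        """(pure-PDE, blending, pure-compartment) region masses."""
        n2 = self.mesh.n_2
        return (pde_mass(self.pde, self.geom.a, self.geom.I1),
                float(self.comp.C[:n2].sum()),
                float(self.comp.C[n2:].sum()))


def make_pc_state(geom: BlendingGeometry, mesh: MeshSpec, dt_p: float,
                  q0=0.0, counts=0.0, J_a: float = 0.0, J_b: float = 0.0,
                  reaction_term=None, debug: bool = False) -> HybridStatePC:
    """Assemble the hybrid state; the blending compartments are synced
    from the PDE so the two representations start consistent."""
    pde = make_pde_field(geom, mesh.dx, span=(geom.a, geom.I2),
                         diffusivity="D1", q0=q0, J_a=J_a, J_b=J_b)
    comp = make_compartment_field(geom, mesh.h, span=(geom.I1, geom.b),
                                  diffusivity="D2", counts=counts)
    state = HybridStatePC(pde=pde, comp=comp, geom=geom, mesh=mesh,
                          dt_p=dt_p, reaction_term=reaction_term, debug=debug)
    sync_pde_to_compartments(state)
    return state


def sync_pde_to_compartments(state: HybridStatePC) -> HybridStatePC:
    """Overwrite each blending compartment count with the PDE mass over
    its voxels; the pure-compartment region is untouched."""
    g, dx, n_p, n2 = (state.mesh.gamma, state.mesh.dx, state.mesh.n_p,
                      state.mesh.n_2)
    blend = state.pde.q[n_p:n_p + g * n2].reshape(n2, g)
    state.comp.C[:n2] = blend.sum(axis=1) * dx * state.pde.area
    return state


def push_compartment_delta(state: HybridStatePC, i: int, delta: float) -> HybridStatePC:
    """Spread a count change of blending compartment ``i`` uniformly over
    its gamma PDE voxels (concentration ``delta / (gamma dx)`` each)."""
    if delta == 0:
        return state
    g, dx = state.mesh.gamma, state.mesh.dx
    j0 = state.mesh.n_p + g * i
    state.pde.q[j0:j0 + g] += delta / (g * dx * state.pde.area)
    return state


def _masked_reaction(state: HybridStatePC):
    """Reaction term restricted to the pure-PDE voxels [a, I1)."""
    if state.reaction_term is None:
        return None
    n_p = state.mesh.n_p
    inner = state.reaction_term

    def masked(q):
        r = np.asarray(inner(q), dtype=float)
        r[n_p:] = 0.0
        return r

    return masked


def hybrid_window(state: HybridStatePC, reactions: ReactionSystem,
                  rng: np.random.Generator,
                  event_hook=None) -> HybridStatePC:
    """Advance the hybrid by one window ``dt_p`` (PDE first, SSA second)."""
    pde_step(state.pde, state.dt_p, reaction_term=_masked_reaction(state))
    sync_pde_to_compartments(state)
    delta = state._delta
    delta[:] = 0
    ssa_advance_window(state.comp, reactions, state.t, state.t + state.dt_p,
                       rng, event_hook=event_hook, delta_out=delta)
    for i in range(state.mesh.n_2):
        push_compartment_delta(state, i, int(delta[i]))
    state.t += state.dt_p
    if state.debug:
        for i in range(state.mesh.n_2):
            m = state.blending_compartment_mass(i)
            if not np.isclose(m, state.comp.C[i], rtol=1e-8, atol=1e-8):
                raise AssertionError(
                    f"blending consistency violated in compartment {i}: "
                    f"PDE mass {m} vs count {state.comp.C[i]}")
    return state


def run_pc(state: HybridStatePC, reactions: ReactionSystem,
           output_times, rng: np.random.Generator):
    """Run the hybrid, recording at ``output_times`` (multiples of dt_p).

    Returns a dict with snapshots of the PDE profile and compartment
    counts plus the (pure-PDE, blending, pure-compartment) region-mass
    series.
    """
    output_times = np.asarray(output_times, dtype=float)
    steps = np.round((output_times - state.t) / state.dt_p).astype(int)
    if not np.allclose(steps * state.dt_p + state.t, output_times, atol=1e-9):
        raise ValueError("output times must be multiples of dt_p")
    out_q = np.zeros((len(output_times), state.pde.n))
    out_C = np.zeros((len(output_times), state.comp.n))
    masses = np.zeros((len(output_times), 3))
    done = 0
    k = 0
    for target in steps:
        while done < target:
            hybrid_window(state, reactions, rng)
            done += 1
        out_q[k] = state.pde.q
        out_C[k] = state.comp.C
        masses[k] = state.region_masses()
        k += 1
    return {"times": output_times, "pde_q": out_q, "comp_C": out_C,
            "region_masses": masses}
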