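"""Mesoscopic compartment engine (reaction-diffusion master equation).

The domain slice owned by the engine is divided into compartments of
width ``h`` (cross-section ``Ly x Lz`` in 3D) in which particles are
well mixed.  Diffusion is a continuous-time random walk between
neighbouring compartments; the per-particle jump rate across a shared
face is the diffusivity evaluated *at that face* divided by ``h**2``,
whose diffusive limit is the divergence-form equation
``dc/dt = d/dx(D(x) dc/dx)``.  With the split diffusivities this
convention automatically gives a zero rate for jumps across an
interface where the engine's diffusivity vanishes.  Outer faces carry
zero-flux (zero-rate) conditions.

Reactions fire within compartments with mass-action propensities:

* order 0 (production, rate ``kappa2`` per volume): propensity
  ``kappa2 * V_i``, adds one particle;
* order 1 (decay, rate ``mu``): propensity ``mu * C_i``, removes one;
* order 2 (pair annihilation ``2A -> 0``, rate ``kappa1``): propensity
  ``kappa1 * C_i * (C_i - 1) / (2 * V_i)``, removes two — the choice
  that reproduces the ``-kappa1 c**2`` mean-field term under the
  Poisson moment closure;
* an optional boundary influx (``influx_left``, particles/time) enters
  the first compartment, the jump-process counterpart of a prescribed
  boundary flux.

Counts are real-valued inside a blending region (the PDE-compartment
coupler syncs fractional mass in): waiting times are computed from the
real-valued propensities, events still change counts by integers, and
propensities floor at zero.

Realization: Gillespie's direct method.  ``ssa_advance_window`` runs a
compiled kernel by default; passing an ``event_hook`` switches to a
pure-Python loop that reports every event, which is what the couplers'
synchronization (and the tests) attach to.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple, Optional

import numpy as np

from . import _kernels
from .geometry import BlendingGeometry, ConfigurationError

__all__ = [
    "CompartmentField",
    "ReactionSystem",
    "Event",
    "make_compartment_field",
    "jump_rates",
    "propensities",
    "ssa_advance_window",
]


@dataclass
class ReactionSystem:
    """Reaction channels of a single-species system.

    kappa2 : order-0 production rate (particles / (volume * time))
    mu : order-1 decay rate (1 / time)
    kappa1 : order-2 pair-annihilation rate (volume / (particle * time))
    rho, p_lambda : microscopic parameterization of the order-2 channel
        (interaction radius and per-step reaction probability) used by
        the Brownian engine; the mesoscopic and microscopic rates are
        configured independently.
    influx_left : boundary source rate (particles / time) into the
        engine's first compartment.
    """

    kappa2: float = 0.0
    mu: float = 0.0
    kappa1: float = 0.0
    rho: float = 0.0
    p_lambda: float = 0.0
    influx_left: float = 0.0

    def __post_init__(self):
        for name in ("kappa2", "mu", "kappa1", "rho", "p_lambda", "influx_left"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"reaction parameter {name} must be >= 0")

    @property
    def is_null(self) -> bool:
        return (self.kappa2 == 0 and self.mu == 0 and self.kappa1 == 0
                and self.influx_left == 0)


NULL_REACTIONS = ReactionSystem()


@dataclass
class CompartmentField:
    """Per-compartment counts on ``[x_lo, x_lo + n*h]``.

    ``C`` is float-valued to admit the fractional counts of the
    blending region; outside it the counts stay integral.  ``volume``
    is the compartment volume ``h * area``.
    """

    C: np.ndarray
    h: float
    x_lo: float
    volume: float
    rate_left: np.ndarray
    rate_right: np.ndarray
    area: float = 1.0

    @property
    def n(self) -> int:
        return self.C.shape[0]

    @property
    def x_hi(self) -> float:
        return self.x_lo + self.n * self.h

    @property
    def centers(self) -> np.ndarray:
        return self.x_lo + (np.arange(self.n) + 0.5) * self.h

    def copy(self) -> "CompartmentField":
        return CompartmentField(C=self.C.copy(), h=self.h, x_lo=self.x_lo,
                                volume=self.volume, rate_left=self.rate_left,
                                rate_right=self.rate_right, area=self.area)


def make_compartment_field(
    geom: BlendingGeometry,
    h: float,
    span: Optional[tuple[float, float]] = None,
    diffusivity: str = "full",
    counts=0.0,
) -> CompartmentField:
    """Build a compartment field over ``span`` (default the whole domain).

    ``diffusivity`` assigns the engine's diffusion coefficient: the full
    ``D`` standalone, ``"D1"`` in the compartment-Brownian hybrid (the
    compartment engine owns the left of the domain), ``"D2"`` in the
    PDE-compartment hybrid (it owns the right).
    """
    x_lo, x_hi = span if span is not None else (geom.a, geom.b)
    n = (x_hi - x_lo) / h
    if abs(n - round(n)) > 1e-9 * max(1.0, n) or round(n) <= 0:
        raise ConfigurationError(f"span {span} is not an integer multiple of h={h}")
    n = int(round(n))
    faces = x_lo + np.arange(n + 1) * h
    if diffusivity == "full":
        D_face = np.full(n + 1, geom.D)
    elif diffusivity == "D1":
        D_face = np.asarray(geom.D1(faces), dtype=float)
    elif diffusivity == "D2":
        D_face = np.asarray(geom.D2(faces), dtype=float)
    else:
        raise ConfigurationError(f"unknown diffusivity {diffusivity!r}")
    rate_left = D_face[:-1] / h ** 2
    rate_right = D_face[1:] / h ** 2
    rate_left = rate_left.copy()
    rate_right = rate_right.copy()
    rate_left[0] = 0.0    # zero flux at the region's outer faces
    rate_right[-1] = 0.0
    C = np.full(n, float(counts)) if np.isscalar(counts) else np.asarray(counts, dtype=float).copy()
    if C.shape != (n,):
        raise ConfigurationError(f"counts have shape {C.shape}, expected ({n},)")
    return CompartmentField(C=C, h=float(h), x_lo=float(x_lo),
                            volume=float(h) * geom.area,
                            rate_left=rate_left, rate_right=rate_right,
                            area=geom.area)


def jump_rates(field: CompartmentField, i: int) -> tuple[float, float]:
    """Per-particle (rate_left, rate_right) of compartment ``i``."""
    return float(field.rate_left[i]), float(field.rate_right[i])


def propensities(field: CompartmentField, reactions: ReactionSystem) -> np.ndarray:
    """Event rates per compartment, columns
    ``[left jump, right jump, production, decay, annihilation]``.

    The boundary influx channel (``reactions.influx_left``) is not part
    of this table; the SSA adds it to the first compartment.
    """
    C = np.maximum(field.C, 0.0)
    a = np.empty((field.n, 5))
    a[:, 0] = C * field.rate_left
    a[:, 1] = C * field.rate_right
    a[:, 2] = reactions.kappa2 * field.volume
    a[:, 3] = reactions.mu * C
    a[:, 4] = reactions.kappa1 * C * np.maximum(C - 1.0, 0.0) / (2.0 * field.volume)
    return a


class Event(NamedTuple):
    """One SSA event: kind in {'jump','production','decay','annihilation',
    'influx'}, the compartment index, and the jump direction (+-1, else 0)."""

    kind: str
    i: int
    direction: int


# stoichiometry applied by each non-jump channel
_CHANNEL = {2: ("production", +1), 3: ("decay", -1), 4: ("annihilation", -2)}


def ssa_advance_window(
    field: CompartmentField,
    reactions: ReactionSystem,
    t0: float,
    t_end: float,
    rng: np.random.Generator,
    event_hook: Optional[Callable[[Event], None]] = None,
    delta_out: Optional[np.ndarray] = None,
) -> CompartmentField:
    """Advance the field to ``t_end`` with Gillespie's direct method.

    The state is left at ``t_end`` (the first event time beyond it is
    discarded, which is exact for a Markov jump process).  If
    ``delta_out`` is given, the net integer count change per compartment
    is accumulated into it.  With an ``event_hook`` every executed event
    is reported through it (pure-Python path); otherwise a compiled
    kernel is used.
    """
    if t_end < t0:
        raise ValueError(f"t_end={t_end} earlier than t0={t0}")
    delta = delta_out if delta_out is not None else np.zeros(field.n, np.int64)
    if event_hook is None:
        _kernels.seed_rng(int(rng.integers(0, 2**31 - 1)))
        _kernels.ssa_window(field.C, field.rate_left, field.rate_right,
                            field.volume, reactions.kappa2, reactions.mu,
                            reactions.kappa1, reactions.influx_left,
                            t0, t_end, delta)
        return field

    C = field.C
    t = t0
    while True:
        a = propensities(field, reactions)
        total = a.sum() + reactions.influx_left
        if total <= 0.0:
            return field
        t += rng.exponential(1.0 / total)
        if t > t_end:
            return field
        r = rng.random() * total
        if r < reactions.influx_left:
            C[0] += 1.0
            delta[0] += 1
            event_hook(Event("influx", 0, 0))
            continue
        flat = np.cumsum(a.ravel()) + reactions.influx_left
        idx = int(np.searchsorted(flat, r, side="right"))
        idx = min(idx, a.size - 1)
        i, ch = divmod(idx, 5)
        if ch == 0:
            C[i] -= 1.0
            C[i - 1] += 1.0
            delta[i] -= 1
            delta[i - 1] += 1
            event_hook(Event("jump", i, -1))
        elif ch == 1:
            C[i] -= 1.0
            C[i + 1] += 1.0
            delta[i] -= 1
            delta[i + 1] += 1
            event_hook(Event("jump", i, +1))
        else:
            kind, st = _CHANNEL[ch]
            C[i] += st
            delta[i] += st
            event_hook(Event(kind, i, 0))
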