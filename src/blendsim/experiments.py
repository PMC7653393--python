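"""Config-driven runner for the four built-in test problems.

Problems (all on the blended domain with interfaces at the thirds):

* ``uniform``        — pure diffusion from a uniform profile (the hybrid
  must hold the uniform steady state without bias);
* ``redistribution`` — pure diffusion with all mass initially uniform on
  ``[a, I1]`` (high interface flux);
* ``morphogen``      — diffusion, decay at rate ``mu`` and boundary
  influx ``D*J`` at ``x = a``, starting from the uniform profile with
  the steady-state mass ``D J / mu``;
* ``bimolecular3d``  — production/pair-annihilation (``2A -> 0`` at
  ``kappa1``, ``0 -> A`` at ``kappa2``) in ``[0,10] x [0,1] x [0,1]``
  from a linear initial gradient.

The default configurations are the study conditions of the built-in
problems (N=1000 particles, D=1, h=1/30, dx=1/300, dt=1e-4, M=500
repeats for the 1D diffusion problems; J=1e4, mu=10, M=1000 for the
morphogen problem; kappa1=0.1, kappa2=89.7, rho=0.06,
p_lambda=2.5e-5, h_x=1/3, M=500 for the 3D problem).

Initialization uses expected values: each stochastic region receives
its share of the initial particle number by largest-remainder
apportionment (positions random); in blending regions the finer
representation is sampled first and the coarser one matched to it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernels, diagnostics
from .brownian import make_particles
from .compartment import ReactionSystem, make_compartment_field
from .geometry import BlendingGeometry, ConfigurationError, MeshSpec, build_geometry, build_mesh
from .hybrid_cb import make_cb_state, run_cb
from .hybrid_pc import make_pc_state, run_pc
from .pde import make_pde_field, pde_mass, pde_step

__all__ = [
    "RunConfig",
    "default_config",
    "make_initial_condition",
    "run_experiment",
    "run_ground_truth",
    "ExperimentResult",
]

PROBLEMS = ("uniform", "redistribution", "morphogen", "bimolecular3d")
COUPLINGS = ("pde-compartment", "compartment-brownian",
             "pure-pde", "pure-compartment", "pure-brownian")

# linear initial gradient of the bimolecular problem: c(x) = 91.5 - 9 x,
# integrating to 465 particles over the unit-cross-section domain
_BIMOL_CA = 183.0 / 2.0
_BIMOL_CB = -9.0


@dataclass
class RunConfig:
    """Complete, serializable description of one experiment."""

    problem: str = "uniform"
    coupling: str = "pde-compartment"
    a: float = 0.0
    b: float = 1.0
    I1: float = 1.0 / 3.0
    I2: float = 2.0 / 3.0
    D: float = 1.0
    dx: float = 1.0 / 300.0
    h: float = 1.0 / 30.0
    dimension: int = 1
    h_y: float = 1.0
    h_z: float = 1.0
    dt_p: float = 1e-4
    dt_b: float = 1e-4
    t_final: float = 1.0
    output_times: list = field(default_factory=list)
    N: float = 1000.0
    J: float = 0.0
    mu: float = 0.0
    kappa1: float = 0.0
    kappa2: float = 0.0
    rho: float = 0.0
    p_lambda: float = 0.0
    repeats: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.problem not in PROBLEMS:
            raise ConfigurationError(f"unknown problem {self.problem!r}")
        if self.coupling not in COUPLINGS:
            raise ConfigurationError(f"unknown coupling {self.coupling!r}")
        if not self.output_times:
            self.output_times = [round(0.05 * k, 10) for k in range(1, 21)
                                 if 0.05 * k <= self.t_final + 1e-12]
            if not self.output_times:
                self.output_times = [self.t_final]

    @property
    def dt(self) -> float:
        return self.dt_p if self.coupling == "pde-compartment" else self.dt_b

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s


def default_config(problem: str, coupling: str = "pde-compartment",
                   **overrides) -> RunConfig:
    """Study conditions of the built-in test problems."""
    base: dict = {"problem": problem, "coupling": coupling}
    if problem in ("uniform", "redistribution"):
        base.update(N=1000.0, repeats=500)
    elif problem == "morphogen":
        base.update(N=1000.0, J=1e4, mu=10.0, repeats=1000)
    elif problem == "bimolecular3d":
        base.update(a=0.0, b=10.0, I1=10.0 / 3.0, I2=20.0 / 3.0,
                    dimension=3, h=1.0 / 3.0, h_y=1.0, h_z=1.0,
                    N=465.0, kappa1=0.1, kappa2=89.7,
                    rho=0.06, p_lambda=2.5e-5, repeats=500)
    base.update(overrides)
    return RunConfig(**base)


def make_geometry(config: RunConfig) -> BlendingGeometry:
    return build_geometry(config.a, config.b, config.I1, config.I2, config.D,
                          dimension=config.dimension,
                          Ly=config.h_y, Lz=config.h_z)


def make_reactions(config: RunConfig, side: str = "stochastic") -> ReactionSystem:
    """Reaction channels for the stochastic engines.  The morphogen
    boundary influx enters the compartment chain only when that chain
    owns the domain boundary x=a (compartment-Brownian hybrid and pure
    compartment runs); in the PDE-compartment hybrid it is a PDE flux
    condition."""
    influx = 0.0
    if config.problem == "morphogen" and side in ("left-boundary",):
        influx = config.D * config.J
    return ReactionSystem(kappa2=config.kappa2, mu=config.mu,
                          kappa1=config.kappa1, rho=config.rho,
                          p_lambda=config.p_lambda, influx_left=influx)


def _pde_reaction_term(config: RunConfig):
    """Pointwise mean-field reaction term R(c) (None if no reactions)."""
    if config.problem == "morphogen":
        mu = config.mu
        return lambda q: -mu * q
    if config.problem == "bimolecular3d":
        k1, k2 = config.kappa1, config.kappa2
        return lambda q: -k1 * q * q + k2
    return None


def apportion(weights, total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` items to ``weights``."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        out = np.zeros(len(w), dtype=int)
        out[0] = total
        return out
    ideal = w / w.sum() * total
    base = np.floor(ideal).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(ideal - base))
    base[order[:rem]] += 1
    return base


def _linear_profile(x):
    return _BIMOL_CA + _BIMOL_CB * np.asarray(x, dtype=float)


def _linear_mass(x0: float, x1: float) -> float:
    return _BIMOL_CA * (x1 - x0) + 0.5 * _BIMOL_CB * (x1 ** 2 - x0 ** 2)


def _sample_linear(rng: np.random.Generator, n: int, x0: float, x1: float) -> np.ndarray:
    """Inverse-CDF samples from the linear density restricted to [x0, x1]."""
    u = rng.random(n)
    Z = _linear_mass(x0, x1)
    target = _BIMOL_CA * x0 + 0.5 * _BIMOL_CB * x0 ** 2 + u * Z
    # solve cb/2 x^2 + ca x - target = 0 for the root in [x0, x1]
    disc = _BIMOL_CA ** 2 + 2.0 * _BIMOL_CB * target
    x = (-_BIMOL_CA + np.sqrt(np.maximum(disc, 0.0))) / _BIMOL_CB
    return np.clip(x, x0, x1)


def _bin_positions(x, x_lo: float, h: float, n: int) -> np.ndarray:
    idx = np.floor((np.asarray(x) - x_lo) / h).astype(int)
    np.clip(idx, 0, n - 1, out=idx)
    return np.bincount(idx, minlength=n).astype(float)


def make_initial_condition(config: RunConfig, rng: np.random.Generator) -> dict:
    """Problem- and coupling-specific initial state.

    Returns a dict with, depending on the coupling, keys ``q0`` (PDE
    concentrations), ``counts`` (pure-compartment counts), ``positions``
    (Brownian x or xyz positions) and ``blend_q0`` (PDE blending voxels
    matched to the sampled compartments, bimolecular problem only).
    """
    geom = make_geometry(config)
    coupling = config.coupling
    p = config.problem
    L = geom.b - geom.a
    N = config.N

    if p in ("uniform", "morphogen"):
        c0 = N / L
        if coupling == "pde-compartment":
            n_c = build_mesh(geom, config.dx, config.h, coupling).n_c
            n_right = int(round(N * (geom.b - geom.I2) / L))
            return {"q0": c0, "counts": apportion(np.ones(n_c), n_right)}
        if coupling == "compartment-brownian":
            mesh = build_mesh(geom, config.dx, config.h, coupling)
            shares = apportion([geom.I1 - geom.a, geom.b - geom.I1], int(round(N)))
            counts = apportion(np.ones(mesh.n_c), shares[0])
            x = rng.uniform(geom.I1, geom.b, shares[1])
            return {"counts": counts, "positions": _with_yz(x, geom, rng)}
        if coupling == "pure-pde":
            return {"q0": c0}
        if coupling == "pure-compartment":
            n = int(round(L / config.h))
            return {"counts": apportion(np.ones(n), int(round(N)))}
        if coupling == "pure-brownian":
            x = rng.uniform(geom.a, geom.b, int(round(N)))
            return {"positions": _with_yz(x, geom, rng)}

    if p == "redistribution":
        c0 = N / (geom.I1 - geom.a)
        if coupling == "pde-compartment":
            mesh = build_mesh(geom, config.dx, config.h, coupling)
            q0 = np.zeros(mesh.n_p + mesh.n_1)
            q0[:mesh.n_p] = c0
            return {"q0": q0, "counts": np.zeros(mesh.n_c)}
        if coupling == "compartment-brownian":
            mesh = build_mesh(geom, config.dx, config.h, coupling)
            return {"counts": apportion(np.ones(mesh.n_c), int(round(N))),
                    "positions": np.empty((0, 3))}
        if coupling == "pure-pde":
            n = int(round(L / config.dx))
            q0 = np.zeros(n)
            q0[:int(round((geom.I1 - geom.a) / config.dx))] = c0
            return {"q0": q0}
        if coupling == "pure-compartment":
            n = int(round(L / config.h))
            counts = np.zeros(n)
            n_left = int(round((geom.I1 - geom.a) / config.h))
            counts[:n_left] = apportion(np.ones(n_left), int(round(N)))
            return {"counts": counts}
        if coupling == "pure-brownian":
            x = rng.uniform(geom.a, geom.I1, int(round(N)))
            return {"positions": _with_yz(x, geom, rng)}

    if p == "bimolecular3d":
        if coupling == "pde-compartment":
            mesh = build_mesh(geom, config.dx, config.h, coupling)
            xc = geom.a + (np.arange(mesh.n_p + mesh.n_1) + 0.5) * config.dx
            q0 = _linear_profile(xc)
            # stochastic side [I1, b]: finer scale sampled per region
            n_blend = int(round(_linear_mass(geom.I1, geom.I2)))
            n_pure = int(round(_linear_mass(geom.I2, geom.b)))
            xb = _sample_linear(rng, n_blend, geom.I1, geom.I2)
            xp = _sample_linear(rng, n_pure, geom.I2, geom.b)
            blend_counts = _bin_positions(xb, geom.I1, config.h, mesh.n_2)
            counts = _bin_positions(xp, geom.I2, config.h, mesh.n_c)
            # match the coarse (PDE) blending density to the sampled counts
            blend_q0 = np.repeat(blend_counts / (config.h * geom.area),
                                 mesh.gamma)
            q0[mesh.n_p:] = blend_q0
            return {"q0": q0, "counts": counts}
        if coupling == "compartment-brownian":
            mesh = build_mesh(geom, config.dx, config.h, coupling)
            n_pc = int(round(_linear_mass(geom.a, geom.I1)))
            n_blend = int(round(_linear_mass(geom.I1, geom.I2)))
            n_b = int(round(_linear_mass(geom.I2, geom.b)))
            xc = _sample_linear(rng, n_pc, geom.a, geom.I1)
            counts = _bin_positions(xc, geom.a, config.h, mesh.n_c)
            x = np.concatenate([_sample_linear(rng, n_blend, geom.I1, geom.I2),
                                _sample_linear(rng, n_b, geom.I2, geom.b)])
            return {"counts": counts, "positions": _with_yz(x, geom, rng)}
        if coupling == "pure-pde":
            n = int(round(L / config.dx))
            xc = geom.a + (np.arange(n) + 0.5) * config.dx
            return {"q0": _linear_profile(xc)}
        if coupling == "pure-compartment":
            n = int(round(L / config.h))
            x = _sample_linear(rng, int(round(N)), geom.a, geom.b)
            return {"counts": _bin_positions(x, geom.a, config.h, n)}
        if coupling == "pure-brownian":
            x = _sample_linear(rng, int(round(N)), geom.a, geom.b)
            return {"positions": _with_yz(x, geom, rng)}

    raise ConfigurationError(f"no initial condition for {p}/{coupling}")


def _with_yz(x: np.ndarray, geom: BlendingGeometry,
             rng: np.random.Generator) -> np.ndarray:
    pos = np.zeros((x.shape[0], 3))
    pos[:, 0] = x
    if geom.dimension == 3:
        pos[:, 1] = rng.uniform(0.0, geom.Ly, x.shape[0])
        pos[:, 2] = rng.uniform(0.0, geom.Lz, x.shape[0])
    return pos


# ---------------------------------------------------------------------------
# Runners
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    config: RunConfig
    times: np.ndarray
    region_masses: np.ndarray        # (n_times, 3) ensemble mean
    region_stderr: np.ndarray
    rme: Optional[diagnostics.RMEReport]
    density: dict                    # component -> (x, (n_times, n) mean values)
    log: list

    def rme_frame(self) -> pd.DataFrame:
        rows = []
        if self.rme is None:
            return pd.DataFrame(columns=["time", "region", "rme", "mc_stderr"])
        for r, name in enumerate(self.rme.regions):
            for k, t in enumerate(self.rme.times):
                se = self.rme.stderr[r, k] if self.rme.stderr is not None else np.nan
                rows.append({"time": t, "region": name,
                             "rme": self.rme.values[r, k], "mc_stderr": se})
        return pd.DataFrame(rows)


def _regions(config: RunConfig):
    return [(config.a, config.I1), (config.I1, config.I2), (config.I2, config.b)]


def _region_labels(coupling: str):
    if coupling == "pde-compartment":
        return ["pde", "blending", "compartment"]
    if coupling == "compartment-brownian":
        return ["compartment", "blending", "brownian"]
    return ["left", "blending", "right"]


def _reference_masses(config: RunConfig, times, seed: int):
    """Reference region masses: analytic u(x,t) for the diffusion and
    morphogen problems, ensemble ground truth of the finest-scale model
    for the bimolecular problem."""
    regions = _regions(config)
    out = np.zeros((3, len(times)))
    if config.problem in ("uniform", "redistribution"):
        ic = "uniform" if config.problem == "uniform" else "step"
        for r, (lo, hi) in enumerate(regions):
            for k, t in enumerate(times):
                out[r, k] = diagnostics.diffusion_region_mass(
                    ic, config.D, t, lo, hi, N=config.N, step_hi=config.I1)
        return out, "analytic", 0
    if config.problem == "morphogen":
        for r, (lo, hi) in enumerate(regions):
            for k, t in enumerate(times):
                out[r, k] = diagnostics.morphogen_region_mass(
                    config.J, config.D, config.mu, t, lo, hi)
        return out, "analytic", 0
    engine = ("compartment" if config.coupling == "pde-compartment"
              else "brownian")
    gt = run_ground_truth(engine, config, config.repeats, seed + 909_090)
    return gt["region_masses"].T, f"ensemble-{engine}", config.repeats


def run_experiment(config: RunConfig, out_dir=None) -> ExperimentResult:
    """Run M seeded repeats of the configured coupling, average the
    density snapshots and compute the region-wise relative mass error
    against the problem's reference."""
    times = np.asarray(config.output_times, dtype=float)
    M = config.repeats
    log = [f"problem={config.problem} coupling={config.coupling} "
           f"M={M} seed={config.seed}"]

    if config.coupling == "pde-compartment":
        masses, dens = _run_pc_repeats(config, times)
    elif config.coupling == "compartment-brownian":
        masses, dens = _run_cb_repeats(config, times, log)
    elif config.coupling == "pure-pde":
        masses, dens = _run_pure_pde(config, times)
        M = 1
    elif config.coupling == "pure-compartment":
        gt = run_ground_truth("compartment", config, M, config.seed)
        masses = gt["region_masses"][None]                        # (1, T, 3)
        dens = {"compartment": (gt["centers"], gt["mean_counts"])}
    else:  # pure-brownian
        gt = run_ground_truth("brownian", config, M, config.seed)
        masses = gt["region_masses"][None]
        dens = {"brownian": (gt["centers"], gt["mean_counts"])}

    mean = masses.mean(axis=0)           # (T, 3)
    if masses.shape[0] > 1:
        stderr = masses.std(axis=0, ddof=1) / np.sqrt(masses.shape[0])
    else:
        stderr = np.zeros_like(mean)

    ref, ref_kind, m_ref = _reference_masses(config, times, config.seed)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = (mean.T - ref) / ref
        se = stderr.T / np.where(ref == 0, np.nan, np.abs(ref))
    report = diagnostics.RMEReport(times=times, regions=_region_labels(config.coupling),
                                   values=vals, reference=ref_kind, M=M,
                                   M_ref=m_ref, stderr=se)
    result = ExperimentResult(config=config, times=times,
                              region_masses=mean, region_stderr=stderr,
                              rme=report, density=dens, log=log)
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _run_pc_repeats(config: RunConfig, times):
    geom = make_geometry(config)
    mesh = build_mesh(geom, config.dx, config.h, "pde-compartment")
    reactions = make_reactions(config, side="stochastic")
    rterm = _pde_reaction_term(config)
    J_a = -config.D * config.J if config.problem == "morphogen" else 0.0
    M = config.repeats
    masses = np.zeros((M, len(times), 3))
    sum_q = None
    sum_C = None
    for r in range(M):
        rng = np.random.default_rng(config.seed + r)
        ic = make_initial_condition(config, rng)
        state = make_pc_state(geom, mesh, config.dt_p, q0=ic["q0"],
                              J_a=J_a, reaction_term=rterm)
        state.comp.C[mesh.n_2:] = ic["counts"]
        out = run_pc(state, reactions, times, rng)
        masses[r] = out["region_masses"]
        if sum_q is None:
            sum_q = out["pde_q"].copy()
            sum_C = out["comp_C"].copy()
        else:
            sum_q += out["pde_q"]
            sum_C += out["comp_C"]
    x_pde = geom.a + (np.arange(mesh.n_p + mesh.n_1) + 0.5) * mesh.dx
    c_comp = geom.I1 + (np.arange(mesh.n_2 + mesh.n_c) + 0.5) * mesh.h
    dens = {"pde": (x_pde, sum_q / M), "compartment": (c_comp, sum_C / M)}
    return masses, dens


def _run_cb_repeats(config: RunConfig, times, log):
    geom = make_geometry(config)
    mesh = build_mesh(geom, config.dx, config.h, "compartment-brownian")
    reactions = make_reactions(config, side="left-boundary")
    M = config.repeats
    masses = np.zeros((M, len(times), 3))
    sum_C = None
    sum_h = None
    reflections = 0
    for r in range(M):
        rng = np.random.default_rng(config.seed + r)
        ic = make_initial_condition(config, rng)
        out = run_cb(geom, mesh, config.dt_b, ic["counts"], ic["positions"],
                     reactions, times, seed=int(rng.integers(2**31 - 1)))
        masses[r] = out["region_masses"]
        reflections += out["reflections"]
        if sum_C is None:
            sum_C = out["comp_C"].copy()
            sum_h = out["brow_hist"].copy()
        else:
            sum_C += out["comp_C"]
            sum_h += out["brow_hist"]
    log.append(f"interface reflections across all repeats: {reflections}")
    c_comp = geom.a + (np.arange(mesh.n_c + mesh.n_2) + 0.5) * mesh.h
    c_brow = geom.I1 + (np.arange(sum_h.shape[1]) + 0.5) * mesh.h
    dens = {"compartment": (c_comp, sum_C / M), "brownian": (c_brow, sum_h / M)}
    return masses, dens


def _run_pure_pde(config: RunConfig, times):
    geom = make_geometry(config)
    rng = np.random.default_rng(config.seed)
    ic = make_initial_condition(config, rng)
    J_a = -config.D * config.J if config.problem == "morphogen" else 0.0
    field = make_pde_field(geom, config.dx, span=(geom.a, geom.b),
                           diffusivity="full", q0=ic["q0"], J_a=J_a)
    rterm = _pde_reaction_term(config)
    dt = config.dt_p
    steps = np.round(times / dt).astype(int)
    out_q = np.zeros((len(times), field.n))
    masses = np.zeros((1, len(times), 3))
    done = 0
    for k, target in enumerate(steps):
        while done < target:
            pde_step(field, dt, reaction_term=rterm)
            done += 1
        out_q[k] = field.q
        for r, (lo, hi) in enumerate(_regions(config)):
            masses[0, k, r] = pde_mass(field, lo, hi)
    x = geom.a + (np.arange(field.n) + 0.5) * config.dx
    return masses, {"pde": (x, out_q)}


def run_ground_truth(engine: str, config: RunConfig, M: int, seed: int) -> dict:
    """Ensemble-averaged single-scale simulation on the full domain.

    Returns times, mean per-compartment (or per-bin) counts with the
    bin centres, mean region masses and their Monte-Carlo standard
    errors.
    """
    geom = make_geometry(config)
    times = np.asarray(config.output_times, dtype=float)
    regions = _regions(config)
    if engine == "compartment":
        n = int(round((geom.b - geom.a) / config.h))
        comp = make_compartment_field(geom, config.h, span=(geom.a, geom.b),
                                      diffusivity="full")
        reactions = make_reactions(config, side="left-boundary")
        counts_sum = np.zeros((len(times), n))
        rmass = np.zeros((M, len(times), 3))
        centers = geom.a + (np.arange(n) + 0.5) * config.h
        reg_idx = [np.flatnonzero((centers >= lo) & (centers < hi))
                   for lo, hi in regions]
        for r in range(M):
            rng = np.random.default_rng(seed + r)
            ic = make_initial_condition(
                dataclasses.replace(config, coupling="pure-compartment"), rng)
            out = _kernels.compartment_run(
                np.asarray(ic["counts"], dtype=float),
                comp.rate_left, comp.rate_right, comp.volume,
                reactions.kappa2, reactions.mu, reactions.kappa1,
                reactions.influx_left, times,
                int(rng.integers(2**31 - 1)))
            counts_sum += out
            for j, idx in enumerate(reg_idx):
                rmass[r, :, j] = out[:, idx].sum(axis=1)
    elif engine == "brownian":
        reactions = make_reactions(config, side="stochastic")
        if config.problem == "morphogen":
            raise ConfigurationError(
                "pure-Brownian ground truth has no boundary-influx channel")
        n = int(round((geom.b - geom.a) / config.h))
        counts_sum = np.zeros((len(times), n))
        rmass = np.zeros((M, len(times), 3))
        centers = geom.a + (np.arange(n) + 0.5) * config.h
        reg_idx = [np.flatnonzero((centers >= lo) & (centers < hi))
                   for lo, hi in regions]
        n_windows = int(round(times[-1] / config.dt_b))
        out_steps = np.round(times / config.dt_b).astype(np.int64)
        for r in range(M):
            rng = np.random.default_rng(seed + r)
            ic = make_initial_condition(
                dataclasses.replace(config, coupling="pure-brownian"), rng)
            pos0 = ic["positions"]
            cap = max(4 * (pos0.shape[0] + 1), 2000)
            hist, n_arr, status = _kernels.brownian_run(
                pos0, pos0.shape[0], geom.a, geom.b, geom.Ly, geom.Lz,
                config.D, geom.dimension, config.dt_b,
                reactions.mu, reactions.kappa2, reactions.kappa1,
                reactions.rho, reactions.p_lambda,
                config.h, out_steps, n_windows, cap,
                int(rng.integers(2**31 - 1)))
            if status != _kernels.OK:
                raise RuntimeError("Brownian ground-truth run overflowed capacity")
            counts_sum += hist
            for j, idx in enumerate(reg_idx):
                rmass[r, :, j] = hist[:, idx].sum(axis=1)
    else:
        raise ConfigurationError(f"unknown ground-truth engine {engine!r}")

    mean_counts = counts_sum / M
    if M > 1:
        stderr = rmass.std(axis=0, ddof=1) / np.sqrt(M)
    else:
        stderr = np.zeros((len(times), 3))
    return {
        "times": times,
        "centers": centers,
        "mean_counts": mean_counts,
        "region_masses": rmass.mean(axis=0),
        "region_stderr": stderr,
        "M": M,
    }


def mean_field_pde_profile(config: RunConfig, times) -> dict:
    """Deterministic mean-field PDE solve of the configured problem on
    the full domain (voxel concentrations at the requested times)."""
    cfg = dataclasses.replace(config, coupling="pure-pde",
                              output_times=list(times))
    masses, dens = _run_pure_pde(cfg, np.asarray(times, dtype=float))
    x, q = dens["pde"]
    return {"x": x, "q": q, "region_masses": masses[0]}


def _write_outputs(result: ExperimentResult, out_dir: Path):
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    (out_dir / "config_resolved.json").write_text(cfg.to_json())
    result.rme_frame().to_csv(out_dir / "rme.csv", index=False)
    for k, t in enumerate(result.times):
        rows = []
        for component, (x, vals) in result.density.items():
            for xi, vi in zip(x, vals[k]):
                rows.append({"time": t, "component": component,
                             "x": xi, "value": vi})
        pd.DataFrame(rows).to_csv(out_dir / f"density_{t:g}.csv", index=False)
    (out_dir / "run_log.txt").write_text("\n".join(result.log) + "\n")
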