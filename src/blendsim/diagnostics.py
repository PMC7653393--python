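"""Reference solutions and relative-mass-error (RME) metrics.

The hybrid runs are validated region by region: for the pure-diffusion
and morphogen problems against the analytic solution ``u(x, t)`` of the
mean-field PDE (cosine eigenfunction series on the zero-flux unit
interval), and for the bimolecular problem against the ensemble mean of
the finest-scale model simulated on the whole domain.  The RME in a
region is ``(hybrid mass - reference mass) / reference mass``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import quad

__all__ = [
    "RMEReport",
    "rme",
    "analytic_diffusion_series",
    "diffusion_region_mass",
    "morphogen_steady",
    "morphogen_analytic",
    "morphogen_region_mass",
    "ensemble_ground_truth",
]

_TOL = 1e-12
_NMAX = 200_000


@dataclass
class RMEReport:
    """Region-wise relative-mass-error time series.

    ``regions`` are the three subdomains of the active coupler (pure
    coarse, blending, pure fine); ``values[r, k]`` is the RME of region
    ``r`` at ``times[k]``.  ``reference`` names the reference kind
    (analytic PDE or ensemble ground truth of size ``M_ref``).
    """

    times: np.ndarray
    regions: list
    values: np.ndarray
    reference: str
    M: int
    M_ref: int = 0
    stderr: Optional[np.ndarray] = None

    def max_abs(self) -> float:
        return float(np.nanmax(np.abs(self.values)))


def rme(hybrid_region_mass: float, reference_region_mass: float) -> float:
    """Relative mass error ``(hybrid - reference) / reference``."""
    if reference_region_mass == 0:
        return np.nan
    return (hybrid_region_mass - reference_region_mass) / reference_region_mass


# ---------------------------------------------------------------------------
# Pure diffusion on [0, 1] with zero-flux boundaries
# ---------------------------------------------------------------------------

def _step_coefficients(N: float, L: float, n: np.ndarray) -> np.ndarray:
    # cosine coefficients of a step of total mass N supported on [0, L]
    return 2.0 * N * np.sin(n * np.pi * L) / (n * np.pi * L)


def _series_nmax(D: float, t: float, amp: float) -> int:
    n = 8
    while n < _NMAX:
        if amp / n * np.exp(-D * (n * np.pi) ** 2 * t) < _TOL:
            return n
        n *= 2
    return _NMAX


def analytic_diffusion_series(ic_spec: str, D: float, t: float, x,
                              N: float = 1000.0, step_hi: float = 1.0 / 3.0):
    """Solution of ``c_t = D c_xx`` on [0, 1] with zero-flux boundaries.

    ``ic_spec``: ``"uniform"`` (mass N spread over [0, 1]) or ``"step"``
    (mass N uniform on ``[0, step_hi]``).  Evaluated as the cosine
    eigenfunction series ``u = N + sum_n A_n cos(n pi x) exp(-D n^2
    pi^2 t)`` truncated once the next term is below 1e-12.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if ic_spec == "uniform":
        out = np.full_like(x, N)
    elif ic_spec != "step":
        raise ValueError(f"unknown ic_spec {ic_spec!r}")
    elif t <= 0:
        out = np.where(x <= step_hi, N / step_hi, 0.0)
    else:
        nmax = _series_nmax(D, t, 2.0 * N / (np.pi * step_hi))
        n = np.arange(1, nmax + 1)
        An = _step_coefficients(N, step_hi, n) * np.exp(-D * (n * np.pi) ** 2 * t)
        out = N + np.cos(np.pi * np.outer(x, n)) @ An
    return float(out[0]) if scalar else out


def diffusion_region_mass(ic_spec: str, D: float, t: float,
                          x_lo: float, x_hi: float,
                          N: float = 1000.0, step_hi: float = 1.0 / 3.0) -> float:
    """Integral of the series solution over ``[x_lo, x_hi]`` (closed form)."""
    if ic_spec == "uniform":
        return N * (x_hi - x_lo)
    if t <= 0:
        return N / step_hi * max(0.0, min(x_hi, step_hi) - min(x_lo, step_hi))
    nmax = _series_nmax(D, t, 2.0 * N / (np.pi * step_hi))
    n = np.arange(1, nmax + 1)
    An = _step_coefficients(N, step_hi, n) * np.exp(-D * (n * np.pi) ** 2 * t)
    integ = (np.sin(n * np.pi * x_hi) - np.sin(n * np.pi * x_lo)) / (n * np.pi)
    return N * (x_hi - x_lo) + float(An @ integ)


# ---------------------------------------------------------------------------
# Morphogen gradient: c_t = D c_xx - mu c on [0, 1],
# c_x(0) = -J, c_x(1) = 0, c(x, 0) = D J / mu
# ---------------------------------------------------------------------------

def morphogen_steady(J: float, D: float, mu: float, x):
    """Steady state ``J sqrt(D/mu) cosh(sqrt(mu/D)(1-x)) / sinh(sqrt(mu/D))``;
    its spatial integral over [0, 1] is exactly ``D J / mu``."""
    x = np.asarray(x, dtype=float)
    k = np.sqrt(mu / D)
    return J * np.sqrt(D / mu) * np.cosh(k * (1.0 - x)) / np.sinh(k)

def morphogen_analytic(J: float, D: float, mu: float, t: float, x):
    """Transient solution: steady state plus a cosine series in the
    deviation, each mode decaying at rate ``mu + D n^2 pi^2``.

    The deviation ``v = c - c_steady`` has zero-flux data and zero mean
    (the initial mass D J / mu equals the steady-state mass), and its
    cosine coefficients are ``B_n = -2 J D / (mu + D n^2 pi^2)``.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if t <= 0:
        out = np.full_like(x, D * J / mu)
    else:
        s = morphogen_steady(J, D, mu, x)
        nmax = _series_nmax(D, t, 2.0 * J / (np.pi ** 2))
        n = np.arange(1, nmax + 1)
        lam = mu + D * (n * np.pi) ** 2
        Bn = -2.0 * J * D / lam * np.exp(-lam * t)
        out = s + np.cos(np.pi * np.outer(x, n)) @ Bn
    return float(out[0]) if scalar else out


def morphogen_region_mass(J: float, D: float, mu: float, t: float,
                          x_lo: float, x_hi: float) -> float:
    """Integral of the morphogen solution over ``[x_lo, x_hi]``."""
    k = np.sqrt(mu / D)
    steady = J * np.sqrt(D / mu) / k * (np.sinh(k * (1.0 - x_lo))
                                        - np.sinh(k * (1.0 - x_hi))) / np.sinh(k)
    if t <= 0:
        return D * J / mu * (x_hi - x_lo)
    nmax = _series_nmax(D, t, 2.0 * J / (np.pi ** 2))
    n = np.arange(1, nmax + 1)
    lam = mu + D * (n * np.pi) ** 2
    Bn = -2.0 * J * D / lam * np.exp(-lam * t)
    integ = (np.sin(n * np.pi * x_hi) - np.sin(n * np.pi * x_lo)) / (n * np.pi)
    return float(steady + Bn @ integ)


# ---------------------------------------------------------------------------
# Ensemble ground truth (finest-scale model on the full domain)
# ---------------------------------------------------------------------------

def ensemble_ground_truth(engine: str, config, M: int, seed: int):
    """Average region-mass time series of a single-scale model.

    ``engine`` is ``"compartment"`` or ``"brownian"``; the model runs on
    the whole domain with the full diffusion coefficient, ``M`` seeded
    repeats.  Returns a dict with ``times``, per-region mean masses and
    Monte-Carlo standard errors, and the mean per-compartment (or
    per-bin) counts used for density comparisons.
    """
    from . import experiments  # deferred: experiments imports this module
    return experiments.run_ground_truth(engine, config, M, seed)


def verify_series_against_solver(u_series, solver_profile, rel_tol: float = 1e-6):
    """Max relative L-inf discrepancy between the series and an
    independent fine-grid solve (used by the oracle cross-check tests)."""
    scale = np.max(np.abs(u_series))
    return float(np.max(np.abs(u_series - solver_profile)) / scale)
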