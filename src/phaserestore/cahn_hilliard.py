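"""Boundary-controlled explicit Cahn-Hilliard relaxation (the reconstruction step).

The conservative flow

    phi' = phi + dt * div_h( G_edge * grad_h mu ),
    mu   = G_cell * ( phi^3 - phi - eps^2 * Lap_h phi ),

moves mass only through edges whose control value is 1, so the discrete
total ``sum(phi) h^2`` is conserved to floating-point roundoff at every
step.  Obstacle cells have all incident edge controls equal to 0 and are
therefore never updated: the Dirichlet condition phi = 1 on the damaged
feature is realized by pinning the initial values and letting the flux form
preserve them, never by post-step resetting (which would create or destroy
mass).  Edges on the outer rectangle carry zero control, realizing the
zero-Neumann condition for the chemical potential.
"""

from __future__ import annotations

import time

import numpy as np

from .allen_cahn import SteadyStateReport, _check_finite, diff_norm, laplacian
from .grid import BoundaryControl, Grid
from .initializers import SolverParams

__all__ = ["chemical_potential", "ch_step", "run_reconstruction", "total_mass"]


def total_mass(phi: np.ndarray, grid: Grid) -> float:
    """Discrete mass ``sum(phi) * h^2`` (the conserved quantity)."""
    return float(np.sum(phi) * grid.cell_area())


def chemical_potential(
    phi: np.ndarray, bc: BoundaryControl, epsilon: float, grid: Grid
) -> np.ndarray:
    """``mu = G * (phi^3 - phi - eps^2 Lap_h phi)``; zero wherever G = 0."""
    mu = phi ** 3 - phi - epsilon * epsilon * laplacian(phi, grid.h)
    return bc.g_cell * mu


def _flux_divergence(
    mu: np.ndarray, bc: BoundaryControl, h: float
) -> np.ndarray:
    """Edge-weighted divergence of G grad mu.

    Each interior edge flux enters its two cells with opposite signs, so the
    divergence sums to zero exactly; outer edges (control 0) never appear.
    """
    div = np.zeros_like(mu)
    fx = bc.g_edge_x[:, 1:-1] * (mu[:, 1:] - mu[:, :-1])
    div[:, :-1] += fx
    div[:, 1:] -= fx
    fy = bc.g_edge_y[1:-1, :] * (mu[1:, :] - mu[:-1, :])
    div[:-1, :] += fy
    div[1:, :] -= fy
    return div / (h * h)


def ch_step(
    phi: np.ndarray, bc: BoundaryControl, params: SolverParams, grid: Grid
) -> np.ndarray:
    """One explicit Cahn-Hilliard step; returns a new field.

    Mass-exact by construction: the update is a telescoping sum of edge
    fluxes.
    """
    mu = chemical_potential(phi, bc, params.epsilon, grid)
    out = phi + params.dt * _flux_divergence(mu, bc, grid.h)
    _check_finite(out, 1)
    return out


def run_reconstruction(
    phi0: np.ndarray,
    bc: BoundaryControl,
    params: SolverParams,
    grid: Grid,
    log=None,
    log_stride: int = 0,
) -> tuple[np.ndarray, SteadyStateReport]:
    """Iterate :func:`ch_step` to the steady-state tolerance.

    Same convergence criterion as the capture step; obstacle cells keep
    their pinned value because no controlled edge touches them.
    """
    from . import _kernels

    t0 = time.perf_counter()
    phi = np.array(phi0, dtype=float)
    phi[bc.dirichlet] = 1.0
    h = grid.h
    eps = params.epsilon
    dt = params.dt

    if _kernels.HAVE_NUMBA:
        import math

        chunk = log_stride if (log is not None and log_stride) else params.max_steps
        if params.relative:
            chunk = min(chunk, 2000)
        steps = 0
        norm2 = np.inf
        while steps < params.max_steps:
            tol_eff = params.tol
            if params.relative:
                tol_eff *= max(float(np.sqrt(np.sum(phi * phi)) * h), 1e-30)
            tol2 = tol_eff * tol_eff
            n_chunk = min(chunk, params.max_steps - steps)
            took, norm2 = _kernels.ch_run_kernel(
                phi,
                bc.g_cell,
                bc.g_edge_x,
                bc.g_edge_y,
                eps * eps,
                dt,
                h * h,
                tol2,
                n_chunk,
                params.check_stride,
            )
            steps += took
            _check_finite(phi, steps)
            norm = math.sqrt(norm2)
            if log is not None and log_stride:
                log(
                    f"[reconstruct] step={steps} diff_norm={norm:.3e} "
                    f"mass={total_mass(phi, grid):.9f}"
                )
            if norm2 < tol2:
                return phi, SteadyStateReport(True, steps, norm, time.perf_counter() - t0)
        return phi, SteadyStateReport(False, steps, norm, time.perf_counter() - t0)

    norm = np.inf
    steps = 0
    while steps < params.max_steps:
        for _ in range(params.check_stride - 1):
            mu = chemical_potential(phi, bc, eps, grid)
            phi = phi + dt * _flux_divergence(mu, bc, h)
            steps += 1
        prev = phi
        mu = chemical_potential(phi, bc, eps, grid)
        phi = phi + dt * _flux_divergence(mu, bc, h)
        steps += 1
        _check_finite(phi, steps)
        norm = diff_norm(phi, prev, h)
        if log is not None and log_stride and steps % log_stride < params.check_stride:
            log(
                f"[reconstruct] step={steps} diff_norm={norm:.3e} "
                f"mass={total_mass(phi, grid):.9f}"
            )
        thr = params.tol
        if params.relative:
            thr *= max(float(np.sqrt(np.sum(phi * phi)) * h), 1e-30)
        if norm < thr:
            return phi, SteadyStateReport(True, steps, norm, time.perf_counter() - t0)
    return phi, SteadyStateReport(False, steps, norm, time.perf_counter() - t0)
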