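"""Boundary-controlled explicit Allen-Cahn relaxation (the capture step).

The scheme is

    phi' = phi + dt * G * ( -(phi^3 - phi)/eps^2 + Lap_h phi ),

with the 5-point Laplacian, homogeneous-Neumann outer boundary via ghost-cell
reflection, updates confined to the computational domain by the cell control
values ``G``, and the obstacle cells pinned at phi = 1 (Dirichlet).  The
sharp-interface limit is motion by mean curvature, so a circle of radius R
shrinks as ``R(t)^2 = R0^2 - 2 t``; with the damaged feature pinned, the
zero contour relaxes onto the obstacle and closes the gap with its convex
hull.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grid import BoundaryControl, Grid
from .initializers import SolverParams

__all__ = ["SteadyStateReport", "ac_step", "ac_evolve", "run_capture", "BlowUpError"]


class BlowUpError(RuntimeError):
    """Raised when an explicit step produces non-finite values."""


@dataclass(frozen=True)
class SteadyStateReport:
    """Outcome of an explicit relaxation run."""

    converged: bool
    steps: int
    final_norm: float
    wall_time: float = 0.0


def laplacian(phi: np.ndarray, h: float) -> np.ndarray:
    """5-point Laplacian with ghost-cell reflection on the outer rectangle."""
    p = np.pad(phi, 1, mode="edge")
    return (
        p[1:-1, 2:] + p[1:-1, :-2] + p[2:, 1:-1] + p[:-2, 1:-1] - 4.0 * phi
    ) / (h * h)


def diff_norm(a: np.ndarray, b: np.ndarray, h: float) -> float:
    """h-weighted discrete L2 norm of a - b: sqrt(sum (a-b)^2 * h^2)."""
    d = a - b
    return float(np.sqrt(np.sum(d * d)) * h)


def _check_finite(phi: np.ndarray, step: int) -> None:
    if not np.all(np.isfinite(phi)):
        j, i = np.argwhere(~np.isfinite(phi))[0]
        raise BlowUpError(
            f"blow-up at step {step}: non-finite value at cell (i={i}, j={j}); "
            "reduce dt below the explicit stability bound"
        )


def ac_step(
    phi: np.ndarray, bc: BoundaryControl, params: SolverParams, grid: Grid
) -> np.ndarray:
    """One explicit Allen-Cahn step; returns a new field.

    Cells with ``G = 0`` are unchanged; Dirichlet (obstacle) cells are
    re-pinned to 1.
    """
    eps2 = params.epsilon * params.epsilon
    rhs = -(phi ** 3 - phi) / eps2 + laplacian(phi, grid.h)
    out = phi + params.dt * bc.g_cell * rhs
    out[bc.dirichlet] = 1.0
    _check_finite(out, 1)
    return out


def _pin(phi: np.ndarray, bc: BoundaryControl) -> None:
    phi[bc.dirichlet] = 1.0


def ac_evolve(
    phi0: np.ndarray,
    bc: BoundaryControl,
    params: SolverParams,
    grid: Grid,
    n_steps: int,
    callback=None,
    callback_stride: int = 1,
) -> np.ndarray:
    """Run exactly ``n_steps`` Allen-Cahn steps (no steady-state check).

    ``callback(step, phi)`` is invoked every ``callback_stride`` steps when
    given; used for time-sampled diagnostics such as the shrinking-circle
    benchmark.
    """
    phi = np.array(phi0, dtype=float)
    _pin(phi, bc)
    eps2 = params.epsilon * params.epsilon
    dt = params.dt
    g = bc.g_cell
    for n in range(1, n_steps + 1):
        rhs = -(phi ** 3 - phi) / eps2 + laplacian(phi, grid.h)
        phi = phi + dt * g * rhs
        _pin(phi, bc)
        if n % max(n_steps // 10, 1) == 0 or n == n_steps:
            _check_finite(phi, n)
        if callback is not None and n % callback_stride == 0:
            callback(n, phi)
    return phi


def run_capture(
    phi0: np.ndarray,
    bc: BoundaryControl,
    params: SolverParams,
    grid: Grid,
    log=None,
    log_stride: int = 0,
) -> tuple[np.ndarray, SteadyStateReport]:
    """Iterate :func:`ac_step` to steady state.

    Stops when ``||phi^{n+1} - phi^n||_{2,h} < tol`` (checked every
    ``params.check_stride`` steps) or at ``params.max_steps``; the final
    field is returned either way, with the outcome in the report.  Uses the
    compiled inner loop when available; falls back to repeated numpy steps.
    """
    import time

    from . import _kernels

    t0 = time.perf_counter()
    phi = np.array(phi0, dtype=float)
    _pin(phi, bc)
    eps2 = params.epsilon * params.epsilon
    dt = params.dt
    h = grid.h
    g = bc.g_cell

    if _kernels.HAVE_NUMBA:
        chunk = log_stride if (log is not None and log_stride) else params.max_steps
        if params.relative:
            # re-scale the relative threshold from the current field norm
            # every few thousand steps
            chunk = min(chunk, 2000)
        steps = 0
        norm2 = math.inf
        while steps < params.max_steps:
            tol_eff = params.tol
            if params.relative:
                tol_eff *= max(float(np.sqrt(np.sum(phi * phi)) * h), 1e-30)
            tol2 = tol_eff * tol_eff
            n_chunk = min(chunk, params.max_steps - steps)
            took, norm2 = _kernels.ac_run_kernel(
                phi,
                g,
                bc.dirichlet,
                eps2,
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
                    f"[capture] step={steps} diff_norm={norm:.3e} "
                    f"area={np.sum(phi + 1.0) * 0.5 * h * h:.6f}"
                )
            if norm2 < tol2:
                return phi, SteadyStateReport(True, steps, norm, time.perf_counter() - t0)
        return phi, SteadyStateReport(False, steps, norm, time.perf_counter() - t0)

    norm = math.inf
    steps = 0
    while steps < params.max_steps:
        # advance a stride; the convergence norm compares the last two iterates
        for _ in range(params.check_stride - 1):
            rhs = -(phi ** 3 - phi) / eps2 + laplacian(phi, h)
            phi = phi + dt * g * rhs
            _pin(phi, bc)
            steps += 1
        prev = phi
        rhs = -(phi ** 3 - phi) / eps2 + laplacian(phi, h)
        phi = phi + dt * g * rhs
        _pin(phi, bc)
        steps += 1
        _check_finite(phi, steps)
        norm = diff_norm(phi, prev, h)
        if log is not None and log_stride and steps % log_stride < params.check_stride:
            log(
                f"[capture] step={steps} diff_norm={norm:.3e} "
                f"area={np.sum(phi + 1.0) * 0.5 * h * h:.6f}"
            )
        thr = params.tol
        if params.relative:
            thr *= max(float(np.sqrt(np.sum(phi * phi)) * h), 1e-30)
        if norm < thr:
            return phi, SteadyStateReport(
                True, steps, norm, time.perf_counter() - t0
            )
    return phi, SteadyStateReport(False, steps, norm, time.perf_counter() - t0)
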