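"""Initial conditions for the capture and reconstruction steps.

All interfaces are seeded with the equilibrium tanh profile
``tanh(d / (sqrt(2) * eps))`` of the double-well phase-field model, where
``d`` is the signed distance to the interface (positive inside) and ``eps``
sets the transition-layer width.  The reconstruction step supplements the
captured feature with one or two disks whose total sharp-interface area is
``beta * V0``; the disks are placed a 4-cell standoff away from the captured
interface so the conservative flow merges them into the missing region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grid import Grid

__all__ = [
    "SolverParams",
    "MassBudget",
    "default_epsilon",
    "tanh_circle_field",
    "measure_captured_area",
    "reconstruction_initial",
]

#: steady-state tolerance on the discrete L2 norm of the consecutive difference
DEFAULT_TOL = 0.5e-6


def default_epsilon(h: float, cells: float = 4.0) -> float:
    """Interface-thickness parameter such that the tanh layer spans ``cells`` cells.

    The layer is measured between the -0.9 and +0.9 levels of the profile:
    ``eps = cells * h / (2 * sqrt(2) * atanh(0.9))``.
    """
    return cells * h / (2.0 * math.sqrt(2.0) * math.atanh(0.9))


@dataclass(frozen=True)
class SolverParams:
    """Numerical parameters shared by both relaxation solvers.

    Attributes
    ----------
    epsilon : float
        Interface-thickness coefficient (domain length units).
    dt : float
        Explicit time step.
    tol : float
        Steady-state tolerance on ``||phi^{n+1} - phi^n||_{2,h}``
        (h-weighted discrete L2 norm of the consecutive difference).
    max_steps : int
        Iteration cap; exceeding it returns the last field with
        ``converged = False``.
    check_stride : int
        Evaluate the convergence norm every ``check_stride`` steps.
    relative : bool
        If True the criterion is relative,
        ``||dphi|| < tol * max(||phi||, 1e-30)``; default absolute.
    """

    epsilon: float
    dt: float
    tol: float = DEFAULT_TOL
    max_steps: int = 10_000_000
    check_stride: int = 1
    relative: bool = False

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.dt <= 0 or self.tol <= 0:
            raise ValueError("epsilon, dt and tol must be positive")
        if self.check_stride < 1:
            raise ValueError("check_stride must be >= 1")

    @classmethod
    def for_allen_cahn(
        cls, grid: Grid, epsilon: float | None = None, **kw
    ) -> "SolverParams":
        """Stability-bounded defaults for the explicit Allen-Cahn scheme.

        ``dt = min(h^2/8, eps^2/8)``: h^2/4 is the 2D diffusion CFL limit and
        the 1/eps^2 reaction term bounds the stiffness.
        """
        h = grid.h
        eps = default_epsilon(h) if epsilon is None else epsilon
        dt = kw.pop("dt", min(h * h / 8.0, eps * eps / 8.0))
        return cls(epsilon=eps, dt=dt, **kw)

    @classmethod
    def for_cahn_hilliard(
        cls, grid: Grid, epsilon: float | None = None, **kw
    ) -> "SolverParams":
        """Stability-bounded defaults for the explicit Cahn-Hilliard scheme.

        The G-weighted operator is effectively ``eps^2`` times a biharmonic
        whose explicit Euler limit is ``h^4/(32 eps^2)``; the nonlinear term
        (``3 phi^2 - 1`` up to 2 in the bulk) tightens it further, so the
        default takes a factor-2 safety margin:
        ``dt = min(h^4/(64 eps^2), h^2/8)``.
        """
        h = grid.h
        eps = default_epsilon(h) if epsilon is None else epsilon
        dt = kw.pop("dt", min(h ** 4 / (64.0 * eps * eps), h * h / 8.0))
        return cls(epsilon=eps, dt=dt, **kw)


@dataclass(frozen=True)
class MassBudget:
    """Supplementary-mass bookkeeping for the reconstruction step.

    ``v0`` is the area of the captured feature, ``beta`` the supplementation
    parameter; the target total area is ``(1 + beta) * v0`` and the added
    area ``beta * v0`` is distributed over ``n_disks`` equal disks of radius
    ``r = sqrt(beta * v0 / (n_disks * pi))``.
    """

    v0: float
    beta: float
    n_disks: int = 1

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.n_disks not in (1, 2):
            raise ValueError("n_disks must be 1 or 2")
        if self.v0 < 0:
            raise ValueError("v0 must be non-negative")

    @property
    def target_area(self) -> float:
        return (1.0 + self.beta) * self.v0

    @property
    def disk_radius(self) -> float:
        if self.beta == 0:
            return 0.0
        return math.sqrt(self.beta * self.v0 / (self.n_disks * math.pi))


#: equilibrium layer-width factor of the quartic double well; pass
#: ``profile_scale=2.0`` for the d/(2 eps) convention instead
EQUILIBRIUM_PROFILE_SCALE = math.sqrt(2.0)


def tanh_circle_field(
    center: tuple[float, float],
    radius: float,
    epsilon: float,
    grid: Grid,
    profile_scale: float = EQUILIBRIUM_PROFILE_SCALE,
) -> np.ndarray:
    """Equilibrium tanh profile of a circle: positive inside, zero on it.

    Returns ``tanh((radius - |x - center|) / (profile_scale * epsilon))``
    sampled at the cell centers; the default scale sqrt(2) is the
    equilibrium profile of the potential behind mu = phi^3 - phi - eps^2
    Lap phi.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    X, Y = grid.cell_centers()
    d = radius - np.hypot(X - center[0], Y - center[1])
    return np.tanh(d / (profile_scale * epsilon))


def measure_captured_area(field: np.ndarray, grid: Grid) -> float:
    """Area of the positive phase, ``sum((phi + 1)/2) * h^2``.

    Linear in the field and exact on constant fields; for an equilibrium
    tanh interface the symmetric profile makes this the enclosed area up to
    O(h) quadrature error.
    """
    return float(np.sum(np.asarray(field) + 1.0) * 0.5 * grid.cell_area())


def _disk_centers(
    recipe: str, r: float, grid: Grid, ring_radius: float = 0.2
) -> list[tuple[float, float]]:
    """Supplementary-disk placement with the 4-cell standoff.

    half_circle: one disk just above the mid-height chord, center
    ``(Lx/2, Ly/2 + r + 4h)``.  parentheses: two disks just beyond the top
    and bottom of the ring (inner radius ``ring_radius``), centers
    ``(Lx/2, Ly/2 +- (ring_radius + r/2 + 4h))``.
    """
    h = grid.h
    cx = grid.lx / 2.0
    cy = grid.ly / 2.0
    if recipe == "half_circle":
        return [(cx, cy + r + 4.0 * h)]
    if recipe == "parentheses":
        off = ring_radius + 0.5 * r + 4.0 * h
        return [(cx, cy + off), (cx, cy - off)]
    raise ValueError(f"unknown supplement recipe {recipe!r}")


def reconstruction_initial(
    psi: np.ndarray,
    budget: MassBudget,
    epsilon: float,
    grid: Grid,
    recipe: str = "half_circle",
    centers: list[tuple[float, float]] | None = None,
    ring_radius: float = 0.2,
    profile_scale: float = EQUILIBRIUM_PROFILE_SCALE,
) -> np.ndarray:
    """Supplemented initial condition for the conservative reconstruction step.

    Adds ``n_disks`` tanh disks of total sharp-interface area ``beta * v0``
    to the captured steady state ``psi``:

        ``phi0 = clamp(psi + sum_k (1 + tanh(d_k / (sqrt(2) eps))), -1, 1)``

    which leaves ``psi`` untouched away from the disks and raises the phase
    to +1 inside them.  ``beta = 0`` returns ``psi`` unchanged.  Disk centers
    default to the recipe placement of :func:`_disk_centers`; pass
    ``centers`` to override.  A disk extending outside the domain is
    rejected.
    """
    psi = np.asarray(psi, dtype=float)
    if psi.shape != grid.shape:
        raise ValueError("psi shape does not match grid")
    if budget.beta == 0:
        return psi.copy()
    r = budget.disk_radius
    if centers is None:
        centers = _disk_centers(recipe, r, grid, ring_radius=ring_radius)
    if len(centers) != budget.n_disks:
        raise ValueError(
            f"{budget.n_disks} disks budgeted but {len(centers)} centers given"
        )
    for k, (dx, dy) in enumerate(centers):
        if dx - r < 0 or dx + r > grid.lx or dy - r < 0 or dy + r > grid.ly:
            raise ValueError(
                f"supplementary disk {k} at ({dx:.4g}, {dy:.4g}) with radius "
                f"{r:.4g} extends outside the domain"
            )
    out = psi.copy()
    X, Y = grid.cell_centers()
    s2e = profile_scale * epsilon
    for dx, dy in centers:
        d = r - np.hypot(X - dx, Y - dy)
        out += 1.0 + np.tanh(d / s2e)
    np.clip(out, -1.0, 1.0, out=out)
    return out
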