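"""Computational lattice, obstacle rasterization, and the boundary control function.

The solvers operate on a uniform cell-centered grid over the rectangle
``(0, Lx) x (0, Ly)``.  Fields are stored as ``(ny, nx)`` arrays in image
convention: ``field[j, i]`` is the value at the cell center
``x = (i + 0.5) h``, ``y = (j + 0.5) h`` (0-based; row 0 is the *bottom* of the
domain).  CSV/PNG I/O flips rows so that the first file row is the top of the
domain; see :mod:`phaserestore.io`.

The boundary control function ``G`` is a binary indicator that confines
updates and fluxes to the computational subdomain: ``G = 1`` on computational
cells, ``G = 0`` on obstacle (pinned, Dirichlet) cells.  Its extension to cell
edges is the product of the two adjacent cell values, so an edge carries flux
iff both of its cells are computational.  Edges on the outer rectangle carry
``G = 0``, which realizes the zero-flux outer boundary for conservative
dynamics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Grid",
    "ObstacleSpec",
    "BoundaryControl",
    "rasterize_obstacle",
    "build_boundary_control",
]

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class Grid:
    """Uniform cell-centered lattice with square cells.

    Parameters
    ----------
    nx, ny : int
        Number of cells along x and y.
    lx, ly : float
        Domain edge lengths.  ``lx / nx`` must equal ``ly / ny`` (square
        cells); rectangular cells are rejected.
    """

    nx: int
    ny: int
    lx: float = 1.0
    ly: float = 1.0

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have at least one cell per axis")
        hx = self.lx / self.nx
        hy = self.ly / self.ny
        if not math.isclose(hx, hy, rel_tol=1e-12):
            raise ValueError(
                f"square cells required: lx/nx = {hx:g} but ly/ny = {hy:g}"
            )

    @property
    def h(self) -> float:
        """Grid spacing (common to both axes)."""
        return self.lx / self.nx

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape ``(ny, nx)`` of fields on this grid."""
        return (self.ny, self.nx)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(X, Y)`` arrays of cell-center coordinates, shape (ny, nx)."""
        h = self.h
        x = (np.arange(self.nx) + 0.5) * h
        y = (np.arange(self.ny) + 0.5) * h
        return np.meshgrid(x, y)

    def cell_area(self) -> float:
        return self.h * self.h

    @classmethod
    def unit_square(cls, n: int) -> "Grid":
        """The 1 x 1 domain with ``n`` cells per side used throughout the examples."""
        return cls(nx=n, ny=n, lx=1.0, ly=1.0)


@dataclass(frozen=True)
class ObstacleSpec:
    """Geometric description of the known (undamaged) narrow-band feature.

    The feature is an annular band ``r_inner <= |x - center| <= r_outer``
    restricted to a list of angular ``arcs`` given as ``[theta_start,
    theta_end)`` pairs in radians (measured counter-clockwise from the
    positive x axis; intervals may wrap through 2*pi).
    """

    kind: str
    center: tuple[float, float] = (0.5, 0.5)
    r_inner: float = 0.2
    r_outer: float = 0.24
    arcs: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kind != "custom_mask":
            if not (0.0 < self.r_inner < self.r_outer):
                raise ValueError("require 0 < r_inner < r_outer")

    @classmethod
    def half_annulus(
        cls,
        center: tuple[float, float] = (0.5, 0.5),
        r_inner: float = 0.2,
        r_outer: float = 0.24,
    ) -> "ObstacleSpec":
        """Lower half of the annulus (angles in [pi, 2*pi))."""
        return cls("half_annulus", center, r_inner, r_outer, ((math.pi, _TWO_PI),))

    @classmethod
    def parentheses(
        cls,
        center: tuple[float, float] = (0.5, 0.5),
        r_inner: float = 0.2,
        r_outer: float = 0.24,
        half_angle: float = math.pi / 5.0,
    ) -> "ObstacleSpec":
        """Two opposing arcs "( )" of the annulus, each spanning 2*half_angle.

        Arcs are centred on theta = 0 (right parenthesis) and theta = pi
        (left parenthesis), leaving wide gaps at the top and bottom of the
        ring; the capture step closes them with chords into a tablet shape.
        """
        a = float(half_angle)
        return cls(
            "parentheses",
            center,
            r_inner,
            r_outer,
            ((_TWO_PI - a, _TWO_PI + a), (math.pi - a, math.pi + a)),
        )

    @classmethod
    def full_annulus(
        cls,
        center: tuple[float, float] = (0.5, 0.5),
        r_inner: float = 0.2,
        r_outer: float = 0.24,
    ) -> "ObstacleSpec":
        return cls("full_annulus", center, r_inner, r_outer, ((0.0, _TWO_PI),))


@dataclass(frozen=True)
class BoundaryControl:
    """Discrete boundary control function on cells and cell edges.

    Attributes
    ----------
    g_cell : (ny, nx) int8 array
        1 on computational cells, 0 on obstacle cells.
    g_edge_x : (ny, nx+1) int8 array
        Control values on vertical edges (between x-neighbours); column 0 and
        column nx are the outer-rectangle edges and are always 0.
    g_edge_y : (ny+1, nx) int8 array
        Control values on horizontal edges; rows 0 and ny are always 0.
    dirichlet : (ny, nx) bool array
        Cells where the order parameter is pinned to 1 (the obstacle set).
    """

    g_cell: np.ndarray
    g_edge_x: np.ndarray
    g_edge_y: np.ndarray
    dirichlet: np.ndarray


def _wrap_angle(theta: np.ndarray) -> np.ndarray:
    return np.mod(theta, _TWO_PI)


def rasterize_obstacle(spec: ObstacleSpec, grid: Grid) -> np.ndarray:
    """Rasterize an annular-arc obstacle onto the grid.

    A cell belongs to the mask iff its *center* lies inside the annular band
    and its polar angle falls in one of the listed arcs (center-in
    classification; no sub-cell area weighting).

    Returns a ``(ny, nx)`` boolean array.  Raises ``ValueError`` if the
    obstacle's bounding disk does not intersect the domain rectangle.
    """
    cx, cy = spec.center
    if (
        cx + spec.r_outer <= 0.0
        or cx - spec.r_outer >= grid.lx
        or cy + spec.r_outer <= 0.0
        or cy - spec.r_outer >= grid.ly
    ):
        raise ValueError(
            f"obstacle {spec.kind!r} centred at {spec.center} with outer radius "
            f"{spec.r_outer} lies entirely outside the {grid.lx} x {grid.ly} domain"
        )
    X, Y = grid.cell_centers()
    dx = X - cx
    dy = Y - cy
    r = np.hypot(dx, dy)
    radial = (r >= spec.r_inner) & (r <= spec.r_outer)
    if not spec.arcs:
        return np.zeros(grid.shape, dtype=bool)
    theta = _wrap_angle(np.arctan2(dy, dx))
    angular = np.zeros(grid.shape, dtype=bool)
    for start, end in spec.arcs:
        span = end - start
        if span <= 0:
            continue
        angular |= _wrap_angle(theta - start) < min(span, _TWO_PI)
    return radial & angular


def build_boundary_control(mask: np.ndarray, grid: Grid) -> BoundaryControl:
    """Build the discrete boundary control function from an obstacle mask.

    ``G = 0`` exactly on masked cells and 1 elsewhere; edge values are the
    product of the two adjacent cell values (integer arithmetic), with the
    outer-rectangle edges fixed at 0 (zero flux).  Pure function of its
    inputs; repeated calls are bit-identical.
    """
    mask = np.asarray(mask)
    if mask.shape != grid.shape:
        raise ValueError(f"mask shape {mask.shape} does not match grid {grid.shape}")
    mask = mask.astype(bool)
    if mask.all():
        warnings.warn(
            "obstacle mask covers every cell: the computational domain is empty",
            stacklevel=2,
        )
    g = (~mask).astype(np.int8)
    ny, nx = grid.shape
    gex = np.zeros((ny, nx + 1), dtype=np.int8)
    gey = np.zeros((ny + 1, nx), dtype=np.int8)
    gex[:, 1:-1] = g[:, :-1] * g[:, 1:]
    gey[1:-1, :] = g[:-1, :] * g[1:, :]
    return BoundaryControl(g_cell=g, g_edge_x=gex, g_edge_y=gey, dirichlet=mask)
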