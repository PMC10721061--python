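"""Zero-contour extraction, curvature profiles, and the curvature-variation
statistic used to select the restored shape.

The statistic is ``D_kappa = integral over the contour of (d kappa / d s)^2 ds``:
zero for a circle (constant curvature) and large when the curvature is
concentrated, e.g. at the junctions between a pinned feature and a freshly
closed gap.  Along a sweep of supplemented areas it decreases as the restored
shape rounds out, and the start of its flat tail marks the smallest
supplement that already yields a circle-like restoration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from skimage import measure

from .grid import Grid

__all__ = [
    "ContourCurve",
    "SweepEntry",
    "SweepResult",
    "extract_zero_contour",
    "resample_uniform",
    "curvature_profile",
    "curvature_variation",
    "select_plateau",
]


@dataclass(frozen=True)
class ContourCurve:
    """Ordered polyline in domain coordinates.

    ``vertices`` has shape (m, 2) with columns (x, y).  For closed curves the
    first vertex is not repeated at the end; adjacency wraps.  After
    :func:`resample_uniform` the spacing ``ds`` is uniform and ``kappa``
    may hold curvature samples aligned with the vertices.
    """

    vertices: np.ndarray
    closed: bool
    ds: float | None = None
    kappa: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must have shape (m, 2)")
        object.__setattr__(self, "vertices", v)

    def __len__(self) -> int:
        return len(self.vertices)

    def segment_lengths(self) -> np.ndarray:
        """Lengths of the polyline segments (wrapping for closed curves)."""
        v = self.vertices
        if self.closed:
            d = np.roll(v, -1, axis=0) - v
        else:
            d = np.diff(v, axis=0)
        return np.hypot(d[:, 0], d[:, 1])

    def arc_length(self) -> float:
        return float(self.segment_lengths().sum())

    def enclosed_area(self) -> float:
        """Absolute shoelace area (open curves are closed off by the chord)."""
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return float(
            0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        )

    def isoperimetric_ratio(self) -> float:
        """Perimeter^2 / (4 pi area); 1 for a circle, > 1 otherwise."""
        a = self.enclosed_area()
        if a == 0:
            return np.inf
        return self.arc_length() ** 2 / (4.0 * np.pi * a)


def extract_zero_contour(phi: np.ndarray, grid: Grid) -> list[ContourCurve]:
    """Marching-squares zero isolines of the field, in domain coordinates.

    Linear interpolation along cell edges; saddle cells are disambiguated by
    the sign of the cell-mean (skimage's default decider).  Curves with fewer
    than 8 vertices are discarded; the result is sorted by descending
    enclosed area.  Raises ``ValueError`` when the field has no sign change.
    """
    phi = np.asarray(phi, dtype=float)
    if phi.min() >= 0.0 or phi.max() <= 0.0:
        raise ValueError("no interface: the field does not change sign")
    h = grid.h
    curves: list[ContourCurve] = []
    for rc in measure.find_contours(phi, 0.0):
        closed = bool(np.allclose(rc[0], rc[-1]))
        if closed:
            rc = rc[:-1]
        if len(rc) < 8:
            continue
        # find_contours returns (row, col) in index space; cell centers sit
        # at (index + 0.5) * h
        xy = np.column_stack(((rc[:, 1] + 0.5) * h, (rc[:, 0] + 0.5) * h))
        curves.append(ContourCurve(xy, closed))
    curves.sort(key=lambda c: c.enclosed_area(), reverse=True)
    return curves


def resample_uniform(curve: ContourCurve, ds: float) -> ContourCurve:
    """Resample the polyline at uniform arc-length spacing ~``ds``.

    For closed curves the parameterization is periodic (the last sample does
    not duplicate the first); for open curves both endpoints are kept.  The
    realized spacing divides the total length exactly and is stored on the
    returned curve.
    """
    if ds <= 0:
        raise ValueError("ds must be positive")
    seg = curve.segment_lengths()
    if np.any(seg == 0):
        raise ValueError("degenerate curve: repeated consecutive vertices")
    total = float(seg.sum())
    v = curve.vertices
    if curve.closed:
        s = np.concatenate(([0.0], np.cumsum(seg)))
        pts = np.vstack([v, v[:1]])
        n = max(int(round(total / ds)), 8)
        s_new = np.linspace(0.0, total, n, endpoint=False)
        step = total / n
    else:
        s = np.concatenate(([0.0], np.cumsum(seg)))
        pts = v
        n = max(int(round(total / ds)) + 1, 8)
        s_new = np.linspace(0.0, total, n)
        step = total / (n - 1)
    x = np.interp(s_new, s, pts[:, 0])
    y = np.interp(s_new, s, pts[:, 1])
    return ContourCurve(np.column_stack([x, y]), curve.closed, ds=step)


def _periodic_gradient(a: np.ndarray, ds: float) -> np.ndarray:
    return (np.roll(a, -1) - np.roll(a, 1)) / (2.0 * ds)


def _periodic_second(a: np.ndarray, ds: float) -> np.ndarray:
    return (np.roll(a, -1) - 2.0 * a + np.roll(a, 1)) / (ds * ds)


def curvature_profile(
    curve: ContourCurve, smooth_window: int = 5, coord_sigma: float = 0.0
) -> ContourCurve:
    """Signed curvature along a uniformly resampled curve.

    Central differences on the uniform parameterization give
    ``kappa = (x' y'' - y' x'') / (x'^2 + y'^2)^{3/2}``, positive for a
    counter-clockwise circle.  ``smooth_window`` > 1 applies a moving
    average of that many samples (periodic wrap for closed curves) to damp
    vertex noise.  ``coord_sigma`` > 0 additionally smooths the *coordinates*
    with a Gaussian of that arc-length bandwidth before differentiating:
    contours extracted from diffuse-interface fields carry sub-grid vertex
    jitter whose third derivative otherwise dominates the curvature-variation
    statistic, so solver contours are scored with ``coord_sigma`` of a few
    grid cells while analytic curves need none.  Returns a copy of the curve
    with ``kappa`` attached.
    """
    if curve.ds is None:
        raise ValueError("curve must be resampled to uniform spacing first")
    v = curve.vertices
    if len(v) < 5:
        raise ValueError("need at least 5 samples for curvature")
    if np.any(curve.segment_lengths() == 0):
        raise ValueError("degenerate curve: repeated consecutive vertices")
    ds = curve.ds
    x, y = v[:, 0], v[:, 1]
    if coord_sigma and coord_sigma > 0:
        from scipy.ndimage import gaussian_filter1d

        mode = "wrap" if curve.closed else "nearest"
        sig = coord_sigma / ds
        x = gaussian_filter1d(x, sig, mode=mode)
        y = gaussian_filter1d(y, sig, mode=mode)
    if curve.closed:
        xp, yp = _periodic_gradient(x, ds), _periodic_gradient(y, ds)
        xpp, ypp = _periodic_second(x, ds), _periodic_second(y, ds)
    else:
        xp, yp = np.gradient(x, ds), np.gradient(y, ds)
        xpp, ypp = np.gradient(xp, ds), np.gradient(yp, ds)
    speed2 = xp * xp + yp * yp
    kappa = (xp * ypp - yp * xpp) / np.maximum(speed2, 1e-300) ** 1.5
    if smooth_window and smooth_window > 1:
        mode = "wrap" if curve.closed else "nearest"
        kappa = uniform_filter1d(kappa, size=smooth_window, mode=mode)
    return replace(curve, kappa=kappa)


def curvature_variation(curve: ContourCurve) -> float:
    """The curvature-variation statistic ``sum (d kappa/d s)^2 ds``.

    Central differences with periodic wrap for closed curves; open curves
    use one-sided differences at the ends and exclude the two terminal
    samples from the quadrature.  Requires a curvature profile (see
    :func:`curvature_profile`) with at least 5 samples.
    """
    if curve.kappa is None:
        kcurve = curvature_profile(curve)
        return curvature_variation(kcurve)
    k = curve.kappa
    if len(k) < 5:
        raise ValueError("need at least 5 curvature samples")
    ds = curve.ds
    if curve.closed:
        dk = _periodic_gradient(k, ds)
        return float(np.sum(dk * dk) * ds)
    dk = np.gradient(k, ds)
    inner = dk[2:-2]
    return float(np.sum(inner * inner) * ds)


@dataclass(frozen=True)
class SweepEntry:
    """One supplemented-area trial of the reconstruction sweep."""

    beta: float
    d_kappa: float
    area: float
    converged: bool
    steps: int
    contour: ContourCurve | None = None
    field: np.ndarray | None = field(default=None, repr=False)


@dataclass(frozen=True)
class SweepResult:
    """Outcome of a beta sweep with plateau-based selection.

    ``selected_beta`` is None when no plateau was found; ``status`` then says
    "no knee found".
    """

    entries: tuple[SweepEntry, ...]
    selected_beta: float | None
    status: str
    rule: str = "plateau"
    threshold: float = 0.5

    @property
    def betas(self) -> np.ndarray:
        return np.array([e.beta for e in self.entries])

    @property
    def d_kappas(self) -> np.ndarray:
        return np.array([e.d_kappa for e in self.entries])

    @property
    def selected(self) -> SweepEntry | None:
        if self.selected_beta is None:
            return None
        for e in self.entries:
            if e.beta == self.selected_beta:
                return e
        return None


def select_plateau(
    betas: Sequence[float], d_kappas: Sequence[float], threshold: float = 0.5
) -> tuple[float | None, str]:
    """Pick the smallest beta at which the curvature-variation curve flattens.

    The selected beta is the first whose relative drop to the next entry,
    ``|D(b_k) - D(b_{k+1})| / D(b_k)``, falls below ``threshold`` — the start
    of the flat tail.  Entries with ``D = 0`` count as already flat.
    Returns ``(beta, status)``; ``(None, "no knee found")`` when the curve is
    still falling at the end of the sweep.
    """
    betas = list(betas)
    d = list(d_kappas)
    if len(betas) < 2:
        raise ValueError("need at least 2 sweep entries to select")
    for k in range(len(betas) - 1):
        if d[k] <= 0.0:
            return betas[k], "selected"
        drop = abs(d[k] - d[k + 1]) / d[k]
        if drop < threshold:
            return betas[k], "selected"
    return None, "no knee found"
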