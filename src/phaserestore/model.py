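"""Model/results interface for the two-step interface restoration pipeline.

:class:`InterfaceRestoration` bundles a damaged-feature mask with the solver
configuration; :meth:`InterfaceRestoration.fit` runs the capture step once,
the conservative reconstruction step for each supplementation level beta,
scores every steady contour with the curvature-variation statistic, and
selects the restored shape.  The returned :class:`RestorationResults` holds
the captured field, the sweep table, and the selection, and renders a
summary table.

The solvers are deterministic (no randomness anywhere in the pipeline), so
two fits from the same configuration are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .allen_cahn import SteadyStateReport, run_capture
from .cahn_hilliard import run_reconstruction
from .curvature import (
    ContourCurve,
    SweepEntry,
    SweepResult,
    curvature_profile,
    curvature_variation,
    extract_zero_contour,
    resample_uniform,
    select_plateau,
)
from .grid import BoundaryControl, Grid, ObstacleSpec, build_boundary_control, rasterize_obstacle
from .initializers import (
    EQUILIBRIUM_PROFILE_SCALE,
    MassBudget,
    SolverParams,
    measure_captured_area,
    reconstruction_initial,
    tanh_circle_field,
)

__all__ = ["InterfaceRestoration", "RestorationResults", "sweep_and_select"]

#: supplementation sweeps of the two worked scenarios: the half-circle sweep
#: brackets the circle-completion point near beta ~ 0.8, the parentheses
#: sweep ends at the completion point near beta ~ 0.4
HALF_CIRCLE_BETAS = (0.2, 0.4, 0.6, 0.8, 1.0, 1.2)
PARENTHESES_BETAS = (0.1, 0.15, 0.2, 0.25, 0.3, 0.4)

_PRESETS = {
    # unit square, ring of radii 0.2/0.24 centred at (0.5, 0.5), seed circle
    # R0 = 0.35; one supplementary disk for the half-circle damage, two for
    # the parentheses damage
    "half_circle": dict(radii=(0.2, 0.24), r0=0.35, n_disks=1),
    "parentheses": dict(radii=(0.2, 0.24), r0=0.35, n_disks=2),
}


class InterfaceRestoration:
    """Curvature-based restoration of a damaged narrow-band feature.

    Parameters
    ----------
    mask : (ny, nx) bool array
        Cells of the known (undamaged) feature; pinned at phi = 1
        throughout.
    grid : Grid
        The lattice the mask lives on.
    seed_center, seed_radius :
        Center and radius of the tanh seed circle whose zero contour must
        cover the feature; defaults to the domain center and 0.35.
    supplement : {"half_circle", "parentheses"}
        Placement recipe for the supplementary mass disks (one disk above
        the mid-height chord, or two disks beyond the top and bottom of the
        ring).
    epsilon : float, optional
        Interface thickness; defaults to the 4-cell heuristic for the grid.
    ac_params, ch_params : SolverParams, optional
        Override the stability-bounded defaults of the two solvers.
    ring_radius : float
        Inner ring radius used by the parentheses disk placement.
    """

    def __init__(
        self,
        mask: np.ndarray,
        grid: Grid,
        *,
        seed_center: tuple[float, float] | None = None,
        seed_radius: float = 0.35,
        supplement: str = "half_circle",
        epsilon: float | None = None,
        ac_params: SolverParams | None = None,
        ch_params: SolverParams | None = None,
        ring_radius: float = 0.2,
        profile_scale: float = EQUILIBRIUM_PROFILE_SCALE,
    ) -> None:
        self.grid = grid
        self.mask = np.asarray(mask, dtype=bool)
        self.bc: BoundaryControl = build_boundary_control(self.mask, grid)
        self.seed_center = (
            (grid.lx / 2.0, grid.ly / 2.0) if seed_center is None else seed_center
        )
        self.seed_radius = seed_radius
        if supplement not in ("half_circle", "parentheses"):
            raise ValueError(f"unknown supplement recipe {supplement!r}")
        self.supplement = supplement
        self.n_disks = 1 if supplement == "half_circle" else 2
        self.ring_radius = ring_radius
        self.profile_scale = profile_scale
        self.ac_params = ac_params or SolverParams.for_allen_cahn(grid, epsilon)
        self.ch_params = ch_params or SolverParams.for_cahn_hilliard(
            grid, epsilon if epsilon is not None else self.ac_params.epsilon
        )

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_spec(
        cls, spec: ObstacleSpec, grid: Grid, **kw
    ) -> "InterfaceRestoration":
        """Build from an analytic obstacle description."""
        return cls(rasterize_obstacle(spec, grid), grid, **kw)

    @classmethod
    def from_preset(cls, name: str, n: int = 128, **kw) -> "InterfaceRestoration":
        """The two worked damage scenarios on the unit square.

        ``half_circle``: lower half of the 0.2/0.24 ring survives;
        ``parentheses``: two lateral 72-degree arcs survive.
        """
        if name not in _PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
        grid = Grid.unit_square(n)
        if name == "half_circle":
            spec = ObstacleSpec.half_annulus()
        else:
            spec = ObstacleSpec.parentheses()
        kw.setdefault("supplement", name)
        kw.setdefault("seed_radius", _PRESETS[name]["r0"])
        return cls.from_spec(spec, grid, **kw)

    # -- pipeline stages ---------------------------------------------------

    def capture(
        self, log: Callable[[str], None] | None = None, log_stride: int = 0
    ) -> tuple[np.ndarray, SteadyStateReport]:
        """Relax the seed circle onto the feature (non-conservative flow).

        Returns the steady captured field psi~ (convex-hull envelope of the
        feature) and the convergence report.
        """
        psi0 = tanh_circle_field(
            self.seed_center,
            self.seed_radius,
            self.ac_params.epsilon,
            self.grid,
            profile_scale=self.profile_scale,
        )
        return run_capture(
            psi0, self.bc, self.ac_params, self.grid, log=log, log_stride=log_stride
        )

    def reconstruct(
        self,
        psi: np.ndarray,
        beta: float,
        v0: float | None = None,
        log: Callable[[str], None] | None = None,
        log_stride: int = 0,
    ) -> tuple[np.ndarray, SteadyStateReport]:
        """Conservative relaxation from the supplemented initial condition."""
        if v0 is None:
            v0 = measure_captured_area(psi, self.grid)
        budget = MassBudget(v0=v0, beta=beta, n_disks=self.n_disks)
        phi0 = reconstruction_initial(
            psi,
            budget,
            self.ch_params.epsilon,
            self.grid,
            recipe=self.supplement,
            ring_radius=self.ring_radius,
            profile_scale=self.profile_scale,
        )
        return run_reconstruction(
            phi0, self.bc, self.ch_params, self.grid, log=log, log_stride=log_stride
        )

    def score_contour(
        self,
        phi: np.ndarray,
        smooth_window: int = 5,
        ds: float | None = None,
        coord_sigma: float | None = None,
    ) -> tuple[float, ContourCurve]:
        """Curvature-variation statistic of the field's principal zero contour.

        Solver contours carry sub-grid marching-squares jitter, so the
        coordinates are smoothed with a Gaussian of bandwidth 4 cells
        (override with ``coord_sigma``, arc-length units) before the
        curvature differences.
        """
        ds = self.grid.h / 2.0 if ds is None else ds
        coord_sigma = 4.0 * self.grid.h if coord_sigma is None else coord_sigma
        curve = extract_zero_contour(phi, self.grid)[0]
        curve = curvature_profile(
            resample_uniform(curve, ds), smooth_window, coord_sigma=coord_sigma
        )
        return curvature_variation(curve), curve

    # -- fit ---------------------------------------------------------------

    def fit(
        self,
        betas: Sequence[float] = (),
        *,
        threshold: float = 0.5,
        smooth_window: int = 5,
        coord_sigma: float | None = None,
        contour_ds: float | None = None,
        keep_fields: bool = True,
        log: Callable[[str], None] | None = None,
        log_stride: int = 0,
    ) -> "RestorationResults":
        """Run capture, the beta sweep, and the plateau selection.

        ``betas`` must be strictly increasing; an empty sequence runs the
        capture step only.  A beta whose reconstruction blows up or fails to
        converge is flagged and excluded from selection.
        """
        betas = [float(b) for b in betas]
        if any(b2 <= b1 for b1, b2 in zip(betas, betas[1:])):
            raise ValueError("betas must be strictly increasing")
        psi, cap_report = self.capture(log=log, log_stride=log_stride)
        v0 = measure_captured_area(psi, self.grid)
        entries: list[SweepEntry] = []
        for beta in betas:
            from .allen_cahn import BlowUpError

            try:
                phi, rep = self.reconstruct(
                    psi, beta, v0=v0, log=log, log_stride=log_stride
                )
                dk, curve = self.score_contour(
                    phi, smooth_window, ds=contour_ds, coord_sigma=coord_sigma
                )
                area = measure_captured_area(phi, self.grid)
                entries.append(
                    SweepEntry(
                        beta=beta,
                        d_kappa=dk,
                        area=area,
                        converged=rep.converged,
                        steps=rep.steps,
                        contour=curve,
                        field=phi if keep_fields else None,
                    )
                )
            except BlowUpError:
                entries.append(
                    SweepEntry(beta, np.nan, np.nan, False, 0, None, None)
                )
        sweep = None
        if entries:
            ok = [e for e in entries if e.converged and np.isfinite(e.d_kappa)]
            if len(ok) >= 2:
                sel, status = select_plateau(
                    [e.beta for e in ok], [e.d_kappa for e in ok], threshold
                )
            else:
                sel, status = None, "too few converged sweep entries"
            sweep = SweepResult(
                entries=tuple(entries),
                selected_beta=sel,
                status=status,
                threshold=threshold,
            )
        return RestorationResults(
            model=self,
            psi=psi,
            capture_report=cap_report,
            v0=v0,
            sweep=sweep,
            smooth_window=smooth_window,
        )


@dataclass
class RestorationResults:
    """Fitted restoration: captured field, sweep table, and selection."""

    model: InterfaceRestoration
    psi: np.ndarray
    capture_report: SteadyStateReport
    v0: float
    sweep: SweepResult | None
    smooth_window: int = 5

    @property
    def selected_beta(self) -> float | None:
        return None if self.sweep is None else self.sweep.selected_beta

    @property
    def selected_contour(self) -> ContourCurve | None:
        if self.sweep is None or self.sweep.selected is None:
            return None
        return self.sweep.selected.contour

    def capture_contour(self) -> ContourCurve:
        """Principal zero contour of the captured field."""
        return extract_zero_contour(self.psi, self.model.grid)[0]

    def to_frame(self) -> pd.DataFrame:
        """The sweep table as a DataFrame (beta, D_kappa, area, steps, converged)."""
        if self.sweep is None:
            return pd.DataFrame(
                columns=["beta", "d_kappa", "area", "steps", "converged"]
            )
        return pd.DataFrame(
            {
                "beta": [e.beta for e in self.sweep.entries],
                "d_kappa": [e.d_kappa for e in self.sweep.entries],
                "area": [e.area for e in self.sweep.entries],
                "steps": [e.steps for e in self.sweep.entries],
                "converged": [e.converged for e in self.sweep.entries],
            }
        )

    def provenance(self) -> dict:
        """All parameters needed to re-run this fit bit-identically."""
        m = self.model
        return {
            "version": __version__,
            "grid": {"nx": m.grid.nx, "ny": m.grid.ny, "lx": m.grid.lx, "ly": m.grid.ly},
            "seed_center": list(m.seed_center),
            "seed_radius": m.seed_radius,
            "supplement": m.supplement,
            "ring_radius": m.ring_radius,
            "profile_scale": m.profile_scale,
            "ac_params": vars(m.ac_params).copy()
            if not hasattr(m.ac_params, "__dataclass_fields__")
            else {k: getattr(m.ac_params, k) for k in m.ac_params.__dataclass_fields__},
            "ch_params": {k: getattr(m.ch_params, k) for k in m.ch_params.__dataclass_fields__},
            "smooth_window": self.smooth_window,
            "threshold": None if self.sweep is None else self.sweep.threshold,
            "capture": {
                "converged": self.capture_report.converged,
                "steps": self.capture_report.steps,
                "final_norm": self.capture_report.final_norm,
            },
            "v0": self.v0,
        }

    def summary(self) -> str:
        """Human-readable report of the fit."""
        m = self.model
        lines = [
            "Interface restoration results",
            "=" * 64,
            f"grid: {m.grid.nx} x {m.grid.ny} on {m.grid.lx:g} x {m.grid.ly:g}"
            f"  (h = {m.grid.h:.5g})",
            f"epsilon: {m.ac_params.epsilon:.5g}"
            f"   supplement recipe: {m.supplement} ({m.n_disks} disk(s))",
            f"capture: {'converged' if self.capture_report.converged else 'NOT converged'}"
            f" in {self.capture_report.steps} steps"
            f" (final diff-norm {self.capture_report.final_norm:.3e})",
            f"captured area V0 = {self.v0:.6f}",
        ]
        if self.sweep is not None:
            lines.append("-" * 64)
            lines.append(f"{'beta':>8} {'D_kappa':>14} {'area':>12} {'steps':>10}  conv")
            for e in self.sweep.entries:
                mark = "  <== selected" if e.beta == self.sweep.selected_beta else ""
                lines.append(
                    f"{e.beta:>8.3f} {e.d_kappa:>14.5g} {e.area:>12.6f}"
                    f" {e.steps:>10d}  {'yes' if e.converged else 'NO'}{mark}"
                )
            lines.append("-" * 64)
            if self.sweep.selected_beta is not None:
                lines.append(
                    f"selected beta = {self.sweep.selected_beta:g}"
                    f" (plateau rule, threshold {self.sweep.threshold:g})"
                )
            else:
                lines.append(f"selection: {self.sweep.status}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Contours of obstacle, capture, and the selected restoration."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        m = self.model
        ax.imshow(
            m.mask,
            origin="lower",
            extent=(0, m.grid.lx, 0, m.grid.ly),
            cmap="Reds",
            alpha=0.4,
        )
        cap = self.capture_contour()
        ax.plot(cap.vertices[:, 0], cap.vertices[:, 1], "k--", label="captured")
        sel = self.selected_contour
        if sel is not None:
            ax.plot(sel.vertices[:, 0], sel.vertices[:, 1], "b-", label="restored")
        ax.set_aspect("equal")
        ax.legend(loc="upper right")
        return ax


def sweep_and_select(
    obstacle: ObstacleSpec | np.ndarray,
    betas: Sequence[float],
    grid: Grid,
    *,
    threshold: float = 0.5,
    **model_kw,
) -> SweepResult:
    """Functional wrapper: capture once, reconstruct per beta, select.

    ``obstacle`` may be an :class:`ObstacleSpec` or a boolean mask.  Requires
    at least 3 increasing beta values.
    """
    if len(betas) < 3:
        raise ValueError("need at least 3 beta values for a sweep")
    if isinstance(obstacle, ObstacleSpec):
        model = InterfaceRestoration.from_spec(obstacle, grid, **model_kw)
    else:
        model = InterfaceRestoration(obstacle, grid, **model_kw)
    res = model.fit(betas, threshold=threshold)
    assert res.sweep is not None
    return res.sweep
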