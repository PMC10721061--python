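"""Compiled inner loops for the explicit relaxation solvers.

The numpy single-step functions in :mod:`phaserestore.allen_cahn` and
:mod:`phaserestore.cahn_hilliard` define the schemes; these kernels run many
steps without temporaries for the long relaxations and are checked against
repeated single steps in the test suite.  ``fastmath`` stays off so the
evaluation order (and hence every run) is deterministic.  When numba is not
importable the drivers fall back to the numpy path.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def deco(fn):
            return fn

        return deco if not (a and callable(a[0])) else a[0]


@njit(cache=True)
def ac_run_kernel(
    phi: np.ndarray,
    g: np.ndarray,
    dirichlet: np.ndarray,
    eps2: float,
    dt: float,
    h2: float,
    tol2: float,
    max_steps: int,
    check_stride: int,
) -> tuple[int, float]:
    """Run Allen-Cahn steps in place until the consecutive-difference
    criterion ``sum(dphi^2) * h^2 < tol^2`` or ``max_steps``.

    Returns ``(steps_taken, final_squared_norm * h^2)``; the caller decides
    convergence.  Ghost reflection at the rectangle: the missing neighbour
    equals the cell itself, so its difference term vanishes.
    """
    ny, nx = phi.shape
    new = np.empty_like(phi)
    steps = 0
    norm2 = 1e300
    while steps < max_steps:
        check = (steps + check_stride) if check_stride > 1 else steps + 1
        # advance one stride; measure the norm on its last step
        for _ in range(check_stride):
            acc = 0.0
            for j in range(ny):
                for i in range(nx):
                    p = phi[j, i]
                    if g[j, i] == 0:
                        new[j, i] = p
                        continue
                    lap = -4.0 * p
                    lap += phi[j, i + 1] if i + 1 < nx else p
                    lap += phi[j, i - 1] if i - 1 >= 0 else p
                    lap += phi[j + 1, i] if j + 1 < ny else p
                    lap += phi[j - 1, i] if j - 1 >= 0 else p
                    v = p + dt * (-(p * p * p - p) / eps2 + lap / h2)
                    new[j, i] = v
            steps += 1
            last = steps == check
            acc = 0.0
            for j in range(ny):
                for i in range(nx):
                    v = new[j, i]
                    if dirichlet[j, i]:
                        v = 1.0
                        new[j, i] = v
                    if last:
                        d = v - phi[j, i]
                        acc += d * d
                    phi[j, i] = v
            if last:
                norm2 = acc * h2
        if not np.isfinite(norm2):
            return steps, norm2
        if norm2 < tol2:
            return steps, norm2
    return steps, norm2


@njit(cache=True)
def ch_run_kernel(
    phi: np.ndarray,
    g: np.ndarray,
    gex: np.ndarray,
    gey: np.ndarray,
    eps2: float,
    dt: float,
    h2: float,
    tol2: float,
    max_steps: int,
    check_stride: int,
) -> tuple[int, float]:
    """Run Cahn-Hilliard steps in place (same stopping contract as
    :func:`ac_run_kernel`).

    The update sums signed edge fluxes ``G_edge * (mu_r - mu_l)``, so mass
    telescopes to roundoff; cells whose edges all carry ``G_edge = 0``
    (obstacle and its rim) are never changed.
    """
    ny, nx = phi.shape
    mu = np.empty_like(phi)
    steps = 0
    norm2 = 1e300
    while steps < max_steps:
        check = (steps + check_stride) if check_stride > 1 else steps + 1
        for _ in range(check_stride):
            for j in range(ny):
                for i in range(nx):
                    p = phi[j, i]
                    if g[j, i] == 0:
                        mu[j, i] = 0.0
                        continue
                    lap = -4.0 * p
                    lap += phi[j, i + 1] if i + 1 < nx else p
                    lap += phi[j, i - 1] if i - 1 >= 0 else p
                    lap += phi[j + 1, i] if j + 1 < ny else p
                    lap += phi[j - 1, i] if j - 1 >= 0 else p
                    mu[j, i] = p * p * p - p - eps2 * lap / h2
            steps += 1
            last = steps == check
            acc = 0.0
            c = dt / h2
            for j in range(ny):
                for i in range(nx):
                    div = 0.0
                    if gex[j, i + 1] != 0:
                        div += mu[j, i + 1] - mu[j, i]
                    if gex[j, i] != 0:
                        div -= mu[j, i] - mu[j, i - 1]
                    if gey[j + 1, i] != 0:
                        div += mu[j + 1, i] - mu[j, i]
                    if gey[j, i] != 0:
                        div -= mu[j, i] - mu[j - 1, i]
                    d = c * div
                    phi[j, i] += d
                    if last:
                        acc += d * d
            if last:
                norm2 = acc * h2
        if not np.isfinite(norm2):
            return steps, norm2
        if norm2 < tol2:
            return steps, norm2
    return steps, norm2
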