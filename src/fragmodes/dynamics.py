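"""Population dynamics of competing clonal life cycles.

The state of a population executing life cycle ``kappa`` is the vector ``x``
of group abundances by size.  Groups of size ``i`` grow by cell division at
rate ``i * b_i``, die spontaneously at rate ``d_i``, die from competition
with groups of size ``j`` at rate ``K_ij * x_j``, and fragment immediately on
reaching ``m + 1`` cells.  The dynamics is

    dx/dt = A x - diag(K x) x,

where ``A`` is the population projection matrix (growth, fragmentation
births, frequency-independent death) and the nonlinear term is the
frequency-dependent competitive death.  Several life cycles sharing a habitat
are described by the block-diagonal composite projection matrix and a tiled
competition matrix; only the competition term couples the subpopulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .lifecycles import FragmentationPattern

__all__ = [
    "ModelParameters",
    "CompositeSystem",
    "projection_matrix",
    "composite_system",
    "rhs",
    "integrate",
    "stationary_state",
    "IntegrationError",
    "ConvergenceError",
]

#: abundances more negative than this are treated as an error, not noise
NEGATIVE_TOL = 1e-12


class IntegrationError(RuntimeError):
    """The ODE solver failed or the trajectory blew up."""


class ConvergenceError(RuntimeError):
    """No stationary state found within the time / iteration caps."""

    def __init__(self, message: str, last_state: np.ndarray | None = None):
        super().__init__(message)
        self.last_state = last_state


@dataclass(frozen=True)
class ModelParameters:
    """Vital rates and competition kernel on group sizes ``1..n``.

    Parameters
    ----------
    b : array, shape (n,)
        Per-cell division rates ``b_i`` (1/time).
    d : array, shape (n,)
        Frequency-independent group death rates ``d_i`` (1/time).
    K : array, shape (n, n)
        Competition kernel: groups of size ``i`` die at rate
        ``K_ij * x_j`` per encounter partner of size ``j``
        (1/(time * abundance)).
    """

    b: np.ndarray
    d: np.ndarray
    K: np.ndarray

    def __init__(self, b, d, K):
        b = np.atleast_1d(np.asarray(b, dtype=float))
        d = np.atleast_1d(np.asarray(d, dtype=float))
        K = np.atleast_2d(np.asarray(K, dtype=float))
        n = b.shape[0]
        if d.shape != (n,) or K.shape != (n, n):
            raise ValueError(
                f"inconsistent dimensions: b {b.shape}, d {d.shape}, K {K.shape}"
            )
        if (b < 0).any() or (d < 0).any() or (K < 0).any():
            raise ValueError("all rates must be nonnegative")
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "K", K)

    @property
    def n(self) -> int:
        return self.b.shape[0]

    def check_covers(self, kappa: FragmentationPattern) -> None:
        if kappa.maturity > self.n:
            raise ValueError(
                f"parameters cover sizes 1..{self.n} but {kappa} matures at "
                f"{kappa.maturity}"
            )


def projection_matrix(
    kappa: FragmentationPattern,
    params: ModelParameters,
    size: int | None = None,
) -> np.ndarray:
    """Population projection matrix ``A`` of a single life cycle.

    Nonzero entries: diagonal ``-i b_i - d_i`` (growth out of size ``i`` and
    spontaneous death), lower subdiagonal ``(i-1) b_{i-1}`` (growth in), and
    the fragmentation column ``m b_m pi_i(kappa)`` added to column ``m``.

    With ``size > m`` the matrix is padded for use as a composite block: the
    extra rows keep their growth/death terms, except that the ``(m+1, m)``
    entry is zero — growth out of size ``m`` feeds fragmentation, never size
    ``m + 1``, so the padded sizes are never populated.
    """
    params.check_covers(kappa)
    m = kappa.maturity
    n = int(size) if size is not None else m
    if n < m:
        raise ValueError(f"size {n} smaller than maturity {m} of {kappa}")
    b, d = params.b, params.d
    A = np.zeros((n, n))
    i = np.arange(1, n + 1)
    A[i - 1, i - 1] = -i * b[:n] - d[:n]
    if n > 1:
        A[i[1:] - 1, i[1:] - 2] = (i[1:] - 1) * b[: n - 1]
    if n > m:
        A[m, m - 1] = 0.0
    A[:, m - 1] += m * b[m - 1] * kappa.offspring_vector(n)
    return A


@dataclass
class CompositeSystem:
    """Composite population of ``r`` life cycles on sizes ``1..n``.

    Flattened state layout: ``x = (x(1), ..., x(r))`` with ``x(j)`` the
    abundance vector of life cycle ``j`` padded to length ``n``.
    """

    lifecycles: tuple[FragmentationPattern, ...]
    params: ModelParameters
    blocks: np.ndarray = field(repr=False)  # (r, n, n)

    @property
    def r(self) -> int:
        return len(self.lifecycles)

    @property
    def n(self) -> int:
        return self.params.n

    @property
    def dim(self) -> int:
        return self.r * self.n

    @property
    def A_tilde(self) -> np.ndarray:
        """Block-diagonal composite projection matrix (rn x rn)."""
        r, n = self.r, self.n
        A = np.zeros((r * n, r * n))
        for j in range(r):
            A[j * n:(j + 1) * n, j * n:(j + 1) * n] = self.blocks[j]
        return A

    @property
    def K_tilde(self) -> np.ndarray:
        """r x r tiling of the competition kernel (rn x rn)."""
        return np.tile(self.params.K, (self.r, self.r))

    def rhs(self, x: np.ndarray) -> np.ndarray:
        """Time derivative ``A~ x - diag(K~ x) x`` (flattened state)."""
        X = np.asarray(x, dtype=float).reshape(self.r, self.n)
        load = self.params.K @ X.sum(axis=0)
        dX = np.einsum("jab,jb->ja", self.blocks, X) - load[None, :] * X
        return dX.reshape(-1)

    def split(self, x: np.ndarray) -> np.ndarray:
        """View the flattened state as an (r, n) array."""
        return np.asarray(x, dtype=float).reshape(self.r, self.n)


def composite_system(
    lifecycles: Sequence[FragmentationPattern],
    params: ModelParameters,
) -> CompositeSystem:
    """Build the composite system for several life cycles.

    The life-cycle list may contain repeats (duplicated subpopulations are
    dynamically neutral and useful as a consistency check).
    """
    lifecycles = tuple(lifecycles)
    if not lifecycles:
        raise ValueError("need at least one life cycle")
    n = params.n
    if max(k.maturity for k in lifecycles) > n:
        raise ValueError("parameters do not cover the largest maturity size")
    blocks = np.stack([projection_matrix(k, params, size=n) for k in lifecycles])
    return CompositeSystem(lifecycles, params, blocks)


def rhs(x: np.ndarray, A: np.ndarray, K: np.ndarray) -> np.ndarray:
    """``A x - diag(K x) x`` for a plain (single-block) system."""
    x = np.asarray(x, dtype=float)
    if x.min(initial=0.0) < -NEGATIVE_TOL:
        raise ValueError(f"negative abundance beyond tolerance: {x.min()}")
    return A @ x - (K @ x) * x


def _clip_negatives(x: np.ndarray) -> np.ndarray:
    if x.min(initial=0.0) < -1e-8 * max(1.0, abs(x).max(initial=1.0)):
        raise IntegrationError(f"trajectory went negative: min {x.min()}")
    return np.maximum(x, 0.0)


def integrate(
    x0: np.ndarray,
    A: np.ndarray,
    K: np.ndarray,
    t_end: float,
    *,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
):
    """Integrate ``dx/dt = A x - diag(K x) x`` from ``x0`` to ``t_end``.

    Returns the scipy solution object with tiny negative abundances clipped.
    """
    x0 = np.asarray(x0, dtype=float)
    if x0.min(initial=0.0) < -NEGATIVE_TOL:
        raise ValueError("initial state has negative abundances")
    sol = solve_ivp(
        lambda t, y: A @ y - (K @ y) * y,
        (0.0, float(t_end)),
        np.maximum(x0, 0.0),
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        jac=lambda t, y: A - np.diag(K @ y) - y[:, None] * K,
    )
    if not sol.success:
        raise IntegrationError(f"solver failed: {sol.message}")
    sol.y = np.apply_along_axis(_clip_negatives, 0, sol.y)
    return sol


def _newton_polish(
    x: np.ndarray, A: np.ndarray, K: np.ndarray, tol: float = 1e-12, maxit: int = 50
) -> np.ndarray:
    """Polish a near-equilibrium state by damped Newton on A x = diag(K x) x."""
    x = x.copy()
    n = x.shape[0]
    scale = max(1.0, abs(x).max())
    res = abs(rhs_raw(x, A, K)).max()
    for _ in range(maxit):
        if res < tol * scale:
            break
        F = rhs_raw(x, A, K)
        J = A - np.diag(K @ x) - x[:, None] * K
        try:
            step = np.linalg.solve(J, F)
        except np.linalg.LinAlgError:
            break
        lam = 1.0
        while lam > 1e-4:
            x_new = x - lam * step
            res_new = abs(rhs_raw(x_new, A, K)).max()
            if res_new < res:
                x, res = x_new, res_new
                break
            lam /= 2
        else:
            break
    return np.where(np.abs(x) < 1e-14, 0.0, x)


def rhs_raw(x: np.ndarray, A: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Like :func:`rhs` but without the negativity guard (internal)."""
    return A @ x - (K @ x) * x


def stationary_state(
    x0: np.ndarray,
    A: np.ndarray,
    K: np.ndarray,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    conv_tol: float = 1e-9,
    t_start: float = 100.0,
    t_cap: float = 1e5,
) -> tuple[np.ndarray, dict]:
    """Integrate to convergence, then Newton-polish the stationary state.

    Convergence: ``||dx/dt||_inf < conv_tol * max(1, ||x||_inf)``, with the
    integration horizon doubling from ``t_start`` up to ``t_cap``.

    Returns ``(x_star, report)``; ``report`` carries the total time
    integrated, the final residual and a ``degenerate`` flag for the empty
    (all-extinct) equilibrium.

    Raises
    ------
    ConvergenceError
        If the criterion is not met by ``t_cap`` (the last state is attached
        to the exception).
    """
    x = np.asarray(x0, dtype=float)
    t_total = 0.0
    horizon = t_start
    converged = False
    while True:
        sol = integrate(x, A, K, horizon, rtol=rtol, atol=atol)
        x = sol.y[:, -1]
        t_total += horizon
        resid = abs(rhs_raw(x, A, K)).max()
        if resid < conv_tol * max(1.0, abs(x).max()):
            converged = True
            break
        if t_total >= t_cap:
            break
        horizon = min(horizon * 2, t_cap - t_total)
    if not converged:
        raise ConvergenceError(
            f"no stationary state by t={t_total:g} (residual {resid:.2e})",
            last_state=x,
        )
    x = _newton_polish(x, A, K)
    x = np.maximum(x, 0.0)
    report = {
        "t_total": t_total,
        "residual": abs(rhs_raw(x, A, K)).max(),
        "degenerate": bool(x.max(initial=0.0) <= 0.0),
    }
    return x, report
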