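"""Vectorized internals for the randomized censuses.

Everything here mirrors the scalar routines in :mod:`fragmodes.dynamics` and
:mod:`fragmodes.invasion` but operates on stacked parameter draws so that a
census of tens of thousands of triplets runs in seconds.  Agreement between
the two routes is asserted in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .lifecycles import FragmentationPattern

#: Newton/validation tolerances for the batched equilibrium solve
_RES_TOL = 1e-10
_STAB_TOL = 1e-7


def batch_projection(
    kappa: FragmentationPattern, b: np.ndarray, d: np.ndarray
) -> np.ndarray:
    """Projection matrices for one life cycle over B parameter draws.

    ``b``, ``d`` have shape ``(B, n)`` with ``n >= m(kappa)``; returns
    ``(B, n, n)`` padded blocks (the ``(m+1, m)`` growth entry zeroed, see
    :func:`fragmodes.dynamics.projection_matrix`).
    """
    B, n = b.shape
    m = kappa.maturity
    A = np.zeros((B, n, n))
    i = np.arange(1, n + 1)
    A[:, i - 1, i - 1] = -i * b - d
    for ii in range(2, n + 1):
        A[:, ii - 1, ii - 2] = (ii - 1) * b[:, ii - 2]
    if n > m:
        A[:, m, m - 1] = 0.0
    pi = kappa.offspring_vector(n)
    A[:, :, m - 1] += m * b[:, m - 1 : m] * pi
    return A


def _leading_eig_batch(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Leading eigenvalue (max real part) and nonnegative eigenvector."""
    vals, vecs = np.linalg.eig(A)
    k = np.argmax(vals.real, axis=1)
    rows = np.arange(A.shape[0])
    lam = vals[rows, k].real
    v = np.abs(vecs[rows, :, k].real)
    s = v.sum(axis=1, keepdims=True)
    v = np.where(s > 0, v / np.where(s > 0, s, 1.0), v)
    return lam, v


def _jacobian_batch(A: np.ndarray, K: np.ndarray, x: np.ndarray) -> np.ndarray:
    Kx = np.einsum("bij,bj->bi", K, x)
    n = A.shape[1]
    return A - Kx[:, :, None] * np.eye(n) - x[:, :, None] * K


def _residual_batch(A: np.ndarray, K: np.ndarray, x: np.ndarray) -> np.ndarray:
    Kx = np.einsum("bij,bj->bi", K, x)
    return np.einsum("bij,bj->bi", A, x) - Kx * x


def batch_equilibria(
    A: np.ndarray, K: np.ndarray, max_newton: int = 80
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Single-life-cycle equilibria for stacked draws.

    Fast path: Newton from the scaled leading eigenvector of ``A``.  Draws
    whose Newton solution fails validation (residual, nonnegativity, local
    stability of the full Jacobian — reducible projection matrices can lead
    Newton to an unstable boundary equilibrium) fall back to batched
    integration-to-convergence followed by a Newton polish.

    Returns ``(x_star, growth_rate, viable, ok)``; non-viable draws get the
    empty equilibrium and ``ok`` reports draws whose equilibrium passed
    validation by either route.
    """
    B, n, _ = A.shape
    lam, v = _leading_eig_batch(A)
    viable = lam > 1e-9
    denom = np.einsum("bi,bi->b", v, np.einsum("bij,bj->bi", K, v) * v)
    safe = denom > 0
    c = np.where(safe & viable, lam * np.einsum("bi,bi->b", v, v)
                 / np.where(safe, denom, 1.0), 0.0)
    x = c[:, None] * v
    active = viable & safe
    for _ in range(max_newton):
        if not active.any():
            break
        idx = np.where(active)[0]
        xa, Aa, Ka = x[idx], A[idx], K[idx]
        F = _residual_batch(Aa, Ka, xa)
        J = _jacobian_batch(Aa, Ka, xa)
        try:
            dx = np.linalg.solve(J, F[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            break
        x[idx] = xa - dx
        res = np.abs(F).max(axis=1)
        done = res < _RES_TOL * np.maximum(1.0, np.abs(xa).max(axis=1))
        active[idx[done]] = False
    ok = _validate(A, K, x) & viable
    # fallback for draws whose fast path failed: integrate toward the basin
    # of the stable equilibrium in short stretches, polishing after each
    fail = viable & ~ok
    if fail.any():
        idx = np.where(fail)[0]
        y = v[idx] + 0.1
        Af, Kf = A[idx], K[idx]
        open_ = np.ones(len(idx), bool)
        t_spent = 0.0
        while open_.any() and t_spent < 5000.0:
            sub = np.where(open_)[0]
            y[sub] = _integrate_chunk(Af[sub], Kf[sub], y[sub], t_chunk=300.0)
            cand = _polish_batch(Af[sub], Kf[sub], y[sub])
            good_now = _validate(Af[sub], Kf[sub], cand)
            x[idx[sub[good_now]]] = cand[good_now]
            open_[sub[good_now]] = False
            t_spent += 300.0
        ok = _validate(A, K, x) & viable
    x[~viable] = 0.0
    np.maximum(x, 0.0, out=x)
    return x, lam, viable, ok


def _validate(A: np.ndarray, K: np.ndarray, x: np.ndarray) -> np.ndarray:
    res = np.abs(_residual_batch(A, K, x)).max(axis=1)
    scale = np.maximum(1.0, np.abs(x).max(axis=1))
    ok = (res < 1e-8 * scale) & (x.min(axis=1) > -1e-9) & (x.max(axis=1) > 1e-12)
    J = _jacobian_batch(A, K, np.maximum(x, 0.0))
    stab = np.linalg.eigvals(J).real.max(axis=1) < _STAB_TOL
    return ok & stab


def _polish_batch(
    A: np.ndarray, K: np.ndarray, x: np.ndarray, iters: int = 40
) -> np.ndarray:
    x = x.copy()
    for _ in range(iters):
        F = _residual_batch(A, K, x)
        if np.abs(F).max(initial=0.0) < _RES_TOL:
            break
        J = _jacobian_batch(A, K, x)
        try:
            dx = np.linalg.solve(J, F[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            break
        # damp: halve steps that would overshoot into large negatives
        x_new = x - dx
        res_new = np.abs(_residual_batch(A, K, x_new)).max(axis=1)
        res_old = np.abs(F).max(axis=1)
        worse = res_new > res_old
        x_new[worse] = x[worse] - 0.5 * dx[worse]
        x = x_new
    return x


def _integrate_chunk(
    A: np.ndarray,
    K: np.ndarray,
    x0: np.ndarray,
    t_chunk: float = 300.0,
    rtol: float = 1e-6,
) -> np.ndarray:
    """Advance a batch of independent single-life-cycle systems by
    ``t_chunk`` time units (used to steer Newton into the stable basin)."""
    B, n = x0.shape

    def f(t, yy):
        X = yy.reshape(B, n)
        dX = np.einsum("bij,bj->bi", A, X) - np.einsum("bij,bj->bi", K, X) * X
        return dX.reshape(-1)

    sol = solve_ivp(
        f, (0.0, t_chunk), x0.reshape(-1), method="RK45", rtol=rtol, atol=1e-12
    )
    return np.maximum(sol.y[:, -1].reshape(B, n), 0.0)


def batch_invasion_eigs(
    kappa_inv: FragmentationPattern,
    b: np.ndarray,
    d: np.ndarray,
    K: np.ndarray,
    x_resident: np.ndarray,
) -> np.ndarray:
    """Leading eigenvalues of ``A(I) - diag(K x(R)*)`` over stacked draws.

    The invasion matrix lives on the invader's own sizes ``1..m(I)``; the
    resident equilibrium enters only through the competition load.
    """
    m = kappa_inv.maturity
    A = batch_projection(kappa_inv, b[:, :m], d[:, :m])
    load = np.einsum("bij,bj->bi", K, x_resident)[:, :m]
    AIR = A - load[:, :, None] * np.eye(m)
    lam = np.linalg.eigvals(AIR)
    return np.max(lam.real, axis=1)
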