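"""Killer and victim competition kernels, and the unicellular-resident
invasion conditions.

Two kernel shapes make the eco-evolutionary dynamics collapse onto a single
optimised trait:

* **killer kernel** ``K_ij = k_j`` — the competitive pressure a group exerts
  depends only on its own (the opponent's) size.  The competition load
  ``(K x)_i = sum_j k_j x_j`` is then the same scalar for every focal size, so
  the stationary state is the leading eigenvector of the projection matrix
  ``A`` and selection reduces to growth-rate competition: the life cycle with
  the largest leading eigenvalue of ``A`` excludes all others.
* **victim kernel** ``K_ij = k_i`` — the load depends only on the focal size:
  ``(K x)_i = k_i N`` with ``N`` the total number of groups.  The stationary
  total ``N*`` equals the leading eigenvalue of the projection matrix built
  with rescaled rates ``b_i' = b_i / k_i``, ``d_i' = d_i / k_i`` (that matrix
  is ``A diag(1/k)``, similar to ``diag(1/k) A``), and selection favours the
  life cycle with the largest carrying capacity ``N*``.

The all-ones kernel is simultaneously killer and victim, so both predictions
must coincide there — a useful consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .dynamics import ModelParameters, projection_matrix
from .invasion import (
    EPS_NEUTRAL,
    InvasionVerdict,
    _leading_eig,
    resident_equilibrium,
)
from .lifecycles import FragmentationPattern

__all__ = [
    "KernelSpec",
    "killer_prediction",
    "victim_carrying_capacity",
    "multicellular_invades_unicellular",
    "unicellular_invades_multicellular",
]

UNICELLULAR = FragmentationPattern((1, 1))


@dataclass(frozen=True)
class KernelSpec:
    """Competition kernel of a special shape.

    ``kind='killer'`` gives ``K_ij = k_j``; ``kind='victim'`` gives
    ``K_ij = k_i``; ``kind='general'`` carries an explicit matrix in ``k``.
    """

    kind: Literal["killer", "victim", "general"]
    k: np.ndarray

    def __init__(self, kind: str, k) -> None:
        k = np.asarray(k, dtype=float)
        if kind in ("killer", "victim"):
            if k.ndim != 1 or (k <= 0).any():
                raise ValueError(f"{kind} kernel needs a positive rate vector")
        elif kind == "general":
            if k.ndim != 2 or k.shape[0] != k.shape[1] or (k < 0).any():
                raise ValueError("general kernel needs a square nonnegative matrix")
        else:
            raise ValueError(f"unknown kernel kind {kind!r}")
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "k", k)

    @property
    def n(self) -> int:
        return self.k.shape[0]

    def matrix(self) -> np.ndarray:
        if self.kind == "killer":
            return np.tile(self.k, (self.n, 1))
        if self.kind == "victim":
            return np.tile(self.k[:, None], (1, self.n))
        return self.k

    def params(self, b, d) -> ModelParameters:
        return ModelParameters(b, d, self.matrix())


def _require(kernel: KernelSpec, kind: str) -> None:
    if kernel.kind != kind:
        raise ValueError(f"expected a {kind} kernel, got {kernel.kind!r}")


def killer_prediction(
    lifecycles: Sequence[FragmentationPattern],
    b,
    d,
    kernel: KernelSpec,
) -> tuple[FragmentationPattern, np.ndarray]:
    """Predicted sole survivor under a killer kernel and its stationary
    composition direction.

    The winner maximises the leading eigenvalue of its projection matrix
    ``A`` (growth competition); its stationary composition is parallel to the
    corresponding leading eigenvector, exactly as in the no-interaction
    model.  The returned composition is the full stationary state: the
    eigenvector scaled so that ``sum_j k_j x_j*`` equals the growth rate.
    """
    _require(kernel, "killer")
    lifecycles = list(lifecycles)
    if not lifecycles:
        raise ValueError("need at least one life cycle")
    best = None
    for kappa in lifecycles:
        m = kappa.maturity
        params = ModelParameters(
            np.asarray(b, float)[:m], np.asarray(d, float)[:m], kernel.matrix()[:m, :m]
        )
        lam, v = _leading_eig(projection_matrix(kappa, params))
        if best is None or lam > best[0]:
            best = (lam, kappa, v)
    lam, winner, v = best
    scale = kernel.k[: winner.maturity] @ v
    x_star = (lam / scale) * v if lam > 0 and scale > 0 else np.zeros_like(v)
    return winner, x_star


def victim_carrying_capacity(
    kappa: FragmentationPattern, b, d, kernel: KernelSpec
) -> float:
    """Stationary total number of groups ``N*`` under a victim kernel.

    ``N*`` is the leading eigenvalue of the projection matrix with rates
    ``b_i' = b_i / k_i`` and ``d_i' = d_i / k_i``; among several life cycles
    the one with the largest ``N*`` excludes the others.
    """
    _require(kernel, "victim")
    m = kappa.maturity
    k = kernel.k[:m]
    b = np.asarray(b, float)[:m] / k
    d = np.asarray(d, float)[:m] / k
    params = ModelParameters(b, d, np.zeros((m, m)))
    lam, _ = _leading_eig(projection_matrix(kappa, params))
    return lam


def multicellular_invades_unicellular(
    kappa_m: FragmentationPattern, params: ModelParameters
) -> InvasionVerdict:
    """Can a multicellular life cycle spread in a unicellular resident?

    Against the unicellular equilibrium ``x1* = (b1 - d1) / K11`` the invader
    grows linearly with its no-competition projection matrix evaluated at
    modified death rates ``d_i' = d_i + x1* K_{i,1}`` — an explicit form of
    the generic invasion eigenvalue.
    """
    b1, d1 = params.b[0], params.d[0]
    if b1 <= d1:
        raise ValueError("unicellular resident is not viable (b1 <= d1)")
    x1 = (b1 - d1) / params.K[0, 0]
    m = kappa_m.maturity
    d_mod = params.d[:m] + x1 * params.K[:m, 0]
    mod = ModelParameters(params.b[:m], d_mod, np.zeros((m, m)))
    lam, _ = _leading_eig(projection_matrix(kappa_m, mod))
    return InvasionVerdict.from_eigenvalue(lam, EPS_NEUTRAL)


def unicellular_invades_multicellular(
    kappa_m: FragmentationPattern, params: ModelParameters
) -> InvasionVerdict:
    """Can the unicellular life cycle spread in a multicellular resident?

    The invasion matrix is 1x1: the rate is
    ``b1 - d1 - sum_i K_{1,i} x_i(M)*`` with ``x(M)*`` the resident
    equilibrium.
    """
    eq = resident_equilibrium(kappa_m, params)
    if not eq.viable:
        raise ValueError(f"resident {kappa_m} is not viable")
    rate = params.b[0] - params.d[0] - params.K[0, :] @ eq.x_star
    return InvasionVerdict.from_eigenvalue(rate, EPS_NEUTRAL)
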