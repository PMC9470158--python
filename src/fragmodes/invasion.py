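"""Invasion from rare: resident equilibria, invasion matrices, and the
classification of pairwise and triplet invasion patterns.

A rare invader executing life cycle ``I`` against a resident ``R`` sitting at
its equilibrium ``x(R)*`` grows linearly with the invasion matrix

    A(I, R) = A(I) - diag(K x(R)*),

whose leading eigenvalue decides the invasion independently of the invader's
initial demography (the matrix is Metzler, so the spectral bound is attained
by a real eigenvalue).  The resident's own invasion matrix ``A(R, R)`` has a
zero eigenvalue with eigenvector ``x(R)*``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .dynamics import (
    ConvergenceError,
    ModelParameters,
    projection_matrix,
    rhs_raw,
    stationary_state,
)
from .lifecycles import FragmentationPattern

__all__ = [
    "EPS_NEUTRAL",
    "InvasionVerdict",
    "ResidentEquilibrium",
    "PairOutcomeKind",
    "PairOutcome",
    "TripletPattern",
    "resident_equilibrium",
    "self_invasion_matrix",
    "invasion_matrix",
    "invasion_rate",
    "pair_outcome",
    "triplet_pattern",
    "classify_pattern",
    "ORDERED_PAIRS",
]

#: eigenvalues within this band of zero are flagged neutral, not classified
EPS_NEUTRAL = 1e-7

#: ordered (invader, resident) index pairs defining the 6-bit pattern code,
#: lexicographic: bit k of the code is invades(ORDERED_PAIRS[k])
ORDERED_PAIRS: tuple[tuple[int, int], ...] = tuple(
    (i, j) for i in range(3) for j in range(3) if i != j
)


@dataclass(frozen=True)
class InvasionVerdict:
    """Sign of the leading eigenvalue of an invasion matrix."""

    leading_eigenvalue: float
    invades: bool
    neutral: bool

    @classmethod
    def from_eigenvalue(cls, lam: float, eps: float = EPS_NEUTRAL):
        return cls(float(lam), bool(lam > eps), bool(abs(lam) <= eps))


@dataclass(frozen=True)
class ResidentEquilibrium:
    """Equilibrium of a life cycle living alone, padded to size ``n``."""

    kappa: FragmentationPattern
    x_star: np.ndarray          # length n (padded with zeros above maturity)
    viable: bool                # leading eigenvalue of A(R) > 0
    converged: bool
    growth_rate: float          # leading eigenvalue of A(R)


def _leading_eig(A: np.ndarray) -> tuple[float, np.ndarray]:
    """Leading (maximal real part) eigenvalue and eigenvector of a Metzler
    matrix; the eigenvalue is asserted real."""
    vals, vecs = np.linalg.eig(A)
    k = int(np.argmax(vals.real))
    lam = vals[k]
    if abs(lam.imag) > 1e-9 * max(1.0, abs(lam.real)):
        raise ValueError(f"leading eigenvalue not real: {lam}")
    v = vecs[:, k].real
    v = np.abs(v)
    s = v.sum()
    return float(lam.real), (v / s if s > 0 else v)


def _check_metzler(A: np.ndarray) -> None:
    off = A - np.diag(np.diag(A))
    if off.min(initial=0.0) < -1e-12:
        raise ValueError("invasion matrix must be Metzler (nonnegative off-diagonals)")


def _equilibrium_newton(
    A: np.ndarray, K: np.ndarray, lam: float, v: np.ndarray
) -> np.ndarray | None:
    """Fast path: damped Newton from the scaled leading eigenvector.

    Returns the equilibrium if Newton converges to a nonnegative, locally
    stable state, else ``None`` (caller falls back to integration).
    """
    n = A.shape[0]
    denom = v @ ((K @ v) * v)
    if denom <= 0:
        return None
    x = (lam * (v @ v) / denom) * v
    res = abs(rhs_raw(x, A, K)).max()
    for _ in range(60):
        if res < 1e-12 * max(1.0, abs(x).max()):
            break
        F = rhs_raw(x, A, K)
        J = A - np.diag(K @ x) - x[:, None] * K
        try:
            step = np.linalg.solve(J, F)
        except np.linalg.LinAlgError:
            return None
        stepped = False
        lam_d = 1.0
        while lam_d > 1e-4:
            x_new = x - lam_d * step
            res_new = abs(rhs_raw(x_new, A, K)).max()
            if res_new < res:
                x, res = x_new, res_new
                stepped = True
                break
            lam_d /= 2
        if not stepped:
            return None
    if res >= 1e-10 * max(1.0, abs(x).max()):
        return None
    if x.min() < -1e-9:
        return None
    x = np.maximum(x, 0.0)
    if x.max(initial=0.0) <= 0.0:
        return None
    J = A - np.diag(K @ x) - x[:, None] * K
    if np.linalg.eigvals(J).real.max() > 1e-7:
        return None  # unstable root (reducible A can mislead Newton)
    return x


def resident_equilibrium(
    kappa: FragmentationPattern, params: ModelParameters
) -> ResidentEquilibrium:
    """Stationary state of ``kappa`` living alone, with viability flag.

    A non-viable resident (leading eigenvalue of ``A`` not positive) decays
    to extinction; it is returned flagged with the empty equilibrium rather
    than raising.
    """
    params.check_covers(kappa)
    m = kappa.maturity
    sub = ModelParameters(params.b[:m], params.d[:m], params.K[:m, :m])
    A = projection_matrix(kappa, sub)
    lam, v = _leading_eig(A)
    n = params.n
    x_full = np.zeros(n)
    if lam <= EPS_NEUTRAL:
        return ResidentEquilibrium(kappa, x_full, False, True, lam)
    x = _equilibrium_newton(A, sub.K, lam, v)
    converged = True
    if x is None:
        try:
            x, _ = stationary_state(0.1 * np.ones(m) + v, A, sub.K)
        except ConvergenceError as err:
            x = np.maximum(err.last_state, 0.0)
            converged = False
    x_full[:m] = x
    return ResidentEquilibrium(kappa, x_full, True, converged, lam)


def self_invasion_matrix(eq: ResidentEquilibrium, params: ModelParameters) -> np.ndarray:
    """``A(R, R) = A(R) - diag(K x(R)*)`` on sizes ``1..m(R)``."""
    m = eq.kappa.maturity
    load = params.K @ eq.x_star
    A = projection_matrix(
        eq.kappa, ModelParameters(params.b[:m], params.d[:m], params.K[:m, :m])
    )
    return A - np.diag(load[:m])


def invasion_matrix(
    kappa_invader: FragmentationPattern,
    x_resident_star: np.ndarray,
    params: ModelParameters,
) -> np.ndarray:
    """``A(I, R) = A(I) - diag(K x(R)*)`` on sizes ``1..m(I)``."""
    params.check_covers(kappa_invader)
    x_star = np.asarray(x_resident_star, dtype=float)
    if x_star.shape != (params.n,):
        raise ValueError(
            f"resident equilibrium must be padded to length {params.n}, "
            f"got shape {x_star.shape}"
        )
    m = kappa_invader.maturity
    sub = ModelParameters(params.b[:m], params.d[:m], params.K[:m, :m])
    A = projection_matrix(kappa_invader, sub)
    load = (params.K @ x_star)[:m]
    return A - np.diag(load)


def invasion_rate(A_IR: np.ndarray, eps: float = EPS_NEUTRAL) -> InvasionVerdict:
    """Verdict from the leading eigenvalue of a Metzler invasion matrix."""
    _check_metzler(A_IR)
    lam, _ = _leading_eig(A_IR)
    return InvasionVerdict.from_eigenvalue(lam, eps)


class PairOutcomeKind(str, Enum):
    DOMINANCE_OF_1 = "dominance_of_1"
    DOMINANCE_OF_2 = "dominance_of_2"
    COEXISTENCE = "coexistence"
    BISTABILITY = "bistability"
    MARGINAL = "marginal"


@dataclass(frozen=True)
class PairOutcome:
    """Cross-invasion classification of a pair of life cycles.

    ``verdict_1_into_2`` is the verdict for life cycle 1 invading resident 2.
    Mapping: (+,-) dominance of 1; (-,+) dominance of 2; (+,+) coexistence;
    (-,-) bistability; any neutral eigenvalue -> marginal.
    """

    kind: PairOutcomeKind
    verdict_1_into_2: InvasionVerdict
    verdict_2_into_1: InvasionVerdict


def pair_outcome(
    kappa1: FragmentationPattern,
    kappa2: FragmentationPattern,
    params: ModelParameters,
) -> PairOutcome:
    eq1 = resident_equilibrium(kappa1, params)
    eq2 = resident_equilibrium(kappa2, params)
    if not (eq1.viable and eq2.viable):
        raise ValueError("pair classification requires both life cycles viable alone")
    v12 = invasion_rate(invasion_matrix(kappa1, eq2.x_star, params))
    v21 = invasion_rate(invasion_matrix(kappa2, eq1.x_star, params))
    if v12.neutral or v21.neutral:
        kind = PairOutcomeKind.MARGINAL
    elif v12.invades and v21.invades:
        kind = PairOutcomeKind.COEXISTENCE
    elif v12.invades:
        kind = PairOutcomeKind.DOMINANCE_OF_1
    elif v21.invades:
        kind = PairOutcomeKind.DOMINANCE_OF_2
    else:
        kind = PairOutcomeKind.BISTABILITY
    return PairOutcome(kind, v12, v21)


class PatternClass(str, Enum):
    HIERARCHICAL = "hierarchical"
    CYCLIC = "cyclic"
    OTHER = "other"


@dataclass(frozen=True)
class TripletPattern:
    """Pairwise invasion pattern of a triplet of life cycles.

    ``invades[k]`` corresponds to ``ORDERED_PAIRS[k]`` (invader, resident
    indices into the triplet); ``code`` packs the six booleans with bit ``k``
    set iff ``invades[k]``.
    """

    invades: tuple[bool, bool, bool, bool, bool, bool]
    eigenvalues: tuple[float, ...] = ()
    flagged: bool = False          # neutral eigenvalue or equilibrium failure

    @property
    def code(self) -> int:
        return sum(1 << k for k, inv in enumerate(self.invades) if inv)

    @classmethod
    def from_code(cls, code: int) -> "TripletPattern":
        if not 0 <= code < 64:
            raise ValueError("pattern code must be in 0..63")
        return cls(tuple(bool((code >> k) & 1) for k in range(6)))

    def invades_pair(self, invader: int, resident: int) -> bool:
        return self.invades[ORDERED_PAIRS.index((invader, resident))]

    @property
    def ess_residents(self) -> tuple[int, ...]:
        """Triplet indices of residents no other member can invade."""
        return tuple(
            j for j in range(3)
            if not any(self.invades_pair(i, j) for i in range(3) if i != j)
        )

    @property
    def ess_count(self) -> int:
        return len(self.ess_residents)

    def dominance(self, i: int, j: int) -> bool:
        """True iff ``i`` strictly dominates ``j`` (invades and resists)."""
        return self.invades_pair(i, j) and not self.invades_pair(j, i)

    @property
    def is_tournament(self) -> bool:
        return all(
            self.dominance(i, j) or self.dominance(j, i)
            for i, j in itertools.combinations(range(3), 2)
        )

    @property
    def is_hierarchical(self) -> bool:
        """Strict total order: every pair decided, relation transitive."""
        if not self.is_tournament:
            return False
        wins = sorted(
            sum(self.dominance(i, j) for j in range(3) if j != i) for i in range(3)
        )
        return wins == [0, 1, 2]

    @property
    def is_cyclic(self) -> bool:
        """Rock-paper-scissors: every pair decided, no transitive order."""
        return self.is_tournament and not self.is_hierarchical


def classify_pattern(pattern: TripletPattern) -> PatternClass:
    if pattern.is_hierarchical:
        return PatternClass.HIERARCHICAL
    if pattern.is_cyclic:
        return PatternClass.CYCLIC
    return PatternClass.OTHER


def triplet_pattern(
    kappa1: FragmentationPattern,
    kappa2: FragmentationPattern,
    kappa3: FragmentationPattern,
    params: ModelParameters,
) -> TripletPattern:
    """Six invasion verdicts for the ordered pairs of a triplet."""
    trio = (kappa1, kappa2, kappa3)
    eqs = [resident_equilibrium(k, params) for k in trio]
    if not all(e.viable for e in eqs):
        raise ValueError("triplet classification requires all residents viable alone")
    flagged = not all(e.converged for e in eqs)
    invades = []
    eigs = []
    for i, j in ORDERED_PAIRS:
        verdict = invasion_rate(invasion_matrix(trio[i], eqs[j].x_star, params))
        invades.append(verdict.invades)
        eigs.append(verdict.leading_eigenvalue)
        flagged = flagged or verdict.neutral
    return TripletPattern(tuple(invades), tuple(eigs), flagged)
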