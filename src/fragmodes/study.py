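"""Randomized parameter censuses over competing life cycles.

Two study designs are implemented:

* :func:`run_multi_lc_study` — the multi-life-cycle outcome census: for each
  randomly drawn parameter set the full composite system of all life cycles
  with maturity up to three is integrated from many random initial conditions
  and the parameter set is classified by the multiset of surviving
  life-cycle sets (single survivor, coexistence, multistability, composites).
* :func:`run_triplet_census` — the pairwise-invasion-pattern census: for each
  draw the three resident equilibria and six invasion eigenvalues of a
  triplet are computed and the resulting 6-bit invasion pattern recorded.

Rates are drawn i.i.d. from the unit-rate exponential distribution.  By
default only the division rates ``b`` and the competition kernel ``K`` are
drawn and spontaneous death rates are zero, which keeps every life cycle
viable on its own; ``sample_death_rates=True`` draws ``d`` from Exp(1) as
well (with death rates most draws contain residents that cannot persist even
alone and are excluded from pattern statistics).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from ._batch import batch_equilibria, batch_invasion_eigs, batch_projection
from .dynamics import ModelParameters, projection_matrix
from .invasion import ORDERED_PAIRS, EPS_NEUTRAL, TripletPattern, classify_pattern
from .lifecycles import (
    FragmentationPattern,
    constrained_triplet_roles,
    enumerate_life_cycles,
)

__all__ = [
    "StudyConfig",
    "DEFAULT_LIFECYCLES",
    "sample_parameters",
    "sample_initial_state",
    "survivor_set",
    "classify_replicates",
    "run_multi_lc_study",
    "run_triplet_census",
    "MultiLCStudyResult",
    "TripletCensusResult",
]

#: the seven life cycles whose groups never exceed three cells
DEFAULT_LIFECYCLES: tuple[FragmentationPattern, ...] = tuple(
    sorted(enumerate_life_cycles(3))
)


def sample_parameters(
    rng: np.random.Generator,
    n_sizes: int,
    sample_death_rates: bool = False,
) -> ModelParameters:
    """Draw one Exp(1) parameter set on sizes ``1..n_sizes``.

    ``b`` and ``K`` are always drawn; ``d`` is zero unless
    ``sample_death_rates``.  Draw order (b, then d if sampled, then K) is
    part of the reproducibility contract.
    """
    if n_sizes < 1:
        raise ValueError("n_sizes must be >= 1")
    b = rng.exponential(1.0, n_sizes)
    d = rng.exponential(1.0, n_sizes) if sample_death_rates else np.zeros(n_sizes)
    K = rng.exponential(1.0, (n_sizes, n_sizes))
    return ModelParameters(b, d, K)


def sample_initial_state(
    rng: np.random.Generator,
    lifecycles: Sequence[FragmentationPattern],
    n_sizes: int | None = None,
) -> np.ndarray:
    """Random initial composite state: every size up to each life cycle's
    maturity gets an i.i.d. Exp(1) abundance, sizes above maturity are zero.

    Returns an ``(r, n)`` array matching the composite state layout.
    """
    lifecycles = list(lifecycles)
    if not lifecycles:
        raise ValueError("need at least one life cycle")
    n = n_sizes or max(k.maturity for k in lifecycles)
    X = rng.exponential(1.0, (len(lifecycles), n))
    for j, kappa in enumerate(lifecycles):
        X[j, kappa.maturity :] = 0.0
    return X


def survivor_set(
    final_state: np.ndarray,
    lifecycles: Sequence[FragmentationPattern],
    threshold: float = 1e-3,
    params: ModelParameters | None = None,
    neutral_tol: float = 1e-3,
    floor: float = 1e-8,
) -> frozenset[FragmentationPattern]:
    """Life cycles that persist in a (converged) final composite state.

    The primary rule is a relative-abundance cut: a life cycle survives if
    its total abundance exceeds ``threshold`` times the total population.

    Constrained triplets admit a continuum of neutrally stable coexistence
    states on which a member's share can be arbitrarily small without the
    member going extinct.  When ``params`` is given, a member below the cut
    (but above ``floor``) is therefore also counted as a survivor if its
    invasion eigenvalue against the final community is not significantly
    negative (> -``neutral_tol``): it is sitting on the neutral manifold,
    not decaying.  Genuinely extinct members fail this test by orders of
    magnitude.
    """
    X = np.asarray(final_state, dtype=float)
    totals = X.sum(axis=1)
    total = totals.sum()
    if total <= 0:
        return frozenset()
    survivors = set()
    load = params.K @ X.sum(axis=0) if params is not None else None
    for j, (kappa, t) in enumerate(zip(lifecycles, totals)):
        if t > threshold * total:
            survivors.add(kappa)
        elif params is not None and t > floor * total:
            m = kappa.maturity
            sub = ModelParameters(params.b[:m], params.d[:m], params.K[:m, :m])
            A = projection_matrix(kappa, sub) - np.diag(load[:m])
            if np.linalg.eigvals(A).real.max() > -neutral_tol:
                survivors.add(kappa)
    return frozenset(survivors)


def classify_replicates(
    survivor_sets: Sequence[frozenset[FragmentationPattern]],
) -> str:
    """Classify a parameter set by its replicate outcomes.

    ``single`` — same lone survivor everywhere; ``coexistence_of_k`` — the
    same k-member set everywhere; ``multistability_between_k`` — every
    replicate a singleton but k distinct singletons occur;
    ``bistability_with_coexisting_pair`` — exactly two outcomes, one a
    singleton and one a pair; anything else ``other_composite``.
    """
    sets = [s for s in survivor_sets if s]
    if len(sets) < 2:
        raise ValueError("need at least 2 replicates with survivors")
    uniq = set(sets)
    if len(uniq) == 1:
        k = len(next(iter(uniq)))
        return "single" if k == 1 else f"coexistence_of_{k}"
    if all(len(s) == 1 for s in uniq):
        return f"multistability_between_{len(uniq)}"
    if len(uniq) == 2 and sorted(len(s) for s in uniq) == [1, 2]:
        return "bistability_with_coexisting_pair"
    return "other_composite"


@dataclass
class StudyConfig:
    """Configuration of the multi-life-cycle outcome census."""

    lifecycles: tuple[FragmentationPattern, ...] = DEFAULT_LIFECYCLES
    n_sets: int = 500
    n_replicates: int = 30
    sample_death_rates: bool = False
    extinction_threshold: float = 1e-3
    seed: int = 0
    # numerics: soft horizon with early stop on convergence, then extension
    # only while some life cycle sits in an ambiguous relative-abundance band
    t_soft: float = 2500.0
    t_hard: float = 12000.0
    t_chunk: float = 250.0
    rtol: float = 1e-5
    conv_tol: float = 1e-8
    clip_rel: float = 1e-9
    ambiguous_band: tuple[float, float] = (1e-6, 0.05)

    def __post_init__(self):
        if self.n_sets < 1 or self.n_replicates < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 < self.extinction_threshold < 0.1:
            raise ValueError("extinction threshold must be in (0, 0.1)")


def _simulate_replicates(
    lifecycles: Sequence[FragmentationPattern],
    params: ModelParameters,
    X0: np.ndarray,
    cfg: StudyConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate ``R`` replicates of the composite system together.

    Returns ``(X_final, resolved)`` with ``X_final`` of shape ``(R, r, n)``.
    A replicate is resolved when its derivative criterion is met or when no
    life cycle's relative abundance lies in the ambiguous band after the
    soft horizon.
    """
    R, r, n = X0.shape
    M = np.stack([projection_matrix(k, params, size=n) for k in lifecycles])
    K = params.K
    active = np.ones(R, bool)
    y = X0.reshape(-1).copy()
    lo, hi = cfg.ambiguous_band

    def f(t, yy):
        X = yy.reshape(R, r, n)
        load = X.sum(axis=1) @ K.T
        dX = np.einsum("jab,rjb->rja", M, X) - load[:, None, :] * X
        dX[~active] = 0.0
        return dX.reshape(-1)

    t = 0.0
    converged = np.zeros(R, bool)
    while active.any() and t < cfg.t_hard:
        sol = solve_ivp(
            f, (t, t + cfg.t_chunk), y, method="RK45", rtol=cfg.rtol, atol=1e-10
        )
        t += cfg.t_chunk
        X = np.maximum(sol.y[:, -1].reshape(R, r, n), 0.0)
        tot_lc = X.sum(axis=2)
        tot_all = np.maximum(tot_lc.sum(axis=1, keepdims=True), 1e-300)
        X[tot_lc < cfg.clip_rel * tot_all] = 0.0
        y = X.reshape(-1)
        dY = np.abs(f(t, y)).reshape(R, -1).max(axis=1)
        scale = np.maximum(1.0, X.reshape(R, -1).max(axis=1))
        converged = dY < cfg.conv_tol * scale
        rel = tot_lc / tot_all
        ambiguous = ((rel > lo) & (rel < hi)).any(axis=1)
        if t >= cfg.t_soft:
            active &= ~converged & ambiguous
        else:
            active &= ~converged
    X = y.reshape(R, r, n)
    resolved = ~active | converged
    return X, resolved


@dataclass
class MultiLCStudyResult:
    config: StudyConfig
    counts: Counter
    n_classified: int
    n_unresolved_sets: int          # sets with an unresolved replicate (kept)
    per_set: list = field(repr=False, default_factory=list)

    def frequencies(self) -> dict[str, float]:
        return {k: v / self.n_classified for k, v in sorted(self.counts.items())}

    def frequency(self, outcome: str) -> float:
        return self.counts.get(outcome, 0) / self.n_classified

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"outcome": k, "count": v, "frequency": v / self.n_classified}
            for k, v in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary_dict(self) -> dict:
        from . import __version__

        cfg = asdict(self.config)
        cfg["lifecycles"] = [str(k) for k in self.config.lifecycles]
        return {
            "fragmodes_version": __version__,
            "config": cfg,
            "n_classified": self.n_classified,
            "n_unresolved_sets": self.n_unresolved_sets,
            "frequencies": self.frequencies(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2)


def run_multi_lc_study(config: StudyConfig) -> MultiLCStudyResult:
    """Outcome census over random Exp(1) parameter sets.

    For each set, ``n_replicates`` random initial conditions of the full
    composite system are integrated to (near-)stationarity and the set is
    classified by its survivor sets.  Unresolved replicates (still ambiguous
    at the hard time cap) are classified as they stand and the set is
    counted in ``n_unresolved_sets``.
    """
    lifecycles = tuple(config.lifecycles)
    n = max(k.maturity for k in lifecycles)
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(config.n_sets)
    counts: Counter = Counter()
    per_set = []
    unresolved_sets = 0
    for s, child in enumerate(children):
        rng = np.random.default_rng(child)
        params = sample_parameters(rng, n, config.sample_death_rates)
        X0 = np.stack(
            [
                sample_initial_state(rng, lifecycles, n)
                for _ in range(config.n_replicates)
            ]
        )
        Xf, resolved = _simulate_replicates(lifecycles, params, X0, config)
        if not resolved.all():
            unresolved_sets += 1
        survivors = [
            survivor_set(
                Xf[i], lifecycles, config.extinction_threshold, params=params
            )
            for i in range(config.n_replicates)
        ]
        label = classify_replicates(survivors)
        counts[label] += 1
        per_set.append({"set": s, "outcome": label, "resolved": bool(resolved.all())})
    return MultiLCStudyResult(
        config=config,
        counts=counts,
        n_classified=sum(counts.values()),
        n_unresolved_sets=unresolved_sets,
        per_set=per_set,
    )


@dataclass
class TripletCensusResult:
    """Invasion-pattern frequencies for one triplet of life cycles."""

    triplet: tuple[FragmentationPattern, ...]
    n_samples: int
    n_classified: int
    n_excluded: int                 # non-viable residents / failed equilibria
    n_neutral: int                  # |eigenvalue| within the neutrality band
    code_counts: Counter
    seed: int
    sample_death_rates: bool
    constrained_middle: FragmentationPattern | None = None

    @property
    def n_distinct_codes(self) -> int:
        return len(self.code_counts)

    def fraction(self, predicate) -> float:
        """Fraction of classified draws whose pattern satisfies a predicate
        on :class:`TripletPattern`."""
        hit = sum(
            c for code, c in self.code_counts.items()
            if predicate(TripletPattern.from_code(code))
        )
        return hit / self.n_classified

    @property
    def hierarchical_fraction(self) -> float:
        return self.fraction(lambda p: p.is_hierarchical)

    @property
    def cyclic_fraction(self) -> float:
        return self.fraction(lambda p: p.is_cyclic)

    def _roles(self) -> tuple[int, int, int]:
        """Indices (c1, c2, m) of the constraining and constrained members."""
        if self.constrained_middle is None:
            raise ValueError("triplet is not constrained")
        m = self.triplet.index(self.constrained_middle)
        c1, c2 = [i for i in range(3) if i != m]
        return c1, c2, m

    @property
    def constraining_bistability_fraction(self) -> float:
        """Draws where neither constraining life cycle invades the other."""
        c1, c2, _ = self._roles()
        return self.fraction(
            lambda p: not p.invades_pair(c1, c2) and not p.invades_pair(c2, c1)
        )

    @property
    def three_way_coexistence_fraction(self) -> float:
        """Draws where the constraining life cycles mutually invade (every
        member of the triplet can then be invaded)."""
        c1, c2, _ = self._roles()
        return self.fraction(
            lambda p: p.invades_pair(c1, c2) and p.invades_pair(c2, c1)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for code in sorted(self.code_counts):
            p = TripletPattern.from_code(code)
            row = {"code": code}
            for k, (i, j) in enumerate(ORDERED_PAIRS):
                row[f"invades_{i+1}_into_{j+1}"] = p.invades[k]
            row["classification"] = classify_pattern(p).value
            row["count"] = self.code_counts[code]
            row["frequency"] = self.code_counts[code] / self.n_classified
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary_dict(self) -> dict:
        from . import __version__

        out = {
            "fragmodes_version": __version__,
            "triplet": [str(k) for k in self.triplet],
            "seed": self.seed,
            "sample_death_rates": self.sample_death_rates,
            "n_samples": self.n_samples,
            "n_classified": self.n_classified,
            "n_excluded": self.n_excluded,
            "n_neutral": self.n_neutral,
            "n_distinct_codes": self.n_distinct_codes,
            "hierarchical_fraction": self.hierarchical_fraction,
            "cyclic_fraction": self.cyclic_fraction,
        }
        if self.constrained_middle is not None:
            out["constrained_middle"] = str(self.constrained_middle)
            out["constraining_bistability_fraction"] = (
                self.constraining_bistability_fraction
            )
            out["three_way_coexistence_fraction"] = (
                self.three_way_coexistence_fraction
            )
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2)


def run_triplet_census(
    triplet: Sequence[FragmentationPattern],
    n_samples: int,
    seed: int = 0,
    *,
    sample_death_rates: bool = False,
    linear_model: bool = False,
    chunk: int = 20000,
    ensure_distinct: int | None = None,
    max_samples: int | None = None,
) -> TripletCensusResult:
    """Pairwise-invasion-pattern census for one triplet.

    For each Exp(1) draw the three single-resident equilibria are solved and
    the six invasion eigenvalues computed; the 6-bit pattern (bit ``k`` set
    iff invader ``i`` spreads in resident ``j`` for the k-th ordered pair,
    lexicographic) is tallied.  ``linear_model=True`` analyses the
    unconstrained-growth model (``K = 0``) instead: there an invader's
    frequency rises iff its growth rate exceeds the resident's, so invasion
    reduces to comparing leading eigenvalues of the projection matrices.

    Draws with a non-viable resident, a failed equilibrium solve, or an
    invasion eigenvalue inside the neutrality band are excluded and counted.

    The rarest patterns can occur at frequencies of 1e-4 and below; with
    ``ensure_distinct`` the census keeps drawing (in ``chunk``-sized batches,
    up to ``max_samples``) until that many distinct patterns have been seen.
    """
    trio = tuple(triplet)
    if len(trio) != 3 or len(set(trio)) != 3:
        raise ValueError("need three distinct life cycles")
    if n_samples < 0:
        raise ValueError("n_samples must be >= 0")
    n = max(k.maturity for k in trio)
    rng = np.random.default_rng(seed)
    code_counts: Counter = Counter()
    n_excluded = 0
    n_neutral = 0
    n_drawn = 0
    target = int(n_samples)
    cap = int(max_samples) if max_samples is not None else target
    while n_drawn < target or (
        ensure_distinct is not None
        and len(code_counts) < ensure_distinct
        and n_drawn < cap
    ):
        bound = target if n_drawn < target else cap
        B = min(chunk, bound - n_drawn)
        n_drawn += B
        b = rng.exponential(1.0, (B, n))
        d = (
            rng.exponential(1.0, (B, n))
            if sample_death_rates
            else np.zeros((B, n))
        )
        K = rng.exponential(1.0, (B, n, n))
        ok = np.ones(B, bool)
        X = {}
        growth = {}
        for kappa in trio:
            m = kappa.maturity
            A = batch_projection(kappa, b[:, :m], d[:, :m])
            if linear_model:
                lam = np.linalg.eigvals(A).real.max(axis=1)
                x = np.zeros((B, m))
                viable = lam > 1e-9
                good = np.ones(B, bool)
            else:
                x, lam, viable, good = batch_equilibria(A, K[:, :m, :m])
            ok &= viable & good
            growth[kappa] = lam
            xp = np.zeros((B, n))
            xp[:, :m] = x
            X[kappa] = xp
        codes = np.zeros(B, dtype=np.int64)
        neutral = np.zeros(B, bool)
        for k, (i, j) in enumerate(ORDERED_PAIRS):
            if linear_model:
                lam_ij = growth[trio[i]] - growth[trio[j]]
            else:
                lam_ij = batch_invasion_eigs(trio[i], b, d, K, X[trio[j]])
            codes |= (lam_ij > EPS_NEUTRAL).astype(np.int64) << k
            neutral |= np.abs(lam_ij) <= EPS_NEUTRAL
        n_excluded += int((~ok).sum())
        n_neutral += int((ok & neutral).sum())
        keep = ok & ~neutral
        vals, cnts = np.unique(codes[keep], return_counts=True)
        for v, c in zip(vals, cnts):
            code_counts[int(v)] += int(c)
    return TripletCensusResult(
        triplet=trio,
        n_samples=n_drawn,
        n_classified=sum(code_counts.values()),
        n_excluded=n_excluded,
        n_neutral=n_neutral,
        code_counts=code_counts,
        seed=int(seed),
        sample_death_rates=sample_death_rates,
        constrained_middle=constrained_triplet_roles(*trio),
    )
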